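"""Coordinate systems shared by every analysis stage.

This module houses the four foundational objects: :class:`GeneticMap`
(piecewise-linear bp <-> cM interpolation per chromosome),
:class:`MarkerSet` (ordered ancestry-informative marker positions),
:class:`AnnotationTrack` (BED-style interval sets, half-open, 0-based) and
:class:`WindowGrid` (non-overlapping window tilings in bp or cM units).

Conventions
-----------
All coordinates are 0-based and intervals are half-open ``[start, end)``.
A marker lying exactly on a window boundary belongs to the right-hand
window.  Genetic maps may contain zero-recombination plateaus; inverse
interpolation returns the leftmost basepair attaining a map position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "MarkerSet",
    "AnnotationTrack",
    "WindowGrid",
    "make_windows",
    "count_annotation_bp",
    "thin_markers",
]

ANNOTATION_CLASSES = ("coding", "conserved", "repeat", "inversion", "custom")


class GeneticMap:
    """Per-chromosome monotone bp <-> cM anchor lists.

    Parameters
    ----------
    anchors : dict
        Mapping ``chromosome -> (positions_bp, positions_cm)`` where both
        arrays are equal-length, positions strictly increasing in bp,
        non-decreasing in cM, and the first anchor is ``(0, 0.0)``.
    """

    def __init__(self, anchors: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=np.int64)
            cm = np.asarray(cm, dtype=np.float64)
            if bp.shape != cm.shape or bp.ndim != 1 or bp.size < 2:
                raise ValueError(f"{chrom}: need >= 2 equal-length anchor arrays")
            if bp[0] != 0 or cm[0] != 0.0:
                raise ValueError(f"{chrom}: first anchor must be (0 bp, 0 cM)")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"{chrom}: anchor bp must be strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"{chrom}: anchor cM must be non-decreasing")
            if np.any(cm < 0):
                raise ValueError(f"{chrom}: cM must be non-negative")
            self._anchors[chrom] = (bp, cm)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._anchors)

    def length_bp(self, chrom: str) -> int:
        return int(self._anchors[chrom][0][-1])

    def length_cm(self, chrom: str) -> float:
        return float(self._anchors[chrom][1][-1])

    def total_length_bp(self) -> int:
        return sum(self.length_bp(c) for c in self.chromosomes)

    def total_length_cm(self) -> float:
        return sum(self.length_cm(c) for c in self.chromosomes)

    def _get(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            return self._anchors[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def interpolate_cm(self, chrom: str, position_bp) -> np.ndarray | float:
        """Piecewise-linear interpolation of bp position(s) to cM.

        Raises for positions outside ``[0, chromosome length]``.
        """
        bp, cm = self._get(chrom)
        pos = np.asarray(position_bp, dtype=np.float64)
        if np.any(pos < 0) or np.any(pos > bp[-1]):
            raise ValueError(
                f"position out of range [0, {bp[-1]}] on chromosome {chrom!r}"
            )
        out = np.interp(pos, bp, cm)
        return float(out) if np.isscalar(position_bp) else out

    def interpolate_bp(self, chrom: str, position_cm) -> np.ndarray | float:
        """Inverse interpolation cM -> bp (leftmost bp on plateaus)."""
        bp, cm = self._get(chrom)
        pos = np.asarray(position_cm, dtype=np.float64)
        if np.any(pos < 0) or np.any(pos > cm[-1] + 1e-12):
            raise ValueError(
                f"map position out of range [0, {cm[-1]}] on chromosome {chrom!r}"
            )
        pos = np.minimum(pos, cm[-1])
        # index of the first anchor with cm >= pos -> leftmost on plateaus
        idx = np.searchsorted(cm, pos, side="left")
        idx = np.clip(idx, 1, len(cm) - 1)
        exact = cm[idx] == pos
        lo, hi = idx - 1, idx
        span_cm = cm[hi] - cm[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(span_cm > 0, (pos - cm[lo]) / np.where(span_cm > 0, span_cm, 1.0), 0.0)
        out = bp[lo] + frac * (bp[hi] - bp[lo])
        out = np.where(exact, bp[idx], out)
        # pos == 0 maps to the first anchor
        out = np.where(pos == 0.0, bp[0], out)
        return float(out) if np.isscalar(position_cm) else out

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GeneticMap":
        anchors = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("pos_bp")
            anchors[str(chrom)] = (
                sub["pos_bp"].to_numpy(np.int64),
                sub["pos_cM"].to_numpy(np.float64),
            )
        return cls(anchors)

    @classmethod
    def read_tsv(cls, path) -> "GeneticMap":
        """Read a tab-delimited map with header columns chrom, pos_bp, pos_cM."""
        df = pd.read_csv(path, sep="\t")
        required = {"chrom", "pos_bp", "pos_cM"}
        if not required.issubset(df.columns):
            raise ValueError(f"genetic map must have columns {sorted(required)}")
        return cls.from_dataframe(df)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for chrom, (bp, cm) in self._anchors.items():
            rows.append(pd.DataFrame({"chrom": chrom, "pos_bp": bp, "pos_cM": cm}))
        return pd.concat(rows, ignore_index=True)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


class MarkerSet:
    """Ordered, per-chromosome-unique marker positions.

    ``df`` has columns ``chrom``, ``pos`` (bp) and optionally ``freq_diff``
    (diagnostic allele-frequency difference).  Row order defines the column
    order of any companion ancestry matrix.
    """

    def __init__(self, df: pd.DataFrame):
        if not {"chrom", "pos"}.issubset(df.columns):
            raise ValueError("marker set needs columns chrom, pos")
        df = df.reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: marker positions must be sorted and unique")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy(np.int64)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice per chromosome (markers grouped by chromosome)."""
        out: dict[str, slice] = {}
        chroms = self.df["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    def cm_positions(self, gmap: GeneticMap) -> np.ndarray:
        """cM position of every marker (within its chromosome)."""
        out = np.empty(len(self), dtype=np.float64)
        for chrom, sl in self.chrom_slices().items():
            out[sl] = gmap.interpolate_cm(chrom, self.pos[sl])
        return out

    @classmethod
    def read_tsv(cls, path) -> "MarkerSet":
        df = pd.read_csv(path, sep="\t")
        return cls(df)

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class AnnotationTrack:
    """Named interval set with a class label per interval (half-open bp)."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "cls"]))

    def __post_init__(self):
        df = self.df
        if len(df) and np.any(df["start"].to_numpy() >= df["end"].to_numpy()):
            raise ValueError("annotation intervals must satisfy start < end")

    def classes(self) -> list[str]:
        return sorted(set(self.df["cls"])) if len(self.df) else []

    def merged(self, cls: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Disjoint sorted (starts, ends) per chromosome for one class."""
        sub = self.df[self.df["cls"] == cls]
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in sub.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy(np.int64)
            ends = grp["end"].to_numpy(np.int64)
            order = np.argsort(starts, kind="stable")
            starts, ends = starts[order], ends[order]
            m_starts, m_ends = [], []
            for s, e in zip(starts, ends):
                if m_ends and s <= m_ends[-1]:
                    m_ends[-1] = max(m_ends[-1], e)
                else:
                    m_starts.append(s)
                    m_ends.append(e)
            out[chrom] = (np.asarray(m_starts, np.int64), np.asarray(m_ends, np.int64))
        return out

    def total_bp(self, cls: str) -> int:
        return int(sum((e - s).sum() for s, e in self.merged(cls).values()))

    @classmethod
    def read_bed(cls, path, default_class: str = "custom") -> "AnnotationTrack":
        """Read BED (3+ columns); class taken from the 4th column if present."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 3:
            raise ValueError("BED needs at least 3 columns")
        out = df.iloc[:, :3].copy()
        out.columns = ["chrom", "start", "end"]
        out["cls"] = df.iloc[:, 3] if df.shape[1] >= 4 else default_class
        return cls(out)

    def write_bed(self, path) -> None:
        self.df[["chrom", "start", "end", "cls"]].to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass
class WindowGrid:
    """Ordered non-overlapping windows tiled left-to-right per chromosome.

    ``df`` columns: chrom, start, end (bp, half-open) and cm_start, cm_end.
    """

    df: pd.DataFrame
    unit: str
    size: float

    def __len__(self) -> int:
        return len(self.df)

    def chrom_slices(self) -> dict[str, slice]:
        out: dict[str, slice] = {}
        chroms = self.df["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    def window_index(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Grid row index of each (chrom, pos) point; -1 if outside the tiling.

        Relies on the windows tiling each chromosome contiguously from 0.
        Positions exactly on a boundary fall in the right-hand window.
        """
        chrom = np.asarray(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.full(len(pos), -1, dtype=np.int64)
        for c, sl in self.chrom_slices().items():
            mask = chrom == c
            if not mask.any():
                continue
            starts = self.df["start"].to_numpy()[sl]
            ends = self.df["end"].to_numpy()[sl]
            idx = np.searchsorted(starts, pos[mask], side="right") - 1
            ok = (idx >= 0) & (pos[mask] < ends[np.clip(idx, 0, len(ends) - 1)])
            res = np.where(ok, idx + sl.start, -1)
            out[mask] = res
        return out


def make_windows(gmap: GeneticMap, unit: str, size: float) -> WindowGrid:
    """Tile every chromosome with non-overlapping windows of ``size``.

    ``unit`` is ``"bp"`` or ``"cM"``.  cM windows are materialized as bp
    intervals by exact inverse interpolation on the piecewise-linear map;
    the last window per chromosome may be short.  Zero-bp-width cM windows
    (map plateaus at a chromosome end) are dropped.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    if unit not in ("bp", "cM"):
        raise ValueError("unit must be 'bp' or 'cM'")
    rows = []
    for chrom in gmap.chromosomes:
        if unit == "bp":
            length = gmap.length_bp(chrom)
            edges = np.arange(0, length, int(size), dtype=np.int64)
            edges = np.append(edges, length)
            cm_edges = gmap.interpolate_cm(chrom, edges)
        else:
            length_cm = gmap.length_cm(chrom)
            n = int(np.ceil(length_cm / size - 1e-12))
            cm_edges = np.minimum(np.arange(n + 1, dtype=np.float64) * size, length_cm)
            edges = np.rint(gmap.interpolate_bp(chrom, cm_edges)).astype(np.int64)
        for i in range(len(edges) - 1):
            if edges[i + 1] <= edges[i]:
                continue
            rows.append(
                (chrom, int(edges[i]), int(edges[i + 1]), float(cm_edges[i]), float(cm_edges[i + 1]))
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "cm_start", "cm_end"])
    return WindowGrid(df=df, unit=unit, size=float(size))


def _coverage_before(starts: np.ndarray, ends: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Total merged-interval bp covered in [0, x) for each x."""
    if len(starts) == 0:
        return np.zeros(len(x), dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(ends - starts)])
    i = np.searchsorted(starts, x, side="right")  # intervals with start < x
    out = cum[np.maximum(i - 1, 0)]
    prev = np.maximum(i - 1, 0)
    partial = np.clip(x - starts[prev], 0, ends[prev] - starts[prev])
    return np.where(i > 0, out + partial, 0)


def count_annotation_bp(track: AnnotationTrack, grid: WindowGrid, cls: str) -> np.ndarray:
    """Per-window basepairs covered by ``cls`` intervals (merged semantics)."""
    if cls not in ANNOTATION_CLASSES and cls not in track.classes():
        if len(track.df) and cls not in set(track.df["cls"]):
            raise KeyError(f"unknown annotation class {cls!r}")
    merged = track.merged(cls)
    out = np.zeros(len(grid), dtype=np.int64)
    for chrom, sl in grid.chrom_slices().items():
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        a = grid.df["start"].to_numpy()[sl]
        b = grid.df["end"].to_numpy()[sl]
        out[sl] = _coverage_before(starts, ends, b) - _coverage_before(starts, ends, a)
    return out


def interval_bp_in_range(track: AnnotationTrack, cls: str, chrom: str, start: int, end: int) -> int:
    """Merged bp of ``cls`` intervals within one [start, end) range."""
    merged = track.merged(cls)
    if chrom not in merged:
        return 0
    starts, ends = merged[chrom]
    cov = _coverage_before(starts, ends, np.asarray([start, end], dtype=np.int64))
    return int(cov[1] - cov[0])


def thin_markers(markers: MarkerSet, min_spacing_bp: int) -> MarkerSet:
    """Greedy left-to-right thinning: keep a marker iff it lies at least
    ``min_spacing_bp`` from the last kept marker on its chromosome.

    A typical default spacing for ancestry-informative sites is 395 bp.
    """
    if min_spacing_bp <= 0:
        raise ValueError("min_spacing_bp must be positive")
    keep = np.zeros(len(markers), dtype=bool)
    pos = markers.pos
    for chrom, sl in markers.chrom_slices().items():
        last = -np.inf
        for i in range(sl.start, sl.stop):
            if pos[i] - last >= min_spacing_bp:
                keep[i] = True
                last = pos[i]
    return MarkerSet(markers.df[keep].reset_index(drop=True))


def thin_indices(pos: np.ndarray, min_spacing: float) -> np.ndarray:
    """Greedy thinning on a sorted position array; returns kept indices."""
    keep = []
    last = -np.inf
    for i, p in enumerate(pos):
        if p - last >= min_spacing:
            keep.append(i)
            last = p
    return np.asarray(keep, dtype=np.int64)
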