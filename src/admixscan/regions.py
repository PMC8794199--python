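"""Minor-parent ancestry desert/island detection and sharing analysis.

The detection workflow: focal ancestry-informative sites beyond the 2.5%
tail seed regions that are expanded to the outermost flanking sites still
beyond the 5% tail; regions are vetted on a 0.05 cM window grid (10% tail,
>= 10 AIMs, > 10 kb windows), merged when closer than 50 kb, length
filtered, and (islands) checked for thinned-vs-unthinned agreement.
Sharing in another population is called from the 0.05 cM window containing
the region midpoint against that population's own 10% tail.  Three null
schemes are provided: value shuffling, block (circular-rotation) shuffling
and per-region matched-window probabilities, plus a bootstrap over the
observed sharing flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calls import AncestryMatrix
from .genome import AnnotationTrack, GeneticMap, WindowGrid, interval_bp_in_range, make_windows
from .winstats import window_mean_ancestry

__all__ = [
    "DetectionConfig",
    "site_quantiles",
    "find_outlier_regions",
    "refine_regions",
    "classify_shared",
    "permutation_null_shuffle",
    "permutation_null_blocks",
    "matched_window_null",
    "bootstrap_observed_counts",
    "audit_regions",
]


@dataclass
class DetectionConfig:
    q_focal: float = 0.025
    q_edge: float = 0.05
    q_window: float = 0.10
    window_size_cm: float = 0.05
    min_aims: int = 10
    min_len: int = 10_000
    merge_dist: int = 50_000
    thinned_diff_max: float = 0.10
    share_quantile: float = 0.10

    def __post_init__(self):
        if not (0 < self.q_focal <= self.q_edge <= self.q_window < 0.5):
            raise ValueError("need 0 < q_focal <= q_edge <= q_window < 0.5")


def site_quantiles(values: np.ndarray, q: float) -> float:
    """Empirical quantile with linear interpolation (type-7 convention)."""
    values = np.asarray(values, dtype=np.float64)
    values = values[np.isfinite(values)]
    return float(np.quantile(values, q))


def _tail_threshold(values: np.ndarray, q: float, kind: str) -> float:
    """Lower-q threshold for deserts, upper-q for islands, on minor ancestry."""
    return site_quantiles(values, q if kind == "desert" else 1.0 - q)


def _beyond(values: np.ndarray, thr: float, kind: str) -> np.ndarray:
    """Tail membership on the minor-ancestry scale (inclusive at the
    threshold, so heavily tied extremes — fixed regions — stay detectable)."""
    return values <= thr if kind == "desert" else values >= thr


def _tail_rule(values: np.ndarray, q: float, kind: str) -> tuple[float, bool]:
    """Threshold plus a degeneracy flag: a (near-)constant vector defines no
    tail at all, so nothing is an outlier against it."""
    vals = np.asarray(values, dtype=np.float64)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0 or np.ptp(vals) == 0:
        return np.nan, True
    return _tail_threshold(vals, q, kind), False


def find_outlier_regions(
    site_ancestry: np.ndarray,
    markers,
    config: DetectionConfig,
    kind: str,
) -> pd.DataFrame:
    """Seed-and-expand scan for raw ancestry outlier regions.

    Every site beyond the ``q_focal`` genome-wide threshold seeds a region
    expanded to the maximal run of contiguous sites beyond the ``q_edge``
    threshold; overlapping expansions coalesce.  Returns one row per
    region with half-open bp bounds spanning the contained sites.
    """
    if kind not in ("desert", "island"):
        raise ValueError("kind must be 'desert' or 'island'")
    anc = np.asarray(site_ancestry, dtype=np.float64)
    thr_focal, degenerate = _tail_rule(anc, config.q_focal, kind)
    thr_edge, _ = _tail_rule(anc, config.q_edge, kind)
    if degenerate:
        return pd.DataFrame(
            columns=["kind", "chrom", "start", "end", "focal_bp", "n_sites", "n_focal"]
        )
    rows = []
    pos = markers.pos
    for chrom, sl in markers.chrom_slices().items():
        a = anc[sl]
        finite = np.isfinite(a)
        focal = finite & _beyond(a, thr_focal, kind)
        edge_ok = finite & _beyond(a, thr_edge, kind)
        if not focal.any():
            continue
        # maximal runs of edge_ok containing >= 1 focal site
        padded = np.concatenate([[False], edge_ok, [False]])
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1])  # exclusive
        for s, e in zip(starts, ends):
            infoc = focal[s:e]
            if not infoc.any():
                continue
            foc_idx = np.flatnonzero(infoc)
            foc_vals = a[s:e][foc_idx]
            pick = int(np.argmin(foc_vals)) if kind == "desert" else int(np.argmax(foc_vals))
            focal_local = s + int(foc_idx[pick])
            p = pos[sl][s:e]
            rows.append(
                (
                    kind,
                    chrom,
                    int(p[0]),
                    int(p[-1]) + 1,
                    int(pos[sl][focal_local]),
                    int(e - s),
                    int(infoc.sum()),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["kind", "chrom", "start", "end", "focal_bp", "n_sites", "n_focal"],
    )


def _window_tail_thresholds(window_anc: np.ndarray, q: float, kind: str) -> float:
    return _tail_threshold(window_anc, q, kind)


def _midpoint_window(
    grid: WindowGrid, chrom: np.ndarray, mid: np.ndarray
) -> np.ndarray:
    idx = grid.window_index(chrom, mid)
    # midpoints past the tiling (rounding at chromosome ends) -> last window
    return idx


def refine_regions(
    raw: pd.DataFrame,
    matrix: AncestryMatrix,
    grid: WindowGrid,
    config: DetectionConfig,
    kind: str,
    thinned_matrix: AncestryMatrix | None = None,
) -> pd.DataFrame:
    """Filter raw regions into final calls.

    Order: (1) midpoint-window checks — the 0.05 cM window containing the
    region midpoint must fall in the ``q_window`` tail of the genome-wide
    window-ancestry distribution, contain at least ``min_aims`` markers and
    exceed ``min_len`` bp; (2) merge regions with gaps under ``merge_dist``;
    (3) drop merged regions shorter than ``min_len``; (4) for islands,
    drop regions whose thinned/unthinned midpoint-window ancestry differs
    by more than ``thinned_diff_max`` (absolute).
    """
    window_anc, n_aims = window_mean_ancestry(matrix, grid)
    thr_window, w_degenerate = _tail_rule(window_anc, config.q_window, kind)
    wstart = grid.df["start"].to_numpy()
    wend = grid.df["end"].to_numpy()

    if thinned_matrix is not None:
        thin_anc, _ = window_mean_ancestry(thinned_matrix, grid)
    else:
        thin_anc = None

    def midpoint_ok(chrom, start, end):
        mid = (start + end) // 2
        w = int(grid.window_index(np.asarray([chrom]), np.asarray([mid]))[0])
        if w < 0:
            return False, w
        if w_degenerate or not np.isfinite(window_anc[w]):
            return False, w
        if not _beyond(np.asarray([window_anc[w]]), thr_window, kind)[0]:
            return False, w
        if n_aims[w] < config.min_aims:
            return False, w
        if wend[w] - wstart[w] <= config.min_len:
            return False, w
        return True, w

    # (1) midpoint-window checks
    passed = []
    for _, r in raw.iterrows():
        ok, w = midpoint_ok(r["chrom"], r["start"], r["end"])
        if ok:
            passed.append(r)
    if not passed:
        return _empty_regions(kind)
    cur = pd.DataFrame(passed).reset_index(drop=True)

    # (2) merge nearby regions on the same chromosome
    merged_rows = []
    for chrom, sub in cur.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cs, ce, nf, ns = None, None, 0, 0
        for _, r in sub.iterrows():
            if cs is None:
                cs, ce, nf, ns = r["start"], r["end"], r["n_focal"], r["n_sites"]
            elif r["start"] - ce < config.merge_dist:
                ce = max(ce, r["end"])
                nf += r["n_focal"]
                ns += r["n_sites"]
            else:
                merged_rows.append((kind, chrom, cs, ce, ns, nf))
                cs, ce, nf, ns = r["start"], r["end"], r["n_focal"], r["n_sites"]
        merged_rows.append((kind, chrom, cs, ce, ns, nf))
    merged = pd.DataFrame(
        merged_rows, columns=["kind", "chrom", "start", "end", "n_sites", "n_focal"]
    )

    # (3) drop short regions
    merged = merged[(merged["end"] - merged["start"]) >= config.min_len].reset_index(drop=True)

    # decorate with midpoint-window info; (4) island thinned filter
    keep = np.ones(len(merged), dtype=bool)
    mid_w = np.full(len(merged), -1, dtype=np.int64)
    mid_anc = np.full(len(merged), np.nan)
    for i, r in merged.iterrows():
        mid = (r["start"] + r["end"]) // 2
        w = int(grid.window_index(np.asarray([r["chrom"]]), np.asarray([mid]))[0])
        mid_w[i] = w
        mid_anc[i] = window_anc[w] if w >= 0 else np.nan
        if kind == "island" and thin_anc is not None and w >= 0:
            if not np.isfinite(thin_anc[w]) or abs(thin_anc[w] - window_anc[w]) > config.thinned_diff_max:
                keep[i] = False
    merged["mid_window"] = mid_w
    merged["mid_window_ancestry"] = mid_anc
    merged["length"] = merged["end"] - merged["start"]
    return merged[keep].reset_index(drop=True)


def _empty_regions(kind: str) -> pd.DataFrame:
    return pd.DataFrame(
        columns=["kind", "chrom", "start", "end", "n_sites", "n_focal",
                 "mid_window", "mid_window_ancestry", "length"]
    )


def detect_regions(
    matrix: AncestryMatrix,
    grid: WindowGrid,
    config: DetectionConfig,
    kind: str,
    thinned_matrix: AncestryMatrix | None = None,
) -> pd.DataFrame:
    """End-to-end detection: seed-and-expand then refine."""
    raw = find_outlier_regions(matrix.site_mean_ancestry(), matrix.markers, config, kind)
    return refine_regions(raw, matrix, grid, config, kind, thinned_matrix=thinned_matrix)


def classify_shared(
    regions: pd.DataFrame,
    other_window_anc: np.ndarray,
    grid: WindowGrid,
    config: DetectionConfig,
    kind: str,
) -> np.ndarray:
    """Shared flag per region: is the other population's 0.05 cM window at
    the region midpoint beyond that population's own share-quantile tail?"""
    other = np.asarray(other_window_anc, dtype=np.float64)
    thr, degenerate = _tail_rule(other, config.share_quantile, kind)
    flags = np.zeros(len(regions), dtype=bool)
    if degenerate:
        return flags
    for i, (_, r) in enumerate(regions.iterrows()):
        mid = (int(r["start"]) + int(r["end"])) // 2
        w = int(grid.window_index(np.asarray([r["chrom"]]), np.asarray([mid]))[0])
        if w >= 0 and np.isfinite(other[w]):
            flags[i] = bool(_beyond(np.asarray([other[w]]), thr, kind)[0])
    return flags


def _region_mid_windows(regions: pd.DataFrame, grid: WindowGrid) -> np.ndarray:
    mids = ((regions["start"].to_numpy() + regions["end"].to_numpy()) // 2).astype(np.int64)
    return grid.window_index(regions["chrom"].to_numpy(), mids)


def _count_shared(values: np.ndarray, widx: np.ndarray, thr: float, kind: str) -> int:
    if not np.isfinite(thr):
        return 0
    ok = widx >= 0
    v = values[widx[ok]]
    fin = np.isfinite(v)
    return int(_beyond(v[fin], thr, kind).sum())


def _empirical_p(null: np.ndarray, observed: int, rng=None, randomized: bool = False) -> float:
    if randomized:
        u = (np.random.default_rng() if rng is None else rng).random()
        return float((np.sum(null > observed) + u * (1 + np.sum(null == observed))) / (len(null) + 1))
    return float((1 + np.sum(null >= observed)) / (len(null) + 1))


def permutation_null_shuffle(
    regions: pd.DataFrame,
    other_window_anc: np.ndarray,
    grid: WindowGrid,
    config: DetectionConfig,
    kind: str,
    n_perm: int = 1000,
    seed: int | None = None,
    randomized: bool = False,
) -> dict:
    """Value-shuffle permutation null for the shared-region count.

    Each replicate permutes the other population's window ancestries
    uniformly at random among windows with finite values and recounts
    regions whose midpoint window is a share-quantile outlier.  Returns
    observed count, the null counts, and the +1-corrected empirical p
    (optionally the randomized-tie variant, exactly uniform under the null).
    """
    rng = np.random.default_rng(seed)
    other = np.asarray(other_window_anc, dtype=np.float64)
    thr, _ = _tail_rule(other, config.share_quantile, kind)
    widx = _region_mid_windows(regions, grid)
    observed = _count_shared(other, widx, thr, kind)
    finite_idx = np.flatnonzero(np.isfinite(other))
    vals = other[finite_idx]
    null = np.zeros(n_perm, dtype=np.int64)
    perm = other.copy()
    for r in range(n_perm):
        perm[finite_idx] = vals[rng.permutation(len(vals))]
        null[r] = _count_shared(perm, widx, thr, kind)
    return {
        "observed": observed,
        "null": null,
        "pvalue": _empirical_p(null, observed, rng=rng, randomized=randomized),
    }


def permutation_null_blocks(
    regions: pd.DataFrame,
    other_window_anc: np.ndarray,
    grid: WindowGrid,
    config: DetectionConfig,
    kind: str,
    offsets: np.ndarray | None = None,
    n_offsets: int = 130,
    randomized: bool = False,
    seed: int | None = None,
) -> dict:
    """Block-preserving null: circular rotations of the window-ancestry vector.

    Default offsets tile the genome with ``n_offsets`` evenly spaced
    rotations (offset 0 excluded; rotation by 0 reproduces the observed
    count).  Counting and p as in :func:`permutation_null_shuffle`.
    """
    other = np.asarray(other_window_anc, dtype=np.float64)
    nw = len(other)
    if offsets is None:
        offsets = np.unique((np.arange(1, n_offsets + 1) * nw // (n_offsets + 1)) % nw)
        offsets = offsets[offsets > 0]
    offsets = np.asarray(offsets, dtype=np.int64)
    thr, _ = _tail_rule(other, config.share_quantile, kind)
    widx = _region_mid_windows(regions, grid)
    observed = _count_shared(other, widx, thr, kind)
    null = np.zeros(len(offsets), dtype=np.int64)
    for i, off in enumerate(offsets):
        null[i] = _count_shared(np.roll(other, int(off)), widx, thr, kind)
    rng = np.random.default_rng(seed)
    return {
        "observed": observed,
        "null": null,
        "offsets": offsets,
        "pvalue": _empirical_p(null, observed, rng=rng, randomized=randomized),
    }


def matched_window_null(
    region: pd.Series,
    other_matrix: AncestryMatrix,
    gmap: GeneticMap,
    coding_track: AnnotationTrack,
    config: DetectionConfig,
    tolerance_bp: float,
    kind: str,
) -> float:
    """Chance probability that a window matched to the region (same cM
    length, similar coding bp) is a share-quantile ancestry outlier in the
    other population.

    The candidate set is a fresh genome tiling at the region's cM length;
    the ancestry threshold comes from all candidate windows, the
    probability is the outlier fraction among coding-matched candidates.
    """
    chrom = region["chrom"]
    start, end = int(region["start"]), int(region["end"])
    region_cm = float(
        gmap.interpolate_cm(chrom, min(end, gmap.length_bp(chrom)))
        - gmap.interpolate_cm(chrom, start)
    )
    region_cm = max(region_cm, 1e-6)
    grid = make_windows(gmap, "cM", region_cm)
    anc, _ = window_mean_ancestry(other_matrix, grid)
    coding = np.asarray(
        [
            interval_bp_in_range(coding_track, "coding", c, s, e)
            for c, s, e in zip(grid.df["chrom"], grid.df["start"], grid.df["end"])
        ],
        dtype=np.float64,
    )
    region_coding = interval_bp_in_range(coding_track, "coding", chrom, start, end)
    finite = np.isfinite(anc)
    thr, degenerate = _tail_rule(anc, config.share_quantile, kind)
    cand = finite & (np.abs(coding - region_coding) <= tolerance_bp)
    if not cand.any():
        return np.nan
    if degenerate:
        return 0.0
    return float(_beyond(anc[cand], thr, kind).mean())


def bootstrap_observed_counts(
    shared_flags: np.ndarray, n_boot: int = 1000, seed: int | None = None
) -> np.ndarray:
    """Distribution of shared counts under resampling regions with replacement."""
    rng = np.random.default_rng(seed)
    flags = np.asarray(shared_flags, dtype=bool)
    n = len(flags)
    if n == 0:
        return np.zeros(n_boot, dtype=np.int64)
    idx = rng.integers(0, n, size=(n_boot, n))
    return flags[idx].sum(axis=1)


def audit_regions(
    regions: pd.DataFrame,
    matrix: AncestryMatrix,
    grid: WindowGrid,
    config: DetectionConfig,
    kind: str,
) -> bool:
    """Post-hoc check of the predicates guaranteed for every emitted region.

    Regions must be at least ``min_len`` long, contain at least one focal
    site, have well-ordered bounds, gaps between same-chromosome regions of
    at least ``merge_dist`` (otherwise they would have merged), and a
    resolvable midpoint window.  The q_window ancestry check applies to
    the pre-merge components, so it is not re-audited on merged spans.
    """
    if len(regions) == 0:
        return True
    lengths = regions["end"].to_numpy() - regions["start"].to_numpy()
    if np.any(lengths < config.min_len):
        return False
    if np.any(regions["start"].to_numpy() >= regions["end"].to_numpy()):
        return False
    if np.any(regions["n_focal"].to_numpy() < 1):
        return False
    widx = _region_mid_windows(regions, grid)
    if np.any(widx < 0):
        return False
    for _, sub in regions.groupby("chrom", sort=False):
        s = sub.sort_values("start")
        gaps = s["start"].to_numpy()[1:] - s["end"].to_numpy()[:-1]
        if np.any(gaps < config.merge_dist):
            return False
    return True
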