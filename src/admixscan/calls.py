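"""Post-HMM ancestry-call processing.

Hard-calling at a posterior threshold, site masking by missingness, exact
Hardy-Weinberg marker filtering, ancestry-transition interval detection,
tract-length computation and short-tract masking.

Boundary rules are inclusive throughout: a posterior of exactly 0.9 is
assigned, a marker present in exactly 25% of individuals is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genome import GeneticMap, MarkerSet

__all__ = [
    "AncestryMatrix",
    "hard_call",
    "mask_sites",
    "hwe_exact_test",
    "hwe_filter",
    "detect_transitions",
    "tract_lengths",
    "mask_short_tracts",
]

MISSING = -1


@dataclass
class AncestryMatrix:
    """Individuals x markers diploid minor-parent dosages.

    ``dosage`` holds values in {0, 1, 2} with -1 for missing; an optional
    companion ``posteriors`` array of shape (n, m, 3) carries the per-site
    3-state posteriors the dosages were called from.
    """

    dosage: np.ndarray
    markers: MarkerSet
    posteriors: np.ndarray | None = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x markers)")
        if self.dosage.shape[1] != len(self.markers):
            raise ValueError("dosage columns must match the marker set")
        vals = np.unique(self.dosage)
        if not np.isin(vals, [-1, 0, 1, 2]).all():
            raise ValueError("dosages must lie in {0, 1, 2} or -1 for missing")
        if self.posteriors is not None:
            p = np.asarray(self.posteriors, dtype=np.float64)
            if p.shape != (*self.dosage.shape, 3):
                raise ValueError("posteriors must have shape (n, m, 3)")
            if not np.allclose(p.sum(axis=2), 1.0, atol=1e-9):
                raise ValueError("posterior triples must sum to 1")
            self.posteriors = p

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def present(self) -> np.ndarray:
        return self.dosage >= 0

    def present_fraction(self) -> np.ndarray:
        """Per-marker fraction of individuals with a call."""
        return self.present().mean(axis=0)

    def site_mean_ancestry(self) -> np.ndarray:
        """Per-marker mean minor ancestry (dosage/2) over called individuals."""
        present = self.present()
        d = np.where(present, self.dosage, 0).astype(np.float64)
        n = present.sum(axis=0)
        with np.errstate(invalid="ignore"):
            out = d.sum(axis=0) / (2.0 * n)
        out[n == 0] = np.nan
        return out

    def hybrid_index(self) -> np.ndarray:
        present = self.present()
        d = np.where(present, self.dosage, 0).astype(np.float64)
        n = present.sum(axis=1)
        with np.errstate(invalid="ignore"):
            out = d.sum(axis=1) / (2.0 * n)
        out[n == 0] = np.nan
        return out

    def select_markers(self, keep: np.ndarray) -> "AncestryMatrix":
        """Subset to a boolean or index array of markers."""
        post = self.posteriors[:, keep, :] if self.posteriors is not None else None
        return AncestryMatrix(
            dosage=self.dosage[:, keep],
            markers=MarkerSet(self.markers.df[keep].reset_index(drop=True))
            if np.asarray(keep).dtype == bool
            else MarkerSet(self.markers.df.iloc[keep].reset_index(drop=True)),
            posteriors=post,
        )

    # -- tab-delimited interchange -------------------------------------
    def write_tsv(self, path) -> None:
        cols = [f"{c}:{p}" for c, p in zip(self.markers.chrom, self.markers.pos)]
        df = pd.DataFrame(self.dosage, columns=cols).astype("object")
        df = df.mask(self.dosage < 0, "NA")
        df.insert(0, "individual", np.arange(self.n_individuals))
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "AncestryMatrix":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        df = df.drop(columns=["individual"], errors="ignore")
        chroms, poss = zip(*(c.rsplit(":", 1) for c in df.columns))
        markers = MarkerSet(pd.DataFrame({"chrom": chroms, "pos": [int(p) for p in poss]}))
        dosage = df.to_numpy(dtype=np.float64)
        dosage = np.where(np.isnan(dosage), MISSING, dosage).astype(np.int8)
        return cls(dosage=dosage, markers=markers)


def hard_call(
    posteriors: np.ndarray, markers: MarkerSet, threshold: float = 0.9
) -> AncestryMatrix:
    """Assign the state whose posterior is >= threshold, else missing."""
    if threshold <= 1.0 / 3.0:
        raise ValueError("threshold must exceed 1/3 for an unambiguous arg-max")
    p = np.asarray(posteriors, dtype=np.float64)
    best = p.argmax(axis=2)
    conf = p.max(axis=2) >= threshold
    dosage = np.where(conf, best, MISSING).astype(np.int8)
    return AncestryMatrix(dosage=dosage, markers=markers, posteriors=p)


def mask_sites(matrix: AncestryMatrix, min_present_fraction: float = 0.25) -> AncestryMatrix:
    """Drop markers with a present fraction strictly below the threshold."""
    keep = matrix.present_fraction() >= min_present_fraction
    return matrix.select_markers(keep)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional (Levene-Haldane) Hardy-Weinberg test p-value.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one.  Monomorphic markers return p = 1.
    """
    n = n_hom_ref + n_het + n_hom_alt
    na = 2 * n_hom_alt + n_het  # minor allele count
    if n == 0 or na == 0 or na == 2 * n:
        return 1.0
    rare = min(na, 2 * n - na)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(h | n, rare) up to a constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln((rare - hets) / 2 + 1)
        - gammaln(n - (rare + hets) / 2 + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = np.flatnonzero(hets == n_het)
    if obs.size == 0:
        raise ValueError("heterozygote count incompatible with allele counts")
    p_obs = p[obs[0]]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def hwe_filter(
    matrix: AncestryMatrix,
    alpha: float = 0.1,
    min_called: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni-corrected exact HWE marker filter.

    Returns ``(keep, pvalues)``: a marker is removed iff its exact HWE
    p-value is below ``alpha / n_markers``.  Markers called in fewer than
    ``min_called`` individuals are retained untested (p = NaN).
    """
    d = matrix.dosage
    counts = np.stack([(d == k).sum(axis=0) for k in (0, 1, 2)], axis=1)
    m = matrix.n_markers
    pvals = np.full(m, np.nan)
    keep = np.ones(m, dtype=bool)
    cutoff = alpha / m
    cache: dict[tuple[int, int, int], float] = {}
    for j in range(m):
        c = (int(counts[j, 0]), int(counts[j, 1]), int(counts[j, 2]))
        if sum(c) < min_called:
            continue
        if c not in cache:
            cache[c] = hwe_exact_test(*c)
        pvals[j] = cache[c]
        if pvals[j] < cutoff:
            keep[j] = False
    return keep, pvals


def detect_transitions(matrix: AncestryMatrix) -> pd.DataFrame:
    """Ancestry-transition intervals per individual per chromosome.

    Scans confident (non-missing) sites in marker order; every change of
    state emits an interval whose endpoints are the flanking confident
    sites.  Missing sites never terminate the scan; they are skipped.
    """
    rows = []
    pos = matrix.markers.pos
    for chrom, sl in matrix.markers.chrom_slices().items():
        d = matrix.dosage[:, sl]
        p = pos[sl]
        for i in range(matrix.n_individuals):
            conf = np.flatnonzero(d[i] >= 0)
            if conf.size < 2:
                continue
            states = d[i, conf]
            change = np.flatnonzero(np.diff(states) != 0)
            for c in change:
                rows.append(
                    (i, chrom, int(p[conf[c]]), int(p[conf[c + 1]]),
                     int(states[c]), int(states[c + 1]))
                )
    return pd.DataFrame(
        rows, columns=["individual", "chrom", "left_bp", "right_bp", "state_from", "state_to"]
    )


def _runs_with_bounds(dosage_row: np.ndarray, cm: np.ndarray):
    """Maximal constant non-missing dosage runs with midpoint cM bounds.

    Missing entries terminate runs.  Yields (start_idx, end_idx inclusive,
    dosage, start_cm, end_cm).
    """
    n = len(dosage_row)
    i = 0
    while i < n:
        if dosage_row[i] < 0:
            i += 1
            continue
        j = i
        while j + 1 < n and dosage_row[j + 1] == dosage_row[i]:
            j += 1
        start_cm = cm[i] if i == 0 else (cm[i - 1] + cm[i]) / 2.0
        end_cm = cm[j] if j == n - 1 else (cm[j] + cm[j + 1]) / 2.0
        yield i, j, int(dosage_row[i]), float(start_cm), float(end_cm)
        i = j + 1


def tract_lengths(matrix: AncestryMatrix, gmap: GeneticMap) -> pd.DataFrame:
    """Per-tract cM lengths by ancestry class over all individuals.

    A tract is a maximal run of identical non-missing diploid dosage; runs
    with dosage > 0 belong to the minor class, dosage 0 to the major class.
    Run boundaries fall midway between flanking markers.
    """
    cm = matrix.markers.cm_positions(gmap)
    rows = []
    for chrom, sl in matrix.markers.chrom_slices().items():
        c = cm[sl]
        d = matrix.dosage[:, sl]
        for i in range(matrix.n_individuals):
            for _, _, dos, s, e in _runs_with_bounds(d[i], c):
                rows.append((i, chrom, dos, "minor" if dos > 0 else "major", s, e, e - s))
    return pd.DataFrame(
        rows,
        columns=["individual", "chrom", "dosage", "ancestry", "start_cm", "end_cm", "length_cm"],
    )


def mask_short_tracts(
    matrix: AncestryMatrix,
    gmap: GeneticMap,
    min_minor_cm: float = 0.004,
    min_major_cm: float = 0.035,
) -> AncestryMatrix:
    """Set dosage runs shorter than their class threshold to missing."""
    cm = matrix.markers.cm_positions(gmap)
    dosage = matrix.dosage.copy()
    for chrom, sl in matrix.markers.chrom_slices().items():
        c = cm[sl]
        d = matrix.dosage[:, sl]
        for i in range(matrix.n_individuals):
            for a, b, dos, s, e in _runs_with_bounds(d[i], c):
                thr = min_minor_cm if dos > 0 else min_major_cm
                if e - s < thr:
                    dosage[i, sl.start + a : sl.start + b + 1] = MISSING
    return replace(matrix, dosage=dosage)
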