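"""F2-cross analytics: segregation-distortion scan, viability-selection
rejection simulation, and the two-locus incompatibility chi-square scan
with a simulation-based genome-wide false-positive threshold."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneticMap, thin_indices
from .simulate import F2Panel

__all__ = [
    "exact_binom_two_sided",
    "segdist_scan",
    "viability_selection_expectation",
    "segdist_selection_abc",
    "DistortionFit",
    "two_locus_expected",
    "two_locus_chisq",
    "TwoLocusResult",
    "incompatibility_scan",
    "scan_fpr_threshold",
]


def exact_binom_two_sided(k, n, p0: float = 0.5):
    """Exact two-sided binomial p by minimum-likelihood summation.

    Sums the probabilities of all outcomes whose pmf does not exceed the
    observed outcome's pmf.  Vectorized fast path for p0 = 0.5 (where the
    rule reduces to 2 * CDF(min(k, n - k)), capped at 1).
    """
    k = np.asarray(k, dtype=np.int64)
    scalar = k.ndim == 0
    k = np.atleast_1d(k)
    if p0 == 0.5:
        m = np.minimum(k, n - k)
        p = np.minimum(1.0, 2.0 * stats.binom.cdf(m, n, 0.5))
        p = np.where(2 * m == n, 1.0, p)
    else:
        pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
        p = np.array([pmf[pmf <= pmf[ki] * (1 + 1e-12)].sum() for ki in k])
        p = np.minimum(p, 1.0)
    return float(p[0]) if scalar else p


def segdist_scan(
    panel: F2Panel,
    thin_spacing_bp: int = 50_000,
    alpha: float = 5e-4,
) -> pd.DataFrame:
    """Per-marker exact binomial test of minor-allele counts against 0.5.

    Markers are thinned to one per ``thin_spacing_bp``; markers with
    p < alpha are flagged and contiguous flagged runs are reported via the
    ``region`` column (consecutive integers label one region, -1 = not
    flagged).
    """
    if panel.n_individuals == 0:
        raise ValueError("empty panel")
    keep_rows = []
    for chrom, sl in panel.markers.chrom_slices().items():
        idx = thin_indices(panel.markers.pos[sl], thin_spacing_bp)
        keep_rows.append(idx + sl.start)
    keep = np.concatenate(keep_rows)
    g = panel.genotypes[:, keep]
    present = g >= 0
    kminor = np.where(present, g, 0).sum(axis=0).astype(np.int64)
    nallele = 2 * present.sum(axis=0).astype(np.int64)
    pvals = np.ones(len(keep))
    for nv in np.unique(nallele):
        m = nallele == nv
        if nv == 0:
            continue
        pvals[m] = exact_binom_two_sided(kminor[m], int(nv))
    flagged = pvals < alpha
    region = np.full(len(keep), -1, dtype=np.int64)
    rid = 0
    chroms = panel.markers.chrom[keep]
    for j in range(len(keep)):
        if not flagged[j]:
            continue
        if j > 0 and flagged[j - 1] and chroms[j] == chroms[j - 1]:
            region[j] = region[j - 1]
        else:
            region[j] = rid
            rid += 1
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": panel.markers.pos[keep],
            "marker": keep,
            "k_minor": kminor,
            "n_alleles": nallele,
            "pvalue": pvals,
            "flagged": flagged,
            "region": region,
        }
    )


def viability_selection_expectation(s: float, h: float) -> tuple[np.ndarray, float]:
    """Post-selection F2 genotype fractions and disfavored-allele frequency.

    Survival is 1-s for the disfavored homozygote, 1-hs for heterozygotes
    and 1 otherwise, applied to the Mendelian (0.25, 0.5, 0.25) expectation
    and renormalized.  Fractions are ordered (disfavored hom, het, other
    hom); the frequency is of the disfavored allele.
    """
    if not (0.0 <= s <= 1.0 and 0.0 <= h <= 1.0):
        raise ValueError("s and h must lie in [0, 1]")
    raw = np.array([0.25 * (1.0 - s), 0.5 * (1.0 - h * s), 0.25])
    frac = raw / raw.sum()
    freq = float(frac[0] + frac[1] / 2.0)
    return frac, freq


@dataclass
class DistortionFit:
    accepted_s: np.ndarray
    accepted_h: np.ndarray
    n_reps: int
    acceptance_rate: float

    def s_percentile(self, q: float) -> float:
        return float(np.percentile(self.accepted_s, q))


def segdist_selection_abc(
    n_individuals: int = 943,
    n_reps: int = 10_000,
    acceptance_alpha: float = 5e-4,
    seed: int | None = None,
    s_fixed: float | None = None,
    h_fixed: float | None = None,
) -> DistortionFit:
    """Rejection simulation for the selection strength behind a distorter.

    Per replicate: s, h ~ U(0, 1) (unless fixed), genotypes sampled from
    the post-selection expectation, and the replicate is accepted when the
    exact binomial test on 2 * n_individuals alleles calls the mean
    ancestry distorted at ``acceptance_alpha`` (the printed proxy for the
    5% tail of the real cross).
    """
    rng = np.random.default_rng(seed)
    s = np.full(n_reps, s_fixed) if s_fixed is not None else rng.uniform(0, 1, n_reps)
    h = np.full(n_reps, h_fixed) if h_fixed is not None else rng.uniform(0, 1, n_reps)
    raw = np.stack(
        [0.25 * (1.0 - s), 0.5 * (1.0 - h * s), np.full(n_reps, 0.25)], axis=1
    )
    frac = raw / raw.sum(axis=1, keepdims=True)
    counts = rng.multinomial(n_individuals, frac)
    k_disfavored = 2 * counts[:, 0] + counts[:, 1]
    n_alleles = 2 * n_individuals
    pvals = exact_binom_two_sided(k_disfavored, n_alleles)
    acc = pvals < acceptance_alpha
    if not acc.any():
        raise RuntimeError("no accepted replicates")
    return DistortionFit(
        accepted_s=s[acc],
        accepted_h=h[acc],
        n_reps=n_reps,
        acceptance_rate=float(acc.mean()),
    )


def two_locus_expected(counts_a: np.ndarray, counts_b: np.ndarray, n: int) -> np.ndarray:
    """Expected 3x3 genotype-combination table from per-locus marginals."""
    a = np.asarray(counts_a, dtype=np.float64)
    b = np.asarray(counts_b, dtype=np.float64)
    if a.sum() != n or b.sum() != n:
        raise ValueError("marginal totals must equal n (complete cases only)")
    return np.outer(a, b) / n


@dataclass
class TwoLocusResult:
    focal: int
    marker: int
    observed: np.ndarray
    expected: np.ndarray
    chisq: float
    df: int
    pvalue: float
    n: int
    n_zero_expected: int = 0


def two_locus_chisq(observed: np.ndarray, expected: np.ndarray) -> tuple[float, int, float, int]:
    """Chi-square over cells with positive expectation, df = 4.

    Returns (statistic, df, p, number of excluded zero-expectation cells).
    """
    obs = np.asarray(observed, dtype=np.float64)
    exp = np.asarray(expected, dtype=np.float64)
    if obs.sum() == 0:
        raise ValueError("all-zero table")
    if not np.isclose(obs.sum(), exp.sum()):
        raise ValueError("observed and expected totals differ")
    mask = exp > 0
    stat = float((((obs - exp) ** 2)[mask] / exp[mask]).sum())
    df = 4
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p, int((~mask).sum())


def _pair_counts(focal: np.ndarray, geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized complete-case 3x3 counts of (focal, marker) genotype pairs.

    ``focal`` is (n,), ``geno`` is (n, M); missing entries are < 0.
    Returns (counts (M, 3, 3), n per marker).
    """
    n, m = geno.shape
    valid = (geno >= 0) & (focal >= 0)[:, None]
    cat = np.where(valid, focal[:, None] * 3 + geno, 9).astype(np.int64)
    cat += 10 * np.arange(m, dtype=np.int64)[None, :]
    flat = np.bincount(cat.ravel(), minlength=10 * m).reshape(m, 10)
    counts = flat[:, :9].reshape(m, 3, 3)
    return counts, counts.sum(axis=(1, 2))


def _scan_stats(focal: np.ndarray, geno: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chi-square statistics and p-values of focal vs every marker column."""
    counts, ns = _pair_counts(focal, geno)
    a = counts.sum(axis=2)  # (M, 3) focal marginals
    b = counts.sum(axis=1)  # (M, 3) marker marginals
    with np.errstate(invalid="ignore", divide="ignore"):
        exp = a[:, :, None] * b[:, None, :] / ns[:, None, None]
    mask = exp > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(mask, (counts - exp) ** 2 / np.where(mask, exp, 1.0), 0.0)
    chisq = terms.sum(axis=(1, 2))
    pvals = stats.chi2.sf(chisq, 4)
    return chisq, pvals, ns


def incompatibility_scan(panel: F2Panel, focal_marker: int) -> pd.DataFrame:
    """Two-locus chi-square scan of a focal marker against the genome.

    Complete-case analysis per pair; the focal marker itself is excluded.
    Markers on the focal chromosome are reported but flagged ``linked``:
    F2 ancestry linkage disequilibrium extends across whole chromosomes
    (~1.5 crossovers per meiosis), so same-chromosome pairs show large
    chi-square values without any epistasis and must be excluded from
    genome-wide minimum-p bookkeeping.
    """
    g = panel.genotypes
    focal = g[:, focal_marker].astype(np.int64)
    chisq, pvals, ns = _scan_stats(focal, g)
    out = pd.DataFrame(
        {
            "marker": np.arange(g.shape[1]),
            "chrom": panel.markers.chrom,
            "pos": panel.markers.pos,
            "chisq": chisq,
            "df": 4,
            "pvalue": pvals,
            "n": ns,
        }
    )
    out["linked"] = panel.markers.chrom == panel.markers.chrom[focal_marker]
    return out.drop(index=focal_marker).reset_index(drop=True)


def scan_fpr_threshold(
    panel: F2Panel,
    n_reps: int = 500,
    quantile: float = 0.05,
    seed: int | None = None,
) -> tuple[float, np.ndarray]:
    """Genome-wide minimum-p threshold from null focal-genotype simulations.

    Per replicate, each individual's focal genotype is drawn
    Binomial(2, hybrid index) — an unlinked locus consistent with the
    individual's genome-wide ancestry — and the scan's minimum p is
    recorded; the threshold is the lower ``quantile`` of minimum p values.
    Returns (threshold, minimum p values).
    """
    rng = np.random.default_rng(seed)
    hi = panel.hybrid_index()
    hi = np.clip(np.nan_to_num(hi, nan=0.5), 0.0, 1.0)
    g = panel.genotypes
    min_ps = np.empty(n_reps)
    for r in range(n_reps):
        focal = rng.binomial(2, hi).astype(np.int64)
        _, pvals, ns = _scan_stats(focal, g)
        ok = ns > 0
        min_ps[r] = pvals[ok].min() if ok.any() else 1.0
    return float(np.quantile(min_ps, quantile)), min_ps
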