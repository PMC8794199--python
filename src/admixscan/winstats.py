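"""Windowed ancestry summaries and (partial) Spearman correlations.

Summaries pool dosage/2 over individuals and markers per window; partial
correlations follow the rank-residual projection convention (equivalent to
the recursive formula for a single covariate, and to R's ppcor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calls import AncestryMatrix
from .genome import AnnotationTrack, GeneticMap, WindowGrid, count_annotation_bp, thin_indices

__all__ = [
    "UndefinedCorrelationError",
    "CorrelationResult",
    "summarize_windows",
    "window_mean_ancestry",
    "spearman",
    "spearman_partial",
    "thin_windows",
    "exclude_regions",
    "chromosome_stats",
    "ancestry_by_distance",
    "region_ancestry_summary",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (constant or degenerate input)."""


@dataclass
class CorrelationResult:
    rho: float
    pvalue: float
    n: int
    covariates: tuple[str, ...] = ()


def window_mean_ancestry(
    matrix: AncestryMatrix, grid: WindowGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window pooled mean minor ancestry and marker counts.

    Returns ``(mean, n_aims)``; windows without any called entry get NaN.
    """
    widx = grid.window_index(matrix.markers.chrom, matrix.markers.pos)
    present = matrix.present()
    dsum = np.where(present, matrix.dosage, 0).sum(axis=0).astype(np.float64)
    ncalled = present.sum(axis=0).astype(np.float64)
    inside = widx >= 0
    num = np.bincount(widx[inside], weights=dsum[inside], minlength=len(grid))
    den = np.bincount(widx[inside], weights=ncalled[inside], minlength=len(grid))
    n_aims = np.bincount(widx[inside], minlength=len(grid))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = num / (2.0 * den)
    mean[den == 0] = np.nan
    return mean, n_aims


def summarize_windows(
    matrix: AncestryMatrix,
    grid: WindowGrid,
    tracks: AnnotationTrack | None = None,
    min_aims: int = 1,
) -> pd.DataFrame:
    """Window summary table: ancestry, AIM counts, feature bp, recombination rate."""
    out = grid.df.copy()
    mean, n_aims = window_mean_ancestry(matrix, grid)
    out["mean_ancestry"] = mean
    out["n_aims"] = n_aims
    if tracks is not None:
        for cls in ("coding", "conserved", "repeat"):
            if cls in tracks.classes():
                out[f"{cls}_bp"] = count_annotation_bp(tracks, grid, cls)
    span_mb = (out["end"] - out["start"]).to_numpy() / 1e6
    out["rec_rate"] = (out["cm_end"] - out["cm_start"]).to_numpy() / span_mb
    out["valid"] = (n_aims >= min_aims) & np.isfinite(mean)
    return out


def _check_paired(x, y):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise UndefinedCorrelationError("need >= 3 paired finite values")
    return x, y


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average-rank ties and t-approximate p."""
    x, y = _check_paired(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), pvalue=float(p), n=len(x))


def spearman_partial(x, y, covariates=None, names: tuple[str, ...] = ()) -> CorrelationResult:
    """Partial Spearman correlation of x and y given covariates.

    All variables are rank-transformed (average ranks); x and y ranks are
    projected off the covariate ranks by least squares, and the Pearson
    correlation of the residuals is returned with a t-approximate p-value
    on n - 2 - k degrees of freedom.
    """
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        return spearman(x, y)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    cov = np.asarray(covariates, dtype=np.float64)
    if cov.ndim == 1:
        cov = cov[:, None]
    elif cov.shape[0] != len(x) and cov.shape[1] == len(x):
        cov = cov.T  # list of covariate arrays
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(cov).all(axis=1)
    x, y, cov = x[ok], y[ok], cov[ok]
    k = cov.shape[1]
    n = len(x)
    if n < k + 3:
        raise UndefinedCorrelationError(f"need >= {k + 3} complete rows for {k} covariates")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rc = np.column_stack([stats.rankdata(cov[:, j]) for j in range(k)])
    design = np.column_stack([np.ones(n), rc])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise UndefinedCorrelationError("collinear covariates")
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    sx, sy = np.sqrt((ex ** 2).sum()), np.sqrt((ey ** 2).sum())
    if sx < 1e-10 * n or sy < 1e-10 * n:
        raise UndefinedCorrelationError("degenerate projection (residual variance ~ 0)")
    rho = float((ex @ ey) / (sx * sy))
    df = n - 2 - k
    if df <= 0:
        raise UndefinedCorrelationError("no residual degrees of freedom")
    t = rho * np.sqrt(df / max(1e-300, 1.0 - rho ** 2))
    p = float(2 * stats.t.sf(abs(t), df))
    return CorrelationResult(rho=rho, pvalue=p, n=n, covariates=tuple(names))


def thin_windows(summaries: pd.DataFrame, min_separation_bp: int = 500_000) -> pd.DataFrame:
    """Greedy per-chromosome retention of one window per ``min_separation_bp``."""
    kept = []
    for _, sub in summaries.groupby("chrom", sort=False):
        idx = thin_indices(sub["start"].to_numpy(), min_separation_bp)
        kept.append(sub.iloc[idx])
    return pd.concat(kept).sort_index()


def exclude_regions(summaries: pd.DataFrame, track: AnnotationTrack) -> pd.DataFrame:
    """Flag windows overlapping any track interval as invalid (any-overlap rule)."""
    out = summaries.copy()
    if len(track.df) == 0:
        return out
    valid = out["valid"].to_numpy().copy() if "valid" in out else np.ones(len(out), dtype=bool)
    for cls in track.classes():
        for chrom, (starts, ends) in track.merged(cls).items():
            mask = out["chrom"].to_numpy() == chrom
            if not mask.any():
                continue
            a = out["start"].to_numpy()[mask]
            b = out["end"].to_numpy()[mask]
            # overlap iff some interval starts before the window end and ends after its start
            i = np.searchsorted(starts, b, side="left") - 1
            hit = (i >= 0) & (ends[np.clip(i, 0, len(ends) - 1)] > a)
            # also catch intervals fully inside the window beyond index i? merged
            # disjoint intervals: interval i is the last starting before b; any
            # earlier interval ends before starts[i] <= b, so checking i suffices
            # unless it ends before a while a later part of an earlier interval
            # overlaps -- impossible for disjoint sorted intervals.
            vm = valid[mask]
            vm[hit] = False
            valid[mask] = vm
    out["valid"] = valid
    return out


def chromosome_stats(
    summaries: pd.DataFrame,
    gmap: GeneticMap,
    gene_counts: dict[str, int] | None = None,
) -> dict:
    """Per-chromosome mean ancestry and its Spearman correlation with
    chromosome bp length (and gene count when provided)."""
    valid = summaries[summaries.get("valid", True) == True]  # noqa: E712
    per = valid.groupby("chrom")["mean_ancestry"].mean()
    chroms = list(per.index)
    lengths = np.asarray([gmap.length_bp(c) for c in chroms], dtype=np.float64)
    anc = per.to_numpy()
    out = {
        "per_chromosome": pd.DataFrame(
            {"chrom": chroms, "mean_ancestry": anc, "length_bp": lengths}
        ),
        "vs_length": spearman(anc, lengths),
    }
    if gene_counts is not None:
        genes = np.asarray([gene_counts.get(c, 0) for c in chroms], dtype=np.float64)
        out["per_chromosome"]["gene_count"] = genes
        out["vs_gene_count"] = spearman(anc, genes)
    return out


def ancestry_by_distance(
    summaries: pd.DataFrame,
    sites: pd.DataFrame,
    n_boot: int = 500,
    seed: int | None = None,
    bin_edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean ancestry binned by distance to the nearest selected site.

    ``sites`` has columns chrom, pos.  Distance is 0 for windows containing
    a site.  Bins default to logarithmic edges; the bootstrap envelope
    resamples windows with replacement ``n_boot`` times.
    """
    if len(sites) == 0:
        raise ValueError("sites must be non-empty")
    rng = np.random.default_rng(seed)
    sub = summaries[summaries.get("valid", True) == True].copy()  # noqa: E712
    dists = np.full(len(sub), np.inf)
    chroms = sub["chrom"].to_numpy()
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    for chrom, grp in sites.groupby("chrom", sort=False):
        pos = np.sort(grp["pos"].to_numpy(np.int64))
        mask = chroms == chrom
        if not mask.any():
            continue
        a, b = starts[mask], ends[mask]
        # distance from interval [a, b) to nearest site
        i = np.searchsorted(pos, a)
        d = np.full(mask.sum(), np.inf)
        for shift in (-1, 0):
            j = np.clip(i + shift, 0, len(pos) - 1)
            p = pos[j]
            dj = np.where((p >= a) & (p < b), 0.0, np.minimum(np.abs(p - a), np.abs(p - (b - 1))))
            d = np.minimum(d, dj)
        dists[mask] = d
    ok = np.isfinite(dists) & np.isfinite(sub["mean_ancestry"].to_numpy())
    dists = dists[ok]
    anc = sub["mean_ancestry"].to_numpy()[ok]
    if bin_edges is None:
        top = max(dists.max(), 1.0)
        bin_edges = np.concatenate([[0.0, 1.0], np.geomspace(10.0, top + 1, 12)])
    idx = np.clip(np.searchsorted(bin_edges, dists, side="right") - 1, 0, len(bin_edges) - 2)
    nbins = len(bin_edges) - 1
    rows = []
    boot = np.full((n_boot, nbins), np.nan)
    for r in range(n_boot):
        res = rng.integers(0, len(anc), size=len(anc))
        bm = np.bincount(idx[res], weights=anc[res], minlength=nbins)
        bc = np.bincount(idx[res], minlength=nbins)
        with np.errstate(invalid="ignore"):
            boot[r] = np.where(bc > 0, bm / np.maximum(bc, 1), np.nan)
    for b in range(nbins):
        sel = idx == b
        if not sel.any():
            continue
        env = boot[:, b][np.isfinite(boot[:, b])]
        rows.append(
            (
                bin_edges[b],
                bin_edges[b + 1],
                int(sel.sum()),
                float(anc[sel].mean()),
                float(np.quantile(env, 0.025)) if env.size else np.nan,
                float(np.quantile(env, 0.975)) if env.size else np.nan,
            )
        )
    return pd.DataFrame(
        rows, columns=["dist_lo", "dist_hi", "n_windows", "mean_ancestry", "boot_lo", "boot_hi"]
    )


def region_ancestry_summary(
    matrix: AncestryMatrix, regions: pd.DataFrame
) -> pd.DataFrame:
    """Mean minor ancestry per region and its ratio to the genome-wide mean.

    ``regions`` has columns chrom, start, end (half-open bp).
    """
    site_anc = matrix.site_mean_ancestry()
    called = np.isfinite(site_anc)
    genome_mean = float(np.nanmean(site_anc))
    chroms = matrix.markers.chrom
    pos = matrix.markers.pos
    rows = []
    for _, r in regions.iterrows():
        inside = (chroms == r["chrom"]) & (pos >= r["start"]) & (pos < r["end"]) & called
        mean = float(site_anc[inside].mean()) if inside.any() else np.nan
        rows.append((r["chrom"], r["start"], r["end"], inside.sum(), mean, mean / genome_mean))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_markers", "mean_ancestry", "ratio_to_genome"]
    )
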