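"""Rejection-ABC inference of hybrid-population demographic history.

Parameters (population size, generations since admixture, initial
admixture proportion, migration rates) are drawn from uniform or
log-uniform priors, the forward simulator produces a population sample,
and summary statistics (median minor-parent tract length, mean hybrid
index, coefficient of variation of chromosome-wide ancestry — or of
local 250 kb-window ancestry) drive nearest-neighbour rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .calls import AncestryMatrix, tract_lengths
from .genome import GeneticMap, MarkerSet, make_windows
from .simulate import SelectionConfig, SimParams, simulate_admixed_population
from .winstats import window_mean_ancestry

__all__ = [
    "ABCPrior",
    "compute_summary_stats",
    "ReferenceTable",
    "simulate_reference",
    "run_rejection",
    "map_estimate",
]

STAT_NAMES = ("median_minor_tract_cm", "mean_hybrid_index", "ancestry_cv")
PARAM_NAMES = ("n", "generations", "admixture_prop", "mig_minor", "mig_major")


@dataclass
class ABCPrior:
    """Per-parameter prior: ``{name: (dist, low, high)}`` with dist in
    {uniform, log-uniform}.  Parameters absent from the dict are fixed to
    the values in ``fixed``."""

    dists: dict[str, tuple[str, float, float]]
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, (dist, lo, hi) in self.dists.items():
            if dist not in ("uniform", "log-uniform"):
                raise ValueError(f"{name}: unknown distribution {dist!r}")
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"{name}: bounds must be finite with lower < upper")
            if dist == "log-uniform" and lo <= 0:
                raise ValueError(f"{name}: log-uniform needs positive bounds")

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        cols = {}
        for name, (dist, lo, hi) in self.dists.items():
            if dist == "uniform":
                cols[name] = rng.uniform(lo, hi, size=n)
            else:
                cols[name] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        for name, value in self.fixed.items():
            cols[name] = np.full(n, value)
        return pd.DataFrame(cols)

    def is_log(self, name: str) -> bool:
        return name in self.dists and self.dists[name][0] == "log-uniform"


def compute_summary_stats(
    matrix: AncestryMatrix,
    gmap: GeneticMap,
    mode: str = "global",
    window_bp: int = 250_000,
) -> dict[str, float]:
    """Summary statistics for ABC.

    ``global`` mode: CV (sd/mean) of per-individual per-chromosome mean
    ancestry across individuals and chromosomes.  ``local250kb`` mode: CV
    of pooled ancestry across 250 kb windows.  Plus the median cM length of
    minor-parent tracts and the mean hybrid index.
    """
    if matrix.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    hi = matrix.hybrid_index()
    mean_hi = float(np.nanmean(hi))

    tr = tract_lengths(matrix, gmap)
    minor = tr[tr["ancestry"] == "minor"]["length_cm"].to_numpy()
    median_tract = float(np.median(minor)) if minor.size else np.nan

    if mode == "global":
        vals = []
        for chrom, sl in matrix.markers.chrom_slices().items():
            d = matrix.dosage[:, sl]
            present = d >= 0
            with np.errstate(invalid="ignore"):
                v = np.where(present, d, 0).sum(axis=1) / (2.0 * present.sum(axis=1))
            vals.append(v)
        vals = np.concatenate(vals)
        vals = vals[np.isfinite(vals)]
    elif mode == "local250kb":
        grid = make_windows(gmap, "bp", window_bp)
        anc, _ = window_mean_ancestry(matrix, grid)
        vals = anc[np.isfinite(anc)]
    else:
        raise ValueError("mode must be 'global' or 'local250kb'")
    m = vals.mean()
    if m == 0:
        raise ValueError("mean ancestry is 0: CV undefined")
    cv = float(vals.std(ddof=1) / m)
    return {
        "median_minor_tract_cm": median_tract,
        "mean_hybrid_index": mean_hi,
        "ancestry_cv": cv,
    }


@dataclass
class ReferenceTable:
    params: pd.DataFrame
    stats: pd.DataFrame
    n_failed: int = 0


def simulate_reference(
    prior: ABCPrior,
    n_sims: int,
    gmap: GeneticMap,
    markers: MarkerSet,
    seed: int | None = None,
    mode: str = "global",
) -> ReferenceTable:
    """Draw from the prior and simulate the reference table of summary stats.

    Simulations with undefined stats (e.g. minor ancestry lost entirely)
    are excluded and counted in ``n_failed``.
    """
    rng = np.random.default_rng(seed)
    draws = prior.sample(n_sims, rng)
    rows, kept = [], []
    n_failed = 0
    for i in range(n_sims):
        p = draws.iloc[i]
        params = SimParams(
            n=max(2, int(round(p.get("n", 500)))),
            generations=max(1, int(round(p.get("generations", 100)))),
            admixture_prop=float(np.clip(p.get("admixture_prop", 0.5), 1e-3, 1 - 1e-3)),
            mig_minor=float(p.get("mig_minor", 0.0)),
            mig_major=float(p.get("mig_major", 0.0)),
        )
        sim = simulate_admixed_population(
            params, SelectionConfig.neutral(), gmap, markers,
            seed=int(rng.integers(2 ** 63)),
        )
        matrix = AncestryMatrix(dosage=sim.dosage, markers=markers)
        try:
            st = compute_summary_stats(matrix, gmap, mode=mode)
        except ValueError:
            n_failed += 1
            continue
        if not all(np.isfinite(v) for v in st.values()):
            n_failed += 1
            continue
        rows.append(st)
        kept.append(i)
    return ReferenceTable(
        params=draws.iloc[kept].reset_index(drop=True),
        stats=pd.DataFrame(rows),
        n_failed=n_failed,
    )


@dataclass
class ABCPosterior:
    accepted: pd.DataFrame  # parameters + stats + distance
    prior: ABCPrior
    n_simulated: int
    n_failed: int

    def map_and_interval(self, name: str) -> tuple[float, float, float]:
        return map_estimate(
            self.accepted[name].to_numpy(), log_scale=self.prior.is_log(name)
        )


def run_rejection(
    observed: dict[str, float],
    prior: ABCPrior,
    table: ReferenceTable | None = None,
    n_sims: int | None = None,
    gmap: GeneticMap | None = None,
    markers: MarkerSet | None = None,
    accept_mode: str = "top_k",
    k: int = 500,
    epsilon: float | None = None,
    seed: int | None = None,
    mode: str = "global",
) -> ABCPosterior:
    """Rejection sampling against a (possibly precomputed) reference table.

    Distances are Euclidean over stats standardized by the MAD of the
    simulated stats.  ``top_k`` accepts the k nearest draws (default 500);
    ``epsilon`` accepts every draw with distance <= epsilon.
    """
    if table is None:
        if n_sims is None or gmap is None or markers is None:
            raise ValueError("provide either a reference table or n_sims + genome")
        table = simulate_reference(prior, n_sims, gmap, markers, seed=seed, mode=mode)
    stats = table.stats[list(STAT_NAMES)].to_numpy(np.float64)
    obs = np.asarray([observed[s] for s in STAT_NAMES], dtype=np.float64)
    med = np.median(stats, axis=0)
    mad = np.median(np.abs(stats - med), axis=0)
    scale = np.where(mad > 0, mad, np.maximum(np.abs(med), 1e-12))
    dist = np.sqrt((((stats - obs) / scale) ** 2).sum(axis=1))
    if accept_mode == "top_k":
        if k > len(dist):
            k = len(dist)
        order = np.argsort(dist, kind="stable")[:k]
    elif accept_mode == "epsilon":
        if epsilon is None:
            raise ValueError("epsilon mode needs epsilon")
        order = np.flatnonzero(dist <= epsilon)
    else:
        raise ValueError("accept_mode must be 'top_k' or 'epsilon'")
    accepted = pd.concat(
        [table.params.iloc[order].reset_index(drop=True),
         table.stats.iloc[order].reset_index(drop=True)],
        axis=1,
    )
    accepted["distance"] = dist[order]
    return ABCPosterior(
        accepted=accepted, prior=prior,
        n_simulated=len(dist) + table.n_failed, n_failed=table.n_failed,
    )


def map_estimate(samples: np.ndarray, log_scale: bool = False) -> tuple[float, float, float]:
    """MAP (mode of a Silverman-bandwidth KDE on a 512-point grid) and the
    2.5-97.5% quantile interval of accepted draws.

    Returns ``(map, lo, hi)``.  Log-uniform parameters are density-estimated
    on the log scale.
    """
    x = np.asarray(samples, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no accepted draws")
    lo, hi = np.quantile(x, [0.025, 0.975])
    if np.ptp(x) == 0:
        return float(x[0]), float(lo), float(hi)
    z = np.log(x) if log_scale else x
    kde = gaussian_kde(z, bw_method="silverman")
    grid = np.linspace(z.min(), z.max(), 512)
    dens = kde(grid)
    mode = grid[int(np.argmax(dens))]
    m = float(np.exp(mode)) if log_scale else float(mode)
    m = float(min(max(m, lo), hi))  # interval always contains the MAP
    return m, float(lo), float(hi)
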