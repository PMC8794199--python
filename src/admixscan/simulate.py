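"""Forward-in-time simulation of admixed populations and F2 intercross panels.

The engine tracks each haplotype as a 0/1 minor-ancestry vector over the
marker lattice.  Gametes are formed by drawing a crossover count per
chromosome ~ Poisson(cM length / 100) with breakpoints uniform in cM; each
breakpoint toggles the contributing parental haplotype from its position
onward.  Because ancestry is only ever observed at the markers, this is
distributionally exact at marker resolution (crossover parity within an
inter-marker interval is preserved) while vectorizing across the whole
population.  Selection is soft: parents are sampled with probability
proportional to viability, keeping N constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneticMap, MarkerSet

__all__ = [
    "SimParams",
    "SelectionConfig",
    "DmiPair",
    "F2CrossConfig",
    "PopulationSample",
    "F2Panel",
    "simulate_admixed_population",
    "simulate_f2_panel",
    "emit_posteriors",
    "tracts_from_haplotypes",
]


@dataclass
class SimParams:
    """Demographic parameterization of one hybrid population."""

    n: int
    generations: int
    admixture_prop: float  # m0: minor-parent fraction among founders
    mig_minor: float = 0.0
    mig_major: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("population size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0.0 < self.admixture_prop < 1.0:
            raise ValueError("admixture proportion must lie in (0, 1)")
        for m in (self.mig_minor, self.mig_major):
            if not 0.0 <= m < 0.5:
                raise ValueError("migration rates must lie in [0, 0.5)")


@dataclass(frozen=True)
class DmiPair:
    locus_a: int  # marker index, minor-parent dosage side
    locus_b: int  # marker index, major-parent dosage side
    s: float
    h: float

    def __post_init__(self):
        if not (0.0 <= self.s <= 1.0 and 0.0 <= self.h <= 1.0):
            raise ValueError("s and h must lie in [0, 1]")


@dataclass
class SelectionConfig:
    """Selection model applied each generation via viability weights.

    ``mode`` is one of ``neutral``, ``dmi_pairs``, ``hybridization_load``
    or ``single_parent``.  For random placement, leave loci empty and set
    ``n_pairs``/``n_sites``; loci are drawn uniformly from the marker set
    when the simulation starts.
    """

    mode: str = "neutral"
    pairs: list[DmiPair] = field(default_factory=list)
    n_pairs: int = 0
    sites: list[int] = field(default_factory=list)
    n_sites: int = 0
    s: float = 0.0
    h: float = 0.5
    target_parent: str = "minor"  # load carrier / disfavored parent

    def __post_init__(self):
        if self.mode not in ("neutral", "dmi_pairs", "hybridization_load", "single_parent"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if not (0.0 <= self.s <= 1.0 and 0.0 <= self.h <= 1.0):
            raise ValueError("s and h must lie in [0, 1]")
        if self.target_parent not in ("minor", "major"):
            raise ValueError("target_parent must be 'minor' or 'major'")

    @classmethod
    def neutral(cls) -> "SelectionConfig":
        return cls(mode="neutral")

    def realize(self, n_markers: int, rng: np.random.Generator) -> "SelectionConfig":
        """Materialize randomly-placed loci on a marker lattice."""
        if self.mode == "dmi_pairs" and not self.pairs and self.n_pairs > 0:
            loci = rng.choice(n_markers, size=2 * self.n_pairs, replace=False)
            pairs = [
                DmiPair(int(loci[2 * i]), int(loci[2 * i + 1]), self.s, self.h)
                for i in range(self.n_pairs)
            ]
            return SelectionConfig(mode="dmi_pairs", pairs=pairs, s=self.s, h=self.h)
        if self.mode in ("hybridization_load", "single_parent") and not self.sites and self.n_sites > 0:
            sites = sorted(int(x) for x in rng.choice(n_markers, size=self.n_sites, replace=False))
            return SelectionConfig(
                mode=self.mode, sites=sites, s=self.s, h=self.h,
                target_parent=self.target_parent,
            )
        return self

    def selected_loci(self) -> list[int]:
        if self.mode == "dmi_pairs":
            out: list[int] = []
            for p in self.pairs:
                out.extend((p.locus_a, p.locus_b))
            return out
        return list(self.sites)


def _dominance(dosage: np.ndarray, h: float) -> np.ndarray:
    """f(0) = 0, f(1) = h, f(2) = 1."""
    return np.where(dosage == 2, 1.0, np.where(dosage == 1, h, 0.0))


def _fitness(hap: np.ndarray, sel: SelectionConfig) -> np.ndarray:
    """Viability per individual given haplotypes ``hap`` of shape (2N, M)."""
    n = hap.shape[0] // 2
    if sel.mode == "neutral":
        return np.ones(n)
    w = np.ones(n)
    if sel.mode == "dmi_pairs":
        for p in sel.pairs:
            a = hap[0::2, p.locus_a].astype(np.int64) + hap[1::2, p.locus_a]
            b_minor = hap[0::2, p.locus_b].astype(np.int64) + hap[1::2, p.locus_b]
            b = 2 - b_minor  # major-parent dosage at the partner locus
            w *= 1.0 - p.s * _dominance(a, p.h) * _dominance(b, p.h)
        return w
    sites = np.asarray(sel.sites, dtype=np.int64)
    minor_dosage = hap[0::2][:, sites].astype(np.int64) + hap[1::2][:, sites]
    dosage = minor_dosage if sel.target_parent == "minor" else 2 - minor_dosage
    w = np.prod(1.0 - sel.s * _dominance(dosage, sel.h), axis=1)
    return w


class _Lattice:
    """Precomputed marker geometry for the gamete machinery."""

    def __init__(self, gmap: GeneticMap, markers: MarkerSet):
        slices = markers.chrom_slices()
        self.chroms = list(slices)
        for c in self.chroms:
            if c not in gmap.chromosomes:
                raise ValueError(f"marker chromosome {c!r} not on the genetic map")
        self.marker_cm = markers.cm_positions(gmap)
        self.offsets = np.asarray([slices[c].start for c in self.chroms], dtype=np.int64)
        self.chrom_cm = np.asarray([gmap.length_cm(c) for c in self.chroms])
        self.chrom_marker_cm = [self.marker_cm[slices[c]] for c in self.chroms]
        self.n_markers = len(markers)

    def gamete_masks(self, n_gametes: int, rng: np.random.Generator) -> np.ndarray:
        """Boolean (n_gametes, M) array: which parental haplotype (A/B)
        contributes at each marker.  Chromosomes assort independently."""
        m = self.n_markers
        events_g: list[np.ndarray] = []
        events_i: list[np.ndarray] = []
        gidx = np.arange(n_gametes, dtype=np.int64)
        for c, chrom in enumerate(self.chroms):
            # independent assortment: random start parity per chromosome
            start = rng.integers(0, 2, size=n_gametes)
            sel = start == 1
            events_g.append(gidx[sel])
            events_i.append(np.full(sel.sum(), self.offsets[c], dtype=np.int64))
            lam = self.chrom_cm[c] / 100.0
            counts = rng.poisson(lam, size=n_gametes)
            total = int(counts.sum())
            if total:
                g = np.repeat(gidx, counts)
                xs = rng.uniform(0.0, self.chrom_cm[c], size=total)
                idx = self.offsets[c] + np.searchsorted(self.chrom_marker_cm[c], xs, side="left")
                inside = idx < self.offsets[c] + len(self.chrom_marker_cm[c])
                events_g.append(g[inside])
                events_i.append(idx[inside])
        g = np.concatenate(events_g)
        i = np.concatenate(events_i)
        # sparse event scatter + int8 running parity (overflow mod 256 is even,
        # so cumsum wrap-around preserves parity)
        arr = np.zeros((n_gametes, m), dtype=np.int8)
        np.add.at(arr, (g, i), 1)
        np.cumsum(arr, axis=1, out=arr)
        return (arr & 1).astype(bool)


@dataclass
class PopulationSample:
    """Simulation output: diploid dosages at markers plus full haplotypes."""

    dosage: np.ndarray  # (N, M) int8 minor-parent dosage
    haplotypes: np.ndarray  # (2N, M) uint8
    markers: MarkerSet
    params: SimParams
    selection: SelectionConfig
    seed: int | None = None

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    def hybrid_index(self) -> np.ndarray:
        return self.dosage.mean(axis=1) / 2.0


def simulate_admixed_population(
    params: SimParams,
    sel: SelectionConfig,
    gmap: GeneticMap,
    markers: MarkerSet,
    seed: int | None = None,
) -> PopulationSample:
    """Run a Wright-Fisher admixture simulation and return marker dosages.

    Founders are pure minor-parent with probability ``m0``, else pure
    major.  Each generation: migrants replace a Binomial(N, mig) subset
    with pure parentals, then N offspring are produced by sampling two
    parents with probability proportional to viability and recombining
    each parent's haplotypes into one gamete.
    """
    from ._engine import wf_run

    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    lat = _Lattice(gmap, markers)
    n, m = params.n, lat.n_markers
    sel = sel.realize(m, rng)

    hap = np.zeros((2 * n, m), dtype=np.uint8)
    founders_minor = rng.random(n) < params.admixture_prop
    hap[0::2][founders_minor] = 1
    hap[1::2][founders_minor] = 1

    # encode selection for the jitted kernel
    if sel.mode == "neutral":
        mode = 0
    elif sel.mode == "dmi_pairs":
        mode = 1
    else:
        mode = 2
    if mode == 1 and sel.pairs:
        pair_a = np.asarray([p.locus_a for p in sel.pairs], dtype=np.int64)
        pair_b = np.asarray([p.locus_b for p in sel.pairs], dtype=np.int64)
        pair_s = np.asarray([p.s for p in sel.pairs], dtype=np.float64)
        pair_h = np.asarray([p.h for p in sel.pairs], dtype=np.float64)
    else:
        pair_a = pair_b = np.empty(0, dtype=np.int64)
        pair_s = pair_h = np.empty(0, dtype=np.float64)
        if mode == 1:
            mode = 0
    if mode == 2 and sel.sites:
        sites = np.asarray(sel.sites, dtype=np.int64)
        site_s = np.full(len(sites), sel.s, dtype=np.float64)
        site_h = np.full(len(sites), sel.h, dtype=np.float64)
    else:
        sites = np.empty(0, dtype=np.int64)
        site_s = site_h = np.empty(0, dtype=np.float64)
        if mode == 2:
            mode = 0
    target_major = 1 if sel.target_parent == "major" else 0

    chrom_starts = np.append(lat.offsets, lat.n_markers).astype(np.int64)
    hap = wf_run(
        hap, params.generations, float(params.mig_minor), float(params.mig_major),
        chrom_starts, lat.chrom_cm.astype(np.float64), lat.marker_cm,
        mode, pair_a, pair_b, pair_s, pair_h,
        sites, site_s, site_h, target_major,
        int(rng.integers(2 ** 32)),
    )

    dosage = (hap[0::2].astype(np.int8) + hap[1::2]).astype(np.int8)
    return PopulationSample(
        dosage=dosage, haplotypes=hap, markers=markers,
        params=params, selection=sel, seed=seed,
    )


def tracts_from_haplotypes(
    haplotypes: np.ndarray, markers: MarkerSet, gmap: GeneticMap
) -> pd.DataFrame:
    """Maximal constant-ancestry runs per haplotype, with cM boundaries.

    Tract boundaries fall midway (in cM) between flanking markers of
    different ancestry; terminal tracts end at the outermost markers, so
    the per-haplotype total equals the marker cM span of each chromosome.
    """
    cm = markers.cm_positions(gmap)
    slices = markers.chrom_slices()
    rows = []
    for hidx in range(haplotypes.shape[0]):
        hap = haplotypes[hidx]
        for chrom, sl in slices.items():
            vals = hap[sl]
            c = cm[sl]
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vals)]])
            bounds = np.concatenate([[c[0]], (c[change - 1] + c[change]) / 2.0, [c[-1]]])
            for k in range(len(starts)):
                rows.append(
                    (hidx // 2, hidx % 2, chrom,
                     float(bounds[k]), float(bounds[k + 1]),
                     "minor" if vals[starts[k]] else "major")
                )
    df = pd.DataFrame(
        rows, columns=["individual", "haplotype", "chrom", "start_cm", "end_cm", "ancestry"]
    )
    df["length_cm"] = df["end_cm"] - df["start_cm"]
    return df


# ---------------------------------------------------------------------------
# F2 intercross panels


@dataclass(frozen=True)
class Distorter:
    locus: int
    s: float
    h: float
    disfavored_dosage: int = 0  # dosage class of the disfavored homozygote

    def __post_init__(self):
        if self.disfavored_dosage not in (0, 2):
            raise ValueError("disfavored homozygote dosage must be 0 or 2")
        if not (0.0 <= self.s <= 1.0 and 0.0 <= self.h <= 1.0):
            raise ValueError("s and h must lie in [0, 1]")


@dataclass(frozen=True)
class EpistaticPair:
    locus_a: int
    locus_b: int
    s: float
    # two-locus genotype combinations (dosage_a, dosage_b) with survival 1-s
    penalized: tuple[tuple[int, int], ...] = ()


@dataclass
class F2CrossConfig:
    n_individuals: int
    distorters: list[Distorter] = field(default_factory=list)
    epistatic_pairs: list[EpistaticPair] = field(default_factory=list)
    seed: int | None = None


@dataclass
class F2Panel:
    """Genotypes of an F1 x F1 intercross (0/1/2 minor dosage, -1 missing)."""

    genotypes: np.ndarray  # (n, M) int8
    markers: MarkerSet
    config: F2CrossConfig | None = None

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    def hybrid_index(self) -> np.ndarray:
        g = np.ma.masked_less(self.genotypes, 0)
        return np.asarray(g.mean(axis=1) / 2.0)


def _f2_survival(geno: np.ndarray, config: F2CrossConfig) -> np.ndarray:
    surv = np.ones(geno.shape[0])
    for d in config.distorters:
        g = geno[:, d.locus]
        hom = g == d.disfavored_dosage
        het = g == 1
        surv *= np.where(hom, 1.0 - d.s, np.where(het, 1.0 - d.h * d.s, 1.0))
    for p in config.epistatic_pairs:
        ga, gb = geno[:, p.locus_a], geno[:, p.locus_b]
        hit = np.zeros(geno.shape[0], dtype=bool)
        for (a, b) in p.penalized:
            hit |= (ga == a) & (gb == b)
        surv *= np.where(hit, 1.0 - p.s, 1.0)
    return surv


def simulate_f2_panel(
    config: F2CrossConfig,
    gmap: GeneticMap,
    markers: MarkerSet,
    seed: int | None = None,
) -> F2Panel:
    """Simulate an F2 panel with per-individual viability selection.

    Each F2 is the union of two independent F1 gametes (an F1 is
    heterozygous everywhere).  Survival is the product over distorter loci
    of 1-s / 1-hs / 1 and over epistatic pairs of 1-s for penalized
    genotype combinations; rejected individuals are redrawn.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    lat = _Lattice(gmap, markers)

    # reject configs in which no genotype can ever survive
    for d in config.distorters:
        if d.s >= 1.0 and d.h >= 1.0:
            raise ValueError("all-lethal distorter: no surviving genotype class")
    for p in config.epistatic_pairs:
        if p.s >= 1.0 and len(set(p.penalized)) >= 9:
            raise ValueError("all-lethal epistatic pair: every combination penalized")

    out = np.empty((0, lat.n_markers), dtype=np.int8)
    batches = 0
    target = config.n_individuals
    while out.shape[0] < target:
        batches += 1
        if batches > 200:
            raise RuntimeError("F2 rejection sampling failed to converge (survival ~ 0)")
        batch = max(target - out.shape[0], 64)
        # gamete mask == gamete ancestry for an everywhere-heterozygous F1
        g1 = lat.gamete_masks(batch, rng).astype(np.int8)
        g2 = lat.gamete_masks(batch, rng).astype(np.int8)
        geno = g1 + g2
        surv = _f2_survival(geno, config)
        keep = rng.random(batch) < surv
        out = np.vstack([out, geno[keep]])
    return F2Panel(genotypes=out[:target], markers=markers, config=config)


# ---------------------------------------------------------------------------
# HMM-like posterior emission


def emit_posteriors(
    dosage: np.ndarray,
    error_rate: float,
    seed: int | None = None,
    ambiguous_rate: float = 0.0,
) -> np.ndarray:
    """Emit 3-state posteriors around true dosages, mimicking HMM output.

    With probability ``1 - error_rate - ambiguous_rate`` the true state
    receives a posterior drawn uniformly from [0.9, 1]; with probability
    ``error_rate`` a wrong state does (so the arg-max error fraction equals
    ``error_rate`` by construction); with probability ``ambiguous_rate``
    the maximum posterior is pushed below 0.9.  Rows always sum to 1.
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    if ambiguous_rate < 0 or error_rate + ambiguous_rate >= 1:
        raise ValueError("invalid ambiguous_rate")
    rng = np.random.default_rng(seed)
    g = np.asarray(dosage)
    n, m = g.shape
    post = np.zeros((n, m, 3))

    u = rng.random((n, m))
    wrong = u < error_rate
    ambig = (u >= error_rate) & (u < error_rate + ambiguous_rate)

    top_state = g.astype(np.int64).copy()
    if wrong.any():
        shift = rng.integers(1, 3, size=wrong.sum())
        top_state[wrong] = (top_state[wrong] + shift) % 3

    top_p = rng.uniform(0.9, 1.0, size=(n, m))
    top_p[ambig] = rng.uniform(0.5, 0.9 - 1e-9, size=ambig.sum())
    split = rng.random((n, m))
    rest = 1.0 - top_p

    idx = np.arange(3)
    for s in range(3):
        sel = top_state == s
        others = [o for o in idx if o != s]
        post[sel, s] = top_p[sel]
        post[sel, others[0]] = rest[sel] * split[sel]
        post[sel, others[1]] = rest[sel] * (1.0 - split[sel])
    return post
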