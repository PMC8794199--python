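# admixscan

Local-ancestry analysis of hybrid genomes: a toolkit for studying how
genomes evolve after recent admixture.  It covers the full analysis loop
used in hybrid-zone population genomics:

- **`admixscan.genome`** — genetic maps (piecewise-linear bp ↔ cM),
  ancestry-informative marker sets, BED annotation tracks, and
  non-overlapping window grids in bp or cM units.
- **`admixscan.simulate`** — a fast (numba-accelerated) Wright–Fisher
  forward simulator of admixed populations with configurable selection
  (pairwise incompatibilities, hybridization load, selection against one
  parent), F2 intercross panels with viability selection, and an
  HMM-like posterior emitter for synthetic ancestry calls.
- **`admixscan.calls`** — post-HMM processing: posterior hard-calling,
  missingness masking, exact Hardy–Weinberg marker filtering,
  ancestry-transition intervals, tract lengths and short-tract masking.
- **`admixscan.winstats`** — windowed ancestry summaries, Spearman and
  partial Spearman correlations (rank-residual projection), window
  thinning/exclusion, chromosome-level statistics, ancestry-by-distance
  profiles with bootstrap envelopes, and region ancestry summaries.
- **`admixscan.regions`** — minor-parent ancestry desert/island
  detection (seed-and-expand from 2.5%-tail sites, 0.05 cM window
  vetting, merging, thinned-data concordance), cross-population sharing
  classification, permutation nulls (value shuffle and block rotation),
  matched-window nulls and sharing-count bootstraps.
- **`admixscan.abc`** — rejection-ABC inference of hybrid-population
  demography (population size, time since admixture, admixture
  proportion, migration) from tract-length / hybrid-index / ancestry-CV
  summary statistics, with MAP + 95% interval reporting.
- **`admixscan.f2`** — F2-cross analytics: exact binomial
  segregation-distortion scan, viability-selection rejection simulation
  for the selection coefficient behind a distorter, and a two-locus
  chi-square (4 df) incompatibility scan with a simulation-based
  genome-wide false-positive-rate threshold.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` contains the slow end-to-end statistical
acceptance suite (power and calibration checks built on simulations); the
other files are fast unit/property tests per module.

## CLI

One top-level command with sub-commands:

```bash
# simulate a hybrid-population fixture (writes ancestry.tsv, tracts.tsv,
# map.tsv, markers.tsv, truth.json, manifest.json)
admixscan simulate --config cfg.yaml --seed 1 --out runs/pop1

# window summaries + correlations + desert/island detection (+ sharing
# against a second population)
admixscan scan --ancestry runs/pop1/ancestry.tsv --map runs/pop1/map.tsv \
    --other-ancestry runs/pop2/ancestry.tsv --seed 1 --out runs/scan1

# rejection-ABC demographic inference
admixscan abc --ancestry runs/pop1/ancestry.tsv --map runs/pop1/map.tsv \
    --markers runs/pop1/markers.tsv --n-sims 2000 --top-k 200 --out runs/abc1

# F2 distortion + incompatibility scans
admixscan simulate --kind f2 --seed 2 --out runs/f2
admixscan f2 --genotypes runs/f2/f2_genotypes.tsv --focal-marker 100 \
    --out runs/f2scan
```

Configuration is YAML; every run writes a `manifest.json` with the seed
and a config hash, and reruns with the same seed are byte-identical.

## File formats

Everything is plain text: ancestry matrices and F2 panels as
tab-delimited tables (rows = individuals, columns = `chrom:pos`, values
0/1/2/NA minor-parent dosage), genetic maps as `chrom  pos_bp  pos_cM`
TSV, annotations as BED (class in column 4), tracts and regions as
BED-like TSV, reports as TSV/JSON.
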