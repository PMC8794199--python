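import numpy as np
import pandas as pd
import pytest

from admixscan.genome import AnnotationTrack, GeneticMap, MarkerSet


@pytest.fixture
def uniform_map():
    """Two chromosomes, uniform 2.5 cM/Mb."""
    return GeneticMap(
        {
            "chr1": (np.array([0, 20_000_000]), np.array([0.0, 50.0])),
            "chr2": (np.array([0, 20_000_000]), np.array([0.0, 50.0])),
        }
    )


@pytest.fixture
def bumpy_map():
    """Single chromosome with strong recombination-rate variation and a plateau."""
    bp = np.array([0, 1_000_000, 2_000_000, 3_000_000, 4_000_000, 5_000_000])
    cm = np.array([0.0, 0.5, 2.5, 2.5, 3.0, 6.0])
    return GeneticMap({"chr1": (bp, cm)})


@pytest.fixture
def dense_markers(uniform_map):
    frames = [
        pd.DataFrame({"chrom": c, "pos": np.arange(0, 20_000_000, 20_000)})
        for c in uniform_map.chromosomes
    ]
    return MarkerSet(pd.concat(frames, ignore_index=True))


@pytest.fixture
def sparse_markers(uniform_map):
    frames = [
        pd.DataFrame({"chrom": c, "pos": np.arange(0, 20_000_000, 200_000)})
        for c in uniform_map.chromosomes
    ]
    return MarkerSet(pd.concat(frames, ignore_index=True))


@pytest.fixture
def coding_track():
    rng = np.random.default_rng(7)
    rows = []
    for chrom in ("chr1", "chr2"):
        starts = np.sort(rng.integers(0, 19_900_000, size=200))
        for s in starts:
            rows.append((chrom, int(s), int(s + rng.integers(500, 20_000)), "coding"))
    return AnnotationTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "cls"]))


def make_uniform_map(n_chrom=1, length_bp=1_000_000, length_cm=1.0):
    return GeneticMap(
        {
            f"chr{i + 1}": (np.array([0, length_bp]), np.array([0.0, length_cm]))
            for i in range(n_chrom)
        }
    )


def make_markers(gmap, spacing_bp):
    frames = [
        pd.DataFrame({"chrom": c, "pos": np.arange(0, gmap.length_bp(c), spacing_bp)})
        for c in gmap.chromosomes
    ]
    return MarkerSet(pd.concat(frames, ignore_index=True))
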