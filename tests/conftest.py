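import numpy as np
import pytest

from sweepscan.haplo_io import HaplotypePanel, GeneticMap, VariantSite


def make_panel(matrix, pops, positions=None, chrom="1", alleles=None):
    """Build a panel from a (n_chrom, n_sites) 0/1 matrix and per-chromosome
    population labels (n_chrom must be even; rows 2k, 2k+1 pair)."""
    matrix = np.asarray(matrix, dtype=np.int8)
    n_chrom, n_sites = matrix.shape
    assert n_chrom % 2 == 0
    if positions is None:
        positions = [(j + 1) * 1000 for j in range(n_sites)]
    if alleles is None:
        alleles = [("A", "G")] * n_sites
    sites = [
        VariantSite(f"snp{j}", chrom, positions[j], alleles[j][0], alleles[j][1])
        for j in range(n_sites)
    ]
    samples = [f"s{k}" for k in range(n_chrom // 2)]
    return HaplotypePanel(sites, matrix, samples, np.asarray(pops, dtype=object))


def random_panel(rng, n_chrom=20, n_sites=30, pops=("P1",)):
    mat = rng.integers(0, 2, size=(n_chrom, n_sites))
    labels = [pops[i % len(pops)] for s in range(n_chrom // 2) for i in (s, s)]
    return make_panel(mat, labels)


@pytest.fixture
def two_pop_panel():
    """10 CEU-like + 10 YRI-like individuals, 6 sites, differentiated."""
    rng = np.random.default_rng(1)
    a = (rng.random((20, 6)) < 0.8).astype(np.int8)
    b = (rng.random((20, 6)) < 0.2).astype(np.int8)
    mat = np.vstack([a, b])
    pops = ["CEU"] * 20 + ["YRI"] * 20
    return make_panel(mat, pops)


@pytest.fixture
def constant_rate_map():
    """1 cM/Mb map over 5 Mb."""
    return GeneticMap(np.array([1, 5_000_000]), np.array([0.0, 4.999999]))
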