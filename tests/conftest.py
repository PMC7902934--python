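from __future__ import annotations

import numpy as np
import pytest

from carpiscan.core_io import PopulationMap, VariantTable


def build_table(
    genotypes,
    positions=None,
    contig="chr1",
    vclass="snp",
    qual=None,
    info=None,
    phased=False,
    samples=None,
    ref="A",
    alt=("T",),
):
    """Assemble a VariantTable from a (sites, samples, 2) genotype array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape[0], g.shape[1]
    if positions is None:
        positions = np.arange(n_sites) * 100
    if samples is None:
        samples = [f"s{i + 1}" for i in range(n_samples)]
    vc = np.full(n_sites, vclass, dtype=object) if isinstance(vclass, str) else np.asarray(vclass, dtype=object)
    return VariantTable(
        contig=np.full(n_sites, contig, dtype=object) if isinstance(contig, str) else np.asarray(contig, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        ref=np.full(n_sites, ref, dtype=object),
        alt=np.array([alt] * n_sites, dtype=object),
        vclass=vc,
        qual=np.full(n_sites, np.nan) if qual is None else np.asarray(qual, dtype=float),
        info={} if info is None else {k: np.asarray(v, dtype=float) for k, v in info.items()},
        genotypes=g,
        phased=np.full((n_sites, n_samples), phased, dtype=bool),
        samples=list(samples),
    )


def random_table(rng, n_sites=200, n_samples=8, missing_rate=0.0, phased=False):
    """Random biallelic genotypes with optional missingness."""
    p = rng.uniform(0.05, 0.95, n_sites)
    g = (rng.random((n_sites, n_samples, 2)) < p[:, None, None]).astype(np.int8)
    if missing_rate:
        miss = rng.random((n_sites, n_samples)) < missing_rate
        g[miss] = -1
    return build_table(g, phased=phased)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_pop_map():
    """Eight samples, two populations of four."""
    return PopulationMap({f"s{i + 1}": ("popA" if i < 4 else "popB") for i in range(8)})
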