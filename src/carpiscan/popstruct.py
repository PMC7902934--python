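"""Sample-level population structure: allele-sharing distances,
neighbor-joining trees with bootstrap support, and PCA of genotype dosages.

Distances are computed from genotypes directly (1 - identity-by-state over
mutually called sites) rather than from a consensus-sequence alignment;
for biallelic SNPs this is the allele-sharing distance and orders samples
the same way a whole-genome consensus distance would.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MISSING, VariantTable
from .qc_filter import ibs_matrix


def distance_matrix(table: VariantTable) -> np.ndarray:
    """Pairwise allele-sharing distance d(i, j) = 1 - IBS(i, j)."""
    if table.n_samples < 3:
        raise ValueError("need >= 3 samples for a distance matrix")
    return 1.0 - ibs_matrix(table)


@dataclass
class NjTree:
    """Neighbor-joining result: newick string plus the non-trivial
    bipartitions (frozensets of the smaller leaf-label side)."""

    newick: str
    bipartitions: set[frozenset]
    labels: list[str]


def _canon(side: frozenset, all_labels: frozenset) -> frozenset:
    other = all_labels - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min(side, other, key=lambda s: sorted(s))


def nj_tree(matrix: np.ndarray, labels: list[str]) -> NjTree:
    """Saitou-Nei neighbor joining via the Q matrix.

    Ties in Q are broken by the lowest index pair; negative branch lengths
    are clamped to 0 with the excess moved to the sister branch (pair sum
    preserved).  Returns an unrooted tree (trifurcating root) in newick form
    together with its non-trivial bipartitions.
    """
    d = np.array(matrix, dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if n < 3:
        raise ValueError("need >= 3 taxa")
    all_labels = frozenset(labels)
    nodes = list(range(n))  # active node ids
    newick = {i: labels[i] for i in range(n)}
    taxa = {i: frozenset([labels[i]]) for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}
    biparts: set[frozenset] = set()
    next_id = n

    def dd(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    while len(nodes) > 3:
        r = len(nodes)
        row_sum = {i: sum(dd(i, k) for k in nodes if k != i) for i in nodes}
        best = None
        for ai, i in enumerate(nodes):
            for j in nodes[ai + 1:]:
                q = (r - 2) * dd(i, j) - row_sum[i] - row_sum[j]
                if best is None or q < best[0]:
                    best = (q, i, j)
        _, i, j = best
        dij = dd(i, j)
        li = dij / 2.0 + (row_sum[i] - row_sum[j]) / (2.0 * (r - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = next_id
        next_id += 1
        newick[u] = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})"
        taxa[u] = taxa[i] | taxa[j]
        if 2 <= len(taxa[u]) <= len(all_labels) - 2:
            biparts.add(_canon(taxa[u], all_labels))
        for k in nodes:
            if k in (i, j):
                continue
            dist[(min(u, k), max(u, k))] = 0.5 * (dd(i, k) + dd(j, k) - dij)
        nodes = [k for k in nodes if k not in (i, j)] + [u]

    a, b, c = nodes
    la = max(0.0, (dd(a, b) + dd(a, c) - dd(b, c)) / 2.0)
    lb = max(0.0, (dd(a, b) + dd(b, c) - dd(a, c)) / 2.0)
    lc = max(0.0, (dd(a, c) + dd(b, c) - dd(a, b)) / 2.0)
    nwk = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g},{newick[c]}:{lc:.10g});"
    return NjTree(nwk, biparts, list(labels))


def nj_from_table(table: VariantTable) -> NjTree:
    return nj_tree(distance_matrix(table), list(table.samples))


def bootstrap_support(
    table: VariantTable, n_reps: int = 1000, seed: int | None = None
) -> dict[frozenset, float]:
    """Bootstrap support (percent) for each bipartition of the full-data tree.

    SNP columns (sites) are resampled with replacement; the tree is rebuilt
    on each replicate and the recovery fraction of every full-tree
    bipartition is reported x 100.  ``n_reps = 0`` yields an empty mapping.
    """
    base = nj_from_table(table)
    if n_reps == 0:
        return {}
    rng = np.random.default_rng(seed)
    hits = {bp: 0 for bp in base.bipartitions}
    for _ in range(n_reps):
        idx = np.sort(rng.integers(0, table.n_sites, size=table.n_sites))
        rep_tree = nj_tree(1.0 - _ibs_resampled(table, idx), list(table.samples))
        for bp in hits:
            if bp in rep_tree.bipartitions:
                hits[bp] += 1
    return {bp: 100.0 * h / n_reps for bp, h in hits.items()}


def _ibs_resampled(table: VariantTable, site_idx: np.ndarray) -> np.ndarray:
    """IBS matrix over a (possibly repeated) site index multiset."""
    # duplicated positions would break the VariantTable invariant, so IBS is
    # computed directly on the resampled genotype array
    g = table.genotypes[site_idx]
    n = table.n_samples
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, 1.0)
    called = g[:, :, 0] != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            if not both.any():
                continue
            a = np.sort(g[both, i, :], axis=1)
            b = np.sort(g[both, j, :], axis=1)
            eq = (a == b).sum(axis=1)
            cross = ((a[:, 0] == b[:, 1]) | (a[:, 1] == b[:, 0])) & (eq == 0)
            out[i, j] = out[j, i] = (eq + cross).mean() / 2.0
    return out


def pca(
    table: VariantTable, scaling: str = "patterson"
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the genotype dosage matrix.

    Dosages (0/1/2 alternate-allele copies) are mean-imputed at missing
    calls, column-centred per site and, with ``scaling="patterson"``, divided
    by sqrt(p(1-p)) with p the sample allele frequency (monomorphic sites
    drop out).  Returns sample coordinates (columns PC1..) and the
    explained-variance fractions (non-increasing, summing to <= 1 over the
    returned components).
    """
    g = table.genotypes
    called = g[:, :, 0] != MISSING
    dosage = ((g > 0) & (g != MISSING)).sum(axis=2).astype(float)
    dosage[~called] = np.nan
    mean = np.nanmean(dosage, axis=1)
    poly = ~np.isnan(mean)
    inds = np.where(np.isnan(dosage), mean[:, None], dosage)
    p = mean / 2.0
    keep = poly & (p > 0) & (p < 1)
    if not keep.any():
        raise ValueError("no polymorphic sites; PCA undefined")
    x = inds[keep] - mean[keep, None]
    if scaling == "patterson":
        x = x / np.sqrt(p[keep] * (1 - p[keep]))[:, None]
    elif scaling != "none":
        raise ValueError("scaling must be 'patterson' or 'none'")
    # samples x sites SVD
    u, s, _ = np.linalg.svd(x.T, full_matrices=False)
    coords = u * s
    frac = s**2 / np.sum(s**2)
    k = min(10, coords.shape[1])
    df = pd.DataFrame(coords[:, :k], index=table.samples,
                      columns=[f"PC{i + 1}" for i in range(k)])
    return df, frac[:k]
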