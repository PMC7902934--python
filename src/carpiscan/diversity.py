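"""Within-population diversity statistics.

Nucleotide diversity (theta-pi), Watterson's theta, Tajima's D, individual
heterozygosity and the folded site-frequency spectrum, all computed from
diploid genotype calls.  Windowed statistics follow the VCFtools convention
of dividing the summed per-site diversity by the full window length in bp,
assuming non-variant positions are callable.

Individual heterozygosity is the observed fraction of heterozygous calls.
This is a deliberate simplification: it does not model sequencing error the
way a full maximum-likelihood estimator (e.g. mlRho) would, and on real
low-coverage data it will be inflated by genotyping error.  On the synthetic
genotypes used throughout this package the two coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .core_io import MISSING, PopulationMap, VariantTable, WindowSet, scan_track


@dataclass(frozen=True)
class TajimaConstants:
    """Normalising constants of Tajima's D for haploid sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@lru_cache(maxsize=None)
def tajima_constants(n: int) -> TajimaConstants:
    if n < 2:
        raise ValueError("need n >= 2 haploid samples")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def site_pi(j: np.ndarray | int, n: np.ndarray | int) -> np.ndarray | float:
    """Unbiased per-site pairwise diversity 2 j (n - j) / (n (n - 1)).

    ``j`` is the alternate-allele count among ``n`` called alleles.  Returns
    NaN where n < 2.
    """
    j = np.asarray(j, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 2.0 * j * (n - j) / (n * (n - 1.0))
    out = np.where(n < 2, np.nan, out)
    return float(out) if out.ndim == 0 else out


def _pop_counts(table: VariantTable, popmap: PopulationMap, population: str):
    idx = popmap.indices_of(population, table.samples)
    if not idx:
        raise ValueError(f"population {population!r} has no samples in the table")
    return table.allele_counts(idx)


def window_pi(
    table: VariantTable,
    windows: WindowSet,
    popmap: PopulationMap,
    population: str,
    per_site: bool = False,
) -> pd.DataFrame:
    """Windowed nucleotide diversity for one population.

    Per window, the sum of per-site pairwise diversity over its SNPs divided
    by the window length in bp (or by the number of variant sites when
    ``per_site``).  Windows without SNPs carry NaN.
    """
    j, n = _pop_counts(table, popmap, population)
    sp = site_pi(j, n)
    assign = windows.assign_sites(table.contig, table.pos)
    vals = np.empty(len(windows))
    counts = np.empty(len(windows), dtype=int)
    for w, idx in enumerate(assign):
        ok = idx[~np.isnan(sp[idx])]
        counts[w] = len(ok)
        total = np.sum(sp[ok]) if len(ok) else np.nan
        denom = len(ok) if per_site else (windows.end[w] - windows.start[w])
        vals[w] = total / denom if len(ok) else np.nan
    return scan_track(windows, vals, counts)


def tajimas_d(S: int, pi_sum: float, n: int) -> float:
    """Tajima's D from S segregating sites and the mean pairwise-difference
    sum ``pi_sum`` (count units) in a sample of ``n`` haploid sequences.

    Returns NaN when S = 0 (the statistic is undefined, not zero).
    """
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4 haploid samples")
    if S <= 0:
        return float("nan")
    c = tajima_constants(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    return (pi_sum - S / c.a1) / np.sqrt(var)


def window_tajima(
    table: VariantTable,
    windows: WindowSet,
    popmap: PopulationMap,
    population: str,
    min_n_fraction: float = 0.8,
) -> pd.DataFrame:
    """Windowed Tajima's D for one population.

    Missing data: per window the haploid sample size n is the modal per-site
    called-allele count; sites with fewer than ``min_n_fraction`` x n called
    alleles are dropped, the rest contribute with their own per-site n to the
    pairwise sum.
    """
    j, ncall = _pop_counts(table, popmap, population)
    sp = site_pi(j, ncall)
    seg = (j > 0) & (j < ncall)
    assign = windows.assign_sites(table.contig, table.pos)
    vals = np.full(len(windows), np.nan)
    counts = np.zeros(len(windows), dtype=int)
    for w, idx in enumerate(assign):
        if len(idx) == 0:
            continue
        nn = ncall[idx]
        modal = int(np.bincount(nn).argmax())
        keep = idx[nn >= min_n_fraction * modal]
        counts[w] = len(keep)
        if modal < 4 or len(keep) == 0:
            continue
        S = int(np.sum(seg[keep]))
        pi_sum = float(np.nansum(sp[keep]))
        vals[w] = tajimas_d(S, pi_sum, modal)
    track = scan_track(windows, vals, counts)
    track.loc[counts == 0, "value"] = np.nan
    return track


def individual_heterozygosity(table: VariantTable, sample: str) -> float:
    """Observed heterozygosity: fraction of called sites with two different
    alleles.  NaN if the sample has no called site."""
    col = table.samples.index(sample)
    g = table.genotypes[:, col, :]
    called = g[:, 0] != MISSING
    if not called.any():
        return float("nan")
    het = g[called, 0] != g[called, 1]
    return float(het.mean())


def folded_sfs(
    table: VariantTable, popmap: PopulationMap, population: str
) -> np.ndarray:
    """Folded 1D site-frequency spectrum at fixed haploid size n = 2 x
    (population samples); sites with any missing call in the population are
    excluded.  Bin i counts sites with minor-allele count i, i = 0..n//2.
    """
    idx = popmap.indices_of(population, table.samples)
    n = 2 * len(idx)
    j, ncall = table.allele_counts(idx)
    full = ncall == n
    minor = np.minimum(j[full], n - j[full]).astype(int)
    return np.bincount(minor, minlength=n // 2 + 1)


def joint_folded_sfs(
    table: VariantTable, popmap: PopulationMap, pop_a: str, pop_b: str
) -> np.ndarray:
    """Joint folded 2D SFS: counts over (count_A, count_B), folded on the
    total minor allele (entries with 2(jA+jB) > nA+nB are mapped to their
    complements)."""
    ia = popmap.indices_of(pop_a, table.samples)
    ib = popmap.indices_of(pop_b, table.samples)
    na, nb = 2 * len(ia), 2 * len(ib)
    ja, ca = table.allele_counts(ia)
    jb, cb = table.allele_counts(ib)
    full = (ca == na) & (cb == nb)
    ja, jb = ja[full].astype(int), jb[full].astype(int)
    flip = 2 * (ja + jb) > na + nb
    ja = np.where(flip, na - ja, ja)
    jb = np.where(flip, nb - jb, jb)
    out = np.zeros((na + 1, nb + 1), dtype=int)
    np.add.at(out, (ja, jb), 1)
    return out


def neutral_folded_expectation(n: int, n_bins: int | None = None) -> np.ndarray:
    """Expected folded-SFS shape under the standard neutral model,
    eta_i ∝ (1/i + 1/(n-i)) / (1 + [i == n-i]), normalised to sum to 1."""
    kmax = n // 2 if n_bins is None else n_bins
    i = np.arange(1, kmax + 1)
    w = (1.0 / i + 1.0 / (n - i)) / (1.0 + (i == n - i))
    return w / w.sum()
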