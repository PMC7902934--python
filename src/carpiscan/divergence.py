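"""Windowed Weir & Cockerham F_ST with z-transform outlier calling.

The per-site variance components follow the Weir & Cockerham (1984)
moment estimator: ``a`` (among populations), ``b`` (among individuals within
populations) and ``c`` (within individuals).  The windowed statistic is the
ratio of sums sum(a) / sum(a+b+c) over usable sites — the "weighted"
estimator of VCFtools — and negative window values are reported as computed,
never clamped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core_io import MISSING, PopulationMap, VariantTable, WindowSet, scan_track


def wc_components(n_i: np.ndarray, p_i: np.ndarray, h_i: np.ndarray) -> tuple[float, float, float]:
    """Per-site Weir-Cockerham variance components for r populations.

    Parameters are per population: ``n_i`` diploid sample sizes, ``p_i``
    alternate-allele frequencies, ``h_i`` observed heterozygote frequencies.
    Returns (a, b, c).  Monomorphic sites yield (0, 0, 0).
    """
    n_i = np.asarray(n_i, dtype=float)
    p_i = np.asarray(p_i, dtype=float)
    h_i = np.asarray(h_i, dtype=float)
    r = len(n_i)
    if r < 2 or np.any(n_i < 1):
        raise ValueError("need >= 2 populations with >= 1 diploid each")
    nbar = n_i.sum() / r
    nc = (r * nbar - np.sum(n_i**2) / (r * nbar)) / (r - 1)
    pbar = np.sum(n_i * p_i) / (r * nbar)
    s2 = np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar)
    hbar = np.sum(n_i * h_i) / (r * nbar)
    if nbar <= 1 or nc <= 0:
        return 0.0, 0.0, 0.0
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return float(a), float(b), float(c)


def _site_components(
    table: VariantTable, popmap: PopulationMap, pops: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-site (a, b, c) for two (or more) populations.

    Sites where any population has no called diploid, and sites monomorphic
    across all populations, contribute (0, 0, 0) and are flagged unusable.
    """
    g = table.genotypes
    groups = [popmap.indices_of(p, table.samples) for p in pops]
    r = len(groups)
    ns = np.zeros((table.n_sites, r))
    ps = np.zeros((table.n_sites, r))
    hs = np.zeros((table.n_sites, r))
    for k, idx in enumerate(groups):
        sub = g[:, idx, :]
        called = sub[:, :, 0] != MISSING
        n = called.sum(axis=1).astype(float)
        alt = ((sub > 0) & (sub != MISSING)).sum(axis=(1, 2)).astype(float)
        het = (called & (sub[:, :, 0] != sub[:, :, 1])).sum(axis=1).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ns[:, k] = n
            ps[:, k] = alt / (2 * n)
            hs[:, k] = het / n

    usable = (ns >= 1).all(axis=1)
    nbar = ns.sum(axis=1) / r
    usable &= nbar > 1
    nc = np.where(usable, (r * nbar - (ns**2).sum(axis=1) / np.where(r * nbar > 0, r * nbar, 1)) / (r - 1), 1.0)
    pbar = (ns * ps).sum(axis=1) / np.where(r * nbar > 0, r * nbar, 1)
    s2 = (ns * (ps - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * np.where(nbar > 0, nbar, 1))
    hbar = (ns * hs).sum(axis=1) / np.where(r * nbar > 0, r * nbar, 1)

    poly = (pbar > 0) & (pbar < 1)
    usable &= poly | (s2 > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
    a = np.where(usable, a, 0.0)
    b = np.where(usable, b, 0.0)
    c = np.where(usable, c, 0.0)
    return a, b, c


def window_fst(
    table: VariantTable,
    windows: WindowSet,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
) -> pd.DataFrame:
    """Windowed Weir-Cockerham F_ST (ratio of summed components).

    Per window, sum(a) / sum(a + b + c) over usable sites.  Windows without a
    usable site are NaN; ``n_sites`` counts usable (polymorphic, fully
    represented) sites.
    """
    a, b, c = _site_components(table, popmap, [pop_a, pop_b])
    usable = (a + b + c) != 0
    assign = windows.assign_sites(table.contig, table.pos)
    vals = np.full(len(windows), np.nan)
    counts = np.zeros(len(windows), dtype=int)
    for w, idx in enumerate(assign):
        use = idx[usable[idx]]
        counts[w] = len(use)
        if len(use) == 0:
            continue
        denom = np.sum(a[use] + b[use] + c[use])
        vals[w] = np.sum(a[use]) / denom if denom != 0 else np.nan
    return scan_track(windows, vals, counts)


def genome_fst(
    table: VariantTable,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    estimator: str = "wc",
) -> float:
    """Genome-wide ratio-of-sums F_ST over all usable sites.

    ``estimator="wc"`` (default) uses the Weir-Cockerham components;
    ``"hudson"`` uses the Hudson estimator (within- vs between-population
    heterozygosity), kept as an independent cross-check.
    """
    if estimator == "wc":
        a, b, c = _site_components(table, popmap, [pop_a, pop_b])
        denom = np.sum(a + b + c)
        return float(np.sum(a) / denom) if denom else float("nan")
    if estimator != "hudson":
        raise ValueError("estimator must be 'wc' or 'hudson'")
    num_sum = den_sum = 0.0
    for pop_pair in [(pop_a, pop_b)]:
        g = table.genotypes
        stats = []
        for pop in pop_pair:
            idx = popmap.indices_of(pop, table.samples)
            sub = g[:, idx, :]
            called = (sub[:, :, 0] != MISSING).sum(axis=1) * 2.0
            alt = ((sub > 0) & (sub != MISSING)).sum(axis=(1, 2)).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                stats.append((alt / called, called))
        (p1, n1), (p2, n2) = stats
        ok = (n1 >= 2) & (n2 >= 2)
        p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        num_sum, den_sum = float(num.sum()), float(den.sum())
    return num_sum / den_sum if den_sum else float("nan")


def z_outliers(track: pd.DataFrame, alpha: float = 0.05, tail: str = "upper") -> pd.DataFrame:
    """Add z-score, p-value and outlier flag columns to a scan track.

    z is computed over non-missing windows; p is the upper-tail normal
    probability for ``tail="upper"`` (divergence scans seek high values),
    the lower tail for ``"lower"``, or two-sided for ``"two"``.  Flags mark
    p < alpha.  Raises on a degenerate (zero-variance) track.
    """
    out = track.copy()
    x = out["value"].to_numpy(dtype=float)
    ok = ~np.isnan(x)
    if ok.sum() < 2:
        raise ValueError("need at least two non-missing windows")
    mu, sd = x[ok].mean(), x[ok].std(ddof=0)
    if sd == 0:
        raise ValueError("all window values identical; z-scores undefined")
    z = (x - mu) / sd
    if tail == "upper":
        p = norm.sf(z)
    elif tail == "lower":
        p = norm.cdf(z)
    elif tail == "two":
        p = 2 * norm.sf(np.abs(z))
    else:
        raise ValueError("tail must be 'upper', 'lower' or 'two'")
    out["z"] = z
    out["p"] = p
    out["outlier"] = (p < alpha) & ok
    return out
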