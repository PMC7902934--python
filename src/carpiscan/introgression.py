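"""ABBA-BABA introgression statistics (D and f_d) with block-jackknife errors.

The frequency (population-sample) form of the four-taxon test is used: for a
site with derived-allele frequencies p1, p2, p3, p4 in populations
(P1, P2, P3, Outgroup),

    ABBA = (1 - p1) p2 p3 (1 - p4)        BABA = p1 (1 - p2) p3 (1 - p4)

and D = sum(ABBA - BABA) / sum(ABBA + BABA).  The admixture-proportion
estimator f_d replaces the numerator's donor by whichever of P2/P3 carries
the higher derived frequency at each site (the "maximal introgression"
substitution), so that f_d approximates the admixed fraction of the genome.

Polarisation uses the outgroup: the outgroup's (pooled) major allele is
ancestral, and sites where the outgroup is polymorphic or missing are
excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core_io import MISSING, PopulationMap, VariantTable, WindowSet


@dataclass
class QuartetSites:
    """Per-site derived-allele frequencies for (P1, P2, P3, Outgroup)."""

    contig: np.ndarray
    pos: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    p4: np.ndarray

    def __len__(self) -> int:
        return len(self.pos)


@dataclass
class JackknifeResult:
    """Delete-one block-jackknife summary for a ratio statistic."""

    estimate: float
    pseudovalues: np.ndarray  # leave-one-out estimates
    se: float
    z: float
    p: float
    degenerate: bool = False


def site_patterns(p1, p2, p3, p4) -> tuple[np.ndarray, np.ndarray]:
    """ABBA and BABA site-pattern weights from derived-allele frequencies."""
    p1, p2, p3, p4 = (np.asarray(x, dtype=float) for x in (p1, p2, p3, p4))
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba


def d_statistic(abba_sum: float, baba_sum: float) -> float:
    """D = (ABBA - BABA) / (ABBA + BABA); NaN when the denominator is zero."""
    denom = abba_sum + baba_sum
    if denom == 0:
        return float("nan")
    return (abba_sum - baba_sum) / denom


def quartet_frequencies(
    table: VariantTable,
    popmap: PopulationMap,
    p1: str,
    p2: str,
    p3: str,
    outgroup: str | list[str],
    max_outgroup_freq: float = 0.0,
) -> QuartetSites:
    """Derived-allele frequencies per site for a (P1, P2, P3, Outgroup) quartet.

    The outgroup may pool several labels; its major allele defines the
    ancestral state.  Sites where the outgroup minor-allele frequency exceeds
    ``max_outgroup_freq`` (default: any polymorphism), or where any
    population lacks called genotypes, are excluded.
    """
    groups = [p1, p2, p3]
    freqs = []
    oks = []
    for pop in groups:
        idx = popmap.indices_of(pop, table.samples)
        alt, called = table.allele_counts(idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs.append(np.where(called > 0, alt / np.maximum(called, 1), np.nan))
        oks.append(called > 0)
    oidx = popmap.indices_of(outgroup if isinstance(outgroup, list) else [outgroup], table.samples)
    if not oidx:
        oidx = popmap.indices_of(outgroup, table.samples)
    oalt, ocalled = table.allele_counts(oidx)
    with np.errstate(invalid="ignore", divide="ignore"):
        ofreq = np.where(ocalled > 0, oalt / np.maximum(ocalled, 1), np.nan)

    keep = np.logical_and.reduce(oks) & (ocalled > 0)
    # ancestral = outgroup major allele; flip so p4 is the outgroup-derived freq
    flip = ofreq > 0.5
    keep &= np.minimum(ofreq, 1 - ofreq) <= max_outgroup_freq

    f = [np.where(flip, 1 - q, q) for q in freqs]
    p4 = np.where(flip, 1 - ofreq, ofreq)
    return QuartetSites(
        contig=table.contig[keep],
        pos=table.pos[keep],
        p1=f[0][keep],
        p2=f[1][keep],
        p3=f[2][keep],
        p4=p4[keep],
    )


def _sums(q: QuartetSites, idx: np.ndarray | slice = slice(None)) -> tuple[float, float, float]:
    """(ABBA, BABA, dynamic-denominator) sums over a site subset."""
    abba, baba = site_patterns(q.p1[idx], q.p2[idx], q.p3[idx], q.p4[idx])
    pd_ = np.maximum(q.p2[idx], q.p3[idx])
    abba_d = (1 - q.p1[idx]) * pd_ * pd_ * (1 - q.p4[idx])
    baba_d = q.p1[idx] * (1 - pd_) * pd_ * (1 - q.p4[idx])
    return float(abba.sum()), float(baba.sum()), float((abba_d - baba_d).sum())


def fd_statistic(
    q: QuartetSites, idx: np.ndarray | slice = slice(None), mask_negative: bool = True
) -> float:
    """f_d over a site set: sum(ABBA - BABA) / sum(ABBA_D - BABA_D) with the
    donor substitution P_D = argmax(p2, p3) per site.

    With ``mask_negative`` (the windowed convention) the statistic is
    reported missing when D < 0 over the same sites, since the estimator is
    only meaningful for excess ABBA sharing; genome-wide summaries pass
    ``mask_negative=False`` to retain near-zero signed values under the
    null.  NaN when the denominator is zero.
    """
    sa, sb, sdyn = _sums(q, idx)
    if sdyn == 0 or (mask_negative and (sa - sb) < 0):
        return float("nan")
    return (sa - sb) / sdyn


def genome_d_fd(q: QuartetSites) -> tuple[float, float]:
    """Genome-wide (D, f_d) over all quartet sites; f_d is signed (no D < 0
    masking) so that a no-introgression genome reports a value near zero."""
    sa, sb, sdyn = _sums(q)
    d = d_statistic(sa, sb)
    fd = (sa - sb) / sdyn if sdyn != 0 else float("nan")
    return d, fd


def windowed_d_fd(q: QuartetSites, windows: WindowSet) -> pd.DataFrame:
    """Per-window D and f_d.  Windows without informative sites are NaN, and
    f_d is NaN wherever the window D is negative."""
    assign = windows.assign_sites(q.contig, q.pos)
    rows = windows.to_frame()
    n_sites = np.zeros(len(windows), dtype=int)
    d_vals = np.full(len(windows), np.nan)
    fd_vals = np.full(len(windows), np.nan)
    for w, idx in enumerate(assign):
        abba, baba = site_patterns(q.p1[idx], q.p2[idx], q.p3[idx], q.p4[idx])
        informative = (abba + baba) > 0
        n_sites[w] = int(informative.sum())
        if n_sites[w] == 0:
            continue
        d_vals[w] = d_statistic(float(abba.sum()), float(baba.sum()))
        fd_vals[w] = fd_statistic(q, idx)
    rows["n_sites"] = n_sites
    rows["d"] = d_vals
    rows["fd"] = fd_vals
    return rows


def block_jackknife(
    numerator: np.ndarray,
    denominator: np.ndarray,
    n_blocks: int = 50,
    weights: np.ndarray | None = None,
) -> JackknifeResult:
    """Delete-one block jackknife for a ratio statistic sum(num)/sum(den).

    Sites must be in genome order; they are cut into ``n_blocks`` contiguous
    blocks of approximately equal informative weight (``weights`` defaults to
    the denominator, i.e. informative-site mass).  SE follows the standard
    delete-one formula SE^2 = (m-1)/m * sum((t_i - tbar)^2); Z = estimate/SE
    and p is the two-sided normal tail.
    """
    numerator = np.asarray(numerator, dtype=float)
    denominator = np.asarray(denominator, dtype=float)
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    total_num, total_den = numerator.sum(), denominator.sum()
    if total_den == 0:
        raise ValueError("denominator sums to zero; statistic undefined")
    w = np.abs(denominator if weights is None else np.asarray(weights, dtype=float))
    cum = np.cumsum(w)
    edges = np.searchsorted(cum, np.linspace(0, cum[-1], n_blocks + 1)[1:-1], side="right")
    bounds = np.concatenate([[0], edges, [len(numerator)]])
    block_num = np.add.reduceat(numerator, bounds[:-1])
    block_den = np.add.reduceat(denominator, bounds[:-1])
    nonempty = np.diff(bounds) > 0
    block_num, block_den = block_num[nonempty], block_den[nonempty]
    m = len(block_num)
    if m < 2:
        raise ValueError("fewer than 2 non-degenerate jackknife blocks")
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (total_num - block_num) / (total_den - block_den)
    estimate = total_num / total_den
    se = float(np.sqrt((m - 1) / m * np.sum((loo - loo.mean()) ** 2)))
    if se == 0:
        return JackknifeResult(estimate, loo, 0.0, float("nan"), float("nan"), degenerate=True)
    z = estimate / se
    p = 2 * norm.sf(abs(z))
    return JackknifeResult(estimate, loo, se, float(z), float(p), degenerate=False)


def d_with_jackknife(q: QuartetSites, n_blocks: int = 50) -> JackknifeResult:
    """Genome-wide D with block-jackknife Z and p over contiguous blocks."""
    abba, baba = site_patterns(q.p1, q.p2, q.p3, q.p4)
    return block_jackknife(abba - baba, abba + baba, n_blocks=n_blocks)
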