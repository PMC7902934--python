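"""Extended haplotype homozygosity (EHH), its integral (iHH) and the
cross-population XP-EHH scan on phased haplotype panels.

Genetic positions default to the physical-distance proxy 1 Mb = 1 cM, as is
common when no fine-scale recombination map exists.  EHH here is the
unconditional (sample-wide) homozygosity used by XP-EHH: EHH at extension x
is the probability that two random haplotypes are identical over all SNPs
strictly between the core and x inclusive of x, so EHH(0) = 1 by the
empty-interval convention.  Curves are truncated when EHH drops below a
cutoff (default 0.05), when a gap between adjacent SNPs exceeds a maximum
(default 200 kb), or at the contig end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MISSING, PopulationMap, VariantTable, WindowSet, scan_track
from .divergence import z_outliers

CM_PER_BP = 1e-6  # 1 Mb = 1 cM proxy map


@dataclass
class HaplotypePanel:
    """Fully phased binary haplotypes on one contig.

    positions : (n_sites,) bp, strictly increasing
    genetic_pos : (n_sites,) cM
    alleles : (n_sites, n_haplotypes) int8 in {0, 1}
    """

    positions: np.ndarray
    genetic_pos: np.ndarray
    alleles: np.ndarray

    @property
    def n_haps(self) -> int:
        return self.alleles.shape[1]

    @classmethod
    def from_table(
        cls,
        table: VariantTable,
        popmap: PopulationMap,
        population: str,
        contig: str | None = None,
        cm_per_bp: float = CM_PER_BP,
        min_maf: float = 0.0,
    ) -> "HaplotypePanel":
        """Extract a phased panel for one population (one contig).

        ``min_maf`` drops sites below a minor-allele-frequency cutoff
        computed over ALL samples in the table (so panels from different
        populations keep a shared site grid).  Low-frequency variants carry
        little haplotype-homozygosity information and EHH-based tools filter
        them by default (0.05 is the usual cutoff).
        """
        if contig is not None:
            table = table.take_sites(table.contig == contig)
        elif len(np.unique(table.contig)) > 1:
            raise ValueError("panel spans several contigs; pass contig=")
        if min_maf > 0:
            alt, called = table.allele_counts()
            with np.errstate(invalid="ignore", divide="ignore"):
                p = alt / np.maximum(called, 1)
            maf = np.minimum(p, 1 - p)
            table = table.take_sites(maf >= min_maf)
        idx = popmap.indices_of(population, table.samples)
        g = table.genotypes[:, idx, :]
        if (g == MISSING).any():
            raise ValueError("panel has missing genotypes; phase/impute upstream")
        het = g[:, :, 0] != g[:, :, 1]
        if (het & ~table.phased[:, idx]).any():
            raise ValueError("panel has unphased heterozygous calls")
        alleles = g.reshape(g.shape[0], -1).astype(np.int8)
        return cls(table.pos.astype(float), table.pos * cm_per_bp, alleles)


def _ehh_one_direction(
    panel: HaplotypePanel,
    core_index: int,
    direction: int,
    truncate: float,
    max_gap_bp: float,
) -> tuple[np.ndarray, np.ndarray]:
    """EHH curve from the core outward; returns (genetic distance, EHH)
    including the (0, 1) origin point."""
    n = panel.n_haps
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    pairs = n * (n - 1) / 2.0
    dists = [0.0]
    ehhs = [1.0]
    classes = np.zeros(n, dtype=np.int64)
    i = core_index
    while True:
        j = i + direction
        if j < 0 or j >= len(panel.positions):
            break
        if abs(panel.positions[j] - panel.positions[i]) > max_gap_bp:
            break
        # refine haplotype classes with the allele column at j
        classes = classes * 2 + panel.alleles[j]
        _, classes = np.unique(classes, return_inverse=True)
        counts = np.bincount(classes)
        ehh = float(np.sum(counts * (counts - 1) / 2.0) / pairs)
        dists.append(abs(panel.genetic_pos[j] - panel.genetic_pos[core_index]))
        ehhs.append(ehh)
        if ehh < truncate:
            break
        i = j
    return np.asarray(dists), np.asarray(ehhs)


def ehh_curve(
    panel: HaplotypePanel,
    core_index: int,
    direction: str = "right",
    truncate: float = 0.05,
    max_gap_bp: float = 200_000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """EHH decay curve from a core SNP in one direction ("left"/"right").

    Returns (genetic distances from the core in cM, EHH values), starting at
    (0, 1).  The first point below the truncation cutoff is included, then
    the curve stops.
    """
    d = {"right": 1, "left": -1}[direction]
    return _ehh_one_direction(panel, core_index, d, truncate, max_gap_bp)


def ihh(
    panel: HaplotypePanel,
    core_index: int,
    truncate: float = 0.05,
    max_gap_bp: float = 200_000.0,
) -> float:
    """Integrated EHH: trapezoidal integral of the EHH curve over genetic
    distance, both directions summed.  A degenerate single-point curve
    contributes 0."""
    total = 0.0
    for d in (-1, 1):
        x, y = _ehh_one_direction(panel, core_index, d, truncate, max_gap_bp)
        if len(x) > 1:
            total += float(np.trapezoid(y, x))
    return total


def xpehh_raw(
    panel_obs: HaplotypePanel,
    panel_ref: HaplotypePanel,
    core_index: int,
    truncate: float = 0.05,
    max_gap_bp: float = 200_000.0,
) -> float:
    """Raw XP-EHH: ln(iHH_observed / iHH_reference) at one core SNP.

    Positive values indicate longer haplotypes (a selection signal) in the
    observed panel; negative values point to the reference panel.  NaN when
    either integral is zero.  Both panels must share the same site grid.
    """
    if panel_obs.alleles.shape[0] != panel_ref.alleles.shape[0]:
        raise ValueError("panels must share the same site grid")
    ia = ihh(panel_obs, core_index, truncate, max_gap_bp)
    ib = ihh(panel_ref, core_index, truncate, max_gap_bp)
    if ia == 0 or ib == 0:
        return float("nan")
    # log difference, not log of the ratio: antisymmetry is then exact
    return float(np.log(ia) - np.log(ib))


def xpehh_scan(
    panel_obs: HaplotypePanel,
    panel_ref: HaplotypePanel,
    cores: np.ndarray | None = None,
    truncate: float = 0.05,
    max_gap_bp: float = 200_000.0,
    contig: str | None = None,
) -> pd.DataFrame:
    """Raw XP-EHH at every core SNP (or a subset of core indices).

    The optional ``contig`` label is attached so scans from several contigs
    can be concatenated before normalisation.
    """
    if cores is None:
        cores = np.arange(len(panel_obs.positions))
    rows = []
    for c in cores:
        rows.append((panel_obs.positions[c], xpehh_raw(panel_obs, panel_ref, int(c), truncate, max_gap_bp)))
    out = pd.DataFrame(rows, columns=["pos", "xpehh_raw"])
    if contig is not None:
        out["contig"] = contig
    return out


def normalize_and_window(
    scores: pd.DataFrame,
    windows: WindowSet,
    alpha: float = 0.05,
    contig: str | None = None,
    agg: str = "mean",
) -> pd.DataFrame:
    """Standardise per-SNP scores genome-wide and aggregate per window.

    The window statistic is the mean (or max, ``agg="max"``) of standardised
    per-SNP scores; flags are two-sided at ``alpha`` per tail (positive tail:
    observed population; negative tail: reference population).  Raises when
    the scores have zero variance.
    """
    x = scores["xpehh_raw"].to_numpy(dtype=float)
    ok = ~np.isnan(x)
    if ok.sum() < 2 or np.std(x[ok]) == 0:
        raise ValueError("degenerate score distribution; cannot standardise")
    z = (x - x[ok].mean()) / x[ok].std(ddof=0)
    if "contig" in scores.columns:
        score_contig = scores["contig"].to_numpy(dtype=object)
    else:
        score_contig = np.full(len(scores), contig if contig is not None
                               else (windows.contig[0] if len(windows) else "chr"), dtype=object)
    pos = scores["pos"].to_numpy()
    assign = windows.assign_sites(score_contig, pos.astype(np.int64))
    vals = np.full(len(windows), np.nan)
    counts = np.zeros(len(windows), dtype=int)
    for w, idx in enumerate(assign):
        use = idx[ok[idx]]
        counts[w] = len(use)
        if len(use) == 0:
            continue
        vals[w] = float(np.mean(z[use])) if agg == "mean" else float(np.max(z[use]))
    track = scan_track(windows, vals, counts)
    track = z_outliers(track, alpha=alpha, tail="two")
    track["tail"] = np.where(track["z"] > 0, "observed", "reference")
    track.loc[track["value"].isna(), "tail"] = ""
    return track
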