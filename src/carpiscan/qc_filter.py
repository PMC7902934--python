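"""Site- and sample-level variant filtering cascade.

The cascade mirrors a conventional GATK-style resequencing workflow on an
already-called callset: per-class hard filters on INFO annotations, then
site-level QUAL/depth/allele-count filters, removal of SNPs close to indels,
and relatedness pruning on an identity-by-state (IBS) matrix.

All inequality clauses are strict: a site sitting exactly on a threshold
passes.  A missing annotation means "clause not applicable" (GATK omits the
rank-sum annotations at sites without heterozygotes), so the clause cannot
fire.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import MISSING, VariantTable

#: SNP hard-filter clauses: (INFO key, comparison, threshold); "lt" fires when
#: value < threshold, "gt" when value > threshold.
SNP_HARD_CLAUSES = (
    ("QD", "lt", 2.0),
    ("FS", "gt", 60.0),
    ("ReadPosRankSum", "lt", -8.0),
    ("MQ", "lt", 40.0),
    ("MQRankSum", "lt", -12.5),
    ("SOR", "gt", 3.0),
)

INDEL_HARD_CLAUSES = (
    ("QD", "lt", 2.0),
    ("ReadPosRankSum", "lt", -20.0),
    ("FS", "gt", 200.0),
)


@dataclass
class FilterReport:
    """Per-clause removal counts plus before/after totals."""

    n_in: int
    n_out: int
    removed_by: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out


def _clause_fires(table: VariantTable, key: str, op: str, threshold: float) -> np.ndarray:
    arr = table.info.get(key)
    if arr is None:
        return np.zeros(table.n_sites, dtype=bool)
    with np.errstate(invalid="ignore"):
        fired = arr < threshold if op == "lt" else arr > threshold
    fired[np.isnan(arr)] = False
    return fired


def _hard_filter(table: VariantTable, clauses) -> tuple[VariantTable, FilterReport]:
    drop = np.zeros(table.n_sites, dtype=bool)
    removed_by = {}
    for key, op, thr in clauses:
        fired = _clause_fires(table, key, op, thr)
        removed_by[key] = int(fired.sum())
        drop |= fired
    kept = table.take_sites(~drop)
    return kept, FilterReport(table.n_sites, kept.n_sites, removed_by)


def hard_filter_snps(table: VariantTable) -> tuple[VariantTable, FilterReport]:
    """Remove SNP sites failing any GATK-style hard-filter clause.

    Clauses (a site is removed if ANY fires): QD < 2.0, FS > 60.0,
    ReadPosRankSum < -8.0, MQ < 40.0, MQRankSum < -12.5, SOR > 3.
    The per-clause counts in the report count sites where each clause fired,
    so their sum can exceed the number of removed sites.
    """
    return _hard_filter(table, SNP_HARD_CLAUSES)


def hard_filter_indels(table: VariantTable) -> tuple[VariantTable, FilterReport]:
    """Remove indel sites with QD < 2.0, ReadPosRankSum < -20.0 or FS > 200.0."""
    return _hard_filter(table, INDEL_HARD_CLAUSES)


def site_level_filter(
    table: VariantTable,
    site_depth: np.ndarray | None = None,
    min_qual: float = 50.0,
    depth_lo: float = 1.0 / 3.0,
    depth_hi: float = 3.0,
    max_alleles: int = 2,
) -> tuple[VariantTable, FilterReport]:
    """Remove sites with QUAL below ``min_qual``, extreme aggregate depth, or
    more than ``max_alleles`` alleles observed across samples.

    ``site_depth`` is the total depth per site pooled over samples (GATK DP);
    when omitted it is taken from the table's ``DP`` INFO field.  The depth
    clause removes sites whose depth exceeds ``depth_hi`` times, or falls
    below ``depth_lo`` times, the mean site depth.  Depth information is
    mandatory — the clause is never silently skipped.
    """
    if site_depth is None:
        site_depth = table.info.get("DP")
    if site_depth is None:
        raise ValueError("no site depth available (supply site_depth or a DP INFO field)")
    site_depth = np.asarray(site_depth, dtype=float)
    if len(site_depth) != table.n_sites:
        raise ValueError("site_depth length must match number of sites")

    low_qual = ~np.isnan(table.qual) & (table.qual < min_qual)
    mean_depth = float(np.nanmean(site_depth)) if table.n_sites else 0.0
    with np.errstate(invalid="ignore"):
        bad_depth = (site_depth > depth_hi * mean_depth) | (site_depth < depth_lo * mean_depth)
    bad_depth[np.isnan(site_depth)] = False
    multi = table.n_observed_alleles() > max_alleles

    removed_by = {
        "qual": int(low_qual.sum()),
        "depth": int(bad_depth.sum()),
        "multiallelic": int(multi.sum()),
    }
    kept = table.take_sites(~(low_qual | bad_depth | multi))
    return kept, FilterReport(table.n_sites, kept.n_sites, removed_by)


def indel_proximity_filter(
    snps: VariantTable, indels: VariantTable, radius: int = 5
) -> tuple[VariantTable, FilterReport]:
    """Remove SNPs at or within ``radius`` bp of any indel.

    Distance is measured between the VCF POS anchors of the SNP and the indel
    (|pos_snp - pos_indel| <= radius); a SNP exactly ``radius + 1`` bp away is
    kept.
    """
    drop = np.zeros(snps.n_sites, dtype=bool)
    for c in np.unique(snps.contig):
        ipos = np.sort(indels.pos[indels.contig == c])
        if len(ipos) == 0:
            continue
        mask = snps.contig == c
        spos = snps.pos[mask]
        j = np.searchsorted(ipos, spos)
        near = np.zeros(len(spos), dtype=bool)
        left = np.clip(j - 1, 0, len(ipos) - 1)
        right = np.clip(j, 0, len(ipos) - 1)
        near |= np.abs(spos - ipos[left]) <= radius
        near |= np.abs(spos - ipos[right]) <= radius
        drop[mask] = near
    kept = snps.take_sites(~drop)
    return kept, FilterReport(snps.n_sites, kept.n_sites, {"near_indel": int(drop.sum())})


def ibs_matrix(table: VariantTable) -> np.ndarray:
    """Pairwise identity-by-state: mean allele-sharing proportion.

    For each sample pair the statistic is the mean, over mutually called
    sites, of (shared alleles between the two diploid genotypes) / 2 — i.e.
    PLINK's (IBS2 + IBS1/2) / sites.  Diagonal is 1.  Pairs with no shared
    called site get NaN.
    """
    n = table.n_samples
    if n < 2:
        raise ValueError("IBS needs at least two samples")
    g = table.genotypes
    called = g[:, :, 0] != MISSING
    # shared-allele count between multisets {a1,a2} and {b1,b2}
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            if not both.any():
                continue
            a = np.sort(g[both, i, :], axis=1)
            b = np.sort(g[both, j, :], axis=1)
            eq_sorted = (a == b).sum(axis=1)
            # sorted elementwise equality equals multiset intersection size
            # for 2-element multisets except the {x,y} vs {y,x}... sorted fixes it
            cross = ((a[:, 0] == b[:, 1]) | (a[:, 1] == b[:, 0])) & (eq_sorted == 0)
            shared = eq_sorted + cross.astype(int)
            out[i, j] = out[j, i] = shared.mean() / 2.0
    return out


def prune_related(
    matrix: np.ndarray, samples: list[str], threshold: float = 0.9
) -> tuple[list[str], list[str]]:
    """Greedily drop one member of each sample pair with IBS > ``threshold``.

    While any surviving pair exceeds the threshold, the member of the
    worst (highest-IBS) pair with the higher overall mean IBS is dropped;
    ties go to the lexicographically later sample id.
    """
    active = list(range(len(samples)))
    dropped: list[str] = []
    m = np.array(matrix, dtype=float)
    while True:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                v = m[i, j]
                if np.isnan(v) or v <= threshold:
                    continue
                if best is None or v > best[0]:
                    best = (v, i, j)
        if best is None:
            break
        _, i, j = best
        mean_i = np.nanmean([m[i, k] for k in active if k != i])
        mean_j = np.nanmean([m[j, k] for k in active if k != j])
        if mean_i > mean_j:
            victim = i
        elif mean_j > mean_i:
            victim = j
        else:
            victim = i if samples[i] > samples[j] else j
        active.remove(victim)
        dropped.append(samples[victim])
    return [samples[k] for k in active], dropped


def biallelic_snps(table: VariantTable) -> VariantTable:
    """Convenience: restrict to SNP sites with at most two observed alleles."""
    mask = (table.vclass == "snp") & (table.n_observed_alleles() <= 2)
    return table.take_sites(mask)
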