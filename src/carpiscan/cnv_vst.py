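"""Read depth -> integer copy number, gene-level aggregation, V_ST
differentiation with permutation significance, and gain/loss classification.

Copy-number calling is a median-ratio scheme: within each sample, a window's
copy number is round(ploidy * depth / median window depth of that sample),
optionally after GC correction (depth divided by the median depth of windows
in the same 1%-GC bin).  This deliberately replaces segmentation-based CNV
callers with a transparent per-window estimator suited to window-level
differentiation scans.

V_ST is the copy-number analogue of F_ST: (V_T - V_S) / V_T, where V_T is
the variance of copy number over all samples pooled and V_S the
size-weighted mean of the within-population variances (population-variance
denominator N throughout).  Significance comes from permuting population
labels.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .core_io import DepthMatrix, GeneTable, PopulationMap, WindowSet, genes_to_windows


@dataclass
class CopyNumberMatrix:
    """Windows x samples integer copy numbers (and optionally gene averages)."""

    windows: WindowSet
    cn: pd.DataFrame  # integer CN, columns = samples
    ploidy: int = 2

    @property
    def samples(self) -> list[str]:
        return list(self.cn.columns)


def depth_to_copynumber(
    depths: DepthMatrix,
    ploidy: int = 2,
    gc: np.ndarray | None = None,
) -> CopyNumberMatrix:
    """Median-ratio integer copy-number calls per window per sample.

    CN_ws = round(ploidy * d_ws / median_w(d_.s)).  With ``gc`` (per-window GC
    fraction) each depth is first divided by the median depth of windows in
    the same 1%-GC bin (per sample) and the ratio is then taken against 1.
    Raises for any sample whose median depth is zero.
    """
    d = depths.depth.to_numpy(dtype=float)
    if gc is not None:
        bins = np.clip((np.asarray(gc) * 100).astype(int), 0, 100)
        norm = np.empty_like(d)
        for b in np.unique(bins):
            rows = bins == b
            med = np.median(d[rows], axis=0)
            if np.any(med == 0):
                raise ValueError("zero median depth in a GC bin")
            norm[rows] = d[rows] / med
        ratio = norm / np.median(norm, axis=0)
    else:
        med = np.median(d, axis=0)
        zero = np.flatnonzero(med == 0)
        if len(zero):
            bad = [depths.samples[i] for i in zero]
            raise ValueError(f"zero median depth for samples: {bad}")
        ratio = d / med
    cn = np.rint(ploidy * ratio).astype(int)
    cn = np.maximum(cn, 0)
    return CopyNumberMatrix(depths.windows, pd.DataFrame(cn, columns=depths.samples), ploidy)


def gene_copynumber(cnm: CopyNumberMatrix, genes: GeneTable) -> pd.DataFrame:
    """Gene x sample mean copy number over the windows overlapping each gene.

    Genes overlapping no window get NaN.
    """
    mapping = genes_to_windows(genes, cnm.windows)
    cn = cnm.cn.to_numpy(dtype=float)
    rows = []
    for gid in genes.gene_id:
        widx = mapping[str(gid)]
        rows.append(cn[widx].mean(axis=0) if len(widx) else np.full(cn.shape[1], np.nan))
    return pd.DataFrame(rows, index=[str(g) for g in genes.gene_id], columns=cnm.samples)


def _pop_columns(popmap: PopulationMap, samples: list[str], pops: list[str]) -> list[np.ndarray]:
    return [np.asarray(popmap.indices_of(p, samples)) for p in pops]


def vst(values: np.ndarray, group_a: np.ndarray, group_b: np.ndarray) -> float:
    """V_ST for one gene: (V_T - V_S) / V_T, NaN when V_T = 0.

    ``values`` is the per-sample copy number; ``group_a``/``group_b`` index
    the two populations.  Variances use denominator N.  Reported unclamped
    (slightly negative values are possible and meaningful).
    """
    a = np.asarray(values, dtype=float)[group_a]
    b = np.asarray(values, dtype=float)[group_b]
    pooled = np.concatenate([a, b])
    vt = pooled.var()
    if vt == 0:
        return float("nan")
    vs = (a.var() * len(a) + b.var() * len(b)) / (len(a) + len(b))
    return float((vt - vs) / vt)


@dataclass
class VstResult:
    """Per-gene V_ST with its permutation threshold and significance flag."""

    table: pd.DataFrame  # gene, vst, threshold, significant, mean_a, mean_b
    n_perm: int
    quantile: float


def vst_permutation_test(
    gene_cn: pd.DataFrame,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    n_perm: int = 1000,
    quantile: float = 0.99,
    seed: int | None = None,
) -> VstResult:
    """Label-permutation significance test of per-gene V_ST.

    For each gene, population labels are permuted ``n_perm`` times (sizes
    preserved, independent permutations per gene); the threshold is the
    ``quantile`` of the permuted V_ST values and a gene is significant iff
    its observed V_ST exceeds the threshold.  Deterministic under a fixed
    seed.  Genes with constant copy number are reported NaN / not significant.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation threshold", stacklevel=2)
    samples = list(gene_cn.columns)
    ga, gb = _pop_columns(popmap, samples, [pop_a, pop_b])
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each population needs >= 2 samples for V_ST")
    cols = np.concatenate([ga, gb])
    na = len(ga)
    rng = np.random.default_rng(seed)
    x = gene_cn.to_numpy(dtype=float)[:, cols]  # genes x (na+nb)
    ntot = x.shape[1]

    def _vst_rows(vals: np.ndarray, asel: np.ndarray) -> np.ndarray:
        # vals: (k, ntot); asel: (k, ntot) bool marking population A
        vt = vals.var(axis=1)
        mean_a = np.where(asel, vals, 0).sum(axis=1) / na
        mean_b = np.where(~asel, vals, 0).sum(axis=1) / (ntot - na)
        va = (np.where(asel, (vals - mean_a[:, None]) ** 2, 0).sum(axis=1)) / na
        vb = (np.where(~asel, (vals - mean_b[:, None]) ** 2, 0).sum(axis=1)) / (ntot - na)
        vs = (va * na + vb * (ntot - na)) / ntot
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(vt > 0, (vt - vs) / vt, np.nan)

    obs_sel = np.zeros((x.shape[0], ntot), dtype=bool)
    obs_sel[:, :na] = True
    observed = _vst_rows(x, obs_sel)
    mean_a = x[:, :na].mean(axis=1)
    mean_b = x[:, na:].mean(axis=1)

    thresholds = np.full(x.shape[0], np.nan)
    for g in range(x.shape[0]):
        vals = np.broadcast_to(x[g], (n_perm, ntot))
        order = np.argsort(rng.random((n_perm, ntot)), axis=1)
        asel = order < na  # each row: a uniform random subset of size na marks pop A
        perm = _vst_rows(vals, asel)
        finite = perm[~np.isnan(perm)]
        if len(finite):
            thresholds[g] = np.quantile(finite, quantile, method="higher")
    significant = ~np.isnan(observed) & ~np.isnan(thresholds) & (observed > thresholds)
    table = pd.DataFrame(
        {
            "gene": gene_cn.index,
            "vst": observed,
            "threshold": thresholds,
            "significant": significant,
            f"mean_{pop_a}": mean_a,
            f"mean_{pop_b}": mean_b,
        }
    ).set_index("gene")
    return VstResult(table, n_perm, quantile)


def classify_cnv_genes(
    gene_cn: pd.DataFrame, popmap: PopulationMap, ploidy: int = 2
) -> pd.DataFrame:
    """Per-population mean counts of duplicated and absent genes.

    Per sample (on rounded gene copy number), a gene is duplicated iff
    CN >= ploidy + 1 and absent iff CN == 0; the population value is the mean
    count over its samples.
    """
    samples = list(gene_cn.columns)
    cn = np.rint(gene_cn.to_numpy(dtype=float))
    dup = np.nansum(cn >= ploidy + 1, axis=0)
    absent = np.nansum((cn == 0) & ~np.isnan(cn), axis=0)
    per_sample = pd.DataFrame({"duplicated": dup, "absent": absent}, index=samples)
    rows = []
    for pop in popmap.populations():
        idx = popmap.indices_of(pop, samples)
        if not idx:
            continue
        rows.append((pop, per_sample.iloc[idx]["duplicated"].mean(), per_sample.iloc[idx]["absent"].mean()))
    return pd.DataFrame(rows, columns=["population", "mean_duplicated", "mean_absent"]).set_index("population")
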