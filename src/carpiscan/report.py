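"""Pipeline orchestration, cross-scan overlap statistics and output tables."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from . import __version__
from .core_io import GeneTable, PopulationMap, WindowSet, genes_to_windows, make_windows, read_vcf

log = logging.getLogger("carpiscan")


def overlap_chisq(
    flags_a: np.ndarray | int,
    flags_b: np.ndarray | int,
    total_windows: int | None = None,
    n_both: int | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Yates-corrected chi-square test of association between two window flag
    sets over the same windows.

    Accepts either boolean flag arrays over a common WindowSet, or printed
    counts (``flags_a``/``flags_b`` as totals, with ``n_both`` and
    ``total_windows``).  Returns (2x2 table, chi2, upper-tail p).  The
    statistic is two-sided in the association sense: a deficit of overlap is
    detected exactly like an excess.  Raises when any expected count is zero.
    """
    if isinstance(flags_a, (int, np.integer)):
        if total_windows is None or n_both is None:
            raise ValueError("count form needs n_both and total_windows")
        a_total, b_total = int(flags_a), int(flags_b)
        both = int(n_both)
    else:
        fa = np.asarray(flags_a, dtype=bool)
        fb = np.asarray(flags_b, dtype=bool)
        if fa.shape != fb.shape:
            raise ValueError("flag arrays must align over the same windows")
        total_windows = len(fa)
        a_total, b_total = int(fa.sum()), int(fb.sum())
        both = int((fa & fb).sum())
    a_only = a_total - both
    b_only = b_total - both
    neither = total_windows - both - a_only - b_only
    table = pd.DataFrame(
        [[both, a_only], [b_only, neither]],
        index=["B_flagged", "B_not"],
        columns=["A_flagged", "A_not"],
    )
    obs = table.to_numpy()
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("a margin of the 2x2 table is zero; expected counts undefined")
    chi2, p, _, expected = chi2_contingency(obs, correction=True)
    if (expected == 0).any():
        raise ValueError("zero expected count in the 2x2 table")
    return table, float(chi2), float(p)


def annotate_outliers(track: pd.DataFrame, genes: GeneTable) -> tuple[pd.DataFrame, dict[str, int]]:
    """Report flagged windows with their overlapping gene ids.

    Returns a table with one row per flagged window (gene ids comma-joined)
    and summary counts of flagged windows and distinct overlapping genes.
    """
    flagged = track[track.get("outlier", pd.Series(False, index=track.index)).astype(bool)]
    rows = []
    seen: set[str] = set()
    for _, w in flagged.iterrows():
        hit = [
            str(g)
            for g, c, s, e in zip(genes.gene_id, genes.contig, genes.start, genes.end)
            if c == w["contig"] and s < w["end"] and e > w["start"]
        ]
        seen.update(hit)
        rows.append({**{k: w[k] for k in ("contig", "start", "end", "value", "z", "p") if k in w},
                     "genes": ",".join(hit)})
    cols = [c for c in ("contig", "start", "end", "value", "z", "p", "genes") if c in (rows[0] if rows else {"contig": 0, "start": 0, "end": 0, "genes": 0})]
    out = pd.DataFrame(rows, columns=cols if rows else ["contig", "start", "end", "genes"])
    summary = {"n_outlier_windows": len(flagged), "n_distinct_genes": len(seen)}
    return out, summary


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: dict[str, Any], outdir: str | Path) -> Path:
    """Run the full scan pipeline on a VCF + population map + depth table.

    ``config`` keys: vcf, pops (TSV path), outgroups (list, optional),
    pop_a, pop_b (focal pair), quartet {p1,p2,p3,outgroup} (optional),
    depths (TSV, optional), genes (BED, optional), window, step, alpha,
    perms, blocks, seed.  Stages run in a fixed order (filter, diversity,
    fst, abba, xpehh, vst, struct, overlap); each writes one TSV and a
    failure aborts naming the stage.  A JSON manifest records parameters,
    seed and input checksums.
    """
    from . import cnv_vst, divergence, diversity, introgression, popstruct, qc_filter, selection_ehh

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    window = int(config.get("window", 50_000))
    step = int(config.get("step", window))
    alpha = float(config.get("alpha", 0.05))
    seed = int(config.get("seed", 0))

    popmap = PopulationMap.from_tsv(config["pops"], outgroups=config.get("outgroups", ()))
    table = read_vcf(config["vcf"])
    popmap.validate(table.samples)
    for key in ("pop_a", "pop_b"):
        if config.get(key) and not popmap.samples_of(config[key]):
            raise ValueError(f"population {config[key]!r} ({key}) has no samples")

    manifest: dict[str, Any] = {
        "tool": "carpiscan",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "parameters": {k: v for k, v in config.items() if not isinstance(v, (list, dict))},
        "inputs": {k: _checksum(Path(config[k])) for k in ("vcf", "pops", "depths", "genes")
                   if config.get(k) and Path(config[k]).exists()},
        "stages": [],
    }

    def stage(name: str, fn):
        log.info("stage %s", name)
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - abort naming the stage
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(name)
        return result

    genes = GeneTable.from_bed(config["genes"]) if config.get("genes") else None

    # ---- filter ---------------------------------------------------------
    def _filter():
        snps = table.take_sites(table.vclass == "snp")
        indels = table.take_sites(table.vclass == "indel")
        snps, rep1 = qc_filter.hard_filter_snps(snps)
        indels, rep2 = qc_filter.hard_filter_indels(indels)
        if "DP" in snps.info:
            snps, rep3 = qc_filter.site_level_filter(snps)
        snps, rep4 = qc_filter.indel_proximity_filter(snps, indels)
        snps = qc_filter.biallelic_snps(snps)
        pd.DataFrame([
            {"stage": "snp_hard", **rep1.removed_by, "kept": rep1.n_out},
            {"stage": "indel_hard", **rep2.removed_by, "kept": rep2.n_out},
            {"stage": "near_indel", **rep4.removed_by, "kept": rep4.n_out},
        ]).to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
        return snps

    snps = stage("filter", _filter)
    lengths = {c: int(snps.pos[snps.contig == c].max()) + 1 for c in np.unique(snps.contig)}
    windows = make_windows(lengths, window, step)

    # ---- diversity ------------------------------------------------------
    def _diversity():
        frames = []
        for pop in popmap.populations():
            if pop in popmap.outgroups:
                continue
            pi = diversity.window_pi(snps, windows, popmap, pop)
            td = diversity.window_tajima(snps, windows, popmap, pop)
            f = pi.rename(columns={"value": "pi"})
            f["tajima_d"] = td["value"]
            f["population"] = pop
            frames.append(f)
        pd.concat(frames).to_csv(outdir / "pi_tajima.tsv", sep="\t", index=False)

    stage("diversity", _diversity)

    # ---- fst ------------------------------------------------------------
    fst_track = None
    if config.get("pop_a") and config.get("pop_b"):
        def _fst():
            tr = divergence.window_fst(snps, windows, popmap, config["pop_a"], config["pop_b"])
            tr = divergence.z_outliers(tr, alpha=alpha, tail="upper")
            tr.to_csv(outdir / "fst.tsv", sep="\t", index=False)
            return tr
        fst_track = stage("fst", _fst)

    # ---- abba -----------------------------------------------------------
    if config.get("quartet"):
        def _abba():
            q = config["quartet"]
            qs = introgression.quartet_frequencies(
                snps, popmap, q["p1"], q["p2"], q["p3"], q["outgroup"])
            tr = introgression.windowed_d_fd(qs, windows)
            jk = introgression.d_with_jackknife(qs, n_blocks=int(config.get("blocks", 50)))
            tr.to_csv(outdir / "dstats.tsv", sep="\t", index=False)
            manifest["d_statistic"] = {"D": jk.estimate, "se": jk.se, "z": jk.z, "p": jk.p}
        stage("abba", _abba)

    # ---- xpehh ----------------------------------------------------------
    xp_track = None
    if config.get("pop_a") and config.get("pop_b") and bool(snps.phased.all()):
        def _xpehh():
            frames = []
            for contig in np.unique(snps.contig):
                pa = selection_ehh.HaplotypePanel.from_table(snps, popmap, config["pop_a"], contig=contig)
                pb = selection_ehh.HaplotypePanel.from_table(snps, popmap, config["pop_b"], contig=contig)
                frames.append(selection_ehh.xpehh_scan(pa, pb))
            scores = pd.concat(frames, ignore_index=True)
            tr = selection_ehh.normalize_and_window(scores, windows, alpha=alpha)
            tr.to_csv(outdir / "xpehh.tsv", sep="\t", index=False)
            return tr
        xp_track = stage("xpehh", _xpehh)

    # ---- vst ------------------------------------------------------------
    if config.get("depths") and genes is not None and config.get("pop_a") and config.get("pop_b"):
        def _vst():
            from .core_io import DepthMatrix
            dm = DepthMatrix.from_tsv(config["depths"])
            cnm = cnv_vst.depth_to_copynumber(dm)
            gcn = cnv_vst.gene_copynumber(cnm, genes)
            res = cnv_vst.vst_permutation_test(
                gcn, popmap, config["pop_a"], config["pop_b"],
                n_perm=int(config.get("perms", 1000)), seed=seed)
            res.table.to_csv(outdir / "vst.tsv", sep="\t")
        stage("vst", _vst)

    # ---- struct ---------------------------------------------------------
    def _struct():
        tree = popstruct.nj_from_table(snps)
        (outdir / "nj_tree.nwk").write_text(tree.newick + "\n")
        coords, frac = popstruct.pca(snps)
        coords.to_csv(outdir / "pca.tsv", sep="\t")
        manifest["pca_explained"] = [float(f) for f in frac[:5]]

    stage("struct", _struct)

    # ---- overlap --------------------------------------------------------
    if fst_track is not None and xp_track is not None:
        def _overlap():
            table2, chi2, p = overlap_chisq(
                fst_track["outlier"].to_numpy(), xp_track["outlier"].to_numpy())
            manifest["overlap"] = {"chi2": chi2, "p": p,
                                   "table": table2.to_numpy().tolist()}
            if genes is not None:
                ann, summary = annotate_outliers(fst_track, genes)
                ann.to_csv(outdir / "fst_outlier_genes.tsv", sep="\t", index=False)
                manifest["fst_outliers"] = summary
        stage("overlap", _overlap)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
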