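"""Shared data model, VCF/BED/GFF/TSV input-output and genomic windows.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based inclusive convention happens only at the VCF/GFF boundary (BED is
already 0-based half-open).  Contig identifiers are opaque strings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: INFO keys carried through filtering (GATK hard-filter annotations).
INFO_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR")

MISSING = -1  # allele index for a missing call


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------


@dataclass
class VariantTable:
    """Sites x samples diploid genotype calls with site annotations.

    Attributes
    ----------
    contig : (n_sites,) str array
    pos : (n_sites,) int array, 0-based
    ref : (n_sites,) str array
    alt : (n_sites,) object array of tuples of alt allele strings
    vclass : (n_sites,) str array, ``"snp"`` or ``"indel"``
    qual : (n_sites,) float array (NaN when absent)
    info : mapping of INFO key -> (n_sites,) float array (NaN when absent);
        may also carry ``"DP"`` (total site depth)
    genotypes : (n_sites, n_samples, 2) int8, allele indices, -1 missing
    phased : (n_sites, n_samples) bool
    samples : list of sample ids
    """

    contig: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    vclass: np.ndarray
    qual: np.ndarray
    info: dict[str, np.ndarray]
    genotypes: np.ndarray
    phased: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must have shape (sites, samples, 2)")
        half = (self.genotypes == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("a call must be fully missing or fully present")
        for c in np.unique(self.contig):
            p = self.pos[self.contig == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take_sites(self, index: np.ndarray) -> "VariantTable":
        """Return a new table restricted to the given site mask/indices."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return VariantTable(
            contig=self.contig[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            vclass=self.vclass[idx],
            qual=self.qual[idx],
            info={k: v[idx] for k, v in self.info.items()},
            genotypes=self.genotypes[idx],
            phased=self.phased[idx],
            samples=list(self.samples),
        )

    def take_samples(self, names: Sequence[str]) -> "VariantTable":
        col = [self.samples.index(s) for s in names]
        return dataclasses.replace(
            self,
            genotypes=self.genotypes[:, col, :],
            phased=self.phased[:, col],
            samples=list(names),
        )

    # -- per-site summaries ------------------------------------------------

    def called_mask(self) -> np.ndarray:
        """(sites, samples) bool: both alleles present."""
        return self.genotypes[:, :, 0] != MISSING

    def allele_counts(self, sample_idx: Sequence[int] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (alt_count, called_allele_count) per site over a sample set.

        ``alt_count`` counts alleles with index >= 1 (any non-reference allele),
        which is the alt dosage for biallelic sites.
        """
        g = self.genotypes if sample_idx is None else self.genotypes[:, list(sample_idx), :]
        called = g != MISSING
        return ((g > 0) & called).sum(axis=(1, 2)), called.sum(axis=(1, 2))

    def n_observed_alleles(self) -> np.ndarray:
        """Number of distinct allele indices observed in called genotypes, per site."""
        out = np.zeros(self.n_sites, dtype=int)
        for i in range(self.n_sites):
            g = self.genotypes[i]
            g = g[g != MISSING]
            out[i] = len(np.unique(g))
        return out


@dataclass
class PopulationMap:
    """Sample -> population label map; outgroup labels are distinguished."""

    labels: dict[str, str]
    outgroups: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.outgroups = frozenset(self.outgroups)

    @classmethod
    def from_tsv(cls, path: str | Path, outgroups: Iterable[str] = ()) -> "PopulationMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str, comment="#")
        return cls(dict(zip(df["sample"], df["population"])), frozenset(outgroups))

    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.labels.values():
            if p not in seen:
                seen.append(p)
        return seen

    def samples_of(self, population: str | Iterable[str]) -> list[str]:
        pops = {population} if isinstance(population, str) else set(population)
        return [s for s, p in self.labels.items() if p in pops]

    def indices_of(self, population: str | Iterable[str], samples: Sequence[str]) -> list[int]:
        """Column indices of a population's samples within a sample list."""
        want = set(self.samples_of(population))
        return [i for i, s in enumerate(samples) if s in want]

    def validate(self, samples: Sequence[str]) -> None:
        missing = [s for s in samples if s not in self.labels]
        if missing:
            raise ValueError(f"samples without population label: {missing}")


@dataclass
class WindowSet:
    """Genomic windows, 0-based half-open, never crossing contig boundaries."""

    contig: np.ndarray
    start: np.ndarray
    end: np.ndarray
    size: int
    step: int

    def __len__(self) -> int:
        return len(self.start)

    def __iter__(self):
        return zip(self.contig, self.start, self.end)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"contig": self.contig, "start": self.start, "end": self.end})

    def assign_sites(self, contig: np.ndarray, pos: np.ndarray) -> list[np.ndarray]:
        """Per window, indices of the sites falling inside it.

        With ``step < size`` a site may belong to several windows.
        """
        out: list[np.ndarray] = []
        order = {}
        for c in np.unique(contig):
            order[c] = np.flatnonzero(contig == c)
        for c, s, e in self:
            idx = order.get(c)
            if idx is None:
                out.append(np.empty(0, dtype=int))
                continue
            p = pos[idx]
            out.append(idx[(p >= s) & (p < e)])
        return out


@dataclass
class GeneTable:
    """Gene spans, 0-based half-open."""

    gene_id: np.ndarray
    contig: np.ndarray
    start: np.ndarray
    end: np.ndarray

    def __len__(self) -> int:
        return len(self.gene_id)

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneTable":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2, 3], names=["contig", "start", "end", "name"])
        return cls(df["name"].astype(str).to_numpy(), df["contig"].astype(str).to_numpy(),
                   df["start"].to_numpy(np.int64), df["end"].to_numpy(np.int64))

    @classmethod
    def from_gff3(cls, path: str | Path) -> "GeneTable":
        """Read ``gene`` features from a GFF3 file (1-based inclusive -> half-open)."""
        ids, contigs, starts, ends = [], [], [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                ids.append(attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}"))
                contigs.append(f[0])
                starts.append(int(f[3]) - 1)
                ends.append(int(f[4]))
        return cls(np.array(ids), np.array(contigs),
                   np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64))


def scan_track(windows: WindowSet, value: np.ndarray, n_sites: np.ndarray) -> pd.DataFrame:
    """Assemble a genome-scan result table (ScanTrack).

    Windows with zero contributing sites carry NaN, never zero.
    """
    value = np.asarray(value, dtype=float).copy()
    n_sites = np.asarray(n_sites)
    value[n_sites == 0] = np.nan
    df = windows.to_frame()
    df["n_sites"] = n_sites
    df["value"] = value
    return df


@dataclass
class DepthMatrix:
    """Windows x samples mean read depth (reads per base)."""

    windows: WindowSet
    depth: pd.DataFrame  # columns = samples, rows aligned with windows

    def __post_init__(self) -> None:
        if len(self.depth) != len(self.windows):
            raise ValueError("depth rows must match windows")
        if (self.depth.to_numpy() < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.depth.columns)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DepthMatrix":
        df = pd.read_csv(path, sep="\t")
        meta = df[["contig", "start", "end"]]
        depth = df.drop(columns=["contig", "start", "end"])
        sizes = (meta["end"] - meta["start"]).to_numpy()
        size = int(sizes.max()) if len(sizes) else 0
        starts = meta["start"].to_numpy()
        step = int(np.diff(starts[meta["contig"] == meta["contig"].iloc[0]]).min()) if len(meta) > 1 else size
        ws = WindowSet(meta["contig"].to_numpy(dtype=object), meta["start"].to_numpy(np.int64),
                       meta["end"].to_numpy(np.int64), size=size, step=max(step, 1))
        return cls(ws, depth)

    def to_tsv(self, path: str | Path) -> None:
        out = self.windows.to_frame()
        out = pd.concat([out, self.depth.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------


def _vclass(ref: str, alts: tuple[str, ...]) -> str:
    if len(ref) == 1 and all(len(a) == 1 for a in alts):
        return "snp"
    return "indel"


def read_vcf(path: str | Path, samples: Sequence[str] | None = None) -> VariantTable:
    """Read a VCF 4.x file into a :class:`VariantTable`.

    Multi-allelic records are preserved; ``vclass`` is set from ref/alt
    lengths.  Raises ``ValueError`` naming the offending record on malformed
    input, and if the file carries no GT FORMAT field.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False, samples=list(samples) if samples else None)
    sample_names = list(vcf.samples)
    contigs, poss, refs, alts, vclasses, quals = [], [], [], [], [], []
    info: dict[str, list[float]] = {k: [] for k in INFO_KEYS + ("DP",)}
    gts, phs = [], []
    for i, rec in enumerate(vcf):
        if rec.REF is None or rec.ALT is None:
            raise ValueError(f"malformed VCF record at line entry {i + 1} ({rec.CHROM}:{rec.POS})")
        contigs.append(rec.CHROM)
        poss.append(rec.POS - 1)  # to 0-based
        refs.append(rec.REF)
        alt = tuple(rec.ALT)
        alts.append(alt)
        vclasses.append(_vclass(rec.REF, alt))
        quals.append(np.nan if rec.QUAL is None else float(rec.QUAL))
        for k in info:
            v = rec.INFO.get(k)
            info[k].append(np.nan if v is None else float(v))
        g = rec.genotype.array()  # (samples, 3): allele1, allele2, phased
        if g is None:
            raise ValueError(f"record {rec.CHROM}:{rec.POS} lacks GT")
        a = g[:, :2].astype(np.int8)
        a[a < 0] = MISSING
        # half-missing calls are treated as fully missing
        half = (a == MISSING).any(axis=1)
        a[half] = MISSING
        gts.append(a)
        phs.append(g[:, 2].astype(bool))
    n = len(poss)
    info_arr = {k: np.asarray(v, dtype=float) for k, v in info.items() if not np.all(np.isnan(v))}
    return VariantTable(
        contig=np.asarray(contigs, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        vclass=np.asarray(vclasses, dtype=object),
        qual=np.asarray(quals, dtype=float),
        info=info_arr,
        genotypes=np.stack(gts) if n else np.empty((0, len(sample_names), 2), dtype=np.int8),
        phased=np.stack(phs) if n else np.empty((0, len(sample_names)), dtype=bool),
        samples=sample_names,
    )


def write_vcf(table: VariantTable, path: str | Path) -> None:
    """Write a VariantTable as VCF 4.2 (GT plus the retained INFO keys)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=carpiscan\n')
        for c in pd.unique(table.contig):
            length = int(table.pos[table.contig == c].max()) + 2 if table.n_sites else 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        for k in INFO_KEYS:
            fh.write(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.samples) + "\n")
        for i in range(table.n_sites):
            qual = "." if np.isnan(table.qual[i]) else f"{table.qual[i]:g}"
            pairs = []
            for k, arr in table.info.items():
                if not np.isnan(arr[i]):
                    v = arr[i]
                    pairs.append(f"{k}={int(v)}" if k == "DP" else f"{k}={v:g}")
            info = ";".join(pairs) if pairs else "."
            cols = [
                str(table.contig[i]), str(table.pos[i] + 1), ".", str(table.ref[i]),
                ",".join(table.alt[i]) or ".", qual, ".", info, "GT",
            ]
            for j in range(table.n_samples):
                a, b = table.genotypes[i, j]
                sep = "|" if table.phased[i, j] else "/"
                cols.append("./." if a == MISSING else f"{a}{sep}{b}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def make_windows(contig_lengths: Mapping[str, int], size: int, step: int | None = None) -> WindowSet:
    """Tile each contig with windows ``[k*step, k*step + size)`` clipped at the
    contig end.  A window is emitted iff its start is < the contig length.
    """
    step = size if step is None else step
    if step < 1 or size < 1:
        raise ValueError("size and step must be >= 1")
    if step > size:
        raise ValueError("step must not exceed size (windows would skip bases)")
    contigs, starts, ends = [], [], []
    for c, length in contig_lengths.items():
        for s in range(0, max(int(length), 0), step):
            contigs.append(c)
            starts.append(s)
            ends.append(min(s + size, int(length)))
    return WindowSet(np.asarray(contigs, dtype=object), np.asarray(starts, dtype=np.int64),
                     np.asarray(ends, dtype=np.int64), size=size, step=step)


def genes_to_windows(genes: GeneTable, windows: WindowSet) -> dict[str, np.ndarray]:
    """Map each gene to the indices of windows it overlaps (half-open intersection)."""
    out: dict[str, np.ndarray] = {}
    wc, ws, we = windows.contig, windows.start, windows.end
    for gid, c, s, e in zip(genes.gene_id, genes.contig, genes.start, genes.end):
        hit = np.flatnonzero((wc == c) & (ws < e) & (we > s))
        out[str(gid)] = hit
    return out
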