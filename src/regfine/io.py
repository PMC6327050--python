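"""Readers and writers for the pipeline's plain-text interchange formats.

Genotypes travel as long-format TSV (sample, variant, hard_call, dosage,
p0, p1, p2) or VCF (GT and, when present, GP fields via pysam); expression
as gene x sample TSV in TPM; peaks as BED (0-based half-open); TSSs,
pileups, copy-number calls, Hi-C contact triples and qPCR Cq tables as
simple TSVs; sequences as FASTA via Biopython.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .allelic import PileupRecord
from .annotate import GenomicInterval, TssRecord

GENO_COLUMNS = ["sample", "variant", "hard_call", "dosage", "p0", "p1", "p2"]


def write_genotype_tsv(path, genotypes: pd.DataFrame,
                       posteriors: dict[str, np.ndarray] | None = None) -> None:
    """Write a samples x variants dosage table in long format."""
    rows = []
    for vi, var in enumerate(genotypes.columns):
        for si, (sample, dosage) in enumerate(genotypes[var].items()):
            p = posteriors[var][si] if posteriors else (np.nan, np.nan, np.nan)
            rows.append((sample, var, int(dosage), float(dosage), *p))
    pd.DataFrame(rows, columns=GENO_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path):
    """Read long-format genotypes; returns (dosage DataFrame, posteriors dict)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(GENO_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"genotype TSV lacks columns: {sorted(missing)}")
    wide = df.pivot(index="sample", columns="variant", values="dosage")
    posteriors = {}
    if {"p0", "p1", "p2"} <= set(df.columns) and df["p0"].notna().any():
        for var, grp in df.groupby("variant", sort=False):
            posteriors[var] = grp[["p0", "p1", "p2"]].to_numpy(dtype=float)
    return wide, posteriors or None


def read_vcf_genotypes(path):
    """Dosages (and GP posteriors when present) from a VCF via pysam."""
    import pysam

    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    dosages: dict[str, list[float]] = {}
    posteriors: dict[str, np.ndarray] = {}
    for rec in vcf:
        vid = rec.id or f"{rec.chrom}:{rec.pos}"
        dos, gps = [], []
        for s in samples:
            call = rec.samples[s]
            gt = call.get("GT")
            dos.append(sum(1 for a in gt if a == 1) if gt and None not in gt else np.nan)
            if "GP" in call:
                gps.append(list(call["GP"]))
        dosages[vid] = dos
        if gps and len(gps) == len(samples):
            posteriors[vid] = np.asarray(gps, dtype=float)
    vcf.close()
    return pd.DataFrame(dosages, index=samples), posteriors or None


def write_expression_tsv(path, expr: pd.DataFrame) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene ids in expression matrix: {dupes[:10]}")
    return df


def write_bed(path, intervals: list[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line has fewer than 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: BED start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 else ""
            out.append(GenomicInterval(chrom, start, end, name=name))
    return out


def write_tss_tsv(path, tss: list[TssRecord]) -> None:
    pd.DataFrame([{"gene": t.gene, "chrom": t.chrom, "position": t.position,
                   "strand": t.strand} for t in tss]).to_csv(path, sep="\t", index=False)


def read_tss_tsv(path) -> list[TssRecord]:
    df = pd.read_csv(path, sep="\t")
    return [TssRecord(r.gene, r.chrom, int(r.position), getattr(r, "strand", "+"))
            for r in df.itertuples(index=False)]


def write_pileup_tsv(path, records: list[PileupRecord]) -> None:
    pd.DataFrame([{"chrom": r.chrom, "pos": r.pos, "base": r.base,
                   "baseq": r.baseq, "mapq": r.mapq, "read_id": r.read_id}
                  for r in records]).to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path) -> list[PileupRecord]:
    df = pd.read_csv(path, sep="\t")
    return [PileupRecord(r.chrom, int(r.pos), str(r.base), int(r.baseq),
                         int(r.mapq), str(r.read_id))
            for r in df.itertuples(index=False)]


def write_contacts_tsv(path, contacts: pd.DataFrame, chrom: str, resolution: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# chrom={chrom} resolution={resolution}\n")
        contacts.to_csv(fh, sep="\t", index=False)


def read_contacts_tsv(path):
    """Returns (contacts DataFrame, chrom, resolution) from a bin-pair TSV."""
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        df = pd.read_csv(fh, sep="\t")
    return df, meta["chrom"], int(meta["resolution"])


def write_fasta(path, sequences: dict[str, str]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_copy_number_tsv(path) -> dict[str, dict[str, int]]:
    """sample/chrom/copy_number TSV -> nested mapping sample -> chrom -> cn."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, int]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.sample), {})[str(r.chrom)] = int(r.copy_number)
    return out


def read_cq_tsv(path) -> pd.DataFrame:
    """qPCR table with columns target/condition/replicate/cq."""
    df = pd.read_csv(path, sep="\t")
    missing = {"target", "condition", "cq"} - set(df.columns)
    if missing:
        raise ValueError(f"Cq table lacks columns: {sorted(missing)}")
    return df
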