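"""File-format helpers: FASTA, BED, minimal two-sample VCF, TSV, JSON.

Genomes travel as FASTA (via Biopython), annotations as 6-column BED
(0-based half-open, name = family:completeness:locus_id), informative
variants as a minimal two-sample VCF or TSV, read observations and depth
tracks as TSV, and run manifests as JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import Genome, ReadObservation, seq_to_str, str_to_seq

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_bed",
    "read_bed",
    "write_variants_vcf",
    "read_variants_vcf",
    "write_reads_tsv",
    "read_reads_tsv",
    "write_json",
    "file_digest",
]


def write_fasta(genome: Genome, path) -> None:
    records = [
        SeqRecord(Seq(seq_to_str(seq)), id=chrom, description="")
        for chrom, seq in genome.chroms.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path, name: str | None = None) -> Genome:
    chroms = {
        rec.id: str_to_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }
    return Genome(name or Path(path).stem, chroms)


def write_bed(annotations: pd.DataFrame, path) -> None:
    """BED6 with name = family:completeness:locus_id."""
    with open(path, "w") as fh:
        for _, r in annotations.iterrows():
            name = f"{r.family}:{r.completeness}:{r.locus_id}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")


def read_bed(path, source: str = "") -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            family, completeness, locus_id = name.split(":")
            rows.append(
                [chrom, int(start), int(end), strand.strip(), family,
                 completeness, source, locus_id]
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand", "family", "completeness",
                 "source", "locus_id"],
    )


def write_variants_vcf(variants: pd.DataFrame, path) -> None:
    """Minimal two-sample VCF of parental-discriminating sites."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\n")
        for _, v in variants.iterrows():
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t{v.var_id}\t{v.P1}\t{v.P2}"
                f"\t.\t.\t.\tGT\t0\t1\n"
            )


def read_variants_vcf(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append([f[2], f[0], int(f[1]) - 1, f[3], f[4]])
    return pd.DataFrame(rows, columns=["var_id", "chrom", "pos", "P1", "P2"])


def write_reads_tsv(reads, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttrue_origin\tlength\tobserved_alleles\n")
        for r in reads:
            obs = ";".join(f"{v}:{a}" for v, a in r.observed_alleles)
            fh.write(f"{r.read_id}\t{r.true_origin}\t{r.length}\t{obs}\n")


def read_reads_tsv(path) -> list:
    reads = []
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for _, r in df.iterrows():
        obs = []
        if r.observed_alleles:
            obs = [tuple(x.split(":")) for x in r.observed_alleles.split(";")]
        reads.append(
            ReadObservation(
                read_id=r.read_id,
                true_origin=r.true_origin or None,
                length=int(r.length),
                observed_alleles=obs,
            )
        )
    return reads


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
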