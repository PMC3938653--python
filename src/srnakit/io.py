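"""File-format helpers: FASTA/FASTQ via Biopython, BED-like annotation TSV.

Annotation intervals are 0-based half-open on disk and in memory; rendered
reports use 1-based coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: RNA class vocabulary for annotation features
CLASS_VOCAB = ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "scRNA",
               "srpRNA", "repeat", "exon", "intron")


@dataclass(frozen=True)
class AnnotatedLocus:
    """A genomic feature used for hierarchical tag classification."""

    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: str
    label: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.label not in CLASS_VOCAB:
            raise ValueError(f"unknown annotation class {self.label!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"malformed interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[str]:
    """Return the read sequences of a FASTQ file (qualities are ignored:
    the pipeline has no quality model)."""
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(path: str | Path, reads: Iterable[str], prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_annotation(path: str | Path) -> list[AnnotatedLocus]:
    """BED-like TSV: chrom, start, end, strand, class[, name]."""
    loci = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            loci.append(AnnotatedLocus(chrom=fields[0], start=int(fields[1]),
                                       end=int(fields[2]), strand=fields[3],
                                       label=fields[4],
                                       name=fields[5] if len(fields) > 5 else ""))
    return loci


def write_annotation(path: str | Path, loci: Iterable[AnnotatedLocus]) -> None:
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.strand}"
                     f"\t{loc.label}\t{loc.name}\n")
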