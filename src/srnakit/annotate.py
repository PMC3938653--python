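"""RNA-class annotation of mapped tags and known-miRNA identification.

Mapped tags are classified into ncRNA/repeat/exon/intron classes by
annotation overlap under a configurable priority order (each tag gets
exactly one class, the highest-priority one among all overlapping
features); tags matching a miRBase-style mature+precursor reference are
accumulated into known-miRNA expression records.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .genome_map import GenomeHit
from .io import AnnotatedLocus, CLASS_VOCAB, read_fasta
from .preprocess import TagSet
from .seqs import to_dna

#: highest first; exon/intron are split sense/antisense in summaries
DEFAULT_PRIORITY = ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "scRNA",
                    "srpRNA", "repeat", "exon", "intron")

#: summary row order, Table-style
SUMMARY_ROWS = ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "scRNA",
                "srpRNA", "repeat", "Exon_sense", "Exon_antisense",
                "Intron_sense", "Intron_antisense", "Unknown")


def _display_label(base: str, sense: bool) -> str:
    if base in ("exon", "intron"):
        return f"{base.capitalize()}_{'sense' if sense else 'antisense'}"
    return base


def classify_tags(hits: dict[str, list[GenomeHit]],
                  loci: list[AnnotatedLocus],
                  tags: TagSet,
                  priority: tuple[str, ...] = DEFAULT_PRIORITY,
                  ) -> tuple[dict[str, str], pd.DataFrame]:
    """Assign one RNA class to every mapped tag.

    Returns (per-tag class label, summary table with unique/total counts
    per class).  Exon and intron assignments are split by strand agreement
    into sense/antisense; tags overlapping no feature are 'Unknown'.
    """
    if set(priority) != set(CLASS_VOCAB):
        raise ValueError("priority must be a total order over the class vocabulary")
    rank = {c: i for i, c in enumerate(priority)}
    by_chrom: dict[str, list[AnnotatedLocus]] = defaultdict(list)
    for loc in loci:
        by_chrom[loc.chrom].append(loc)

    labels: dict[str, str] = {}
    for seq, tag_hits in hits.items():
        best: tuple[int, int, str] | None = None  # (rank, antisense, label)
        for hit in tag_hits:
            for loc in by_chrom.get(hit.chrom, ()):
                if hit.start < loc.end and loc.start < hit.end:
                    sense = hit.strand == loc.strand
                    key = (rank[loc.label], 0 if sense else 1,
                           _display_label(loc.label, sense))
                    if best is None or key < best:
                        best = key
        labels[seq] = best[2] if best is not None else "Unknown"

    rows = []
    for cls in SUMMARY_ROWS:
        member = [s for s, lab in labels.items() if lab == cls]
        rows.append({"class": cls, "unique": len(member),
                     "total": sum(tags[s].total for s in member)})
    summary = pd.DataFrame(rows).set_index("class")
    return labels, summary


@dataclass
class MirnaRecord:
    """A known mature miRNA with precursor context and expression."""

    name: str
    mature: str
    precursor: str
    mature_start: int  # 0-based within precursor
    family: str = ""
    counts: dict[str, int] = field(default_factory=dict)
    precursor_loci: list[GenomeHit] = field(default_factory=list)

    @property
    def mature_end(self) -> int:
        return self.mature_start + len(self.mature)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


class MirnaReference:
    """Paired mature/precursor reference; precursor ids are the mature id
    plus a ``_pre`` suffix and each mature must occur in its precursor."""

    def __init__(self, matures: dict[str, str], precursors: dict[str, str],
                 families: dict[str, str] | None = None) -> None:
        self.records: dict[str, MirnaRecord] = {}
        for name, mat in matures.items():
            pre_name = f"{name}_pre"
            if pre_name not in precursors:
                raise ValueError(f"no precursor {pre_name!r} for mature {name!r}")
            pre = to_dna(precursors[pre_name])
            mat = to_dna(mat)
            pos = pre.find(mat)
            if pos < 0:
                raise ValueError(f"mature {name!r} absent from its precursor")
            self.records[name] = MirnaRecord(
                name=name, mature=mat, precursor=pre, mature_start=pos,
                family=(families or {}).get(name, ""))

    @classmethod
    def from_fasta(cls, mature_path, precursor_path,
                   families: dict[str, str] | None = None) -> "MirnaReference":
        return cls(read_fasta(mature_path), read_fasta(precursor_path), families)


@dataclass(frozen=True)
class KnownAssignment:
    """One tag assigned to a known miRNA, with end offsets relative to the
    annotated mature span within the precursor (isomiR bookkeeping)."""

    tag: str
    name: str
    offset5: int
    offset3: int


def match_known(tags: TagSet, reference: MirnaReference,
                tolerance: int = 4,
                ) -> tuple[dict[str, MirnaRecord], dict[str, KnownAssignment]]:
    """Assign tags to known miRNAs by exact placement within a precursor.

    A tag is assigned when it occurs verbatim in a precursor and both its
    ends are within ``tolerance`` nt of the annotated mature ends (isomiRs
    admitted).  A tag matching several matures goes to the placement with
    the smallest total end offset, ties broken by name.  Counts accumulate
    per mature per library.
    """
    records = {name: MirnaRecord(name=r.name, mature=r.mature,
                                 precursor=r.precursor,
                                 mature_start=r.mature_start, family=r.family)
               for name, r in reference.records.items()}
    assignment: dict[str, KnownAssignment] = {}
    for seq, tag in tags.items():
        best: tuple[int, str, int, int] | None = None
        for name, rec in reference.records.items():
            start = rec.precursor.find(seq)
            while start >= 0:
                off5 = start - rec.mature_start
                off3 = (start + len(seq)) - rec.mature_end
                if abs(off5) <= tolerance and abs(off3) <= tolerance:
                    key = (abs(off5) + abs(off3), name, off5, off3)
                    if best is None or key < best:
                        best = key
                start = rec.precursor.find(seq, start + 1)
        if best is not None:
            _, name, off5, off3 = best
            assignment[seq] = KnownAssignment(tag=seq, name=name,
                                              offset5=off5, offset3=off3)
            for lib, n in tag.counts.items():
                records[name].counts[lib] = records[name].counts.get(lib, 0) + n
    return records, assignment


def chromosome_density(loci_per_chrom: dict[str, int],
                       chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """miRNA loci per chromosome and per Mbp of chromosome sequence."""
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"zero-length chromosome {chrom!r}")
        n = loci_per_chrom.get(chrom, 0)
        rows.append({"chrom": chrom, "loci": n, "length_bp": length,
                     "per_mbp": n / (length / 1e6)})
    return pd.DataFrame(rows).set_index("chrom")
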