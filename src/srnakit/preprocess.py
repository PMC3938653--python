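"""Raw-read cleaning, category accounting and tag collapsing.

Raw small-RNA reads are insert + 3' adapter.  Each read is assigned to
exactly one accounting category (polyA, 5'-adapter contaminant, missing 3'
adapter, empty insert, too short, clean); the clean 18-30 nt inserts are
collapsed into unique tags with per-library counts, the atoms of all
downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .seqs import to_dna

#: accounting row names, rendered bit-exact in reports
STATS_ROWS = ("Total_read", "High_quality", "Adaptor3_null", "Insert_null",
              "Adaptor5_contaminants", "Small_than_18 nt", "PolyA",
              "Clean_reads")


@dataclass
class CleanStats:
    """Per-library read accounting.

    ``high_quality`` equals ``total_read`` (reads are accepted as-is; no
    quality model) and always equals the sum of the six category counts.
    """

    total_read: int = 0
    high_quality: int = 0
    adaptor3_null: int = 0
    insert_null: int = 0
    adaptor5_contaminants: int = 0
    small_than_18nt: int = 0
    polya: int = 0
    clean_reads: int = 0

    def check(self) -> None:
        parts = (self.adaptor3_null + self.insert_null
                 + self.adaptor5_contaminants + self.small_than_18nt
                 + self.polya + self.clean_reads)
        if parts != self.high_quality:
            raise AssertionError("CleanStats categories do not sum to total")

    def as_rows(self) -> list[tuple[str, int]]:
        return list(zip(STATS_ROWS, (self.total_read, self.high_quality,
                                     self.adaptor3_null, self.insert_null,
                                     self.adaptor5_contaminants,
                                     self.small_than_18nt, self.polya,
                                     self.clean_reads)))


@dataclass
class SmallRNATag:
    """A unique clean-read sequence with per-library counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


TagSet = dict[str, SmallRNATag]


def locate_adapter3(read: str, adapter3: str, min_overlap: int = 6,
                    max_mismatch: int = 1) -> int | None:
    """Leftmost position where the 3' adapter starts, or None.

    A match requires the adapter prefix to explain the entire remaining
    tail of the read (up to the adapter length), with at least
    ``min_overlap`` nt and at most ``max_mismatch`` substitutions.
    """
    read = to_dna(read)
    adapter3 = to_dna(adapter3)
    n = len(read)
    for p in range(n - min_overlap + 1):
        span = min(len(adapter3), n - p)
        mismatches = sum(a != b for a, b in zip(read[p:p + span], adapter3[:span]))
        if mismatches <= max_mismatch:
            return p
    return None


def classify_read(read: str, adapter3: str, adapter5: str,
                  min_len: int = 18, max_len: int = 30,
                  polya_frac: float = 0.9,
                  contam_prefix: int = 8) -> tuple[str, str | None]:
    """Assign one accounting category to a raw read.

    Returns (category, insert); insert is non-None only for 'clean'.
    Category names are CleanStats field names.  Assignment order makes the
    categories disjoint: polyA -> 5' contaminant -> no 3' adapter -> empty
    insert -> too short -> clean.  Inserts longer than ``max_len`` are
    counted as ``adaptor3_null``: no usable 3'-adapter position yields a
    plausible small-RNA insert.
    """
    read = to_dna(read)
    pos = locate_adapter3(read, adapter3)
    insert = read[:pos] if pos is not None else read
    if insert and insert.count("A") / len(insert) >= polya_frac:
        return "polya", None
    k = min(contam_prefix, len(adapter5))
    if k and len(insert) >= k and insert.startswith(to_dna(adapter5)[:k]):
        return "adaptor5_contaminants", None
    if pos is None or len(insert) > max_len:
        return "adaptor3_null", None
    if not insert:
        return "insert_null", None
    if len(insert) < min_len:
        return "small_than_18nt", None
    return "clean_reads", insert


def clean_reads(reads: Iterable[str], adapter3: str, adapter5: str,
                min_len: int = 18, max_len: int = 30,
                polya_frac: float = 0.9,
                contam_prefix: int = 8) -> tuple[list[str], CleanStats]:
    """Clean a raw library into inserts plus Table-style accounting."""
    if not adapter3 or not adapter5:
        raise ValueError("adapters must be non-empty")
    stats = CleanStats()
    inserts: list[str] = []
    for read in reads:
        stats.total_read += 1
        stats.high_quality += 1
        cat, insert = classify_read(read, adapter3, adapter5, min_len,
                                    max_len, polya_frac, contam_prefix)
        if cat == "clean_reads":
            inserts.append(insert)
            stats.clean_reads += 1
        else:
            setattr(stats, cat, getattr(stats, cat) + 1)
    stats.check()
    return inserts, stats


def collapse(inserts: Iterable[str], library: str) -> TagSet:
    """Collapse inserts into unique tags; Σ counts equals len(inserts)."""
    tags: TagSet = {}
    for seq in inserts:
        seq = to_dna(seq)
        tag = tags.get(seq)
        if tag is None:
            tags[seq] = SmallRNATag(sequence=seq, counts={library: 1})
        else:
            tag.counts[library] = tag.counts.get(library, 0) + 1
    return tags


def merge_tags(*tagsets: TagSet) -> TagSet:
    """Union of per-library tag sets, summing counts per library."""
    merged: TagSet = {}
    for tags in tagsets:
        for seq, tag in tags.items():
            if seq not in merged:
                merged[seq] = SmallRNATag(sequence=seq, counts=dict(tag.counts))
            else:
                for lib, n in tag.counts.items():
                    merged[seq].counts[lib] = merged[seq].counts.get(lib, 0) + n
    return merged


def length_histogram(tags: TagSet) -> dict[int, tuple[int, int]]:
    """Per-length (total reads, unique tags)."""
    hist: dict[int, tuple[int, int]] = {}
    for tag in tags.values():
        n = len(tag.sequence)
        total, unique = hist.get(n, (0, 0))
        hist[n] = (total + tag.total, unique + 1)
    return dict(sorted(hist.items()))


@dataclass(frozen=True)
class OverlapSummary:
    """Common/specific tag accounting between two libraries."""

    unique_common: int
    unique_a_specific: int
    unique_b_specific: int
    total_common: int
    total_a_specific: int
    total_b_specific: int

    @property
    def unique_fractions(self) -> tuple[float, float, float]:
        u = self.unique_common + self.unique_a_specific + self.unique_b_specific
        if u == 0:
            return (0.0, 0.0, 0.0)
        return (self.unique_common / u, self.unique_a_specific / u,
                self.unique_b_specific / u)

    @property
    def total_fractions(self) -> tuple[float, float, float]:
        t = self.total_common + self.total_a_specific + self.total_b_specific
        if t == 0:
            return (0.0, 0.0, 0.0)
        return (self.total_common / t, self.total_a_specific / t,
                self.total_b_specific / t)


def library_overlap(tags_a: TagSet, tags_b: TagSet) -> OverlapSummary:
    a, b = set(tags_a), set(tags_b)
    common = a & b
    return OverlapSummary(
        unique_common=len(common),
        unique_a_specific=len(a - b),
        unique_b_specific=len(b - a),
        total_common=sum(tags_a[s].total for s in common)
        + sum(tags_b[s].total for s in common),
        total_a_specific=sum(tags_a[s].total for s in a - b),
        total_b_specific=sum(tags_b[s].total for s in b - a),
    )
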