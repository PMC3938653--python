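"""Nucleotide-bias, isomiR, single-base-edit and family profiling.

Works on the tag level: first-nucleotide and positional composition of
clean tags, detection of single-substitution variants of known matures
(seed-aware, positions 2-8), aggregation of templated end variants
(isomiRs), and miRNA family membership with the dominant member.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .annotate import KnownAssignment, MirnaRecord, MirnaReference
from .preprocess import TagSet
from .seqs import to_rna

SEED_SPAN = (2, 8)  # 1-based positions of the seed region


def first_nt_bias(tags: TagSet) -> pd.DataFrame:
    """Read-weighted first-nucleotide fraction per tag length.

    Rows are lengths, columns A/C/G/U; each row sums to 1.
    """
    counts: dict[int, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for tag in tags.values():
        counts[len(tag.sequence)][to_rna(tag.sequence[0])] += tag.total
    rows = {}
    for length in sorted(counts):
        total = sum(counts[length].values())
        rows[length] = {b: counts[length].get(b, 0) / total for b in "ACGU"}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list("ACGU"))


def position_bias(tags: TagSet) -> pd.DataFrame:
    """Read-weighted A/C/G/U fraction at each 1-based position, over tags
    long enough to cover the position."""
    counts: dict[int, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for tag in tags.values():
        for i, base in enumerate(to_rna(tag.sequence), start=1):
            counts[i][base] += tag.total
    rows = {}
    for pos in sorted(counts):
        total = sum(counts[pos].values())
        rows[pos] = {b: counts[pos].get(b, 0) / total for b in "ACGU"}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list("ACGU"))


@dataclass(frozen=True)
class EditRecord:
    """A tag matching a known mature with exactly one substitution."""

    tag: str
    name: str
    position: int  # 1-based from the mature 5' end
    from_base: str
    to_base: str
    in_seed: bool
    count: int


def match_with_mismatches(tags: TagSet, reference: MirnaReference,
                          mismatches: int,
                          expression: dict[str, int] | None = None,
                          ) -> dict[str, tuple[str, list[int]]]:
    """Map each tag onto the mature it matches with exactly ``mismatches``
    substitutions (same length, position-by-position comparison).

    A tag matching several matures goes to the one with the higher library
    expression, ties broken by lexicographically first name.  With
    ``mismatches=0`` this is exact mature identity.
    """
    expression = expression or {}
    out: dict[str, tuple[str, list[int]]] = {}
    for seq in sorted(tags):
        best: tuple[tuple[int, str], str, list[int]] | None = None
        for name in sorted(reference.records):
            mature = reference.records[name].mature
            if len(seq) != len(mature):
                continue
            diffs = [i for i in range(len(seq)) if seq[i] != mature[i]]
            if len(diffs) != mismatches:
                continue
            key = (-expression.get(name, 0), name)
            if best is None or key < best[0]:
                best = (key, name, diffs)
        if best is not None:
            out[seq] = (best[1], best[2])
    return out


def detect_edits(tags: TagSet, reference: MirnaReference,
                 expression: dict[str, int] | None = None) -> list[EditRecord]:
    """Detect single-base edits among unannotated tags.

    A record is emitted when a tag matches a known mature with exactly one
    substitution; ``in_seed`` is set iff the edited position lies in the
    seed region (positions 2-8 from the mature 5' end).
    """
    out: list[EditRecord] = []
    for seq, (name, diffs) in match_with_mismatches(tags, reference, 1,
                                                    expression).items():
        pos = diffs[0] + 1
        mature = reference.records[name].mature
        out.append(EditRecord(tag=seq, name=name, position=pos,
                              from_base=to_rna(mature[pos - 1]),
                              to_base=to_rna(seq[pos - 1]),
                              in_seed=SEED_SPAN[0] <= pos <= SEED_SPAN[1],
                              count=tags[seq].total))
    return sorted(out, key=lambda r: (r.name, r.position, r.tag))


@dataclass(frozen=True)
class EndVariant:
    """Aggregated templated end variant of a known mature; offsets are
    signed nt relative to the annotated ends ((0, 0) = canonical)."""

    name: str
    offset5: int
    offset3: int
    count: int


def end_variants(tags: TagSet,
                 assignments: dict[str, KnownAssignment]) -> list[EndVariant]:
    """Aggregate known-miRNA assignments into (5', 3') offset classes.

    Assignments come from exact placement within the precursor, so all
    variants are templated by construction.
    """
    agg: dict[tuple[str, int, int], int] = defaultdict(int)
    for seq, asn in assignments.items():
        agg[(asn.name, asn.offset5, asn.offset3)] += tags[seq].total
    return [EndVariant(name=k[0], offset5=k[1], offset3=k[2], count=v)
            for k, v in sorted(agg.items())]


_FAMILY_RE = re.compile(
    r"^(?:[a-z]{3,4}-)?"          # species prefix, e.g. bta-
    r"(?P<stem>(?:miR|mir|let)-\d+)"  # family stem, e.g. miR-2284, let-7
    r"[a-z]*"                     # lettered paralog suffix
    r"(?:-\d+)?"                  # numbered locus suffix
    r"(?:-[35]p)?$",              # arm suffix
)


def family_name(name: str) -> str:
    """Family stem of a miRNA name (strip species prefix, paralog letters,
    locus numbers and arm suffixes); unparseable names are their own
    family."""
    m = _FAMILY_RE.match(name)
    return m.group("stem") if m else name


def assign_family(records: dict[str, MirnaRecord]) -> pd.DataFrame:
    """Family table: member count, total reads, and the dominant member
    (highest total count) per family.  Reference-provided family names are
    used when present, otherwise parsed from the miRNA name."""
    fams: dict[str, list[MirnaRecord]] = defaultdict(list)
    for rec in records.values():
        fams[rec.family or family_name(rec.name)].append(rec)
    rows = []
    for fam in sorted(fams):
        members = fams[fam]
        dominant = max(members, key=lambda r: (r.total, r.name))
        rows.append({"family": fam, "members": len(members),
                     "total": sum(r.total for r in members),
                     "dominant": dominant.name,
                     "dominant_count": dominant.total})
    return pd.DataFrame(rows).set_index("family")
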