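"""Exact both-strand tag-to-genome mapping via a k-mer seed index.

Desk-scale replacement for a short-read aligner: tags (18-30 nt) are
located by an exact full-length match on either strand; all hit loci are
reported and the genome-wide hit count is attached to every hit so that
downstream stages can exclude highly repetitive tags.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable

from .seqs import revcomp, to_dna


@dataclass(frozen=True)
class GenomeHit:
    """One exact genomic match of a tag (0-based start, half-open end)."""

    sequence: str
    chrom: str
    start: int
    strand: str
    hit_count: int = 1

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


class GenomeIndex:
    """k-mer position index over a genome dict {chrom: sequence}.

    k must not exceed the shortest query; windows containing non-ACGT
    characters are excluded from the index.
    """

    def __init__(self, genome: dict[str, str], k: int = 16) -> None:
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self.genome = {c: to_dna(s) for c, s in genome.items()}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if set(kmer) <= set("ACGT"):
                    self._index[kmer].append((chrom, i))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """All forward-strand positions of a length-k word."""
        if len(kmer) != self.k:
            raise ValueError(f"lookup requires a {self.k}-mer")
        return list(self._index.get(to_dna(kmer), ()))

    def find(self, query: str) -> list[tuple[str, int, str]]:
        """All (chrom, start, strand) exact full-length matches of query."""
        query = to_dna(query)
        if len(query) < self.k:
            raise ValueError("query shorter than index k")
        out = []
        for strand, seq in (("+", query), ("-", revcomp(query))):
            for chrom, pos in self._index.get(seq[:self.k], ()):
                if self.genome[chrom][pos:pos + len(seq)] == seq:
                    out.append((chrom, pos, strand))
        return sorted(out)


def build_index(genome: dict[str, str], k: int = 16) -> GenomeIndex:
    return GenomeIndex(genome, k=k)


def map_tags(sequences: Iterable[str], index: GenomeIndex,
             max_hits: int = 10) -> tuple[dict[str, list[GenomeHit]], set[str]]:
    """Map tag sequences; returns ({tag: hits}, unmapped set).

    Tags exceeding ``max_hits`` genome-wide are retained with their
    hit_count (downstream stages exclude them); hit_count counts all loci
    on both strands.
    """
    hits: dict[str, list[GenomeHit]] = {}
    unmapped: set[str] = set()
    for seq in sequences:
        seq = to_dna(seq)
        found = index.find(seq)
        if not found:
            unmapped.add(seq)
            continue
        n = len(found)
        hits[seq] = [GenomeHit(sequence=seq, chrom=c, start=p, strand=s,
                               hit_count=n) for c, p, s in found]
    return hits, unmapped
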