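"""Small sequence utilities shared across the pipeline.

All sequences are stored internally in the DNA alphabet (ACGT); U is
accepted on input and RNA output is produced on demand.
"""

from __future__ import annotations

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement in the DNA alphabet."""
    return to_dna(seq).translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return to_rna(revcomp(seq))
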