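"""RNA secondary-structure and hybridization energy engine.

Provides the deterministic minimum-free-energy folder used for hairpin
evaluation (``fold``), the minimal-free-energy-index arithmetic (``mfei``)
used to discriminate miRNA precursors from other RNAs, and an intermolecular
duplex engine (``duplex``) used for miRNA:target and miRNA:star
hybridization energies.  All energies are kcal/mol; more negative is more
stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ._energy import EnergyModel, INF, default_model, encode, structure_energy
from ._zuker import _duplex_fill, mfe_fold

__all__ = ["FoldResult", "DuplexResult", "fold", "mfei", "duplex",
           "structure_energy", "pairs_to_dotbracket"]


def pairs_to_dotbracket(n: int, pairs: list[tuple[int, int]]) -> str:
    dots = ["."] * n
    for i, j in pairs:
        dots[i] = "("
        dots[j] = ")"
    return "".join(dots)


def gc_percent(seq: str) -> float:
    s = seq.upper()
    if not s:
        return 0.0
    return 100.0 * sum(c in "GC" for c in s) / len(s)


@dataclass(frozen=True)
class FoldResult:
    """Folded sequence with its MFE structure and derived indices.

    ``amfe`` is the adjusted MFE (-MFE per 100 nt) and ``mfei`` the minimal
    free energy index, AMFE divided by the GC percentage.
    """

    sequence: str
    structure: str
    mfe: float
    gc: float
    pairs: tuple[tuple[int, int], ...] = field(repr=False, default=())

    @property
    def amfe(self) -> float:
        if not self.sequence:
            return 0.0
        return -self.mfe / len(self.sequence) * 100.0

    @property
    def mfei(self) -> float:
        return mfei(self)

    def partner(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


def fold(seq: str, model: EnergyModel | None = None) -> FoldResult:
    """Fold an RNA sequence into its minimum-free-energy structure.

    Deterministic: energy ties are resolved in favour of the 5'-most
    pairing.  Sequences must be >= 10 nt over the ACGU (or ACGT) alphabet.
    """
    if len(seq) < 10:
        raise ValueError("fold requires sequences of at least 10 nt")
    mfe, pairs = mfe_fold(seq, model)
    rna = seq.upper().replace("T", "U")
    return FoldResult(sequence=rna,
                      structure=pairs_to_dotbracket(len(seq), pairs),
                      mfe=mfe, gc=gc_percent(seq), pairs=tuple(pairs))


def mfei(result: FoldResult) -> float:
    """MFEI = AMFE / GC%; returns NaN when GC% is zero (flagged as a fail
    downstream)."""
    if result.gc == 0.0:
        return math.nan
    return result.amfe / result.gc


@dataclass(frozen=True)
class DuplexResult:
    """Optimal intermolecular hybridization of two RNA strands.

    ``pairs`` maps 0-based positions of ``seq_a`` (5'->3') onto positions of
    ``seq_b`` (5'->3'); the pairing is antiparallel and non-crossing.
    """

    seq_a: str
    seq_b: str
    mfe: float
    pairs: tuple[tuple[int, int], ...]


def duplex(seq_a: str, seq_b: str, model: EnergyModel | None = None) -> DuplexResult:
    """Optimal non-crossing intermolecular pairing energy of two strands.

    Only intermolecular pairs are formed; the energy is a duplex initiation
    cost plus nearest-neighbour stacks and bulge/internal-loop penalties
    between consecutive pairs.  The empty duplex has energy 0, so the MFE is
    never positive.
    """
    if not seq_a or not seq_b:
        raise ValueError("duplex requires two non-empty sequences")
    model = model or default_model()
    a = encode(seq_a)
    b = encode(seq_b)
    na, nb = len(a), len(b)
    dp, back_i, back_j = _duplex_fill(a, b, model.pidx, model.stack,
                                      model.bulge, model.internal,
                                      model.duplex_init,
                                      model.duplex_max_loop)
    mfe = 0.0
    argmin = (-1, -1)
    for i in range(na):
        for j in range(nb):
            if dp[i, j] < mfe - 1e-12:
                mfe = float(dp[i, j])
                argmin = (i, j)
    chain: list[tuple[int, int]] = []
    i, j = argmin
    while i >= 0:
        chain.append((i, j))
        i, j = int(back_i[i, j]), int(back_j[i, j])
    chain.sort()
    return DuplexResult(seq_a=seq_a.upper().replace("T", "U"),
                        seq_b=seq_b.upper().replace("T", "U"),
                        mfe=mfe if chain else 0.0,
                        pairs=tuple(chain))
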