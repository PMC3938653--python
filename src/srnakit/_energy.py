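"""Nearest-neighbour energy model shared by the fold and duplex engines.

The model is deliberately compact: Watson-Crick and G:U pairs, a 6x6 stack
table, size-dependent hairpin/bulge/internal loop penalties with logarithmic
extrapolation, and an affine multiloop cost.  All free energies are in
kcal/mol at 37 C; more negative means more stable.
"""

from __future__ import annotations

import math
from functools import lru_cache
from importlib import resources

import numpy as np

INF = 1e18

BASES = "ACGU"
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}

#: admissible pairs in fixed index order (matches the stack table header)
PAIR_NAMES = ("AU", "UA", "CG", "GC", "GU", "UG")

#: maximum loop size for which penalty arrays are precomputed
_MAX_LOOP = 512


def encode(seq: str) -> np.ndarray:
    """Encode an RNA string (T accepted as U) as int8 codes 0..3."""
    s = seq.upper().replace("T", "U")
    try:
        return np.array([BASE_INDEX[c] for c in s], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid RNA character {exc.args[0]!r} in sequence") from None


class EnergyModel:
    """Loaded parameter set: stack table, loop penalties, multiloop costs."""

    def __init__(self) -> None:
        data = resources.files("srnakit") / "data"
        stack_lines = (data / "stack_energies.tsv").read_text().strip().splitlines()
        header = stack_lines[0].split("\t")[1:]
        if tuple(header) != PAIR_NAMES:
            raise ValueError("stack table header does not match pair order")
        self.stack = np.full((6, 6), INF)
        for line in stack_lines[1:]:
            fields = line.split("\t")
            i = PAIR_NAMES.index(fields[0])
            self.stack[i, :] = [float(x) for x in fields[1:]]
        # physical symmetry: reading a stacked pair of pairs from the other
        # strand must give the same energy
        flip = [1, 0, 3, 2, 5, 4]
        for i in range(6):
            for j in range(6):
                if abs(self.stack[i, j] - self.stack[flip[j], flip[i]]) > 1e-9:
                    raise ValueError("stack table violates flip symmetry")

        params: dict[str, float] = {}
        for line in (data / "loop_params.tsv").read_text().strip().splitlines()[1:]:
            key, value = line.split("\t")
            params[key] = float(value)

        rt = params["loop_extrapolation_rt"]
        self.hairpin = np.full(_MAX_LOOP, INF)
        for n in range(3, _MAX_LOOP):
            if n <= 9:
                self.hairpin[n] = params[f"hairpin_{n}"]
            else:
                self.hairpin[n] = params["hairpin_9"] + 1.75 * rt * math.log(n / 9.0)
        self.bulge = np.full(_MAX_LOOP, INF)
        for n in range(1, _MAX_LOOP):
            if n <= 6:
                self.bulge[n] = params[f"bulge_{n}"]
            else:
                self.bulge[n] = params["bulge_6"] + 1.75 * rt * math.log(n / 6.0)
        self.internal = np.full(_MAX_LOOP, INF)
        for n in range(2, _MAX_LOOP):
            if n <= 6:
                self.internal[n] = params[f"internal_{n}"]
            else:
                self.internal[n] = params["internal_6"] + 1.75 * rt * math.log(n / 6.0)

        self.ml_init = params["multiloop_init"]
        self.ml_branch = params["multiloop_branch"]
        self.ml_unpaired = params["multiloop_unpaired"]
        self.duplex_init = params["duplex_init"]
        self.max_internal = int(params["max_internal_loop"])
        self.duplex_max_loop = int(params["duplex_max_loop"])
        self.min_hairpin = int(params["min_hairpin"])

        # pair index lookup: pidx[a, b] = index into PAIR_NAMES or -1
        self.pidx = np.full((4, 4), -1, dtype=np.int8)
        for k, name in enumerate(PAIR_NAMES):
            self.pidx[BASE_INDEX[name[0]], BASE_INDEX[name[1]]] = k

    def can_pair(self, a: int, b: int) -> bool:
        return self.pidx[a, b] >= 0

    def loop_penalty(self, g1: int, g2: int, outer: int, inner: int) -> float:
        """Energy of the loop between two pairs with g1/g2 unpaired on the
        two sides; ``outer``/``inner`` are pair indices for the stack term."""
        if g1 == 0 and g2 == 0:
            return float(self.stack[outer, inner])
        size = g1 + g2
        if size > self.max_internal or size >= _MAX_LOOP:
            return INF
        if g1 == 0 or g2 == 0:
            return float(self.bulge[size])
        return float(self.internal[size])


@lru_cache(maxsize=1)
def default_model() -> EnergyModel:
    return EnergyModel()


def structure_energy(seq: str, pairs: list[tuple[int, int]],
                     model: EnergyModel | None = None) -> float:
    """Free energy of an explicit pseudoknot-free structure.

    This is the definition of the model: the energy is the sum over all
    loops of the structure (hairpins, stacks, bulges, internal loops and
    multiloops) closed by each pair; the exterior loop is free.  Structures
    containing an inadmissible pair, a hairpin loop shorter than the minimum
    or an internal loop beyond the size cap get +inf.  The dynamic programs
    must agree with the minimum of this function over all structures.
    """
    model = model or default_model()
    codes = encode(seq)
    n = len(codes)
    plist = sorted(pairs)
    partner = {}
    for i, j in plist:
        if not (0 <= i < j < n):
            return INF
        if i in partner or j in partner:
            return INF
        partner[i] = j
        partner[j] = i
    # pseudoknot check
    for i, j in plist:
        for k, l in plist:
            if i < k < j < l:
                return INF

    def children_of(i: int, j: int) -> list[tuple[int, int]]:
        kids = []
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        return kids

    total = 0.0
    for i, j in plist:
        pi = model.pidx[codes[i], codes[j]]
        if pi < 0:
            return INF
        kids = children_of(i, j)
        if not kids:
            size = j - i - 1
            if size < model.min_hairpin or size >= _MAX_LOOP:
                return INF
            total += float(model.hairpin[size])
        elif len(kids) == 1:
            k, l = kids[0]
            inner = model.pidx[codes[k], codes[l]]
            e = model.loop_penalty(k - i - 1, j - l - 1, pi, inner)
            if e >= INF:
                return INF
            total += e
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            total += (model.ml_init + model.ml_branch * (len(kids) + 1)
                      + model.ml_unpaired * unpaired)
    return total
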