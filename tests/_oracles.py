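"""Independent brute-force oracles shared by the unit and acceptance
tests.  Each oracle recomputes its quantity by enumeration or explicit
summation, never through the production DP/engine code paths."""

from __future__ import annotations

import itertools
import math

from srnakit._energy import default_model, encode
from srnakit.fold import structure_energy

MODEL = default_model()

_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}
_GU = {("G", "U"), ("U", "G")}


def enumerate_structures(seq: str):
    """All pseudoknot-free pair sets with hairpin loops >= 3 over the
    admissible pairs (recursive enumeration, independent of the DP)."""
    codes = encode(seq)

    def rec(i, j):
        if j - i < 4:
            yield []
            return
        yield from rec(i + 1, j)
        for k in range(i + MODEL.min_hairpin + 1, j + 1):
            if MODEL.pidx[codes[i], codes[k]] >= 0:
                for s1 in rec(i + 1, k - 1):
                    for s2 in rec(k + 1, j):
                        yield [(i, k)] + s1 + s2

    yield from rec(0, len(codes) - 1)


def brute_force_mfe(seq: str) -> float:
    return min((structure_energy(seq, pairs)
                for pairs in enumerate_structures(seq)), default=0.0)


def brute_force_duplex(a: str, b: str) -> float:
    """Exhaustive DFS over all monotone antiparallel intermolecular pair
    chains (loop-capped as in the model)."""
    ca, cb = encode(a), encode(b)
    sites = [(i, j) for i in range(len(ca)) for j in range(len(cb))
             if MODEL.pidx[ca[i], cb[j]] >= 0]
    best = [0.0]

    def rec(idx, energy):
        if energy < best[0]:
            best[0] = energy
        i, j = sites[idx]
        pi = MODEL.pidx[ca[i], cb[j]]
        for t, (ii, jj) in enumerate(sites):
            if ii <= i or jj >= j:
                continue
            g1, g2 = ii - i - 1, j - jj - 1
            if g1 + g2 > MODEL.duplex_max_loop:
                continue
            e = MODEL.loop_penalty(g1, g2, pi, MODEL.pidx[ca[ii], cb[jj]])
            rec(t, energy + e)

    for s in range(len(sites)):
        rec(s, MODEL.duplex_init)
    return best[0]


def binom_pmf(k: int, n: int, q: float) -> float:
    logp = (math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
            + k * math.log(q) + (n - k) * math.log(1 - q))
    return math.exp(logp)


def conditional_binomial_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Exact two-sided conditional binomial test by explicit tail sums."""
    n = x + y
    if n == 0:
        return 1.0
    q = n2 / (n1 + n2)
    lower = sum(binom_pmf(k, n, q) for k in range(0, y + 1))
    upper = sum(binom_pmf(k, n, q) for k in range(y, n + 1))
    return min(1.0, 2.0 * min(lower, upper))


def target_rule_verdicts(mirna: str, site: str, mfe_ratio: float) -> dict:
    """Independent position-by-position recount of the six target rules."""
    n = len(mirna)
    status = []
    for i in range(n):
        a, b = mirna[i], site[n - 1 - i]
        if _COMP[a] == b:
            status.append("match")
        elif (a, b) in _GU:
            status.append("GU")
        else:
            status.append("mismatch")
    weighted = sum(1.0 for s in status if s == "mismatch") \
        + sum(0.5 for s in status if s == "GU")
    runs = max((sum(1 for _ in g) for s, g in itertools.groupby(status)
                if s == "mismatch"), default=0)
    adj_2_12 = any(status[i] == "mismatch" and status[i + 1] == "mismatch"
                   for i in range(1, 11))
    w12 = sum(1.0 if s == "mismatch" else 0.5 if s == "GU" else 0.0
              for s in status[:12])
    return {
        "max_mismatches": weighted <= 4.0,
        "adjacent_mismatches": runs <= 2,
        "adjacent_in_2_12": not adj_2_12,
        "positions_10_11": status[9] != "mismatch" and status[10] != "mismatch",
        "five_prime_weight": w12 <= 2.5,
        "energy": mfe_ratio >= 0.75,
    }
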