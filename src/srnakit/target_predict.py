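"""Rule-based miRNA target-site prediction with G:U wobble scoring.

Every window of miRNA length across a transcript is aligned ungapped and
antiparallel to the miRNA; positions are numbered 1..L from the miRNA 5'
end.  G:U wobbles count as half a mismatch in the weighted totals but are
not mismatches for the adjacency/position rules.  The energy rule compares
the duplex MFE against the MFE of the miRNA bound to its perfect
Watson-Crick complement.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .fold import duplex
from .seqs import revcomp_rna, to_rna

_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class DuplexAlignment:
    """Ungapped miRNA:site alignment with per-position status.

    ``status[i]`` describes miRNA position i+1 (1-based from the miRNA 5'
    end): 'match', 'GU' or 'mismatch'.  The weighted mismatch total counts
    G:U as 0.5.
    """

    mirna: str
    site: str
    status: tuple[str, ...]
    duplex_mfe: float
    perfect_mfe: float

    @property
    def weighted_mismatches(self) -> float:
        return (self.status.count("mismatch")
                + 0.5 * self.status.count("GU"))

    @property
    def mfe_ratio(self) -> float:
        if self.perfect_mfe >= 0:
            return 0.0
        return min(1.0, self.duplex_mfe / self.perfect_mfe)


def align_site(mirna: str, site_window: str,
               with_energy: bool = True) -> DuplexAlignment:
    """Align a miRNA to an equal-length site window (both given 5'->3').

    miRNA position i pairs the complementary (antiparallel) site position
    L - i + 1; status is Watson-Crick match, G:U wobble, or mismatch.
    """
    mi = to_rna(mirna)
    si = to_rna(site_window)
    if len(mi) != len(si):
        raise ValueError("site window must equal the miRNA length")
    n = len(mi)
    status = []
    for i in range(n):
        pair = (mi[i], si[n - 1 - i])
        if pair in _WC:
            status.append("match")
        elif pair in _GU:
            status.append("GU")
        else:
            status.append("mismatch")
    if with_energy:
        dup = duplex(mi, si).mfe
        perfect = duplex(mi, revcomp_rna(mi)).mfe
    else:
        dup = perfect = 0.0
    return DuplexAlignment(mirna=mi, site=si, status=tuple(status),
                           duplex_mfe=dup, perfect_mfe=perfect)


@dataclass(frozen=True)
class RuleVerdicts:
    """Per-rule verdicts; ``overall`` is the conjunction of all six."""

    max_mismatches: bool      # weighted total <= 4
    adjacent_mismatches: bool  # longest run of full mismatches <= 2
    adjacent_in_2_12: bool    # no two adjacent mismatches in positions 2-12
    positions_10_11: bool     # positions 10-11 are not mismatches
    five_prime_weight: bool   # weighted total over positions 1-12 <= 2.5
    energy: bool              # duplex MFE >= 75% of the perfect-site MFE

    @property
    def overall(self) -> bool:
        return all((self.max_mismatches, self.adjacent_mismatches,
                    self.adjacent_in_2_12, self.positions_10_11,
                    self.five_prime_weight, self.energy))


def apply_rules(aln: DuplexAlignment,
                mfe_ratio_min: float = 0.75) -> RuleVerdicts:
    """Evaluate the six target-prediction rules on an alignment."""
    st = aln.status
    n = len(st)
    longest_run = run = 0
    for s in st:
        run = run + 1 if s == "mismatch" else 0
        longest_run = max(longest_run, run)
    adjacent_2_12 = any(
        st[i] == "mismatch" and st[i + 1] == "mismatch"
        for i in range(1, min(11, n - 1)))  # pairs within positions 2..12
    w_5p = sum(1.0 if st[i] == "mismatch" else 0.5 if st[i] == "GU" else 0.0
               for i in range(min(12, n)))
    pos_10_11 = any(st[i] == "mismatch" for i in (9, 10) if i < n)
    return RuleVerdicts(
        max_mismatches=aln.weighted_mismatches <= 4.0,
        adjacent_mismatches=longest_run <= 2,
        adjacent_in_2_12=not adjacent_2_12,
        positions_10_11=not pos_10_11,
        five_prime_weight=w_5p <= 2.5,
        energy=aln.mfe_ratio >= mfe_ratio_min,
    )


def scan(mirna: str, transcripts: dict[str, str],
         report_all: bool = False) -> pd.DataFrame:
    """Scan transcripts for target sites of one miRNA.

    Every window of miRNA length is evaluated; by default only sites
    passing all six rules are reported (``report_all`` keeps every window
    with its verdicts).  Site coordinates are 1-based inclusive on the
    transcript.  The sequence rules are checked before the energy rule so
    the duplex engine only runs on sequence-plausible windows.
    """
    mi = to_rna(mirna)
    L = len(mi)
    perfect = duplex(mi, revcomp_rna(mi)).mfe
    rows = []
    for tid, seq in sorted(transcripts.items()):
        seq = to_rna(seq)
        if len(seq) < L:
            continue  # transcript shorter than the miRNA
        for start in range(len(seq) - L + 1):
            window = seq[start:start + L]
            aln = align_site(mi, window, with_energy=False)
            pre = apply_rules(aln)
            need_energy = report_all or (
                pre.max_mismatches and pre.adjacent_mismatches
                and pre.adjacent_in_2_12 and pre.positions_10_11
                and pre.five_prime_weight)
            if not need_energy:
                continue
            full = DuplexAlignment(mirna=mi, site=window, status=aln.status,
                                   duplex_mfe=duplex(mi, window).mfe,
                                   perfect_mfe=perfect)
            verdicts = apply_rules(full)
            if verdicts.overall or report_all:
                rows.append({
                    "transcript": tid, "start": start + 1, "end": start + L,
                    "site": window,
                    "weighted_mismatches": full.weighted_mismatches,
                    "duplex_mfe": full.duplex_mfe,
                    "mfe_ratio": full.mfe_ratio,
                    "max_mismatches": verdicts.max_mismatches,
                    "adjacent_mismatches": verdicts.adjacent_mismatches,
                    "adjacent_in_2_12": verdicts.adjacent_in_2_12,
                    "positions_10_11": verdicts.positions_10_11,
                    "five_prime_weight": verdicts.five_prime_weight,
                    "energy": verdicts.energy,
                    "overall": verdicts.overall,
                })
    columns = ["transcript", "start", "end", "site", "weighted_mismatches",
               "duplex_mfe", "mfe_ratio", "max_mismatches",
               "adjacent_mismatches", "adjacent_in_2_12", "positions_10_11",
               "five_prime_weight", "energy", "overall"]
    return pd.DataFrame(rows, columns=columns)
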