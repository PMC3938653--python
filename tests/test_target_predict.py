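"""Target-site alignment, the six rules against a brute-force recount
oracle, and transcript scanning."""

from __future__ import annotations

import random

import pytest

from srnakit.seqs import revcomp_rna, to_rna
from srnakit.target_predict import (DuplexAlignment, align_site, apply_rules,
                                    scan)

from _oracles import target_rule_verdicts as oracle_verdicts  # noqa: E402

MIRNA = "UGAGGUAGUAGGUUGUAUAGU"  # 21 nt
PERFECT_SITE = revcomp_rna(MIRNA)

_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}
_GU = {("G", "U"), ("U", "G")}


class TestAlignSite:
    def test_perfect_complement(self):
        aln = align_site(MIRNA, PERFECT_SITE)
        assert set(aln.status) == {"match"}
        assert aln.weighted_mismatches == 0.0
        assert aln.mfe_ratio == pytest.approx(1.0)

    def test_gu_weighting(self):
        # replace four site bases so they wobble-pair the miRNA
        site = list(PERFECT_SITE)
        changed = 0
        for i in range(len(MIRNA)):
            if changed == 4:
                break
            if MIRNA[i] == "G":
                site[len(MIRNA) - 1 - i] = "U"
                changed += 1
            elif MIRNA[i] == "U":
                site[len(MIRNA) - 1 - i] = "G"
                changed += 1
        assert changed == 4
        aln = align_site(MIRNA, "".join(site), with_energy=False)
        assert aln.status.count("GU") == 4
        assert aln.weighted_mismatches == 2.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            align_site(MIRNA, "ACGU")

    def test_weighted_total_matches_recount(self):
        rng = random.Random(9)
        for _ in range(50):
            site = "".join(rng.choice("ACGU") for _ in range(21))
            aln = align_site(MIRNA, site, with_energy=False)
            n = len(MIRNA)
            recount = 0.0
            for i in range(n):
                a, b = MIRNA[i], site[n - 1 - i]
                if _COMP[a] == b:
                    continue
                recount += 0.5 if (a, b) in _GU else 1.0
            assert aln.weighted_mismatches == recount


def _mutate(site: str, positions: tuple[int, ...], rng: random.Random) -> str:
    out = list(site)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGU" if b != site[p]])
    return "".join(out)


class TestRules:
    def test_perfect_site_passes_all(self):
        verdicts = apply_rules(align_site(MIRNA, PERFECT_SITE))
        assert verdicts.overall

    def test_five_mismatches_fail_rule_one(self):
        site = list(PERFECT_SITE)
        # five full mismatches spread out (avoid G:U by mutating to the
        # same base as the miRNA position)
        for i in (0, 4, 8, 14, 18):
            b = MIRNA[i]
            site[len(MIRNA) - 1 - i] = "C" if b in "AU" else "A"
        aln = align_site(MIRNA, "".join(site), with_energy=False)
        assert aln.status.count("mismatch") == 5
        assert not apply_rules(aln).max_mismatches

    def test_mismatch_at_position_10_fails_rule_four(self):
        site = list(PERFECT_SITE)
        b = MIRNA[9]
        site[len(MIRNA) - 1 - 9] = "C" if b in "AU" else "A"
        verdicts = apply_rules(align_site(MIRNA, "".join(site),
                                          with_energy=False))
        assert not verdicts.positions_10_11
        assert not verdicts.overall

    def test_agrees_with_oracle_on_two_edit_variants(self):
        rng = random.Random(17)
        sites = [PERFECT_SITE]
        for p in range(21):
            sites.append(_mutate(PERFECT_SITE, (p,), rng))
        for _ in range(150):
            p, q = rng.sample(range(21), 2)
            sites.append(_mutate(PERFECT_SITE, (p, q), rng))
        for site in sites:
            aln = align_site(MIRNA, site)
            got = apply_rules(aln)
            want = oracle_verdicts(MIRNA, site, aln.mfe_ratio)
            for rule, value in want.items():
                assert getattr(got, rule) == value, (site, rule)

    def test_adding_mismatches_is_monotone(self):
        """A superset of mismatch positions never flips fail -> pass."""
        rng = random.Random(23)
        for _ in range(40):
            p, q = rng.sample(range(21), 2)
            one = _mutate(PERFECT_SITE, (p,), rng)
            two = _mutate(one, (q,), rng)
            v1 = apply_rules(align_site(MIRNA, one))
            v2 = apply_rules(align_site(MIRNA, two))
            for rule in ("max_mismatches", "adjacent_mismatches",
                         "adjacent_in_2_12", "positions_10_11",
                         "five_prime_weight"):
                if not getattr(v1, rule):
                    assert not getattr(v2, rule)

    def test_mfe_ratio_never_exceeds_perfect(self):
        rng = random.Random(31)
        for _ in range(20):
            site = _mutate(PERFECT_SITE, tuple(rng.sample(range(21), 3)), rng)
            assert align_site(MIRNA, site).mfe_ratio <= 1.0 + 1e-9


class TestScan:
    def test_embedded_perfect_site_found(self):
        rng = random.Random(41)
        flank = "".join(rng.choice("ACGU") for _ in range(200))
        tx = flank[:100] + PERFECT_SITE + flank[100:]
        df = scan(MIRNA, {"t1": tx})
        hits = df[df["overall"]]
        assert len(hits) >= 1
        assert (hits["start"] == 101).any()

    def test_short_transcript_skipped(self):
        assert scan(MIRNA, {"t": "ACGU"}).empty

    def test_shuffled_transcripts_yield_fewer_sites(self, small_world):
        truth = small_world["truth"]
        rng = random.Random(7)
        name = truth.planted_sites[0][1]
        mirna = to_rna(truth.reference_matures[name])
        real = scan(mirna, truth.transcripts)
        shuffled = {}
        for tid, seq in truth.transcripts.items():
            chars = list(seq)
            rng.shuffle(chars)
            shuffled[tid] = "".join(chars)
        null = scan(mirna, shuffled)
        n_sites = len(truth.planted_sites)
        planted_for = sum(1 for _, n, _ in truth.planted_sites if n == name)
        assert len(real) >= planted_for
        assert len(null) < max(1, len(real))

    def test_planted_sites_all_recovered(self, small_world):
        truth = small_world["truth"]
        for tid, name, pos in truth.planted_sites:
            mirna = to_rna(truth.reference_matures[name])
            df = scan(mirna, {tid: truth.transcripts[tid]})
            assert ((df["start"] == pos + 1) & df["overall"]).any(), (tid, name)
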