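"""Nucleotide bias tables, edit detection, end variants, and families."""

from __future__ import annotations

import collections

import numpy as np
import pytest

from srnakit.annotate import MirnaRecord, MirnaReference, match_known
from srnakit.preprocess import SmallRNATag
from srnakit.variant_profile import (assign_family, detect_edits,
                                     end_variants, family_name,
                                     first_nt_bias, match_with_mismatches,
                                     position_bias)


def _tags(*seq_counts):
    return {s: SmallRNATag(s, {"x": n}) for s, n in seq_counts}


class TestBias:
    def test_all_u_first(self):
        tags = _tags(("TACGTACGTACGTACGTACG", 3), ("TGGGGGGGGGGGGGGGGGGG", 1))
        df = first_nt_bias(tags)
        assert df.loc[20, "U"] == 1.0

    def test_equal_mix(self):
        tags = _tags(("AAAAAAAAAAAAAAAAAAAA", 1), ("CAAAAAAAAAAAAAAAAAAA", 1),
                     ("GAAAAAAAAAAAAAAAAAAA", 1), ("TAAAAAAAAAAAAAAAAAAA", 1))
        df = first_nt_bias(tags)
        assert all(df.loc[20, b] == 0.25 for b in "ACGU")

    def test_planted_u_enrichment(self, small_world):
        """Planted matures are 5'-U biased; the bias survives the pipeline."""
        df = first_nt_bias(small_world["tags"])
        weights = {}
        for length, row in df.iterrows():
            weights[length] = row
        # read-weighted overall U fraction dominates every other base
        hist = collections.Counter()
        for tag in small_world["tags"].values():
            hist[tag.sequence[0]] += tag.total
        assert hist["T"] == max(hist.values())

    def test_position_homopolymer(self):
        df = position_bias(_tags(("GGGGGGGGGGGGGGGGGGGG", 4)))
        assert (df["G"] == 1.0).all()

    def test_position_empty(self):
        assert position_bias({}).empty

    def test_position_fractions_sum_to_one(self, small_world):
        df = position_bias(small_world["tags"])
        assert np.allclose(df.sum(axis=1), 1.0)


class TestDetectEdits:
    def _ref(self):
        m1 = "ACGTACGTACGTACGTACGTA"
        m2 = "GGCCGGCCGGCCGGCCGGCCA"
        pres = {"m1_pre": "GGGGG" + m1 + "C" * 30,
                "m2_pre": "GGGGG" + m2 + "C" * 30}
        return MirnaReference({"m1": m1, "m2": m2}, pres), m1, m2

    def test_edit_in_seed(self):
        ref, m1, _ = self._ref()
        edited = m1[:4] + "G" + m1[5:]  # position 5, A->G
        records = detect_edits(_tags((edited, 7)), ref)
        (rec,) = records
        assert (rec.name, rec.position, rec.in_seed) == ("m1", 5, True)
        assert (rec.from_base, rec.to_base) == ("A", "G")
        assert rec.count == 7

    def test_edit_outside_seed(self):
        ref, m1, _ = self._ref()
        edited = m1[:11] + "A" + m1[12:]  # position 12 (C->A)
        (rec,) = detect_edits(_tags((edited, 1)), ref)
        assert rec.position == 12 and rec.in_seed is False

    def test_two_mismatches_not_reported(self):
        ref, m1, _ = self._ref()
        edited = "GG" + m1[2:]
        assert detect_edits(_tags((edited, 1)), ref) == []

    def test_collision_prefers_higher_expression_then_name(self):
        m1 = "AACGTACGTACGTACGTACGT"
        m2 = "CACGTACGTACGTACGTACGT"  # differ only at position 1
        ref = MirnaReference({"b": m1, "a": m2},
                             {"b_pre": m1 + "G" * 30, "a_pre": m2 + "G" * 30})
        tag = "GACGTACGTACGTACGTACGT"  # one mismatch from both
        (rec,) = detect_edits(_tags((tag, 1)), ref, expression={"b": 100, "a": 5})
        assert rec.name == "b"
        (rec,) = detect_edits(_tags((tag, 1)), ref, expression={})
        assert rec.name == "a"  # tie -> lexicographically first

    def test_zero_mismatch_reduces_to_exact_identity(self):
        ref, m1, m2 = self._ref()
        tags = _tags((m1, 2), (m1[:4] + "G" + m1[5:], 1))
        exact = match_with_mismatches(tags, ref, 0)
        assert set(exact) == {m1}
        # and agrees with canonical match_known assignments
        _, assignments = match_known(tags, ref)
        canonical = {s for s, a in assignments.items()
                     if (a.offset5, a.offset3) == (0, 0)}
        assert set(exact) == canonical

    def test_recovers_planted_edits_exactly(self, small_world):
        tags = small_world["tags"]
        assignments = small_world["assignments"]
        unann = {s: t for s, t in tags.items() if s not in assignments}
        expr = {n: r.total for n, r in small_world["records"].items()}
        detected = collections.Counter()
        for e in detect_edits(unann, small_world["reference"], expr):
            detected[(e.name, e.position, e.from_base, e.to_base,
                      e.in_seed)] += e.count
        truth = collections.Counter()
        for lib in small_world["config"].libraries:
            df = small_world["read_truth"][lib]
            for _, row in df[df["kind"] == "edit"].iterrows():
                p = int(row["edit_pos"])
                truth[(row["source"], p,
                       row["edit_from"].replace("T", "U"),
                       row["edit_to"].replace("T", "U"),
                       2 <= p <= 8)] += 1
        assert detected == truth

    def test_edit_and_known_pools_disjoint(self, small_world):
        tags = small_world["tags"]
        assignments = small_world["assignments"]
        unann = {s: t for s, t in tags.items() if s not in assignments}
        expr = {n: r.total for n, r in small_world["records"].items()}
        edited = {e.tag for e in detect_edits(unann, small_world["reference"],
                                              expr)}
        assert edited.isdisjoint(assignments)


class TestEndVariants:
    def test_canonical_and_templated_extension(self):
        mature = "ACGTACGTACGTACGTACGTA"
        pre = "GG" + mature + "CTTTT"
        ref = MirnaReference({"m": mature}, {"m_pre": pre})
        ext = mature + "C"  # templated +1 at the 3' end
        tags = _tags((mature, 4), (ext, 2))
        _, assignments = match_known(tags, ref)
        variants = {(v.offset5, v.offset3): v.count
                    for v in end_variants(tags, assignments)}
        assert variants == {(0, 0): 4, (0, 1): 2}

    def test_recovers_planted_offsets_exactly(self, small_world):
        tags = small_world["tags"]
        variants = {(v.name, v.offset5, v.offset3): v.count
                    for v in end_variants(tags, small_world["assignments"])}
        truth = collections.Counter()
        for lib in small_world["config"].libraries:
            df = small_world["read_truth"][lib]
            for _, row in df[df["kind"] == "isomir"].iterrows():
                truth[(row["source"], int(row["off5"]), int(row["off3"]))] += 1
            for _, row in df[df["kind"] == "canonical"].iterrows():
                if row["source"] in {hp.name for hp in
                                     small_world["truth"].known_mirnas}:
                    truth[(row["source"], 0, 0)] += 1
        for key, count in truth.items():
            assert variants.get(key) == count, key


class TestFamilies:
    @pytest.mark.parametrize("name,family", [
        ("bta-let-7a", "let-7"),
        ("bta-let-7b", "let-7"),
        ("bta-miR-2284e", "miR-2284"),
        ("bta-miR-2284x", "miR-2284"),
        ("bta-miR-199a-3p", "miR-199"),
        ("miR-107", "miR-107"),
        ("hsa-mir-21-5p", "mir-21"),
        ("weird-name", "weird-name"),
    ])
    def test_name_stem_parsing(self, name, family):
        assert family_name(name) == family

    def test_dominant_member(self):
        records = {
            "bta-miR-2284e": MirnaRecord("bta-miR-2284e", "A" * 20, "A" * 60,
                                         0, counts={"x": 0}),
            "bta-miR-2284x": MirnaRecord("bta-miR-2284x", "C" * 20, "C" * 60,
                                         0, counts={"x": 57_585}),
        }
        df = assign_family(records)
        assert df.loc["miR-2284", "members"] == 2
        assert df.loc["miR-2284", "dominant"] == "bta-miR-2284x"
        assert df.loc["miR-2284", "dominant_count"] == 57_585

    def test_single_member_family_is_its_own_dominant(self):
        records = {"bta-miR-107": MirnaRecord("bta-miR-107", "A" * 20,
                                              "A" * 60, 0, counts={"x": 3})}
        df = assign_family(records)
        assert df.loc["miR-107", "dominant"] == "bta-miR-107"

    def test_reference_family_overrides_parsing(self):
        records = {"x-1": MirnaRecord("x-1", "A" * 20, "A" * 60, 0,
                                      family="fam7", counts={"x": 1})}
        assert assign_family(records).index.tolist() == ["fam7"]
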