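"""Tag classification priority logic, known-miRNA matching, and
chromosome density."""

from __future__ import annotations

import itertools

import pytest

from srnakit.annotate import (DEFAULT_PRIORITY, MirnaReference,
                              chromosome_density, classify_tags, match_known)
from srnakit.genome_map import GenomeHit
from srnakit.io import AnnotatedLocus
from srnakit.preprocess import SmallRNATag


def _tag(seq, n=1, lib="x"):
    return {seq: SmallRNATag(seq, {lib: n})}


def _hit(seq, chrom="c", start=100, strand="+", n=1):
    return {seq: [GenomeHit(sequence=seq, chrom=chrom, start=start,
                            strand=strand, hit_count=n)]}


SEQ = "ACGTACGTACGTACGTACGT"


class TestClassifyTags:
    def test_single_overlap(self):
        loci = [AnnotatedLocus("c", 90, 200, "+", "rRNA")]
        labels, _ = classify_tags(_hit(SEQ), loci, _tag(SEQ))
        assert labels[SEQ] == "rRNA"

    def test_no_overlap_is_unknown(self):
        loci = [AnnotatedLocus("c", 500, 600, "+", "rRNA")]
        labels, _ = classify_tags(_hit(SEQ), loci, _tag(SEQ))
        assert labels[SEQ] == "Unknown"

    def test_antisense_exon(self):
        loci = [AnnotatedLocus("c", 90, 200, "-", "exon")]
        labels, _ = classify_tags(_hit(SEQ, strand="+"), loci, _tag(SEQ))
        assert labels[SEQ] == "Exon_antisense"

    def test_priority_two_class_enumeration(self):
        """The higher-priority class wins for every ordered class pair."""
        for a, b in itertools.combinations(DEFAULT_PRIORITY, 2):
            loci = [AnnotatedLocus("c", 90, 200, "+", a),
                    AnnotatedLocus("c", 90, 200, "+", b)]
            labels, _ = classify_tags(_hit(SEQ), loci, _tag(SEQ))
            expected = a if a not in ("exon", "intron") else f"{a.capitalize()}_sense"
            assert labels[SEQ] == expected, (a, b)

    def test_raising_priority_is_monotone(self):
        """Promoting 'repeat' above everything never shrinks its count."""
        loci = [AnnotatedLocus("c", 90, 200, "+", "repeat"),
                AnnotatedLocus("c", 90, 200, "+", "rRNA")]
        _, before = classify_tags(_hit(SEQ), loci, _tag(SEQ))
        promoted = ("repeat",) + tuple(c for c in DEFAULT_PRIORITY
                                       if c != "repeat")
        _, after = classify_tags(_hit(SEQ), loci, _tag(SEQ),
                                 priority=promoted)
        assert (after.loc["repeat", "unique"]
                >= before.loc["repeat", "unique"])

    def test_bad_priority_rejected(self):
        with pytest.raises(ValueError):
            classify_tags(_hit(SEQ), [], _tag(SEQ), priority=("miRNA",))

    def test_partition_property(self, small_world):
        """Every mapped tag gets exactly one class; totals add up."""
        summary = small_world["class_summary"]
        tags, hits = small_world["tags"], small_world["hits"]
        mapped_unique = len(hits)
        mapped_total = sum(tags[s].total for s in hits)
        assert summary["unique"].sum() == mapped_unique
        assert summary["total"].sum() == mapped_total

    def test_decoy_reads_land_in_their_class(self, small_world):
        labels = small_world["labels"]
        truth = small_world["truth"]
        for lib in small_world["config"].libraries:
            df = small_world["read_truth"][lib]
            decoy = df[df["kind"] == "decoy"]
            for name in decoy["source"].unique():
                label = next(l.label for l in truth.decoy_loci
                             if l.name == name)
                if label in ("exon", "intron"):
                    continue  # split into sense/antisense rows
                seqs = [s for s, lab in labels.items() if lab == label]
                assert seqs, label


class TestMatchKnown:
    def _reference(self):
        mature = "ACGTACGTACGTACGTACGTAC"
        pre = "GGGGG" + mature + "TTTTTAAAAA" + "CCCCC"
        return MirnaReference({"m1": mature}, {"m1_pre": pre}), mature, pre

    def test_exact_mature_assigned(self):
        ref, mature, _ = self._reference()
        records, assignments = match_known(_tag(mature, 5), ref)
        assert assignments[mature].name == "m1"
        assert (assignments[mature].offset5, assignments[mature].offset3) == (0, 0)
        assert records["m1"].counts == {"x": 5}

    def test_shifted_tag_recorded_as_variant(self):
        ref, mature, pre = self._reference()
        shifted = pre[5 + 2:5 + len(mature) + 2]  # +2 at both ends
        records, assignments = match_known(_tag(shifted), ref)
        assert assignments[shifted].offset5 == 2
        assert assignments[shifted].offset3 == 2

    def test_no_precursor_match_left_unannotated(self):
        ref, _, _ = self._reference()
        records, assignments = match_known(_tag("GGCCGGCCGGCCGGCCGGCC"), ref)
        assert assignments == {}
        assert records["m1"].counts == {}

    def test_beyond_tolerance_rejected(self):
        ref, mature, pre = self._reference()
        far = pre[0:20]  # starts 5 nt before the mature
        _, assignments = match_known({**_tag(far)}, ref, tolerance=4)
        assert far not in assignments

    def test_mature_absent_from_precursor_errors(self):
        with pytest.raises(ValueError):
            MirnaReference({"m1": "ACGTACGTACGTACGTACGT"},
                           {"m1_pre": "G" * 60})

    def test_missing_precursor_errors(self):
        with pytest.raises(ValueError):
            MirnaReference({"m1": "ACGTACGTACGTACGTACGT"}, {})

    def test_planted_matures_all_assigned(self, small_world):
        records = small_world["records"]
        truth = small_world["truth"]
        for hp in truth.known_mirnas:
            assert records[hp.name].total > 0


class TestChromosomeDensity:
    def test_density_arithmetic(self):
        df = chromosome_density({"X": 38}, {"X": 149_000_000})
        assert df.loc["X", "per_mbp"] == pytest.approx(0.255, abs=5e-4)

    def test_zero_loci(self):
        df = chromosome_density({}, {"c": 1_000_000})
        assert df.loc["c", "per_mbp"] == 0.0

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            chromosome_density({"c": 1}, {"c": 0})

    def test_planted_counts_match_truth(self, small_world):
        truth = small_world["truth"]
        per_chrom: dict[str, int] = {}
        for hp in truth.known_mirnas:
            per_chrom[hp.chrom] = per_chrom.get(hp.chrom, 0) + 1
        lengths = {c: len(s) for c, s in small_world["genome"].items()}
        df = chromosome_density(per_chrom, lengths)
        for chrom, n in per_chrom.items():
            assert df.loc[chrom, "loci"] == n
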