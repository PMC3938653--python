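"""Shared fixtures: one small synthetic world for unit tests and the
default-scale world for the recovery experiments.  All data is generated
in-session from seeds; nothing is read from disk."""

from __future__ import annotations

import pytest

from srnakit.annotate import MirnaReference, classify_tags, match_known
from srnakit.genome_map import build_index, map_tags
from srnakit.preprocess import clean_reads, collapse, merge_tags
from srnakit.synthetic import SyntheticConfig, build_genome, simulate_reads

SMALL_CONFIG = SyntheticConfig(
    n_chrom=2, chrom_len=60_000, n_hairpins=6, n_decoys=7, n_known=10,
    n_de_up=2, n_de_down=2, library_size=20_000, n_transcripts=6,
    transcript_len=500, seed=7)


def _assemble(cfg: SyntheticConfig) -> dict:
    genome, annotation, truth = build_genome(cfg)
    world = {"config": cfg, "genome": genome, "annotation": annotation,
             "truth": truth, "reads": {}, "read_truth": {}, "stats": {},
             "tagsets": {}}
    for lib in cfg.libraries:
        reads, df = simulate_reads(truth, lib, genome)
        inserts, stats = clean_reads(reads, cfg.adapter3, cfg.adapter5)
        world["reads"][lib] = reads
        world["read_truth"][lib] = df
        world["stats"][lib] = stats
        world["tagsets"][lib] = collapse(inserts, lib)
    world["tags"] = merge_tags(*world["tagsets"].values())
    world["index"] = build_index(genome, k=16)
    world["hits"], world["unmapped"] = map_tags(world["tags"].keys(),
                                                world["index"])
    world["labels"], world["class_summary"] = classify_tags(
        world["hits"], annotation, world["tags"])
    world["reference"] = MirnaReference(truth.reference_matures,
                                        truth.reference_precursors)
    world["records"], world["assignments"] = match_known(
        world["tags"], world["reference"])
    return world


@pytest.fixture(scope="session")
def small_world() -> dict:
    """Reduced-scale synthetic experiment shared by the unit tests."""
    return _assemble(SMALL_CONFIG)


@pytest.fixture(scope="session")
def full_world() -> dict:
    """Default-scale synthetic experiment (the study conditions) used by
    the recovery acceptance tests."""
    return _assemble(SyntheticConfig(seed=42))
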