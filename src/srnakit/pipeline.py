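"""End-to-end pipeline orchestration with a deterministic run manifest.

Stages run in order (preprocess -> map -> annotate -> profile -> novel ->
differential expression -> targets); every stage writes its TSV/FASTA
artifacts into the output directory, and the manifest records the seed,
package version, and sha256 checksums of all inputs and outputs.  The
manifest contains no timestamps, so a rerun with the same configuration
and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import (MirnaReference, chromosome_density, classify_tags,
                       match_known)
from .diff_expr import de_frame, differential_expression
from .genome_map import build_index, map_tags
from .io import read_annotation, read_fasta, read_fastq
from .novel_mirna import NovelConfig, predict, prediction_table
from .preprocess import clean_reads, collapse, length_histogram, merge_tags
from .report import clean_stats_table, known_mirna_table, length_table
from .seqs import to_rna
from .target_predict import scan
from .variant_profile import (assign_family, detect_edits, end_variants,
                              first_nt_bias, position_bias)

STAGES = ("preprocess", "map", "annotate", "profile", "novel", "de", "targets")


@dataclass
class PipelineConfig:
    """Paths, thresholds and seed of one pipeline run."""

    reads: dict[str, str]          # library id -> FASTQ path
    genome: str
    annotation: str
    mature_fa: str
    precursor_fa: str
    transcripts: str
    outdir: str
    adapter3: str = "TCGTATGCCGTCTTCTGCTTG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    flank: int = 150
    max_hits: int = 10
    mfei_min: float = 0.85
    dg_max: float = -18.0
    dg_duplex_max: float = -20.0
    p_threshold: float = 0.01
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if len(self.reads) != 2:
            raise ValueError("exactly two read libraries are required")
        for label, path in [("genome", self.genome),
                            ("annotation", self.annotation),
                            ("mature_fa", self.mature_fa),
                            ("precursor_fa", self.precursor_fa),
                            ("transcripts", self.transcripts),
                            *[(f"reads[{k}]", v) for k, v in self.reads.items()]]:
            if not Path(path).exists():
                raise FileNotFoundError(f"{label} path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    libraries = tuple(sorted(config.reads))
    outputs: list[Path] = []

    # --- preprocess -------------------------------------------------------
    stats = {}
    per_lib_tags = {}
    for lib in libraries:
        reads = read_fastq(config.reads[lib])
        inserts, st = clean_reads(reads, config.adapter3, config.adapter5)
        stats[lib] = st
        per_lib_tags[lib] = collapse(inserts, lib)
    tags = merge_tags(*per_lib_tags.values())
    _write_tsv(clean_stats_table(stats), out / "clean_stats.tsv")
    tag_df = pd.DataFrame(
        [{"sequence": seq,
          **{lib: t.counts.get(lib, 0) for lib in libraries}}
         for seq, t in sorted(tags.items())])
    _write_tsv(tag_df, out / "tags.tsv", index=False)
    _write_tsv(length_table(length_histogram(tags)), out / "length_hist.tsv")
    outputs += [out / "clean_stats.tsv", out / "tags.tsv",
                out / "length_hist.tsv"]

    # --- map --------------------------------------------------------------
    genome = read_fasta(config.genome)
    index = build_index(genome, k=16)
    hits, unmapped = map_tags(tags.keys(), index, max_hits=config.max_hits)
    hit_rows = [{"sequence": seq, "chrom": h.chrom, "start": h.start,
                 "end": h.end, "strand": h.strand, "n_hits": h.hit_count}
                for seq in sorted(hits) for h in hits[seq]]
    _write_tsv(pd.DataFrame(hit_rows), out / "hits.tsv", index=False)
    outputs.append(out / "hits.tsv")

    # --- annotate ---------------------------------------------------------
    loci = read_annotation(config.annotation)
    labels, class_summary = classify_tags(hits, loci, tags)
    reference = MirnaReference.from_fasta(config.mature_fa, config.precursor_fa)
    records, assignments = match_known(tags, reference)
    _write_tsv(class_summary, out / "class_summary.tsv")
    known_df = pd.DataFrame(
        [{"name": r.name, "mature": to_rna(r.mature), "family": r.family,
          **{lib: r.counts.get(lib, 0) for lib in libraries}}
         for r in sorted(records.values(), key=lambda r: r.name)])
    _write_tsv(known_df, out / "known_mirna.tsv", index=False)
    _write_tsv(known_mirna_table(records, tags, assignments, libraries),
               out / "known_summary.tsv")
    # chromosome density over known precursor loci
    pre_hits, _ = map_tags([r.precursor for r in reference.records.values()],
                           index, max_hits=config.max_hits)
    loci_per_chrom: dict[str, int] = {}
    for seq_hits in pre_hits.values():
        for h in seq_hits:
            loci_per_chrom[h.chrom] = loci_per_chrom.get(h.chrom, 0) + 1
    density = chromosome_density(loci_per_chrom,
                                 {c: len(s) for c, s in genome.items()})
    _write_tsv(density, out / "chrom_density.tsv")
    outputs += [out / "class_summary.tsv", out / "known_mirna.tsv",
                out / "known_summary.tsv", out / "chrom_density.tsv"]

    # --- profile ----------------------------------------------------------
    _write_tsv(first_nt_bias(tags), out / "first_nt_bias.tsv")
    _write_tsv(position_bias(tags), out / "position_bias.tsv")
    unannotated = {s: t for s, t in tags.items() if s not in assignments}
    expression = {name: r.total for name, r in records.items()}
    edits = detect_edits(unannotated, reference, expression)
    _write_tsv(pd.DataFrame([e.__dict__ for e in edits]),
               out / "edits.tsv", index=False)
    variants = end_variants(tags, assignments)
    _write_tsv(pd.DataFrame([v.__dict__ for v in variants]),
               out / "end_variants.tsv", index=False)
    _write_tsv(assign_family(records), out / "families.tsv")
    outputs += [out / "first_nt_bias.tsv", out / "position_bias.tsv",
                out / "edits.tsv", out / "end_variants.tsv",
                out / "families.tsv"]

    # --- novel ------------------------------------------------------------
    novel_cfg = NovelConfig(flank=config.flank, max_hits=config.max_hits,
                            mfei_min=config.mfei_min, dg_max=config.dg_max,
                            dg_duplex_max=config.dg_duplex_max)
    accepted, _all = predict(hits, labels, tags, genome, novel_cfg)
    pred_df = prediction_table(accepted)
    _write_tsv(pred_df, out / "novel_predictions.tsv", index=False)
    with open(out / "novel_loci.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in pred_df.iterrows():
            fh.write(f"{row['chrom']}\tsrnakit\tpre_miRNA\t{row['start']}\t"
                     f"{row['end']}\t.\t{row['strand']}\t.\t"
                     f"ID={row['name']}\n")
    with open(out / "novel_precursors.fa", "w") as fh:
        for _, row in pred_df.iterrows():
            fh.write(f">{row['name']}\n{row['precursor']}\n")
            fh.write(f">{row['name']}_mature\n{row['mature']}\n")
    outputs += [out / "novel_predictions.tsv", out / "novel_loci.gff3",
                out / "novel_precursors.fa"]

    # --- differential expression -----------------------------------------
    lib1, lib2 = libraries
    counts = {name: (r.counts.get(lib1, 0), r.counts.get(lib2, 0))
              for name, r in records.items()}
    de = differential_expression(counts, stats[lib1].clean_reads,
                                 stats[lib2].clean_reads,
                                 p_threshold=config.p_threshold)
    _write_tsv(de_frame(de), out / "de_results.tsv")
    outputs.append(out / "de_results.tsv")

    # --- targets ----------------------------------------------------------
    transcripts = read_fasta(config.transcripts)
    frames = []
    for name, rec in sorted(records.items()):
        df = scan(rec.mature, transcripts)
        if len(df):
            df.insert(0, "mirna", name)
            frames.append(df)
    target_df = (pd.concat(frames, ignore_index=True) if frames
                 else pd.DataFrame())
    _write_tsv(target_df, out / "target_sites.tsv", index=False)
    outputs.append(out / "target_sites.tsv")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(STAGES),
        "inputs": {str(p): _sha256(Path(p)) for p in sorted(
            {config.genome, config.annotation, config.mature_fa,
             config.precursor_fa, config.transcripts,
             *config.reads.values()})},
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
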