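"""Synthetic two-library small RNA-seq dataset with planted ground truth.

Generates a random genome carrying planted miRNA hairpins (a known set with
an accompanying mature/precursor reference and planted fold changes, and a
novel set left unannotated for hairpin prediction), decoy ncRNA/repeat/
exon/intron loci, and two adapter-ligated read libraries with isomiR end
offsets, single-base edits, contaminant categories and background
degradation reads.  Every planted hairpin is rejection-sampled until it
passes the novel-miRNA prediction criteria under this package's folding
engine, so recovery experiments have a well-defined truth.

All randomness flows from one integer seed; regeneration with the same
seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnnotatedLocus
from .novel_mirna import NovelConfig, Window, evaluate_candidate
from .preprocess import SmallRNATag, classify_read, locate_adapter3
from .seqs import revcomp

_BASES = np.array(list("ACGT"))

#: decoy feature classes and their locus lengths
DECOY_CLASSES = (("rRNA", 120), ("tRNA", 75), ("snRNA", 150),
                 ("snoRNA", 100), ("repeat", 300), ("exon", 200),
                 ("intron", 500))


@dataclass
class SyntheticConfig:
    """Study conditions of the simulated experiment."""

    n_chrom: int = 2
    chrom_len: int = 100_000
    n_hairpins: int = 30          # novel (unannotated) hairpins
    n_decoys: int = 20
    n_known: int = 40             # known miRNAs with a reference entry
    seed: int = 42
    libraries: tuple[str, str] = ("fetal", "adult")
    library_size: int = 100_000
    read_len: int = 36
    adapter3: str = "TCGTATGCCGTCTTCTGCTTG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    isomir_rate: float = 0.15
    edit_rate: float = 0.05
    frac_adaptor3_null: float = 0.02
    frac_insert_null: float = 0.01
    frac_adaptor5: float = 0.01
    frac_short: float = 0.02
    frac_polya: float = 0.001
    background_rate: float = 0.002
    n_de_up: int = 6              # knowns planted higher in library 1
    n_de_down: int = 6
    de_fold: float = 4.0
    de_mean: float = 150.0        # baseline mean count of DE miRNAs
    known_mean_range: tuple[float, float] = (30.0, 1500.0)
    novel_mean: float = 80.0
    star_mean: float = 8.0
    decoy_mean: float = 40.0
    first_nt_u_bias: float = 0.8
    repeat_tag_loci: int = 0      # plant one tag at this many extra loci
    n_transcripts: int = 12
    transcript_len: int = 800
    placement_retries: int = 200
    hairpin_retries: int = 80


@dataclass
class PlantedHairpin:
    """A hairpin embedded in the genome, with its genomic geometry."""

    name: str
    chrom: str
    strand: str
    pre_start: int   # genomic, 0-based
    pre_end: int     # half-open
    precursor: str   # genomic-strand-corrected, 5'->3' (DNA alphabet)
    mature: str
    star: str
    arm: str
    mature_start: int  # genomic
    mature_end: int
    star_start: int
    star_end: int


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for recovery experiments."""

    config: SyntheticConfig
    planted_hairpins: list[PlantedHairpin] = field(default_factory=list)
    known_mirnas: list[PlantedHairpin] = field(default_factory=list)
    decoy_loci: list[AnnotatedLocus] = field(default_factory=list)
    annotation: list[AnnotatedLocus] = field(default_factory=list)
    expression: dict[str, dict[str, float]] = field(default_factory=dict)
    reference_matures: dict[str, str] = field(default_factory=dict)
    reference_precursors: dict[str, str] = field(default_factory=dict)
    transcripts: dict[str, str] = field(default_factory=dict)
    planted_sites: list[tuple[str, str, int]] = field(default_factory=list)
    repeat_tag: str = ""
    repeat_tag_loci: list[tuple[str, int]] = field(default_factory=list)

    @property
    def true_fold(self) -> dict[str, float]:
        lib1, lib2 = self.config.libraries
        return {name: means[lib1] / means[lib2]
                for name, means in self.expression.items()}


def _rand_seq(rng: np.random.Generator, n: int,
              p: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=list(p))])


def _random_mature(rng: np.random.Generator, cfg: SyntheticConfig) -> str:
    # peaked at 22 nt, the canonical mature length
    length = int(rng.choice([20, 21, 22], p=[0.15, 0.3, 0.55]))
    first = "T" if rng.random() < cfg.first_nt_u_bias else str(rng.choice(["A", "C", "G"]))
    # mildly GC-rich body so precursors clear the MFEI threshold comfortably
    body = _rand_seq(rng, length - 1, p=(0.22, 0.28, 0.28, 0.22))
    return first + body


def _construct_precursor(rng: np.random.Generator, cfg: SyntheticConfig,
                         ) -> tuple[str, str, str]:
    """One stem-loop template draw: (precursor, mature, arm).

    Complementary arms around a short loop; one or two point changes in the
    arm opposite the mature introduce wobbles/small imperfections (and keep
    the mature from exact-matching the opposite arm on the other strand).
    """
    mature = _random_mature(rng, cfg)
    loop = _rand_seq(rng, int(rng.integers(10, 15)), p=(0.35, 0.15, 0.15, 0.35))
    other = list(revcomp(mature))
    for _ in range(int(rng.integers(1, 3))):
        pos = int(rng.integers(2, len(other) - 2))
        other[pos] = str(rng.choice([b for b in "ACGT" if b != other[pos]]))
    other_arm = "".join(other)
    arm = "5p" if rng.random() < 0.5 else "3p"
    if arm == "5p":
        precursor = mature + loop + other_arm
    else:
        precursor = other_arm + loop + mature
    return precursor, mature, arm


def _is_clean_insert(seq: str, cfg: SyntheticConfig) -> bool:
    """True iff the insert survives cleaning unchanged; inserts that
    themselves contain an adapter-like match are rejected so that trimming
    is exact (and idempotent) on every planted read."""
    if locate_adapter3(seq, cfg.adapter3) is not None:
        return False
    read = (seq + cfg.adapter3)[:cfg.read_len]
    cat, insert = classify_read(read, cfg.adapter3, cfg.adapter5)
    return cat == "clean_reads" and insert == seq


class PlacementError(RuntimeError):
    pass


class _Placer:
    """Reserves non-overlapping genomic slots with a safety margin so that
    candidate windows of distinct loci never merge."""

    def __init__(self, cfg: SyntheticConfig, margin: int = 360) -> None:
        self.cfg = cfg
        self.margin = margin
        self.occupied: dict[str, list[tuple[int, int]]] = {
            f"chr{i + 1}": [] for i in range(cfg.n_chrom)}

    def place(self, rng: np.random.Generator, length: int,
              what: str) -> tuple[str, int]:
        for _ in range(self.cfg.placement_retries):
            chrom = f"chr{int(rng.integers(1, self.cfg.n_chrom + 1))}"
            lo, hi = self.margin, self.cfg.chrom_len - length - self.margin
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            span = (start - self.margin, start + length + self.margin)
            if all(span[1] <= s or span[0] >= e
                   for s, e in self.occupied[chrom]):
                self.occupied[chrom].append((start, start + length))
                return chrom, start
        raise PlacementError(f"could not place locus {what!r} after "
                             f"{self.cfg.placement_retries} retries")


def _plant_hairpin(rng, cfg, genome_lists, placer, name,
                   novel_cfg: NovelConfig) -> PlantedHairpin:
    """Embed one hairpin that provably passes the prediction criteria.

    Rejection sampling: draw a stem-loop, splice it in with its real
    genomic flanks, run the candidate evaluator on the exact window the
    pipeline would build (mature alone, then mature+star), and keep the
    draw only if the verdict holds both times.
    """
    slot = 46 + 14 + 46 + 4
    chrom, start = placer.place(rng, slot, name)
    clen = cfg.chrom_len
    original = list(genome_lists[chrom][start:start + slot])
    for _ in range(cfg.hairpin_retries):
        precursor, mature, arm = _construct_precursor(rng, cfg)
        if not _is_clean_insert(mature, cfg):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        embedded = precursor if strand == "+" else revcomp(precursor)
        seq = genome_lists[chrom]
        seq[start:start + slot] = original  # clear any previous draw
        seq[start:start + len(precursor)] = list(embedded)
        genome = {c: "".join(s) for c, s in genome_lists.items()}
        # single-locus planting: the mature must occur exactly once
        if sum(g.count(mature) + g.count(revcomp(mature))
               for g in genome.values()) != 1:
            continue
        # genomic span of the mature
        off = precursor.find(mature)
        if strand == "+":
            m_start = start + off
        else:
            m_start = start + (len(precursor) - off - len(mature))
        m_end = m_start + len(mature)
        window = Window(chrom=chrom, strand=strand,
                        start=max(0, m_start - novel_cfg.flank),
                        end=min(clen, m_end + novel_cfg.flank),
                        members=[(mature, m_start)])
        tags = {mature: SmallRNATag(mature, {"sim": 10})}
        cand = evaluate_candidate(window, genome, tags, novel_cfg)
        if not cand.verdict:
            continue
        star = cand.star.replace("U", "T")
        if not _is_clean_insert(star, cfg):
            continue
        # genomic span of the star, then re-check the star-extended window
        if strand == "+":
            s_start = genome[chrom].find(star, start - 5, start + len(precursor) + 5)
        else:
            s_start = genome[chrom].find(revcomp(star), start - 5,
                                         start + len(precursor) + 5)
        if s_start < 0:
            continue
        s_end = s_start + len(star)
        lo, hi = min(m_start, s_start), max(m_end, s_end)
        window2 = Window(chrom=chrom, strand=strand,
                         start=max(0, lo - novel_cfg.flank),
                         end=min(clen, hi + novel_cfg.flank),
                         members=[(mature, m_start), (star, s_start)])
        tags2 = {mature: SmallRNATag(mature, {"sim": 10}),
                 star: SmallRNATag(star, {"sim": 2})}
        cand2 = evaluate_candidate(window2, genome, tags2, novel_cfg)
        if not (cand2.verdict and cand2.mature == mature.replace("T", "U")):
            continue
        return PlantedHairpin(
            name=name, chrom=chrom, strand=strand, pre_start=start,
            pre_end=start + len(precursor), precursor=precursor,
            mature=mature, star=star, arm=arm, mature_start=m_start,
            mature_end=m_end, star_start=s_start, star_end=s_end)
    raise PlacementError(f"could not construct a criteria-passing hairpin "
                         f"for {name!r} after {cfg.hairpin_retries} draws")


def build_genome(config: SyntheticConfig | None = None,
                 ) -> tuple[dict[str, str], list[AnnotatedLocus], SyntheticTruth]:
    """Generate genome, annotation and planted truth for one experiment."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng([cfg.seed, 3])
    genome_lists = {f"chr{i + 1}": list(_rand_seq(rng, cfg.chrom_len))
                    for i in range(cfg.n_chrom)}
    truth = SyntheticTruth(config=cfg)
    placer = _Placer(cfg)
    novel_cfg = NovelConfig()
    lib1, lib2 = cfg.libraries

    for i in range(cfg.n_known):
        name = f"syn-miR-{i + 1}"
        hp = _plant_hairpin(rng, cfg, genome_lists, placer, name, novel_cfg)
        hp.name = name
        truth.known_mirnas.append(hp)
        # reference precursor with 5 nt genomic context so templated isomiRs
        # stay inside the reference precursor
        chrom_seq = "".join(genome_lists[hp.chrom])
        ext = chrom_seq[hp.pre_start - 5:hp.pre_end + 5]
        pre = ext if hp.strand == "+" else revcomp(ext)
        truth.reference_matures[name] = hp.mature
        truth.reference_precursors[f"{name}_pre"] = pre
        truth.annotation.append(AnnotatedLocus(
            chrom=hp.chrom, start=hp.pre_start, end=hp.pre_end,
            strand=hp.strand, label="miRNA", name=name))
        if i < cfg.n_de_up:
            means = {lib1: cfg.de_mean * cfg.de_fold, lib2: cfg.de_mean}
        elif i < cfg.n_de_up + cfg.n_de_down:
            means = {lib1: cfg.de_mean, lib2: cfg.de_mean * cfg.de_fold}
        else:
            m = float(np.exp(rng.uniform(np.log(cfg.known_mean_range[0]),
                                         np.log(cfg.known_mean_range[1]))))
            means = {lib1: m, lib2: m}
        truth.expression[name] = means

    for i in range(cfg.n_hairpins):
        name = f"nv-mir-{i + 1}"
        hp = _plant_hairpin(rng, cfg, genome_lists, placer, name, novel_cfg)
        truth.planted_hairpins.append(hp)
        truth.expression[name] = {lib1: cfg.novel_mean, lib2: cfg.novel_mean}
        truth.expression[f"{name}*"] = {lib1: cfg.star_mean,
                                        lib2: cfg.star_mean}

    for i in range(cfg.n_decoys):
        label, length = DECOY_CLASSES[i % len(DECOY_CLASSES)]
        chrom, start = placer.place(rng, length, f"decoy-{label}-{i + 1}")
        strand = "+" if rng.random() < 0.5 else "-"
        locus = AnnotatedLocus(chrom=chrom, start=start, end=start + length,
                               strand=strand, label=label,
                               name=f"decoy-{label}-{i + 1}")
        truth.decoy_loci.append(locus)
        truth.annotation.append(locus)
        truth.expression[locus.name] = {lib1: cfg.decoy_mean,
                                        lib2: cfg.decoy_mean}

    # scale expression means so that clean reads fill the library size
    junk = (cfg.frac_adaptor3_null + cfg.frac_insert_null + cfg.frac_adaptor5
            + cfg.frac_short + cfg.frac_polya + cfg.background_rate)
    clean_target = cfg.library_size * (1.0 - junk)
    current = sum(m[lib1] for m in truth.expression.values())
    if current > 0:
        factor = clean_target / current
        for means in truth.expression.values():
            means[lib1] *= factor
            means[lib2] *= factor

    if cfg.repeat_tag_loci > 0:
        tag = _rand_seq(rng, 22)
        while not _is_clean_insert(tag, cfg):
            tag = _rand_seq(rng, 22)
        truth.repeat_tag = tag
        for j in range(cfg.repeat_tag_loci):
            chrom, start = placer.place(rng, len(tag), f"repeat-tag-{j}")
            genome_lists[chrom][start:start + len(tag)] = list(tag)
            truth.repeat_tag_loci.append((chrom, start))

    genome = {c: "".join(s) for c, s in genome_lists.items()}

    # uniqueness of planted matures (single-locus planting)
    for hp in truth.known_mirnas + truth.planted_hairpins:
        n = sum(g.count(hp.mature) + g.count(revcomp(hp.mature))
                for g in genome.values())
        if n != 1:
            raise PlacementError(f"mature of {hp.name!r} occurs {n} times "
                                 f"in the genome")

    # transcripts with planted perfect target sites for the first knowns
    for t in range(cfg.n_transcripts):
        tid = f"tx{t + 1}"
        seq = _rand_seq(rng, cfg.transcript_len)
        truth.transcripts[tid] = seq
    for k in range(min(3, cfg.n_known)):
        name = f"syn-miR-{k + 1}"
        site = revcomp(truth.reference_matures[name])
        for _ in range(2):
            tid = f"tx{int(rng.integers(1, cfg.n_transcripts + 1))}"
            seq = truth.transcripts[tid]
            pos = int(rng.integers(50, len(seq) - len(site) - 50))
            truth.transcripts[tid] = (seq[:pos] + site
                                      + seq[pos + len(site):])
            truth.planted_sites.append((tid, name, pos))

    return genome, list(truth.annotation), truth


def _offsets(rng: np.random.Generator, length: int) -> tuple[int, int]:
    """Draw a non-canonical (5', 3') end-offset pair keeping 18-30 nt."""
    for _ in range(50):
        off5 = int(rng.choice([-2, -1, 0, 1, 2], p=[.1, .15, .5, .15, .1]))
        off3 = int(rng.choice([-2, -1, 0, 1, 2], p=[.15, .25, .2, .25, .15]))
        if (off5, off3) == (0, 0):
            continue
        if 18 <= length - off5 + off3 <= 30:
            return off5, off3
    return 0, 1


def _extract_offset_read(genome, hp: PlantedHairpin, off5: int, off3: int) -> str:
    if hp.strand == "+":
        s, e = hp.mature_start + off5, hp.mature_end + off3
        return genome[hp.chrom][s:e]
    s, e = hp.mature_start - off3, hp.mature_end - off5
    return revcomp(genome[hp.chrom][s:e])


def simulate_reads(truth: SyntheticTruth, library: str,
                   genome: dict[str, str],
                   ) -> tuple[list[str], pd.DataFrame]:
    """Simulate one adapter-ligated library; returns (reads, read truth).

    Per-source read counts are Poisson around the expression-table means;
    known-miRNA reads carry isomiR end offsets and single-base edits at the
    configured rates; contaminant categories and genome background reads
    are mixed in at the configured fractions.  The read-truth table has one
    row per emitted read, in emission order.
    """
    cfg = truth.config
    if library not in cfg.libraries:
        raise ValueError(f"unknown library {library!r}")
    lib_index = cfg.libraries.index(library)
    rng = np.random.default_rng([cfg.seed, 11, lib_index])
    by_name_known = {hp.name: hp for hp in truth.known_mirnas}
    by_name_novel = {hp.name: hp for hp in truth.planted_hairpins}
    decoys = {loc.name: loc for loc in truth.decoy_loci}

    inserts: list[tuple[str, dict]] = []  # (insert or raw read, truth row)

    def emit(insert, **row):
        inserts.append((insert, row))

    for name in sorted(truth.expression):
        mean = truth.expression[name][library]
        count = int(rng.poisson(mean))
        base = name.rstrip("*")
        for _ in range(count):
            if name.endswith("*"):
                hp = by_name_novel[base]
                emit(hp.star, source=base, kind="star")
            elif base in by_name_known:
                hp = by_name_known[base]
                u = rng.random()
                if u < cfg.edit_rate:
                    seq = hp.mature
                    for _ in range(30):
                        pos = int(rng.integers(0, len(seq)))
                        alt = str(rng.choice([b for b in "ACGT"
                                              if b != seq[pos]]))
                        cand = seq[:pos] + alt + seq[pos + 1:]
                        if _is_clean_insert(cand, cfg):
                            emit(cand, source=base, kind="edit",
                                 edit_pos=pos + 1, edit_from=seq[pos],
                                 edit_to=alt)
                            break
                elif u < cfg.edit_rate + cfg.isomir_rate:
                    for _ in range(30):
                        off5, off3 = _offsets(rng, len(hp.mature))
                        seq = _extract_offset_read(genome, hp, off5, off3)
                        if _is_clean_insert(seq, cfg):
                            emit(seq, source=base, kind="isomir",
                                 off5=off5, off3=off3)
                            break
                else:
                    emit(hp.mature, source=base, kind="canonical")
            elif base in by_name_novel:
                emit(by_name_novel[base].mature, source=base, kind="canonical")
            else:  # decoy locus: random sub-window, mostly sense
                loc = decoys[base]
                for _ in range(30):
                    ln = int(rng.integers(18, 31))
                    start = int(rng.integers(loc.start, loc.end - ln))
                    seq = genome[loc.chrom][start:start + ln]
                    antisense = (loc.label in ("exon", "intron")
                                 and rng.random() < 0.3)
                    read_strand = loc.strand
                    if antisense:
                        read_strand = "-" if loc.strand == "+" else "+"
                    if read_strand == "-":
                        seq = revcomp(seq)
                    if _is_clean_insert(seq, cfg):
                        emit(seq, source=base, kind="decoy")
                        break

    n_background = int(rng.binomial(cfg.library_size, cfg.background_rate))
    chroms = sorted(genome)
    for _ in range(n_background):
        for _ in range(30):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            ln = int(rng.integers(18, 31))
            start = int(rng.integers(0, len(genome[chrom]) - ln))
            seq = genome[chrom][start:start + ln]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            if _is_clean_insert(seq, cfg):
                emit(seq, source="background", kind="background")
                break

    reads: list[tuple[str, dict]] = []
    for insert, row in inserts:
        read = insert + cfg.adapter3
        if len(read) < cfg.read_len:
            read += _rand_seq(rng, cfg.read_len - len(read))
        reads.append((read[:cfg.read_len], {"category": "clean_reads", **row}))

    # contaminant / junk categories
    def junk(n, builder, category):
        for _ in range(n):
            for _ in range(50):
                read = builder()[:cfg.read_len]
                if classify_read(read, cfg.adapter3, cfg.adapter5)[0] == category:
                    reads.append((read, {"category": category,
                                         "source": "junk", "kind": "junk"}))
                    break

    N = cfg.library_size
    junk(int(rng.binomial(N, cfg.frac_adaptor3_null)),
         lambda: _rand_seq(rng, cfg.read_len), "adaptor3_null")
    junk(int(rng.binomial(N, cfg.frac_insert_null)),
         lambda: cfg.adapter3 + _rand_seq(rng, cfg.read_len), "insert_null")
    junk(int(rng.binomial(N, cfg.frac_adaptor5)),
         lambda: cfg.adapter5 + _rand_seq(rng, 22) + cfg.adapter3,
         "adaptor5_contaminants")
    junk(int(rng.binomial(N, cfg.frac_short)),
         lambda: _rand_seq(rng, int(rng.integers(5, 18))) + cfg.adapter3
         + _rand_seq(rng, cfg.read_len), "small_than_18nt")
    junk(int(rng.binomial(N, cfg.frac_polya)),
         lambda: "A" * int(rng.integers(20, 29)) + cfg.adapter3, "polya")

    order = rng.permutation(len(reads))
    shuffled = [reads[i] for i in order]
    df = pd.DataFrame([row for _, row in shuffled])
    return [r for r, _ in shuffled], df


def dinucleotide_shuffle(genome: dict[str, str], seed: int) -> dict[str, str]:
    """Dinucleotide-preserving shuffle of each chromosome (Altschul-
    Erickson style Eulerian-walk shuffle)."""
    rng = np.random.default_rng([seed, 97])
    out = {}
    for chrom in sorted(genome):
        seq = genome[chrom]
        edges: dict[str, list[str]] = {b: [] for b in "ACGT"}
        for a, b in zip(seq, seq[1:]):
            edges[a].append(b)
        for b in edges:
            arr = np.array(edges[b])
            rng.shuffle(arr)
            edges[b] = list(arr)
        # rebuild by walking; fall back to restart when a node exhausts
        walk = [seq[0]]
        cur = seq[0]
        counts = {b: 0 for b in "ACGT"}
        for _ in range(len(seq) - 1):
            idx = counts[cur]
            if idx >= len(edges[cur]):
                break
            nxt = edges[cur][idx]
            counts[cur] += 1
            walk.append(nxt)
            cur = nxt
        shuffled = "".join(walk)
        if len(shuffled) < len(seq):
            # composition-preserving remainder: the leftover multiset,
            # plainly shuffled
            from collections import Counter
            rest_counts = Counter(seq) - Counter(shuffled)
            rest = np.array(list("".join(b * n for b, n in
                                         sorted(rest_counts.items()))))
            rng.shuffle(rest)
            shuffled += "".join(rest)
        out[chrom] = shuffled
    return out


def write_dataset(outdir, config: SyntheticConfig | None = None) -> dict:
    """Generate and write a complete synthetic dataset to ``outdir``.

    Emits genome/annotation/reference/transcript files, one FASTQ per
    library, per-read truth tables, and a pipeline-ready ``config.yaml``;
    returns the pipeline configuration dictionary.
    """
    from pathlib import Path

    import yaml

    from .io import write_annotation, write_fasta, write_fastq

    cfg = config or SyntheticConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome, annotation, truth = build_genome(cfg)
    write_fasta(out / "genome.fa", genome)
    write_annotation(out / "annotation.tsv", annotation)
    write_fasta(out / "mature.fa", truth.reference_matures)
    write_fasta(out / "precursor.fa", truth.reference_precursors)
    write_fasta(out / "transcripts.fa", truth.transcripts)
    reads_paths = {}
    for lib in cfg.libraries:
        reads, read_truth = simulate_reads(truth, lib, genome)
        path = out / f"reads_{lib}.fastq"
        write_fastq(path, reads, prefix=lib)
        read_truth.to_csv(out / f"truth_reads_{lib}.tsv", sep="\t",
                          index=False)
        reads_paths[lib] = str(path)
    hairpin_rows = [{**{k: getattr(hp, k) for k in (
        "name", "chrom", "strand", "pre_start", "pre_end", "precursor",
        "mature", "star", "arm")}, "planted_as": kind}
        for kind, group in (("novel", truth.planted_hairpins),
                            ("known", truth.known_mirnas))
        for hp in group]
    pd.DataFrame(hairpin_rows).to_csv(out / "truth_hairpins.tsv", sep="\t",
                                      index=False)
    expr_rows = [{"name": n, **m, "fold": truth.true_fold[n]}
                 for n, m in sorted(truth.expression.items())]
    pd.DataFrame(expr_rows).to_csv(out / "truth_expression.tsv", sep="\t",
                                   index=False)
    pipe_cfg = {
        "reads": reads_paths,
        "genome": str(out / "genome.fa"),
        "annotation": str(out / "annotation.tsv"),
        "mature_fa": str(out / "mature.fa"),
        "precursor_fa": str(out / "precursor.fa"),
        "transcripts": str(out / "transcripts.fa"),
        "outdir": str(out / "results"),
        "adapter3": cfg.adapter3,
        "adapter5": cfg.adapter5,
        "seed": cfg.seed,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(pipe_cfg, fh, sort_keys=True)
    return pipe_cfg
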