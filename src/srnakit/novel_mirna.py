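"""Hairpin-based novel miRNA prediction from unannotated mapped tags.

Eligible tags (unannotated, intronic, or antisense-exonic; at most
``max_hits`` genomic loci) seed candidate windows of +/-150 nt flanking
sequence; overlapping same-strand windows are merged.  Each window is
folded, the most abundant tag is taken as the putative mature, the star is
inferred from the pairing partners with the 2-nt 3' overhang rule, and the
excised precursor is re-folded and scored against the prediction criteria:
mature in one arm, star with 2-nt 3' overhang, no large bulge in the
mature:star duplex, precursor dG <= -18 kcal/mol, MFEI > 0.85, mature
length 20-22 nt, and mature:star hybridization dG < -20 kcal/mol.
Candidates with star-supporting reads are tiered 'high'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .fold import FoldResult, duplex, fold, mfei
from .genome_map import GenomeHit
from .preprocess import TagSet
from .seqs import revcomp, to_rna

#: annotation classes whose tags may seed novel miRNA candidates
ELIGIBLE_CLASSES = frozenset({"Unknown", "Intron_sense", "Intron_antisense",
                              "Exon_antisense"})


@dataclass
class NovelConfig:
    """Thresholds of the prediction criteria (defaults as documented)."""

    flank: int = 150
    max_hits: int = 10
    dg_max: float = -18.0       # precursor MFE ceiling, kcal/mol
    dg_duplex_max: float = -20.0  # mature:star hybridization ceiling
    mfei_min: float = 0.85
    max_bulge: int = 4          # largest loop/bulge inside the duplex
    mature_min_len: int = 20
    mature_max_len: int = 22
    min_paired_frac: float = 0.6
    min_support: int = 3        # total reads required to seed a window


@dataclass
class Window:
    """A candidate genomic window with its member tag stack."""

    chrom: str
    strand: str
    start: int
    end: int
    members: list[tuple[str, int]] = field(default_factory=list)  # (tag, gstart)


@dataclass
class HairpinCandidate:
    """A folded candidate with per-criterion flags and final verdict."""

    window: Window
    mature: str
    arm: str                     # 5p / 3p
    star: str
    star_support: int
    precursor: str
    fold_result: FoldResult
    duplex_mfe: float
    counts: dict[str, int]
    mature_in_one_arm: bool = False
    star_overhang_2nt: bool = False
    no_large_bulge: bool = False
    dg_le_minus18: bool = False
    mfei_gt_0_85: bool = False
    length_20_22: bool = False
    dg_lt_minus20: bool = False

    @property
    def verdict(self) -> bool:
        return all((self.mature_in_one_arm, self.star_overhang_2nt,
                    self.no_large_bulge, self.dg_le_minus18,
                    self.mfei_gt_0_85, self.length_20_22,
                    self.dg_lt_minus20))

    @property
    def tier(self) -> str:
        return "high" if self.star_support > 0 else "candidate"


def candidate_windows(hits: dict[str, list[GenomeHit]],
                      classes: dict[str, str],
                      genome: dict[str, str],
                      flank: int = 150,
                      max_hits: int = 10,
                      tags: TagSet | None = None,
                      min_support: int = 0) -> list[Window]:
    """Extract merged, flank-extended candidate windows.

    Tags with more than ``max_hits`` genomic hits or with a known-ncRNA
    class are excluded; windows on the same chromosome and strand that
    overlap are merged, and windows are clipped at chromosome ends.  When
    ``tags`` are given, merged windows supported by fewer than
    ``min_support`` total reads are dropped.
    """
    raw: list[Window] = []
    for seq, tag_hits in hits.items():
        if classes.get(seq, "Unknown") not in ELIGIBLE_CLASSES:
            continue
        if tag_hits and tag_hits[0].hit_count > max_hits:
            continue
        for hit in tag_hits:
            clen = len(genome[hit.chrom])
            raw.append(Window(chrom=hit.chrom, strand=hit.strand,
                              start=max(0, hit.start - flank),
                              end=min(clen, hit.end + flank),
                              members=[(seq, hit.start)]))
    raw.sort(key=lambda w: (w.chrom, w.strand, w.start, w.end))
    merged: list[Window] = []
    for win in raw:
        last = merged[-1] if merged else None
        if (last is not None and last.chrom == win.chrom
                and last.strand == win.strand and win.start <= last.end):
            last.end = max(last.end, win.end)
            last.members.extend(win.members)
        else:
            merged.append(win)
    if tags is not None and min_support > 0:
        merged = [w for w in merged
                  if sum(tags[s].total for s, _ in w.members
                         if s in tags) >= min_support]
    return merged


def _window_coords(window: Window, seq: str, gstart: int, length: int) -> tuple[int, int]:
    """Map a genomic tag span into window-local 5'->3' coordinates."""
    if window.strand == "+":
        s = gstart - window.start
    else:
        s = window.end - (gstart + length)
    return s, s + length


def evaluate_candidate(window: Window, genome: dict[str, str],
                       tags: TagSet,
                       config: NovelConfig | None = None) -> HairpinCandidate:
    """Fold a window and score it against the prediction criteria.

    The most abundant member tag is the putative mature; the star span is
    the pairing partner region of the mature extended 2 nt at its 3' end
    (the Dicer overhang); the precursor is the mature..star-spanning slice
    re-folded on its own, on which the energy flags are computed.
    """
    config = config or NovelConfig()

    def support(seq: str) -> int:
        tag = tags.get(seq)
        return tag.total if tag else 0

    members = sorted(window.members,
                     key=lambda m: (-support(m[0]), m[0]))
    mature, m_gstart = members[0]
    m0, m1 = _window_coords(window, mature, m_gstart, len(mature))
    if not (0 <= m0 < m1 <= window.end - window.start):
        raise ValueError("mature tag lies outside its window")
    # fold a flank-bounded region centred on the dominant tag stack, so
    # long merged windows stay tractable and the folded context is the
    # same regardless of how far the merged window happens to extend
    lo = max(0, m0 - config.flank)
    hi = min(window.end - window.start, m1 + config.flank)
    window = Window(chrom=window.chrom, strand=window.strand,
                    start=(window.start + lo if window.strand == "+"
                           else window.end - hi),
                    end=(window.start + hi if window.strand == "+"
                         else window.end - lo),
                    members=window.members)
    m0, m1 = _window_coords(window, mature, m_gstart, len(mature))
    gseq = genome[window.chrom][window.start:window.end]
    wseq = gseq if window.strand == "+" else revcomp(gseq)
    counts: dict[str, int] = {}
    for seq, _ in window.members:
        tag = tags.get(seq)
        if tag:
            for lib, n in tag.counts.items():
                counts[lib] = counts.get(lib, 0) + n

    wfold = fold(to_rna(wseq))
    partner = wfold.partner()

    paired = [p for p in range(m0, m1) if p in partner]
    in_arm = (len(paired) >= config.min_paired_frac * (m1 - m0)
              and all(not (m0 <= partner[p] < m1) for p in paired))

    def failed(reason_star: str = "", star_s: int = -1, star_e: int = -1
               ) -> HairpinCandidate:
        return HairpinCandidate(
            window=window, mature=to_rna(mature), arm="5p",
            star=reason_star, star_support=0, precursor=wfold.sequence,
            fold_result=wfold, duplex_mfe=0.0, counts=counts,
            mature_in_one_arm=in_arm,
            length_20_22=(config.mature_min_len <= len(mature)
                          <= config.mature_max_len))

    if not in_arm:
        return failed()

    # star inference with the 2-nt 3' overhang rule
    star_start = partner[paired[-1]]
    star_end = partner[paired[0]] + 2  # inclusive
    if star_start > star_end:  # partners ascend: mature is the 3p arm
        star_start = partner[paired[0]]
        star_end = partner[paired[-1]] + 2
    arm = "5p" if m0 < star_start else "3p"
    star_ok = (0 <= star_start <= star_end < len(wseq)
               and (star_end < m0 or m1 <= star_start))
    if not star_ok:
        return failed()
    star = wseq[star_start:star_end + 1]

    star_support = 0
    for seq, gstart in window.members:
        if seq == mature:
            continue
        s0, s1 = _window_coords(window, seq, gstart, len(seq))
        mid = (s0 + s1) // 2
        if star_start <= mid <= star_end:
            star_support += support(seq)

    # excise and re-fold the precursor
    p0 = min(m0, star_start)
    p1 = max(m1 - 1, star_end)
    precursor = wseq[p0:p1 + 1]
    pfold = fold(to_rna(precursor))
    ppartner = pfold.partner()
    pm0, pm1 = m0 - p0, m1 - p0
    ppaired = [p for p in range(pm0, pm1) if p in ppartner]
    p_in_arm = (len(ppaired) >= config.min_paired_frac * (pm1 - pm0)
                and all(not (pm0 <= ppartner[p] < pm1) for p in ppaired))

    # largest unpaired run inside the mature:star duplex, either strand
    max_loop = 0
    for lo, hi in ((pm0, pm1), (star_start - p0, star_end - p0 + 1)):
        run = 0
        for p in range(max(0, lo), min(hi, len(precursor))):
            run = run + 1 if p not in ppartner else 0
            max_loop = max(max_loop, run)

    dup = duplex(to_rna(mature), to_rna(star))
    mfei_val = mfei(pfold)
    cand = HairpinCandidate(
        window=window, mature=to_rna(mature), arm=arm, star=to_rna(star),
        star_support=star_support, precursor=to_rna(precursor),
        fold_result=pfold, duplex_mfe=dup.mfe, counts=counts,
        mature_in_one_arm=p_in_arm,
        star_overhang_2nt=star_ok,
        no_large_bulge=max_loop <= config.max_bulge,
        dg_le_minus18=pfold.mfe <= config.dg_max,
        mfei_gt_0_85=(not math.isnan(mfei_val)) and mfei_val > config.mfei_min,
        length_20_22=(config.mature_min_len <= len(mature)
                      <= config.mature_max_len),
        dg_lt_minus20=dup.mfe < config.dg_duplex_max,
    )
    return cand


def predict(hits: dict[str, list[GenomeHit]], classes: dict[str, str],
            tags: TagSet, genome: dict[str, str],
            config: NovelConfig | None = None,
            ) -> tuple[list[HairpinCandidate], list[HairpinCandidate]]:
    """Run the full prediction; returns (accepted, all candidates)."""
    config = config or NovelConfig()
    windows = candidate_windows(hits, classes, genome,
                                flank=config.flank, max_hits=config.max_hits,
                                tags=tags, min_support=config.min_support)
    candidates = [evaluate_candidate(w, genome, tags, config) for w in windows]
    accepted = [c for c in candidates if c.verdict]
    return accepted, candidates


def prediction_table(accepted: list[HairpinCandidate]) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(accepted, start=1):
        rows.append({
            "name": f"novel-mir-{i}", "chrom": c.window.chrom,
            "strand": c.window.strand, "start": c.window.start + 1,
            "end": c.window.end, "arm": c.arm, "mature": c.mature,
            "star": c.star, "star_support": c.star_support, "tier": c.tier,
            "precursor": c.precursor, "mfe": c.fold_result.mfe,
            "mfei": c.fold_result.mfei, "duplex_mfe": c.duplex_mfe,
            **{f"count_{lib}": n for lib, n in sorted(c.counts.items())},
        })
    return pd.DataFrame(rows)
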