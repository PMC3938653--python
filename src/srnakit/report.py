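"""Publication-style summary tables assembled from stage outputs."""

from __future__ import annotations

import pandas as pd

from .annotate import MirnaRecord
from .preprocess import CleanStats, TagSet


def clean_stats_table(stats: dict[str, CleanStats]) -> pd.DataFrame:
    """Read-accounting table, one column per library, rows named as in
    standard small RNA-seq summaries."""
    cols = {}
    for lib, st in stats.items():
        st.check()
        cols[lib] = dict(st.as_rows())
    df = pd.DataFrame(cols)
    df.index.name = "Type"
    return df


def known_mirna_table(records: dict[str, MirnaRecord],
                      tags: TagSet,
                      assignments: dict[str, object],
                      libraries: tuple[str, ...]) -> pd.DataFrame:
    """Known-miRNA summary per library: expressed mature categories,
    unique tags matched to precursors, and reads matched."""
    rows = {}
    for lib in libraries:
        expressed = sum(1 for r in records.values() if r.counts.get(lib, 0) > 0)
        unique = sum(1 for seq in assignments if tags[seq].counts.get(lib, 0) > 0)
        reads = sum(tags[seq].counts.get(lib, 0) for seq in assignments)
        rows[lib] = {"miR_categories": expressed,
                     "unique_matched": unique,
                     "reads_matched": reads}
    df = pd.DataFrame(rows).T
    df.index.name = "library"
    return df


def length_table(hist: dict[int, tuple[int, int]]) -> pd.DataFrame:
    df = pd.DataFrame(
        [{"length": k, "total": v[0], "unique": v[1]} for k, v in hist.items()]
    )
    return df.set_index("length") if len(df) else df
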