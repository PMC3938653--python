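"""Count-based differential expression between two small-RNA libraries.

Expression is normalized to transcripts per million clean reads
(NE = count / total clean reads x 10^6); the fold change is
log2(NE_1 / NE_2) with a 0.01 pseudo-NE substituted for zero counts.  The
P-value is the exact conditional count test: given the total x + y, the
count y in library 2 is Binomial(x + y, N2 / (N1 + N2)) under the null of
equal relative expression, and the two-sided P-value doubles the smaller
tail.  Multiple testing is Benjamini-Hochberg by default.  The 2^-ddCt
arithmetic for qPCR relative quantification is included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PSEUDO_NE = 0.01


def normalize(count: int, total_clean: int) -> float:
    """Normalized expression in transcripts per million clean reads."""
    if total_clean <= 0:
        raise ValueError("total clean reads must be positive")
    if count < 0:
        raise ValueError("negative count")
    return count / total_clean * 1e6


def fold_change(ne1: float, ne2: float) -> float:
    """log2(NE1/NE2); zero NEs are replaced by the 0.01 pseudo-NE."""
    return float(np.log2(max(ne1, PSEUDO_NE) / max(ne2, PSEUDO_NE)))


def count_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Exact two-sided P-value for a count difference between libraries.

    Conditional on the total, y ~ Binomial(x + y, N2/(N1+N2)) under the
    null; the two-sided P doubles the smaller of the two inclusive tails
    and is capped at 1.  x = y = 0 gives 1 (no evidence of difference).
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    n = x + y
    if n == 0:
        return 1.0
    q = n2 / (n1 + n2)
    lower = stats.binom.cdf(y, n, q)
    upper = stats.binom.sf(y - 1, n, q)
    return float(min(1.0, 2.0 * min(lower, upper)))


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg (default) or Bonferroni adjustment."""
    p = np.asarray(pvalues, dtype=float)
    if method == "bh":
        return stats.false_discovery_control(p, method="bh")
    if method == "bonferroni":
        return np.minimum(1.0, p * len(p))
    raise ValueError(f"unknown adjustment method {method!r}")


@dataclass(frozen=True)
class DEResult:
    """Per-miRNA differential expression between two libraries."""

    name: str
    x: int
    y: int
    n1: int
    n2: int
    ne1: float
    ne2: float
    log2fc: float
    p_value: float
    adjusted_p: float = float("nan")
    cls: str = ""
    significant: bool = False


def classify_ratio(ne1: float, ne2: float) -> str:
    """Fold-change class on the ratio scale: up (> 2), intermediate
    (1/2 < ratio <= 2), down (<= 1/2)."""
    ratio = max(ne1, PSEUDO_NE) / max(ne2, PSEUDO_NE)
    if ratio > 2.0:
        return "up"
    if ratio <= 0.5:
        return "down"
    return "intermediate"


def differential_expression(counts: dict[str, tuple[int, int]],
                            n1: int, n2: int,
                            p_threshold: float = 0.01,
                            method: str = "bh") -> list[DEResult]:
    """Full two-library DE analysis over {name: (count1, count2)}.

    A miRNA is flagged significant iff its adjusted P-value is below
    ``p_threshold`` and its fold-change class is not intermediate.
    """
    names = sorted(counts)
    raw = [count_pvalue(counts[m][0], counts[m][1], n1, n2) for m in names]
    adj = adjust_pvalues(raw, method) if names else np.array([])
    out = []
    for m, p, ap in zip(names, raw, adj):
        x, y = counts[m]
        ne1, ne2 = normalize(x, n1), normalize(y, n2)
        cls = classify_ratio(ne1, ne2)
        out.append(DEResult(name=m, x=x, y=y, n1=n1, n2=n2, ne1=ne1, ne2=ne2,
                            log2fc=fold_change(ne1, ne2), p_value=p,
                            adjusted_p=float(ap), cls=cls,
                            significant=bool(ap < p_threshold
                                             and cls != "intermediate")))
    return out


def de_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("name")


def ddct(ct_target_sample: float, ct_ref_sample: float,
         ct_target_calib: float, ct_ref_calib: float) -> float:
    """Relative expression N = 2^-ddCt against a reference gene and a
    calibrator sample."""
    delta_delta = ((ct_target_sample - ct_ref_sample)
                   - (ct_target_calib - ct_ref_calib))
    return float(2.0 ** (-delta_delta))
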