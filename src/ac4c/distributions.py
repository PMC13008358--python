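"""Expression quantification (TPM) and distribution-level comparisons.

Cumulative FE distributions between conditions are compared with the
two-sample Kolmogorov-Smirnov test; quartile summaries use the type-7
(linear interpolation) convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .peaks import bh_adjust

__all__ = [
    "ExpressionRecord",
    "compute_tpm",
    "ks_compare",
    "quartile_summary",
    "cumulative_curve",
]

# below this combined sample size the exact two-sample KS distribution is used
_KS_EXACT_MAX_N = 50


@dataclass(frozen=True)
class ExpressionRecord:
    """TPM expression of one transcript; detected iff TPM > 1."""

    transcript_id: str
    tpm: float

    @property
    def detected(self) -> bool:
        return self.tpm > 1.0

    @property
    def log2_tpm(self) -> Optional[float]:
        return math.log2(self.tpm) if self.tpm > 0 else None


def compute_tpm(
    counts: Mapping[str, float], lengths: Mapping[str, float]
) -> Dict[str, ExpressionRecord]:
    """Transcripts per million from read counts and transcript lengths (nt).

    rate_i = count_i / length_i; TPM_i = 1e6 * rate_i / Σ rates.  TPM is
    invariant to rescaling all counts by a constant and sums to 1e6.
    """
    if not counts:
        raise ValueError("no counts supplied")
    rates: Dict[str, float] = {}
    for tid, c in counts.items():
        if tid not in lengths:
            raise ValueError(f"no length for transcript {tid!r}")
        if lengths[tid] <= 0:
            raise ValueError(f"{tid}: length must be positive")
        if c < 0:
            raise ValueError(f"{tid}: negative count")
        rates[tid] = c / lengths[tid]
    total = sum(rates.values())
    if total == 0:
        raise ValueError("all counts are zero")
    return {
        tid: ExpressionRecord(tid, 1e6 * rate / total)
        for tid, rate in rates.items()
    }


def ks_compare(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sample two-sided KS statistic D = sup |F̂x - F̂y| and p-value
    (exact for small combined samples, asymptotic otherwise)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if x.size + y.size <= _KS_EXACT_MAX_N else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def ks_family(
    pairs: Mapping[str, Tuple[Sequence[float], Sequence[float]]]
) -> Dict[str, Dict[str, float]]:
    """KS tests across a family of comparisons with BH adjustment across the
    family (both raw and adjusted p-values reported)."""
    names = list(pairs)
    raw = {}
    for name in names:
        x, y = pairs[name]
        d, p = ks_compare(x, y)
        raw[name] = (d, p)
    qs = bh_adjust([raw[name][1] for name in names])
    return {
        name: {"D": raw[name][0], "pvalue": raw[name][1], "qvalue": float(q)}
        for name, q in zip(names, qs)
    }


def quartile_summary(x: Sequence[float]) -> Dict[str, float]:
    """(min, q1, median, mean, q3, max) with type-7 quartiles."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # numpy default = type 7
    return {
        "min": float(x.min()),
        "q1": float(q1),
        "median": float(med),
        "mean": float(x.mean()),
        "q3": float(q3),
        "max": float(x.max()),
    }


def cumulative_curve(
    x: Sequence[float], grid: Optional[Sequence[float]] = None
) -> List[Tuple[float, float]]:
    """Right-continuous empirical CDF sampled at the sorted unique values
    of ``x`` (or at a supplied grid)."""
    x = np.sort(np.asarray(x, dtype=float))
    if x.size == 0:
        raise ValueError("empty sample")
    pts = np.unique(x) if grid is None else np.asarray(grid, dtype=float)
    cdf = np.searchsorted(x, pts, side="right") / x.size
    return list(zip(pts.tolist(), cdf.tolist()))
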