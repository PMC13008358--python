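"""Peak-to-region assignment, metagene profiles and summit-region tests.

A peak is assigned to 5'UTR, CDS or 3'UTR by its summit position alone
(standard for summit-based metagene plots); a summit landing exactly on a
segment boundary belongs to the downstream segment, consistent with the
half-open coordinate convention used throughout.
"""

from __future__ import annotations

import math
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .models import (
    ConsensusPeak,
    MetageneProfile,
    Peak,
    Region,
    TranscriptModel,
)

__all__ = [
    "assign_region",
    "metagene",
    "peaks_per_transcript",
    "region_chisq",
]

AnyPeak = Union[Peak, ConsensusPeak]

_REGION_ORDER = [Region.UTR5, Region.CDS, Region.UTR3]


def _summit(peak: AnyPeak) -> int:
    if isinstance(peak, Peak):
        return peak.summit
    return (peak.start + peak.end) // 2  # consensus peaks carry no summit


def assign_region(peak: AnyPeak, model: TranscriptModel) -> Region:
    """Region of the peak's summit (midpoint for consensus peaks)."""
    if peak.transcript_id != model.transcript_id:
        raise ValueError("peak and model refer to different transcripts")
    if peak.start < 0 or peak.end > model.total_len:
        raise ValueError("peak outside transcript")
    return model.region_of(_summit(peak))


def _region_bounds(model: TranscriptModel, region: Region) -> Tuple[int, int]:
    if region is Region.UTR5:
        return 0, model.cds_start
    if region is Region.CDS:
        return model.cds_start, model.cds_end
    return model.cds_end, model.total_len


def metagene(
    peaks: Sequence[AnyPeak],
    models: Mapping[str, TranscriptModel],
    bins_per_region: int = 30,
) -> MetageneProfile:
    """Summit density over length-normalised UTR5 | CDS | UTR3 bins.

    Each summit maps to (position - region start) / region length within its
    own region; counts are normalised to sum to 1 (all-zero when no peaks).
    """
    counts = np.zeros(3 * bins_per_region)
    n = 0
    for peak in peaks:
        if peak.transcript_id not in models:
            raise ValueError(f"peak on unknown transcript {peak.transcript_id!r}")
        model = models[peak.transcript_id]
        region = assign_region(peak, model)
        lo, hi = _region_bounds(model, region)
        frac = (_summit(peak) - lo) / (hi - lo)
        b = min(int(frac * bins_per_region), bins_per_region - 1)
        counts[_REGION_ORDER.index(region) * bins_per_region + b] += 1
        n += 1
    if n:
        counts /= n
    return MetageneProfile(bins_per_region=bins_per_region, density=counts, n_summits=n)


def peaks_per_transcript(
    peaks: Sequence[AnyPeak], models: Mapping[str, TranscriptModel]
) -> Dict[str, Optional[float]]:
    """Mean and SEM of peaks per acetylated transcript, plus the acetylated
    fraction of all annotated transcripts.  Mean/SEM are over transcripts
    with at least one peak; with no peaks they are reported as None."""
    if not models:
        raise ValueError("models must be non-empty")
    per_tid: Dict[str, int] = {}
    for p in peaks:
        if p.transcript_id not in models:
            raise ValueError(f"peak on unknown transcript {p.transcript_id!r}")
        per_tid[p.transcript_id] = per_tid.get(p.transcript_id, 0) + 1
    n_acetylated = len(per_tid)
    result: Dict[str, Optional[float]] = {
        "n_acetylated": float(n_acetylated),
        "n_transcripts": float(len(models)),
        "fraction_acetylated": n_acetylated / len(models),
    }
    if n_acetylated:
        vals = np.array(list(per_tid.values()), dtype=float)
        result["mean_peaks"] = float(vals.mean())
        result["sem_peaks"] = (
            float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
        )
    else:
        result["mean_peaks"] = None
        result["sem_peaks"] = None
    return result


def region_chisq(
    peaks: Sequence[AnyPeak], models: Mapping[str, TranscriptModel]
) -> Dict[str, object]:
    """Chi-square test of summit counts per region against expectation
    proportional to the aggregate region lengths of the annotated
    transcripts.  Regions absent from every transcript are collapsed; a
    single surviving region makes the test degenerate and it is skipped."""
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks for the region test")
    observed = {r: 0 for r in _REGION_ORDER}
    for p in peaks:
        observed[assign_region(p, models[p.transcript_id])] += 1
    lengths = {r: 0 for r in _REGION_ORDER}
    for m in models.values():
        lengths[Region.UTR5] += m.utr5_len
        lengths[Region.CDS] += m.cds_len
        lengths[Region.UTR3] += m.utr3_len
    kept = [r for r in _REGION_ORDER if lengths[r] > 0]
    obs = np.array([observed[r] for r in kept], dtype=float)
    total_len = sum(lengths[r] for r in kept)
    expected = np.array([lengths[r] / total_len for r in kept]) * obs.sum()
    if len(kept) < 2:
        return {
            "status": "skipped",
            "reason": "single region after collapsing empty regions",
            "observed": {r.value: int(observed[r]) for r in _REGION_ORDER},
        }
    chi2, p = stats.chisquare(obs, f_exp=expected)
    return {
        "status": "ok",
        "chi2": float(chi2),
        "pvalue": float(p),
        "dof": len(kept) - 1,
        "observed": {r.value: int(observed[r]) for r in kept},
        "expected": {r.value: float(e) for r, e in zip(kept, expected)},
    }
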