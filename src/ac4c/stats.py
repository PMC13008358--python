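"""Transcript-level acetylation statistics and classifications.

The transcript-level acetylation score is the arithmetic sum of the fold
enrichments of every peak on the transcript (ΣFE).  Change between
conditions is the pseudocount fold change FC = (ΣFE_case + 1)/(ΣFE_ref + 1),
which is always finite.  MISA (memory-induced synaptic ac4C) transcripts
show FC > 2 at day 6 but not at day 1 or day 20; NASA (NAT10-dependent
synaptic ac4C) transcripts lose their acetylation (FE < 1 or no reliable
peak) or show it attenuated in the knockout.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Sequence, Set, Union

from .models import (
    ConsensusPeak,
    FoldChangeRecord,
    MisaCall,
    NasaCall,
    NasaCategory,
    Peak,
    TranscriptAcetylation,
    TranscriptModel,
)

__all__ = [
    "transcript_fe",
    "fold_change",
    "classify_misa",
    "classify_nasa",
    "overlap_sets",
    "syn_reliability_filter",
    "misa_confusion",
]

AnyPeak = Union[Peak, ConsensusPeak]


def _peak_fe(peak: AnyPeak) -> float:
    return peak.mean_fe if isinstance(peak, ConsensusPeak) else peak.fe


def transcript_fe(
    peaks: Sequence[AnyPeak],
    models: Mapping[str, TranscriptModel],
) -> Dict[str, TranscriptAcetylation]:
    """ΣFE and peak count per transcript; explicit zero records for every
    annotated transcript without peaks."""
    sums: Dict[str, float] = {tid: 0.0 for tid in models}
    counts: Dict[str, int] = {tid: 0 for tid in models}
    for p in peaks:
        if p.transcript_id not in sums:
            raise ValueError(f"peak on unknown transcript {p.transcript_id!r}")
        sums[p.transcript_id] += _peak_fe(p)
        counts[p.transcript_id] += 1
    return {
        tid: TranscriptAcetylation(tid, counts[tid], sums[tid]) for tid in models
    }


def fold_change(
    case: Mapping[str, TranscriptAcetylation],
    ref: Mapping[str, TranscriptAcetylation],
) -> Dict[str, FoldChangeRecord]:
    """Pseudocount FC over the union of transcript ids; a side missing a
    transcript contributes FE = 0 (the pseudocount keeps FC finite)."""
    out: Dict[str, FoldChangeRecord] = {}
    for tid in set(case) | set(ref):
        fe_case = case[tid].fe_sum if tid in case else 0.0
        fe_ref = ref[tid].fe_sum if tid in ref else 0.0
        out[tid] = FoldChangeRecord(tid, fe_case, fe_ref)
    return out


def classify_misa(
    fc_d1: Mapping[str, FoldChangeRecord],
    fc_d6: Mapping[str, FoldChangeRecord],
    fc_d20: Mapping[str, FoldChangeRecord],
    cutoff: float = 2.0,
    strict: bool = False,
) -> Dict[str, MisaCall]:
    """MISA calls over the union of the three day-wise comparisons.

    is_misa iff FC(day6) > cutoff and FC(day1) <= cutoff and
    FC(day20) <= cutoff — upregulation must be day-6 specific.  A transcript
    missing from a day defaults to FC = 1 (no evidence of change) unless
    ``strict``, in which case it is excluded.
    """
    universe = set(fc_d1) | set(fc_d6) | set(fc_d20)
    out: Dict[str, MisaCall] = {}
    for tid in universe:
        if strict and not (tid in fc_d1 and tid in fc_d6 and tid in fc_d20):
            continue
        d1 = fc_d1[tid].fc if tid in fc_d1 else 1.0
        d6 = fc_d6[tid].fc if tid in fc_d6 else 1.0
        d20 = fc_d20[tid].fc if tid in fc_d20 else 1.0
        out[tid] = MisaCall(
            transcript_id=tid,
            fc_d1=d1,
            fc_d6=d6,
            fc_d20=d20,
            is_misa=(d6 > cutoff) and (d1 <= cutoff) and (d20 <= cutoff),
        )
    return out


def classify_nasa(
    ctrl: Mapping[str, TranscriptAcetylation],
    cko: Mapping[str, TranscriptAcetylation],
    attenuation_fc: float = 2.0,
) -> Dict[str, NasaCall]:
    """NAT10-dependence categories for every control transcript.

    Only transcripts acetylated in control (ΣFE > 0) are classifiable:

    * diminished — ΣFE_cko < 1 or no reliable cKO peak ("FE < 1 or peak lost")
    * downregulated — still detectable (ΣFE_cko >= 1) but
      (ΣFE_ctrl + 1)/(ΣFE_cko + 1) > attenuation_fc
    * unchanged — otherwise
    * not_acetylated — no control acetylation to lose

    The three informative categories are disjoint and exhaustive over
    control-acetylated transcripts; NASA = diminished ∪ downregulated.
    """
    out: Dict[str, NasaCall] = {}
    for tid in set(ctrl) | set(cko):
        fe_ctrl = ctrl[tid].fe_sum if tid in ctrl else 0.0
        fe_cko = cko[tid].fe_sum if tid in cko else 0.0
        n_cko = cko[tid].n_peaks if tid in cko else 0
        if fe_ctrl <= 0:
            cat = NasaCategory.NOT_ACETYLATED
        elif fe_cko < 1.0 or n_cko == 0:
            cat = NasaCategory.DIMINISHED
        elif (fe_ctrl + 1.0) / (fe_cko + 1.0) > attenuation_fc:
            cat = NasaCategory.DOWNREGULATED
        else:
            cat = NasaCategory.UNCHANGED
        out[tid] = NasaCall(tid, fe_ctrl, fe_cko, n_cko, cat)
    return out


def overlap_sets(a: Iterable[str], b: Iterable[str]) -> Dict[str, int]:
    """Exact overlap cardinalities of two identifier sets."""
    sa, sb = set(a), set(b)
    inter = sa & sb
    return {
        "n_a": len(sa),
        "n_b": len(sb),
        "n_intersection": len(inter),
        "n_a_only": len(sa - sb),
        "n_b_only": len(sb - sa),
    }


def syn_reliability_filter(
    detected: Iterable[str],
    reference_lists: Sequence[Iterable[str]],
    min_support: int = 2,
) -> Set[str]:
    """Keep transcripts detected here AND present in at least
    ``min_support`` of the reference synaptosome lists."""
    refs = [set(r) for r in reference_lists]
    if not refs or len(refs) < min_support:
        raise ValueError(
            f"need at least {min_support} reference lists, got {len(refs)}"
        )
    detected = set(detected)
    return {
        tid
        for tid in detected
        if sum(tid in ref for ref in refs) >= min_support
    }


def misa_confusion(
    called: Iterable[str], truth: Iterable[str]
) -> Dict[str, float]:
    """Sensitivity and precision of a called id set against a true id set."""
    called, truth = set(called), set(truth)
    tp = len(called & truth)
    sensitivity = tp / len(truth) if truth else float("nan")
    precision = tp / len(called) if called else float("nan")
    return {
        "tp": tp,
        "n_called": len(called),
        "n_true": len(truth),
        "sensitivity": sensitivity,
        "precision": precision,
    }
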