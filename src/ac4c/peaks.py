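"""Peak calling from paired acRIP/input coverage tracks.

The statistical core is a one-sided Poisson enrichment test per window: the
acRIP count in a window is compared against a background rate estimated from
the input library and scaled by the acRIP/input library-size ratio, followed
by Benjamini-Hochberg correction across windows.  Windows passing the screen
(q < 0.05 and FE > 2 by default) are merged into peaks, and peaks found in
at least two of three replicates form the reliable consensus set.

Background estimation (``CallerParams.background``):

* ``"window"`` — λ from the window's own input count only.  This is the
  textbook conditional form but is anti-conservative: the sampling noise of
  the single-window input estimate inflates the upper tail of the test.
* ``"transcript"`` — λ from the transcript-wide mean input per window.
* ``"max"`` (default) — the larger of the two, a background floor in the
  spirit of MACS's lambda flooring; calibrated (conservative) under the
  global null on Poisson data.

acRIP/input scaling (``CallerParams.normalization``):

* ``"background"`` (default) — the acRIP:input scale factor is the median
  per-window count ratio, which tracks the non-enriched background and is
  robust to composition: strongly enriched peaks add mass to the acRIP
  library total, and dividing by total library size would deflate every
  peak's FE in proportion to how much signal the sample carries.
* ``"library"`` — the classical total-library-size ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import ConsensusPeak, CoverageTrack, Peak, TranscriptModel

__all__ = [
    "CallerParams",
    "window_enrichment",
    "bh_adjust",
    "call_peaks",
    "consensus_peaks",
]

_BACKGROUNDS = ("window", "transcript", "max")


@dataclass(frozen=True)
class CallerParams:
    """Screening thresholds and background options for the caller.

    Defaults reproduce the published screen: FE > 2 and adjusted p < 0.05.
    ``raw_fe`` switches FE to unnormalised acRIP/input count ratios instead
    of library-size-normalised ones.
    """

    window_size: int = 50
    min_fe: float = 2.0
    max_q: float = 0.05
    input_pseudocount: float = 1.0
    merge_gap: int = 1
    min_windows: int = 2
    background: str = "max"
    normalization: str = "background"
    summit_flank: int = 1
    raw_fe: bool = False

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be positive")
        if self.min_fe <= 0:
            raise ValueError("min_fe must be positive")
        if not 0 < self.max_q < 1:
            raise ValueError("max_q must be in (0, 1)")
        if self.input_pseudocount < 0:
            raise ValueError("input_pseudocount must be non-negative")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be non-negative")
        if self.min_windows < 1:
            raise ValueError("min_windows must be positive")
        if self.background not in _BACKGROUNDS:
            raise ValueError(f"background must be one of {_BACKGROUNDS}")
        if self.normalization not in ("background", "library"):
            raise ValueError("normalization must be 'background' or 'library'")
        if self.summit_flank < 0:
            raise ValueError("summit_flank must be non-negative")


def _check_pair(acrip: CoverageTrack, inp: CoverageTrack) -> None:
    if acrip.window_size != inp.window_size:
        raise ValueError("acRIP and input tracks use different window sizes")
    if set(acrip.counts) != set(inp.counts):
        raise ValueError("acRIP and input tracks cover different transcripts")
    for tid in acrip.counts:
        if len(acrip.counts[tid]) != len(inp.counts[tid]):
            raise ValueError(f"{tid}: mismatched window grids")


def _scale_ratio(
    acrip: CoverageTrack, inp: CoverageTrack, params: CallerParams
) -> float:
    """acRIP:input scale factor used for both λ and FE."""
    if params.normalization == "library":
        return acrip.library_size / inp.library_size
    ratios = [
        (acrip.counts[tid] + 0.5) / (inp.counts[tid] + 0.5)
        for tid in acrip.counts
    ]
    return float(np.median(np.concatenate(ratios)))


def _fe(
    acrip_count: np.ndarray,
    input_count: np.ndarray,
    ratio: float,
    params: CallerParams,
) -> np.ndarray:
    denom = input_count + params.input_pseudocount
    if params.raw_fe:
        return acrip_count / denom
    return acrip_count / (denom * ratio)


def window_enrichment(
    acrip: CoverageTrack, inp: CoverageTrack, params: CallerParams | None = None
) -> pd.DataFrame:
    """Per-window Poisson enrichment table.

    Returns a DataFrame with columns transcript_id, window, acrip_count,
    input_count, fe, pvalue.  The background rate is
    λ = (input estimate + pseudocount) x scale ratio (see module docstring),
    and pvalue = P(X >= acrip_count | X ~ Poisson(λ)).
    """
    params = params or CallerParams(window_size=acrip.window_size)
    _check_pair(acrip, inp)
    ratio = _scale_ratio(acrip, inp, params)

    tids: List[str] = []
    windows: List[np.ndarray] = []
    a_all: List[np.ndarray] = []
    i_all: List[np.ndarray] = []
    lam_all: List[np.ndarray] = []
    for tid in acrip.counts:
        a = acrip.counts[tid].astype(float)
        i = inp.counts[tid].astype(float)
        local = i + params.input_pseudocount
        if params.background == "window":
            base = local
        else:
            broad = i.mean() + params.input_pseudocount
            base = (
                np.full_like(local, broad)
                if params.background == "transcript"
                else np.maximum(local, broad)
            )
        tids.extend([tid] * len(a))
        windows.append(np.arange(len(a)))
        a_all.append(a)
        i_all.append(i)
        lam_all.append(base * ratio)

    a_arr = np.concatenate(a_all) if a_all else np.array([])
    i_arr = np.concatenate(i_all) if i_all else np.array([])
    lam = np.concatenate(lam_all) if lam_all else np.array([])
    # Upper-tail P(X >= k) = sf(k - 1); k = 0 gives 1 exactly.
    pvalues = stats.poisson.sf(a_arr - 1.0, lam)
    fe = _fe(a_arr, i_arr, ratio, params)
    return pd.DataFrame(
        {
            "transcript_id": tids,
            "window": np.concatenate(windows) if windows else [],
            "acrip_count": a_arr.astype(np.int64),
            "input_count": i_arr.astype(np.int64),
            "fe": fe,
            "pvalue": pvalues,
        }
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_peaks(
    acrip: CoverageTrack,
    inp: CoverageTrack,
    params: CallerParams | None = None,
    models: Mapping[str, TranscriptModel] | None = None,
) -> List[Peak]:
    """Call screened peaks from one acRIP/input pair.

    Windows with q < max_q and FE > min_fe are merged into peaks when
    separated by at most ``merge_gap`` non-significant windows; runs with
    fewer than ``min_windows`` significant windows are discarded (an
    enriched fragment of ~4x the window size should light up several
    adjacent windows, whereas isolated single-window excursions are the
    signature of count noise).  Peak counts sum over the merged span, peak
    p/q are the minima over member windows,
    and the summit is the start of the member window with the highest acRIP
    count (leftmost on ties).  Peak FE is computed from the summed counts of
    a fixed-width core around the summit (``summit_flank`` windows each
    side, clipped to the span): a full-span FE dilutes strong peaks, whose
    partially-covered edge windows pass the screen and widen the span,
    compressing between-condition fold changes, while a summit-only FE is
    width-invariant but noisy.  The fixed core is both width-invariant and
    averaged.  Every returned peak satisfies the screen.
    """
    params = params or CallerParams(window_size=acrip.window_size)
    table = window_enrichment(acrip, inp, params)
    if table.empty:
        return []
    ratio = _scale_ratio(acrip, inp, params)
    table = table.assign(qvalue=bh_adjust(table["pvalue"].to_numpy()))
    sig = (table["qvalue"] < params.max_q) & (table["fe"] > params.min_fe)
    table = table.assign(significant=sig)

    w = params.window_size
    peaks: List[Peak] = []
    for tid, sub in table.groupby("transcript_id", sort=False):
        sig_windows = sub.loc[sub["significant"], "window"].to_numpy()
        if len(sig_windows) == 0:
            continue
        a = sub["acrip_count"].to_numpy()
        i = sub["input_count"].to_numpy()
        p = sub["pvalue"].to_numpy()
        q = sub["qvalue"].to_numpy()
        # trim the rightmost window to the transcript end when known
        total_len = (
            models[tid].total_len if models and tid in models else len(a) * w
        )
        # group significant windows into runs bridging <= merge_gap gaps
        runs: List[Tuple[int, int, int]] = []  # (first, last, n significant)
        run_start = prev = int(sig_windows[0])
        n_sig = 1
        for widx in sig_windows[1:]:
            widx = int(widx)
            if widx - prev - 1 <= params.merge_gap:
                prev = widx
                n_sig += 1
            else:
                runs.append((run_start, prev, n_sig))
                run_start = prev = widx
                n_sig = 1
        runs.append((run_start, prev, n_sig))
        for w0, w1, run_sig in runs:
            if run_sig < params.min_windows:
                continue
            member = slice(w0, w1 + 1)
            a_sum = int(a[member].sum())
            i_sum = int(i[member].sum())
            summit_w = w0 + int(np.argmax(a[member]))
            core = slice(
                max(w0, summit_w - params.summit_flank),
                min(w1, summit_w + params.summit_flank) + 1,
            )
            fe = float(
                _fe(
                    np.array([a[core].sum()], dtype=float),
                    np.array([i[core].sum()], dtype=float),
                    ratio,
                    params,
                )[0]
            )
            if not fe > params.min_fe:
                continue  # summit below the screen after merging
            peaks.append(
                Peak(
                    transcript_id=tid,
                    start=w0 * w,
                    end=min((w1 + 1) * w, total_len),
                    summit=summit_w * w,
                    acrip_count=a_sum,
                    input_count=i_sum,
                    fe=fe,
                    pvalue=float(p[member].min()),
                    qvalue=float(q[member].min()),
                )
            )
    return peaks


def consensus_peaks(
    replicate_peaks: Sequence[Sequence[Peak]], min_support: int = 2
) -> List[ConsensusPeak]:
    """Cluster replicate peaks by single-linkage >= 1 nt overlap per
    transcript and keep clusters supported by >= ``min_support`` distinct
    replicates.  The cluster interval is the union span; mean_fe averages
    member-peak FE.  The result is invariant to replicate ordering."""
    if min_support < 1:
        raise ValueError("min_support must be positive")
    if len(replicate_peaks) < min_support:
        raise ValueError(
            f"min_support {min_support} exceeds number of replicate sets "
            f"({len(replicate_peaks)})"
        )
    by_tid: Dict[str, List[Tuple[int, int, float, int]]] = {}
    for rep_i, peak_set in enumerate(replicate_peaks):
        for p in peak_set:
            by_tid.setdefault(p.transcript_id, []).append(
                (p.start, p.end, p.fe, rep_i)
            )
    out: List[ConsensusPeak] = []
    for tid, items in sorted(by_tid.items()):
        items.sort()
        cluster: List[Tuple[int, int, float, int]] = []
        cluster_end = -1

        def flush() -> None:
            if not cluster:
                return
            support = len({rep for *_x, rep in cluster})
            if support >= min_support:
                out.append(
                    ConsensusPeak(
                        transcript_id=tid,
                        start=min(s for s, *_ in cluster),
                        end=max(e for _s, e, *_ in cluster),
                        support=support,
                        mean_fe=float(np.mean([fe for _s, _e, fe, _r in cluster])),
                    )
                )

        for start, end, fe, rep in items:
            if cluster and start < cluster_end:  # >=1 nt overlap, half-open
                cluster.append((start, end, fe, rep))
                cluster_end = max(cluster_end, end)
            else:
                flush()
                cluster = [(start, end, fe, rep)]
                cluster_end = end
        flush()
    return out
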