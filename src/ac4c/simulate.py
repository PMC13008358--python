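"""Synthetic acRIP/input experiment generator with known ground truth.

The generator emulates the statistical structure the analysis assumes:
transcripts with 5'UTR/CDS/3'UTR segments, ~200 nt enriched regions planted
preferentially in the CDS, replicate-level negative-binomial (or Poisson)
count noise, a memory effect that multiplies peak enrichment only in
(memory, day6) samples on a designated MISA subset, and a knockout regime
that abolishes or attenuates peaks on a NAT10-dependent subset.

Generation is a pure function of :class:`SimConfig` — the same seed yields
bit-identical output.  Replicate and library noise streams are spawned from
independent, deterministically derived seed sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .models import CoverageTrack, LibraryRole, Timepoint, TranscriptModel

__all__ = [
    "SegmentLengthParams",
    "SimConfig",
    "PlantedPeak",
    "TranscriptTruth",
    "GroundTruth",
    "simulate_annotation",
    "simulate_experiment",
    "memory_design",
    "knockout_design",
]

KNOWN_CONDITIONS = ("control", "memory", "cko")


@dataclass(frozen=True)
class SegmentLengthParams:
    """Gamma-distributed segment lengths (nt); defaults echo typical mouse
    mRNA architecture (short 5'UTR, ~1.5 kb CDS, mid-length 3'UTR)."""

    utr5_mean: float = 150.0
    cds_mean: float = 1500.0
    utr3_mean: float = 800.0
    shape: float = 4.0
    utr5_min: int = 20
    cds_min: int = 300
    utr3_min: int = 50

    def __post_init__(self) -> None:
        if min(self.utr5_mean, self.cds_mean, self.utr3_mean) <= 0:
            raise ValueError("segment means must be positive")
        if self.shape <= 0:
            raise ValueError("gamma shape must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters for one synthetic experiment.

    ``dispersion`` is the negative-binomial size parameter; ``None`` gives
    Poisson counts (used by the calibration studies).  ``misa_effect``
    multiplies peak enrichment only in (memory, day6) samples on the
    MISA-true subset; ``cko_*`` control the knockout regime on the
    NAT10-dependent subset.
    """

    n_transcripts: int = 1000
    segment_length_params: SegmentLengthParams = field(
        default_factory=SegmentLengthParams
    )
    window_size: int = 50
    n_replicates: int = 3
    mean_input_depth: float = 50.0
    dispersion: Optional[float] = 10.0
    peak_rate: float = 1.8
    acetylated_fraction: float = 0.55
    cds_placement_bias: float = 0.8
    baseline_enrichment: float = 6.0
    acrip_background_ratio: float = 0.25
    expression_sd: float = 0.5
    peak_width_mean: int = 200
    peak_width_jitter: float = 0.25
    misa_fraction: float = 0.30
    misa_effect: float = 3.0
    nat10_dependent_fraction: float = 0.85
    cko_diminish_prob: float = 0.75
    cko_attenuation: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 0:
            raise ValueError("n_transcripts must be non-negative")
        if self.window_size < 1 or self.n_replicates < 1:
            raise ValueError("window_size and n_replicates must be positive")
        if self.mean_input_depth <= 0:
            raise ValueError("mean_input_depth must be positive")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be positive (or None for Poisson)")
        if self.peak_rate <= 0:
            raise ValueError("peak_rate must be positive")
        if not 0 < self.acetylated_fraction <= 1:
            raise ValueError("acetylated_fraction must be in (0, 1]")
        for name in ("cds_placement_bias", "misa_fraction",
                     "nat10_dependent_fraction", "cko_diminish_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.misa_fraction >= 1:
            raise ValueError("misa_fraction must be < 1")
        # >= 1 (not > 1) so the global-null scenario (enrichment 1 everywhere)
        # used for caller calibration is expressible.
        if self.baseline_enrichment < 1:
            raise ValueError("baseline_enrichment must be >= 1")
        if self.misa_effect < 1:
            raise ValueError("misa_effect must be >= 1")
        if not 0 < self.cko_attenuation < 1:
            raise ValueError("cko_attenuation must be in (0, 1)")
        if not 0 < self.acrip_background_ratio:
            raise ValueError("acrip_background_ratio must be positive")
        if self.peak_width_mean < self.window_size:
            raise ValueError("peak_width_mean must be >= window_size")
        if not 0 <= self.peak_width_jitter < 1:
            raise ValueError("peak_width_jitter must be in [0, 1)")


@dataclass(frozen=True)
class PlantedPeak:
    start: int
    end: int
    summit: int
    cko_fate: str  # "kept" | "attenuated" | "abolished"


@dataclass
class TranscriptTruth:
    acetylated: bool
    planted_peaks: List[PlantedPeak]
    is_misa_true: bool
    nat10_dependent: bool
    expression: float


@dataclass
class GroundTruth:
    transcripts: Dict[str, TranscriptTruth]

    @property
    def acetylated_ids(self) -> set:
        return {t for t, v in self.transcripts.items() if v.acetylated}

    @property
    def misa_ids(self) -> set:
        return {t for t, v in self.transcripts.items() if v.is_misa_true}

    @property
    def nat10_dependent_ids(self) -> set:
        return {t for t, v in self.transcripts.items() if v.nat10_dependent}

    @property
    def fully_abolished_ids(self) -> set:
        """Acetylated transcripts whose planted peaks were all abolished."""
        return {
            t for t, v in self.transcripts.items()
            if v.acetylated and v.planted_peaks
            and all(p.cko_fate == "abolished" for p in v.planted_peaks)
        }


def _rng(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *key]))


def simulate_annotation(config: SimConfig) -> Dict[str, TranscriptModel]:
    """Draw ``n_transcripts`` transcript models from the configured
    segment-length distributions; total length is at least 4 windows."""
    rng = _rng(config, 0)
    p = config.segment_length_params
    models: Dict[str, TranscriptModel] = {}
    min_total = 4 * config.window_size
    for i in range(config.n_transcripts):
        utr5 = max(p.utr5_min, int(rng.gamma(p.shape, p.utr5_mean / p.shape)))
        cds = max(p.cds_min, int(rng.gamma(p.shape, p.cds_mean / p.shape)))
        utr3 = max(p.utr3_min, int(rng.gamma(p.shape, p.utr3_mean / p.shape)))
        if utr5 + cds + utr3 < min_total:
            cds = min_total - utr5 - utr3
        tid = f"tx{i + 1:05d}"
        models[tid] = TranscriptModel(tid, f"g{i + 1:05d}", utr5, cds, utr3)
    if models and max(m.total_len for m in models.values()) < min_total:
        raise ValueError("infeasible segment length parameters")
    return models


def _place_peaks(
    rng: np.random.Generator, model: TranscriptModel, config: SimConfig
) -> List[Tuple[int, int, int]]:
    """Plant non-overlapping (start, end, summit) intervals; summits fall in
    the CDS with probability ``cds_placement_bias``."""
    n = 1 + rng.poisson(max(config.peak_rate - 1.0, 0.0))
    placed: List[Tuple[int, int, int]] = []
    # Planted peaks stay >= 4 windows apart so peak-edge bleed into adjacent
    # windows cannot bridge two true peaks into one called peak.
    gap = config.window_size * 4
    for _ in range(n):
        # the target region is drawn once per peak so that overlap rejection
        # cannot spill crowded-CDS draws into the UTRs and erode the bias;
        # an unplaceable peak is dropped instead
        if rng.random() < config.cds_placement_bias or (
            model.utr5_len == 0 and model.utr3_len == 0
        ):
            lo, hi = model.cds_start, model.cds_end
        else:
            utr_tot = model.utr5_len + model.utr3_len
            if utr_tot == 0 or rng.random() < model.utr5_len / max(utr_tot, 1):
                lo, hi = 0, model.cds_start
            else:
                lo, hi = model.cds_end, model.total_len
            if lo >= hi:
                lo, hi = model.cds_start, model.cds_end
        for _attempt in range(30):
            w = config.peak_width_mean
            width = int(round(w * rng.uniform(1 - config.peak_width_jitter,
                                              1 + config.peak_width_jitter)))
            width = max(config.window_size, min(width, model.total_len))
            summit = int(rng.integers(lo, hi))
            start = max(0, summit - width // 2)
            end = min(model.total_len, start + width)
            start = max(0, end - width)
            if all(end + gap <= s or e + gap <= start for s, e, _ in placed):
                placed.append((start, end, summit))
                break
    return sorted(placed)


def _simulate_truth(
    config: SimConfig, models: Dict[str, TranscriptModel]
) -> GroundTruth:
    rng = _rng(config, 1)
    truth: Dict[str, TranscriptTruth] = {}
    for tid, model in models.items():
        acetylated = bool(rng.random() < config.acetylated_fraction)
        expression = float(np.exp(rng.normal(0.0, config.expression_sd)))
        peaks: List[PlantedPeak] = []
        is_misa = False
        nat10_dep = False
        if acetylated:
            is_misa = bool(rng.random() < config.misa_fraction)
            nat10_dep = bool(rng.random() < config.nat10_dependent_fraction)
            for start, end, summit in _place_peaks(rng, model, config):
                if nat10_dep:
                    fate = (
                        "abolished"
                        if rng.random() < config.cko_diminish_prob
                        else "attenuated"
                    )
                else:
                    fate = "kept"
                peaks.append(PlantedPeak(start, end, summit, fate))
        truth[tid] = TranscriptTruth(
            acetylated=acetylated,
            planted_peaks=peaks,
            is_misa_true=is_misa,
            nat10_dependent=nat10_dep,
            expression=expression,
        )
    return GroundTruth(truth)


def memory_design(config: SimConfig) -> List[Tuple[str, str, int]]:
    """control/memory x day1/day6/day20 x replicates — the memory study."""
    return [
        (cond, day, rep)
        for cond in ("control", "memory")
        for day in ("day1", "day6", "day20")
        for rep in range(1, config.n_replicates + 1)
    ]


def knockout_design(n_replicates: int = 2) -> List[Tuple[str, str, int]]:
    """control/cko at day6 — the conditional-knockout study (2 replicates,
    matching the sequencing design this scenario emulates)."""
    return [
        (cond, "day6", rep)
        for cond in ("control", "cko")
        for rep in range(1, n_replicates + 1)
    ]


def _window_fractions(total_len: int, window_size: int) -> np.ndarray:
    """Fraction of each window actually covered by the transcript."""
    n = math.ceil(total_len / window_size)
    frac = np.ones(n)
    rem = total_len - (n - 1) * window_size
    frac[-1] = rem / window_size
    return frac


def _peak_multiplier(
    model: TranscriptModel,
    truth: TranscriptTruth,
    config: SimConfig,
    condition: str,
    timepoint: str,
) -> np.ndarray:
    """Per-window enrichment multiplier for one sample."""
    n = model.n_windows(config.window_size)
    mult = np.ones(n)
    if not truth.acetylated:
        return mult
    for peak in truth.planted_peaks:
        enrich = config.baseline_enrichment
        if condition == "cko":
            if peak.cko_fate == "abolished":
                enrich = 1.0
            elif peak.cko_fate == "attenuated":
                enrich = max(1.0, enrich * config.cko_attenuation)
        elif (
            condition == "memory"
            and timepoint == "day6"
            and truth.is_misa_true
        ):
            enrich = enrich * config.misa_effect
        if enrich == 1.0:
            continue
        w0 = peak.start // config.window_size
        w1 = (peak.end - 1) // config.window_size
        for w in range(w0, w1 + 1):
            ws, we = w * config.window_size, (w + 1) * config.window_size
            overlap = min(peak.end, we) - max(peak.start, ws)
            mult[w] += (enrich - 1.0) * overlap / config.window_size
    return mult


def _draw_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: Optional[float]
) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    if dispersion is None or not np.isfinite(dispersion):
        return rng.poisson(mean).astype(np.int64)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p).astype(np.int64)


def simulate_experiment(
    config: SimConfig,
    design: Optional[Sequence[Tuple[str, str, int]]] = None,
    models: Optional[Dict[str, TranscriptModel]] = None,
) -> Tuple[List[CoverageTrack], GroundTruth]:
    """Generate paired acRIP/input tracks for every design cell.

    The ground truth depends only on ``config`` (not on the design), so two
    designs simulated under the same config share transcript labels.
    """
    if design is None:
        design = memory_design(config)
    if not design:
        raise ValueError("design must be non-empty")
    for cond, day, rep in design:
        if cond not in KNOWN_CONDITIONS:
            raise ValueError(
                f"unknown condition {cond!r}; expected one of {KNOWN_CONDITIONS}"
            )
        Timepoint(day)
        if rep < 1:
            raise ValueError("replicate numbers start at 1")
    if models is None:
        models = simulate_annotation(config)
    truth = _simulate_truth(config, models)

    fracs = {
        tid: _window_fractions(m.total_len, config.window_size)
        for tid, m in models.items()
    }
    tracks: List[CoverageTrack] = []
    cond_idx = {c: i for i, c in enumerate(KNOWN_CONDITIONS)}
    day_idx = {t.value: i for i, t in enumerate(Timepoint)}
    for cond, day, rep in design:
        for role_i, role in enumerate((LibraryRole.INPUT, LibraryRole.ACRIP)):
            rng = _rng(config, 2, cond_idx[cond], day_idx[day], rep, role_i)
            counts: Dict[str, np.ndarray] = {}
            for tid, model in models.items():
                tr = truth.transcripts[tid]
                base = config.mean_input_depth * tr.expression * fracs[tid]
                if role is LibraryRole.INPUT:
                    mean = base
                else:
                    mult = _peak_multiplier(model, tr, config, cond, day)
                    mean = config.acrip_background_ratio * base * mult
                counts[tid] = _draw_counts(rng, mean, config.dispersion)
            total = int(sum(int(v.sum()) for v in counts.values()))
            tracks.append(
                CoverageTrack(
                    library_id=f"{cond}_{day}_r{rep}_{role.value}",
                    role=role,
                    condition=cond,
                    timepoint=Timepoint(day),
                    replicate=rep,
                    window_size=config.window_size,
                    counts=counts,
                    library_size=max(total, 1),
                )
            )
    return tracks, truth
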