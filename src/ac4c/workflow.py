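"""End-to-end orchestration of the ac4C analysis on synthetic or user data.

``run_full`` executes the published decision flow: per-replicate peak
calling → replicate consensus (2-of-3) → optional synaptosome-database
reliability filter → transcript-level ΣFE → day-wise pseudocount fold
changes → MISA classification → optional control/cKO NASA classification →
MISA/NASA overlap → metagene and KS summaries.  Every stage logs records in
and out, and the run report records all thresholds, so each count is
recomputable from the emitted intermediates.

The pipeline is a pure function of (inputs, parameters): rerunning on the
same inputs yields a byte-identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from . import __version__
from . import io as ac4c_io
from .distributions import ks_compare, quartile_summary
from .models import (
    ConsensusPeak,
    CoverageTrack,
    LibraryRole,
    Peak,
    Timepoint,
    TranscriptModel,
)
from .peaks import CallerParams, call_peaks, consensus_peaks
from .regions import metagene, peaks_per_transcript, region_chisq
from .simulate import (
    GroundTruth,
    SimConfig,
    knockout_design,
    memory_design,
    simulate_annotation,
    simulate_experiment,
)
from .stats import (
    classify_misa,
    classify_nasa,
    fold_change,
    misa_confusion,
    overlap_sets,
    syn_reliability_filter,
    transcript_fe,
)

log = logging.getLogger("ac4c")

__all__ = ["RunConfig", "run_full", "report_to_json"]

DAYS = ("day1", "day6", "day20")


@dataclass
class RunConfig:
    """Parameters of one full synthetic-experiment analysis."""

    sim: SimConfig = field(default_factory=SimConfig)
    caller: CallerParams = field(default_factory=CallerParams)
    min_support: int = 2
    misa_cutoff: float = 2.0
    attenuation_fc: float = 2.0
    knockout: bool = True
    cko_replicates: int = 2
    exclude: Set[str] = field(default_factory=set)
    syn_reference_lists: Optional[List[Set[str]]] = None
    syn_min_support: int = 2


def _pair_tracks(
    tracks: Sequence[CoverageTrack],
) -> Dict[Tuple[str, str, int], Tuple[CoverageTrack, CoverageTrack]]:
    """Group tracks into (condition, timepoint, replicate) -> (acrip, input)."""
    cells: Dict[Tuple[str, str, int], Dict[LibraryRole, CoverageTrack]] = {}
    for t in tracks:
        key = (t.condition, t.timepoint.value, t.replicate)
        cells.setdefault(key, {})[t.role] = t
    out = {}
    for key, libs in sorted(cells.items()):
        if LibraryRole.ACRIP not in libs or LibraryRole.INPUT not in libs:
            raise ValueError(f"design cell {key} is missing a library")
        out[key] = (libs[LibraryRole.ACRIP], libs[LibraryRole.INPUT])
    return out


def _cell_consensus(
    pairs: Mapping[Tuple[str, str, int], Tuple[CoverageTrack, CoverageTrack]],
    models: Mapping[str, TranscriptModel],
    cfg: RunConfig,
    report: Dict,
    prefix: str = "",
) -> Dict[Tuple[str, str], List[ConsensusPeak]]:
    """Call peaks per replicate and build the reliable consensus per
    (condition, timepoint) cell."""
    by_cell: Dict[Tuple[str, str], List[List[Peak]]] = {}
    for (cond, day, rep), (acrip, inp) in pairs.items():
        peaks = call_peaks(acrip, inp, cfg.caller, models)
        by_cell.setdefault((cond, day), []).append(peaks)
        report["stages"]["peak_calling"]["n_peaks_per_replicate"][
            f"{prefix}{cond}_{day}_r{rep}"
        ] = len(peaks)
    consensus: Dict[Tuple[str, str], List[ConsensusPeak]] = {}
    for cell, replicate_sets in sorted(by_cell.items()):
        if len(replicate_sets) == 1:
            # pooled single-library designs pass through with support 1
            cons = [
                ConsensusPeak(p.transcript_id, p.start, p.end, 1, p.fe)
                for p in replicate_sets[0]
            ]
            report["warnings"].append(
                f"cell {cell[0]}/{cell[1]}: single replicate; consensus "
                "filtering skipped (support=1)"
            )
        else:
            support = min(cfg.min_support, len(replicate_sets))
            cons = consensus_peaks(replicate_sets, min_support=support)
        consensus[cell] = cons
        report["stages"]["consensus"][f"{prefix}{cell[0]}_{cell[1]}"] = len(cons)
    return consensus


def _apply_filters(
    consensus: Dict[Tuple[str, str], List[ConsensusPeak]],
    cfg: RunConfig,
    report: Dict,
    prefix: str = "",
) -> Dict[Tuple[str, str], List[ConsensusPeak]]:
    """Exclusion list (mito/lncRNA stand-in) and synaptosome-database filter."""
    out: Dict[Tuple[str, str], List[ConsensusPeak]] = {}
    for cell, peaks in consensus.items():
        kept = [p for p in peaks if p.transcript_id not in cfg.exclude]
        if cfg.syn_reference_lists is not None:
            detected = {p.transcript_id for p in kept}
            reliable = syn_reliability_filter(
                detected, cfg.syn_reference_lists, cfg.syn_min_support
            )
            kept = [p for p in kept if p.transcript_id in reliable]
        out[cell] = kept
        report["stages"]["reliability_filter"][f"{prefix}{cell[0]}_{cell[1]}"] = len(
            kept
        )
    return out


def run_full(
    cfg: RunConfig,
    outdir: Optional[Path | str] = None,
) -> Dict:
    """Simulate a full experiment under ``cfg.sim`` and analyse it.

    Returns the run report (a JSON-serialisable dict).  When ``outdir`` is
    given, all intermediates (annotation, counts, peaks, consensus,
    transcript FE, fold changes, classifications) and ``report.json`` are
    written there.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    report: Dict = {
        "version": __version__,
        "seed": cfg.sim.seed,
        "parameters": {
            "caller": asdict(cfg.caller),
            "min_support": cfg.min_support,
            "misa_cutoff": cfg.misa_cutoff,
            "attenuation_fc": cfg.attenuation_fc,
            "sim": {
                **{k: v for k, v in asdict(cfg.sim).items()
                   if k != "segment_length_params"},
                "segment_length_params": asdict(
                    cfg.sim.segment_length_params
                ),
            },
        },
        "stages": {
            "simulate": {},
            "peak_calling": {"n_peaks_per_replicate": {}},
            "consensus": {},
            "reliability_filter": {},
            "transcript_fe": {},
            "classification": {},
        },
        "warnings": [],
    }

    models = simulate_annotation(cfg.sim)
    tracks, truth = simulate_experiment(
        cfg.sim, memory_design(cfg.sim), models=models
    )
    report["stages"]["simulate"]["n_transcripts"] = len(models)
    report["stages"]["simulate"]["n_tracks_memory"] = len(tracks)

    if outdir is not None:
        ac4c_io.write_annotation(models, outdir / "annotation.tsv")
        for t in tracks:
            ac4c_io.write_counts(t, outdir / f"counts_{t.library_id}.tsv")

    pairs = _pair_tracks(tracks)
    consensus = _cell_consensus(pairs, models, cfg, report)
    consensus = _apply_filters(consensus, cfg, report)

    if outdir is not None:
        for (cond, day), peaks in consensus.items():
            ac4c_io.write_consensus(peaks, outdir / f"consensus_{cond}_{day}.tsv")

    # transcript-level ΣFE per cell
    fe_by_cell = {
        cell: transcript_fe(peaks, models) for cell, peaks in consensus.items()
    }
    for (cond, day), recs in fe_by_cell.items():
        n_acet = sum(1 for r in recs.values() if r.n_peaks > 0)
        report["stages"]["transcript_fe"][f"{cond}_{day}"] = n_acet
        if outdir is not None:
            ac4c_io.write_transcript_fe(
                list(recs.values()), outdir / f"transcript_fe_{cond}_{day}.tsv"
            )

    # day-wise pseudocount fold changes, memory vs control
    fcs = {}
    for day in DAYS:
        fcs[day] = fold_change(
            fe_by_cell[("memory", day)], fe_by_cell[("control", day)]
        )
        if outdir is not None:
            ac4c_io.write_fold_changes(
                list(fcs[day].values()), outdir / f"fc_memory_vs_control_{day}.tsv"
            )

    misa = classify_misa(
        fcs["day1"], fcs["day6"], fcs["day20"], cutoff=cfg.misa_cutoff
    )
    misa_ids = {t for t, c in misa.items() if c.is_misa}
    report["stages"]["classification"]["n_misa"] = len(misa_ids)
    report["recovery"] = {
        "misa": misa_confusion(misa_ids, truth.misa_ids),
    }
    if outdir is not None:
        ac4c_io.write_misa_calls(list(misa.values()), outdir / "misa.tsv")

    # descriptive summaries on the control day-6 cell
    ctrl_d6 = consensus[("control", "day6")]
    ppt = peaks_per_transcript(ctrl_d6, models)
    report["summaries"] = {
        "peaks_per_transcript_control_day6": ppt,
        "metagene_bins": 30,
    }
    prof = metagene(ctrl_d6, models, bins_per_region=30)
    from .models import Region  # local to avoid top-level cycle noise

    report["summaries"]["metagene_cds_density"] = float(
        prof.density[prof.region_slice(Region.CDS)].sum()
    )
    if len(ctrl_d6) >= 2:
        report["summaries"]["region_chisq_control_day6"] = region_chisq(
            ctrl_d6, models
        )

    fe_mem = [
        r.fe_sum for r in fe_by_cell[("memory", "day6")].values() if r.n_peaks > 0
    ]
    fe_ctl = [
        r.fe_sum for r in fe_by_cell[("control", "day6")].values() if r.n_peaks > 0
    ]
    if fe_mem and fe_ctl:
        d, p = ks_compare(fe_mem, fe_ctl)
        report["summaries"]["ks_fe_day6"] = {
            "D": d,
            "pvalue": p,
            "memory_quartiles": quartile_summary(fe_mem),
            "control_quartiles": quartile_summary(fe_ctl),
        }

    if cfg.knockout:
        ko_tracks, _ = simulate_experiment(
            cfg.sim, knockout_design(cfg.cko_replicates), models=models
        )
        report["stages"]["simulate"]["n_tracks_knockout"] = len(ko_tracks)
        if outdir is not None:
            for t in ko_tracks:
                ac4c_io.write_counts(t, outdir / f"counts_ko_{t.library_id}.tsv")
        ko_pairs = _pair_tracks(ko_tracks)
        ko_consensus = _cell_consensus(ko_pairs, models, cfg, report, prefix="ko_")
        ko_consensus = _apply_filters(ko_consensus, cfg, report, prefix="ko_")
        fe_ctrl_ko = transcript_fe(ko_consensus[("control", "day6")], models)
        fe_cko = transcript_fe(ko_consensus[("cko", "day6")], models)
        nasa = classify_nasa(fe_ctrl_ko, fe_cko, cfg.attenuation_fc)
        nasa_ids = {t for t, c in nasa.items() if c.is_nasa}
        cats = {}
        for c in nasa.values():
            cats[c.category.value] = cats.get(c.category.value, 0) + 1
        report["stages"]["classification"]["n_nasa"] = len(nasa_ids)
        report["stages"]["classification"]["nasa_categories"] = cats
        report["overlap_misa_nasa"] = overlap_sets(misa_ids, nasa_ids)
        report["recovery"]["nasa_vs_nat10_truth"] = misa_confusion(
            nasa_ids, truth.nat10_dependent_ids & truth.acetylated_ids
        )
        if outdir is not None:
            ac4c_io.write_nasa_calls(list(nasa.values()), outdir / "nasa.tsv")
            ac4c_io.write_consensus(
                ko_consensus[("control", "day6")],
                outdir / "consensus_ko_control_day6.tsv",
            )
            ac4c_io.write_consensus(
                ko_consensus[("cko", "day6")], outdir / "consensus_ko_cko_day6.tsv"
            )

    if outdir is not None:
        (outdir / "report.json").write_text(report_to_json(report))
    return report


def report_to_json(report: Mapping) -> str:
    """Deterministic JSON rendering (sorted keys, no timestamps)."""
    return json.dumps(report, indent=2, sort_keys=True) + "\n"
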