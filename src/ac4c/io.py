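"""Readers and writers for the plain-text formats the pipeline touches.

Formats
-------
* annotation: "GTF-lite" — tab-separated, header row, five columns
  (transcript_id, gene_id, utr5_len, cds_len, utr3_len).  Only segment
  lengths are consumed downstream, so strand/exon structure is omitted.
* windowed counts: TSV with header (transcript_id, window_index, count)
  plus ``#key=value`` comment lines carrying library metadata.
* peaks: BED6+3 — transcript_id, start, end, name, FE (4 dp), strand ".",
  p-value, q-value, summit offset from start.
* consensus peaks, transcript FE, fold changes, classifications: headered
  TSVs.

All files are UTF-8 with '.' for missing values.  Every reader/writer pair
round-trips at the printed precision.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

from .models import (
    ConsensusPeak,
    CoverageTrack,
    FoldChangeRecord,
    LibraryRole,
    MisaCall,
    NasaCall,
    NasaCategory,
    Peak,
    Timepoint,
    TranscriptAcetylation,
    TranscriptModel,
    validate_annotation,
)

log = logging.getLogger("ac4c")

ANNOTATION_COLUMNS = ["transcript_id", "gene_id", "utr5_len", "cds_len", "utr3_len"]
COUNTS_COLUMNS = ["transcript_id", "window_index", "count"]
PEAK_COLUMNS = [
    "transcript_id", "start", "end", "name", "score", "strand",
    "pvalue", "qvalue", "summit_offset",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def read_annotation(path: str | Path) -> Dict[str, TranscriptModel]:
    """Read a GTF-lite annotation into transcript models keyed by id."""
    models: List[TranscriptModel] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "transcript_id":  # header row
                continue
            if len(fields) != 5:
                raise ParseError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                model = TranscriptModel(
                    transcript_id=fields[0],
                    gene_id=fields[1],
                    utr5_len=int(fields[2]),
                    cds_len=int(fields[3]),
                    utr3_len=int(fields[4]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            models.append(model)
    out = validate_annotation(models)
    log.info("read_annotation: %d transcripts from %s", len(out), path)
    return out


def write_annotation(models: Mapping[str, TranscriptModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for m in models.values():
            fh.write(
                f"{m.transcript_id}\t{m.gene_id}\t{m.utr5_len}\t"
                f"{m.cds_len}\t{m.utr3_len}\n"
            )


def read_counts(
    path: str | Path,
    models: Mapping[str, TranscriptModel],
    window_size: int,
    *,
    library_id: Optional[str] = None,
    role: str = LibraryRole.INPUT,
    condition: str = "na",
    timepoint: str = Timepoint.NA,
    replicate: int = 1,
    library_size: Optional[int] = None,
) -> CoverageTrack:
    """Read a windowed count TSV into a coverage track.

    Windows absent from the file are zero-padded; ``#key=value`` comment
    lines override the keyword metadata.  ``library_size`` defaults to the
    total count in the file.
    """
    meta: Dict[str, str] = {}
    counts: Dict[str, np.ndarray] = {
        tid: np.zeros(m.n_windows(window_size), dtype=np.int64)
        for tid, m in models.items()
    }
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    k, _, v = line[1:].partition("=")
                    meta[k.strip()] = v.strip()
                continue
            fields = line.split("\t")
            if fields[0] == "transcript_id":
                continue
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 fields, got {len(fields)}"
                )
            tid, widx_s, count_s = fields
            if tid not in counts:
                raise ParseError(f"{path}:{lineno}: unknown transcript {tid!r}")
            try:
                widx, count = int(widx_s), int(count_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field") from exc
            if count < 0:
                raise ParseError(f"{path}:{lineno}: negative count")
            if not 0 <= widx < len(counts[tid]):
                raise ParseError(
                    f"{path}:{lineno}: window_index {widx} out of range for "
                    f"{tid} ({len(counts[tid])} windows)"
                )
            counts[tid][widx] += count
    total = int(sum(int(v.sum()) for v in counts.values()))
    if "library_size" in meta:
        library_size = int(meta["library_size"])
    elif library_size is None:
        library_size = total
    track = CoverageTrack(
        library_id=meta.get("library_id", library_id or Path(path).stem),
        role=LibraryRole(meta.get("role", role)),
        condition=meta.get("condition", condition),
        timepoint=Timepoint(meta.get("timepoint", timepoint)),
        replicate=int(meta.get("replicate", replicate)),
        window_size=window_size,
        counts=counts,
        library_size=library_size,
    )
    track.check_grid(models)
    log.info(
        "read_counts: %s (%s/%s rep %d), %d reads from %s",
        track.library_id, track.condition, track.timepoint.value,
        track.replicate, total, path,
    )
    return track


def write_counts(track: CoverageTrack, path: str | Path, *, sparse: bool = True) -> None:
    """Write a coverage track; zero windows are omitted when ``sparse``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#library_id={track.library_id}\n")
        fh.write(f"#role={track.role.value}\n")
        fh.write(f"#condition={track.condition}\n")
        fh.write(f"#timepoint={track.timepoint.value}\n")
        fh.write(f"#replicate={track.replicate}\n")
        fh.write(f"#library_size={track.library_size}\n")
        fh.write("\t".join(COUNTS_COLUMNS) + "\n")
        for tid in sorted(track.counts):
            vec = track.counts[tid]
            for widx, c in enumerate(vec):
                if sparse and c == 0:
                    continue
                fh.write(f"{tid}\t{widx}\t{int(c)}\n")


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as BED6+3 (FE in the score column, rounded to 4 dp)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(PEAK_COLUMNS) + "\n")
        for i, p in enumerate(
            sorted(peaks, key=lambda p: (p.transcript_id, p.start, p.end))
        ):
            fh.write(
                f"{p.transcript_id}\t{p.start}\t{p.end}\tpeak_{i + 1}\t"
                f"{round(p.fe, 4)}\t.\t{p.pvalue:.6e}\t{p.qvalue:.6e}\t"
                f"{p.summit - p.start}\n"
            )
    log.info("write_peaks: %d peaks to %s", len(peaks), path)


def read_peaks(
    path: str | Path,
    *,
    counts: Optional[Mapping[str, tuple]] = None,
) -> List[Peak]:
    """Read a BED6+3 peak file written by :func:`write_peaks`.

    acRIP/input counts are not part of the BED contract; they are restored
    as 0 unless supplied via ``counts`` keyed by (transcript_id, start, end).
    """
    peaks: List[Peak] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 fields, got {len(fields)}"
                )
            tid, start, end = fields[0], int(fields[1]), int(fields[2])
            a_count, i_count = 0, 0
            if counts is not None and (tid, start, end) in counts:
                a_count, i_count = counts[(tid, start, end)]
            peaks.append(
                Peak(
                    transcript_id=tid,
                    start=start,
                    end=end,
                    summit=start + int(fields[8]),
                    acrip_count=a_count,
                    input_count=i_count,
                    fe=float(fields[4]),
                    pvalue=float(fields[6]),
                    qvalue=float(fields[7]),
                )
            )
    return peaks


def write_consensus(peaks: Sequence[ConsensusPeak], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#transcript_id\tstart\tend\tsupport\tmean_fe\n")
        for p in sorted(peaks, key=lambda p: (p.transcript_id, p.start, p.end)):
            fh.write(
                f"{p.transcript_id}\t{p.start}\t{p.end}\t{p.support}\t"
                f"{round(p.mean_fe, 4)}\n"
            )


def read_consensus(path: str | Path) -> List[ConsensusPeak]:
    out: List[ConsensusPeak] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tid, start, end, support, mean_fe = line.split("\t")
            out.append(
                ConsensusPeak(tid, int(start), int(end), int(support), float(mean_fe))
            )
    return out


def write_transcript_fe(
    records: Sequence[TranscriptAcetylation], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#transcript_id\tn_peaks\tfe_sum\n")
        for r in sorted(records, key=lambda r: r.transcript_id):
            fh.write(f"{r.transcript_id}\t{r.n_peaks}\t{round(r.fe_sum, 6)}\n")


def read_transcript_fe(path: str | Path) -> List[TranscriptAcetylation]:
    out: List[TranscriptAcetylation] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tid, n_peaks, fe_sum = line.split("\t")
            out.append(TranscriptAcetylation(tid, int(n_peaks), float(fe_sum)))
    return out


def write_fold_changes(records: Sequence[FoldChangeRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#transcript_id\tfe_case\tfe_ref\tfc\n")
        for r in sorted(records, key=lambda r: r.transcript_id):
            fh.write(
                f"{r.transcript_id}\t{round(r.fe_case, 6)}\t"
                f"{round(r.fe_ref, 6)}\t{round(r.fc, 6)}\n"
            )


def read_fold_changes(path: str | Path) -> List[FoldChangeRecord]:
    out: List[FoldChangeRecord] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tid, fe_case, fe_ref, _fc = line.split("\t")
            out.append(FoldChangeRecord(tid, float(fe_case), float(fe_ref)))
    return out


def write_misa_calls(calls: Sequence[MisaCall], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#transcript_id\tfc_d1\tfc_d6\tfc_d20\tis_misa\n")
        for c in sorted(calls, key=lambda c: c.transcript_id):
            fh.write(
                f"{c.transcript_id}\t{round(c.fc_d1, 6)}\t{round(c.fc_d6, 6)}\t"
                f"{round(c.fc_d20, 6)}\t{int(c.is_misa)}\n"
            )


def write_nasa_calls(calls: Sequence[NasaCall], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#transcript_id\tfe_ctrl\tfe_cko\tn_peaks_cko\tcategory\n")
        for c in sorted(calls, key=lambda c: c.transcript_id):
            fh.write(
                f"{c.transcript_id}\t{round(c.fe_ctrl, 6)}\t"
                f"{round(c.fe_cko, 6)}\t{c.n_peaks_cko}\t{c.category.value}\n"
            )


def read_id_list(path: str | Path) -> List[str]:
    """Read one identifier per line (first tab-separated field; '#' skipped)."""
    out: List[str] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line.split("\t")[0])
    return out
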