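"""Domain types shared by every stage of the acRIP-seq pipeline.

Everything downstream works in transcript space: 0-based, half-open
coordinates over the concatenated 5'UTR | CDS | 3'UTR of each transcript.
A :class:`TranscriptModel` therefore only needs the three segment lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np

__all__ = [
    "LibraryRole",
    "Timepoint",
    "Region",
    "NasaCategory",
    "TranscriptModel",
    "CoverageTrack",
    "Peak",
    "ConsensusPeak",
    "TranscriptAcetylation",
    "FoldChangeRecord",
    "MisaCall",
    "NasaCall",
    "MetageneProfile",
    "validate_annotation",
]


class LibraryRole(str, Enum):
    ACRIP = "acrip"
    INPUT = "input"


class Timepoint(str, Enum):
    DAY1 = "day1"
    DAY6 = "day6"
    DAY20 = "day20"
    NA = "na"


class Region(str, Enum):
    UTR5 = "UTR5"
    CDS = "CDS"
    UTR3 = "UTR3"


class NasaCategory(str, Enum):
    DIMINISHED = "diminished"
    DOWNREGULATED = "downregulated"
    UNCHANGED = "unchanged"
    NOT_ACETYLATED = "not_acetylated"


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript partitioned into 5'UTR, CDS and 3'UTR segments (nt)."""

    transcript_id: str
    gene_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValueError("transcript_id must be non-empty")
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ValueError(
                f"{self.transcript_id}: UTR lengths must be non-negative"
            )
        if self.cds_len <= 0:
            raise ValueError(f"{self.transcript_id}: cds_len must be positive")

    @property
    def total_len(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def cds_start(self) -> int:
        return self.utr5_len

    @property
    def cds_end(self) -> int:
        return self.utr5_len + self.cds_len

    def n_windows(self, window_size: int) -> int:
        return math.ceil(self.total_len / window_size)

    def region_of(self, position: int) -> Region:
        """Region containing ``position``; boundaries belong downstream."""
        if not 0 <= position < self.total_len:
            raise ValueError(
                f"position {position} outside transcript "
                f"{self.transcript_id} of length {self.total_len}"
            )
        if position < self.cds_start:
            return Region.UTR5
        if position < self.cds_end:
            return Region.CDS
        return Region.UTR3


def validate_annotation(models: Iterable[TranscriptModel]) -> Dict[str, TranscriptModel]:
    """Index models by transcript_id, rejecting duplicates."""
    out: Dict[str, TranscriptModel] = {}
    for m in models:
        if m.transcript_id in out:
            raise ValueError(f"duplicate transcript_id {m.transcript_id!r}")
        out[m.transcript_id] = m
    return out


@dataclass
class CoverageTrack:
    """Per-window read counts of one sequencing library over an annotation.

    ``counts`` maps transcript_id to a vector of non-negative integers, one
    entry per ``window_size`` nt window (the last window may be partial).
    ``library_size`` is the total number of mapped reads and must cover the
    sum of all windowed counts.
    """

    library_id: str
    role: LibraryRole
    condition: str
    timepoint: Timepoint
    replicate: int
    window_size: int
    counts: Dict[str, np.ndarray]
    library_size: int

    def __post_init__(self) -> None:
        self.role = LibraryRole(self.role)
        self.timepoint = Timepoint(self.timepoint)
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")
        if self.window_size < 1:
            raise ValueError("window_size must be a positive integer")
        total = 0
        for tid, vec in self.counts.items():
            arr = np.asarray(vec)
            if arr.ndim != 1:
                raise ValueError(f"{tid}: counts must be a 1-D vector")
            if np.any(arr < 0):
                raise ValueError(f"{tid}: negative count")
            self.counts[tid] = arr.astype(np.int64)
            total += int(arr.sum())
        if self.library_size < 1:
            raise ValueError("library_size must be positive")
        if self.library_size < total:
            raise ValueError(
                f"library_size {self.library_size} < total counts {total}"
            )

    @property
    def total_counts(self) -> int:
        return int(sum(int(v.sum()) for v in self.counts.values()))

    def check_grid(self, models: Mapping[str, TranscriptModel]) -> None:
        """Verify window vectors match the annotation's window grid."""
        for tid, vec in self.counts.items():
            if tid not in models:
                raise ValueError(f"track references unknown transcript {tid!r}")
            expect = models[tid].n_windows(self.window_size)
            if len(vec) != expect:
                raise ValueError(
                    f"{tid}: {len(vec)} windows, annotation implies {expect}"
                )


# Tolerance for q >= p after round-tripping values at printed precision.
_Q_TOL = 1e-9


@dataclass(frozen=True)
class Peak:
    """An acRIP-enriched interval on one transcript."""

    transcript_id: str
    start: int
    end: int
    summit: int
    acrip_count: int
    input_count: int
    fe: float
    pvalue: float
    qvalue: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.transcript_id}: start must precede end")
        if not self.start <= self.summit < self.end:
            raise ValueError(f"{self.transcript_id}: summit outside peak")
        if self.acrip_count < 0 or self.input_count < 0:
            raise ValueError("counts must be non-negative")
        if self.fe < 0:
            raise ValueError("fe must be non-negative")
        for name, v in (("pvalue", self.pvalue), ("qvalue", self.qvalue)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.qvalue < self.pvalue * (1.0 - _Q_TOL):
            raise ValueError("qvalue below pvalue")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ConsensusPeak:
    """Union interval of overlapping replicate peaks on one transcript."""

    transcript_id: str
    start: int
    end: int
    support: int
    mean_fe: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("start must precede end")
        if self.support < 1:
            raise ValueError("support must be positive")
        if self.mean_fe < 0:
            raise ValueError("mean_fe must be non-negative")

    def reliable(self, min_support: int = 2) -> bool:
        return self.support >= min_support


@dataclass(frozen=True)
class TranscriptAcetylation:
    """Per-transcript acetylation summary: peak count and cumulative FE.

    ``fe_sum`` is the arithmetic sum of the FE values of every peak on the
    transcript (5'UTR, CDS and 3'UTR alike) — the transcript-level "FE of
    ac4C" statistic.
    """

    transcript_id: str
    n_peaks: int
    fe_sum: float

    def __post_init__(self) -> None:
        if self.n_peaks < 0 or self.fe_sum < 0:
            raise ValueError("n_peaks and fe_sum must be non-negative")
        if (self.n_peaks == 0) != (self.fe_sum == 0):
            raise ValueError("n_peaks == 0 iff fe_sum == 0")


@dataclass(frozen=True)
class FoldChangeRecord:
    """Pseudocount fold change of transcript-level FE: (FE_case+1)/(FE_ref+1)."""

    transcript_id: str
    fe_case: float
    fe_ref: float

    def __post_init__(self) -> None:
        if self.fe_case < 0 or self.fe_ref < 0:
            raise ValueError("FE values must be non-negative")

    @property
    def fc(self) -> float:
        return (self.fe_case + 1.0) / (self.fe_ref + 1.0)


@dataclass(frozen=True)
class MisaCall:
    """Memory-induced synaptic ac4C call from three day-wise fold changes."""

    transcript_id: str
    fc_d1: float
    fc_d6: float
    fc_d20: float
    is_misa: bool

    scheme = "MISA"


@dataclass(frozen=True)
class NasaCall:
    """NAT10-dependence call for one control-vs-cKO transcript."""

    transcript_id: str
    fe_ctrl: float
    fe_cko: float
    n_peaks_cko: int
    category: NasaCategory

    scheme = "NASA"

    @property
    def is_nasa(self) -> bool:
        return self.category in (NasaCategory.DIMINISHED, NasaCategory.DOWNREGULATED)


@dataclass
class MetageneProfile:
    """Summit density over length-normalised UTR5 | CDS | UTR3 segments."""

    bins_per_region: int
    density: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_summits: int = 0

    def __post_init__(self) -> None:
        if self.bins_per_region < 1:
            raise ValueError("bins_per_region must be positive")
        if self.density is None:
            self.density = np.zeros(3 * self.bins_per_region)
        self.density = np.asarray(self.density, dtype=float)
        if len(self.density) != 3 * self.bins_per_region:
            raise ValueError("density length must be 3 * bins_per_region")

    def region_slice(self, region: Region) -> slice:
        i = [Region.UTR5, Region.CDS, Region.UTR3].index(region)
        return slice(i * self.bins_per_region, (i + 1) * self.bins_per_region)
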