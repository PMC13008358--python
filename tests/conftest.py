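"""Shared fixtures: a tiny hand-built annotation and track constructors."""

from __future__ import annotations

import numpy as np
import pytest

from ac4c.models import CoverageTrack, LibraryRole, Timepoint, TranscriptModel


@pytest.fixture
def tiny_models():
    """Three transcripts with distinct segment architectures."""
    return {
        "tx1": TranscriptModel("tx1", "g1", 100, 900, 400),
        "tx2": TranscriptModel("tx2", "g2", 0, 600, 0),
        "tx3": TranscriptModel("tx3", "g3", 50, 300, 150),
    }


def make_track(
    counts,
    *,
    role="input",
    window_size=50,
    library_size=None,
    condition="control",
    timepoint="day6",
    replicate=1,
    library_id=None,
):
    """Build a CoverageTrack from a dict of python lists."""
    counts = {tid: np.asarray(v, dtype=np.int64) for tid, v in counts.items()}
    total = int(sum(v.sum() for v in counts.values()))
    return CoverageTrack(
        library_id=library_id or f"{condition}_{timepoint}_r{replicate}_{role}",
        role=LibraryRole(role),
        condition=condition,
        timepoint=Timepoint(timepoint),
        replicate=replicate,
        window_size=window_size,
        counts=counts,
        library_size=library_size if library_size is not None else max(total, 1),
    )


@pytest.fixture
def track_factory():
    return make_track
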