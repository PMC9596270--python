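"""Shared fixtures and table-building helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from deepemo.au_io import VideoAUTable

DEFAULT_UNIVERSE = (1, 2, 4, 5, 6, 7, 9, 12, 15, 16, 20, 23, 26)


def make_table(
    presence_rows,
    *,
    universe=DEFAULT_UNIVERSE,
    video_id="id0_0000",
    target=0,
    donor=None,
    variant="dynamic",
    frame_index=None,
    success=None,
    confidence=None,
):
    """Build a VideoAUTable from per-frame sets of active AU ids."""
    n = len(presence_rows)
    bits = np.zeros((n, len(universe)), dtype=np.int8)
    col = {au: j for j, au in enumerate(universe)}
    for i, row in enumerate(presence_rows):
        for au in row:
            bits[i, col[au]] = 1
    return VideoAUTable(
        video_id=video_id,
        target_performer=target,
        donor_performer=donor,
        model_variant=variant,
        frame_index=(
            np.arange(1, n + 1) if frame_index is None else np.asarray(frame_index)
        ),
        confidence=(
            np.ones(n) if confidence is None else np.asarray(confidence, float)
        ),
        success=(
            np.ones(n, dtype=bool) if success is None else np.asarray(success, bool)
        ),
        presence=pd.DataFrame(bits, columns=list(universe), dtype=np.int8),
    )


@pytest.fixture
def happy_then_blank():
    """Two frames: a full Happiness combination, then a blank (Neutral) one."""
    return make_table([{6, 12}, set()])
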