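"""Read and write per-frame facial action-unit tables (OpenFace CSV dialect).

OpenFace emits one CSV per video with one row per photogram.  The columns this
package consumes are ``frame`` (1-based index), optional ``timestamp``,
``confidence`` (face-tracking confidence in [0, 1]), ``success`` (0/1 flag for
a detected face), binary AU presence columns ``AU##_c`` and real-valued AU
intensity columns ``AU##_r`` in [0, 5].  Column names may carry leading
whitespace (OpenFace pads its headers); both padded and unpadded forms are
accepted.

Video files are named by the Celeb-DF convention: ``id<T>_<seq>`` for an
original recording by performer T and ``id<T>_id<D>_<seq>`` for a deepfake
made on that original with donor performer D's face.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AUFormatError, AUParseError, VideoNameError

MODEL_VARIANTS = ("static", "dynamic")

_AU_PRESENCE_RE = re.compile(r"^AU(\d+)_c$")
_AU_INTENSITY_RE = re.compile(r"^AU(\d+)_r$")
_ORIGINAL_NAME_RE = re.compile(r"^id(\d+)_(\d+)$")
_FAKE_NAME_RE = re.compile(r"^id(\d+)_id(\d+)_(\d+)$")


@dataclass(frozen=True)
class VideoIdentity:
    """Parsed Celeb-DF-style video identity."""

    video_id: str
    is_fake: bool
    target_performer: int
    donor_performer: int | None
    sequence_number: int

    def __post_init__(self) -> None:
        if self.is_fake != (self.donor_performer is not None):
            raise ValueError("is_fake must hold exactly when a donor is set")


@dataclass(frozen=True)
class AUFrame:
    """A single photogram's action-unit record."""

    frame_index: int
    confidence: float
    success: bool
    au_presence: Mapping[int, int]
    au_intensity: Mapping[int, float] | None = None
    timestamp_s: float | None = None


@dataclass
class VideoAUTable:
    """An ordered per-video sequence of AU records, stored column-wise.

    ``presence`` is a 0/1 DataFrame whose columns are integer AU ids; its rows
    align positionally with ``frame_index``, ``confidence`` and ``success``.
    """

    video_id: str
    target_performer: int
    donor_performer: int | None
    model_variant: str
    frame_index: np.ndarray
    confidence: np.ndarray
    success: np.ndarray
    presence: pd.DataFrame
    intensity: pd.DataFrame | None = None
    timestamp_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.model_variant not in MODEL_VARIANTS:
            raise ValueError(f"model_variant must be one of {MODEL_VARIANTS}")
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        if self.frame_index.size and np.any(np.diff(self.frame_index) <= 0):
            raise ValueError("frame_index must be strictly increasing")
        if len(self.presence) != len(self.frame_index):
            raise ValueError("presence rows must match frame count")

    @property
    def is_fake(self) -> bool:
        return self.donor_performer is not None

    @property
    def n_frames(self) -> int:
        return int(self.frame_index.size)

    @property
    def au_universe(self) -> tuple[int, ...]:
        return tuple(int(c) for c in self.presence.columns)

    @property
    def frames(self) -> list[AUFrame]:
        return list(self.iter_frames())

    def iter_frames(self) -> Iterator[AUFrame]:
        aus = self.au_universe
        pres = self.presence.to_numpy()
        inten = self.intensity.to_numpy() if self.intensity is not None else None
        for i in range(self.n_frames):
            yield AUFrame(
                frame_index=int(self.frame_index[i]),
                confidence=float(self.confidence[i]),
                success=bool(self.success[i]),
                au_presence={au: int(pres[i, j]) for j, au in enumerate(aus)},
                au_intensity=(
                    None
                    if inten is None
                    else {au: float(inten[i, j]) for j, au in enumerate(aus)}
                ),
                timestamp_s=(
                    None if self.timestamp_s is None else float(self.timestamp_s[i])
                ),
            )

    def take(self, positions: np.ndarray) -> "VideoAUTable":
        """Positional row subset preserving original frame indices."""
        return replace(
            self,
            frame_index=self.frame_index[positions],
            confidence=np.asarray(self.confidence)[positions],
            success=np.asarray(self.success)[positions],
            presence=self.presence.iloc[positions].reset_index(drop=True),
            intensity=(
                None
                if self.intensity is None
                else self.intensity.iloc[positions].reset_index(drop=True)
            ),
            timestamp_s=(
                None
                if self.timestamp_s is None
                else np.asarray(self.timestamp_s)[positions]
            ),
        )


def parse_video_name(filename: str, donor_first: bool = False) -> VideoIdentity:
    """Parse a Celeb-DF-style filename into a :class:`VideoIdentity`.

    ``id<T>_<seq>`` is an original; ``id<A>_id<B>_<seq>`` is a fake.  By
    default the first id of a fake names the target performer (the performer
    whose original recording was re-rendered) and the second the face donor;
    ``donor_first=True`` swaps that reading.
    """
    stem = Path(filename).name
    # strip at most one extension; ids themselves contain no dots
    stem = stem.split(".", 1)[0]
    m = _ORIGINAL_NAME_RE.match(stem)
    if m:
        return VideoIdentity(
            video_id=stem,
            is_fake=False,
            target_performer=int(m.group(1)),
            donor_performer=None,
            sequence_number=int(m.group(2)),
        )
    m = _FAKE_NAME_RE.match(stem)
    if m:
        first, second = int(m.group(1)), int(m.group(2))
        target, donor = (second, first) if donor_first else (first, second)
        return VideoIdentity(
            video_id=stem,
            is_fake=True,
            target_performer=target,
            donor_performer=donor,
            sequence_number=int(m.group(3)),
        )
    raise VideoNameError(
        f"cannot parse video name {filename!r}: expected 'id<int>_<seq>' "
        "(original) or 'id<int>_id<int>_<seq>' (fake), extension ignored"
    )


def _normalize_columns(columns: Sequence[str]) -> list[str]:
    return [c.strip() for c in columns]


def read_au_csv(
    path: str | Path,
    model_variant: str = "dynamic",
    *,
    identity: VideoIdentity | None = None,
    donor_first: bool = False,
    presence_threshold: float = 0.0,
) -> VideoAUTable:
    """Read one OpenFace-dialect AU CSV into a :class:`VideoAUTable`.

    Presence is taken from the binary ``AU##_c`` columns when present; for AUs
    carrying only an intensity column, presence is derived as
    ``intensity > presence_threshold``.

    Raises
    ------
    AUFormatError
        if a mandatory column (frame, confidence, success, or any AU column)
        is missing.
    AUParseError
        if a cell fails numeric conversion (reported with its row number).
    """
    path = Path(path)
    if identity is None:
        identity = parse_video_name(path.name, donor_first=donor_first)
    try:
        raw = pd.read_csv(path, skipinitialspace=True, dtype=str)
    except pd.errors.EmptyDataError:
        raise AUFormatError(f"{path}: empty file, no header row") from None
    raw.columns = _normalize_columns(raw.columns)

    for col in ("frame", "confidence", "success"):
        if col not in raw.columns:
            raise AUFormatError(f"{path}: missing mandatory column {col!r}")

    presence_cols = {
        int(m.group(1)): c
        for c in raw.columns
        if (m := _AU_PRESENCE_RE.match(c))
    }
    intensity_cols = {
        int(m.group(1)): c
        for c in raw.columns
        if (m := _AU_INTENSITY_RE.match(c))
    }
    if not presence_cols and not intensity_cols:
        raise AUFormatError(
            f"{path}: missing mandatory column 'AU##_c' (no AU columns found)"
        )

    def to_numeric(col: str) -> np.ndarray:
        series = pd.to_numeric(raw[col], errors="coerce")
        bad = series.isna() & raw[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise AUParseError(
                f"{path}: non-numeric value {raw[col].iloc[row]!r} in column "
                f"{col!r}, data row {row + 1}"
            )
        if series.isna().any():
            row = int(np.flatnonzero(series.isna().to_numpy())[0])
            raise AUParseError(
                f"{path}: missing value in column {col!r}, data row {row + 1}"
            )
        return series.to_numpy(dtype=float)

    frame = to_numeric("frame").astype(np.int64)
    confidence = to_numeric("confidence")
    success = to_numeric("success").astype(bool)
    timestamp = to_numeric("timestamp") if "timestamp" in raw.columns else None

    au_ids = sorted(set(presence_cols) | set(intensity_cols))
    intensity = None
    if intensity_cols:
        intensity = pd.DataFrame(
            {au: to_numeric(c) for au, c in sorted(intensity_cols.items())}
        )
    presence_data = {}
    for au in au_ids:
        if au in presence_cols:
            presence_data[au] = (to_numeric(presence_cols[au]) > 0).astype(np.int8)
        else:
            presence_data[au] = (
                intensity[au].to_numpy() > presence_threshold
            ).astype(np.int8)
    presence = pd.DataFrame(presence_data, columns=au_ids, dtype=np.int8)
    if len(presence) == 0:
        presence = pd.DataFrame(
            {au: np.empty(0, dtype=np.int8) for au in au_ids}, columns=au_ids
        )

    return VideoAUTable(
        video_id=identity.video_id,
        target_performer=identity.target_performer,
        donor_performer=identity.donor_performer,
        model_variant=model_variant,
        frame_index=frame,
        confidence=confidence,
        success=success,
        presence=presence,
        intensity=intensity,
        timestamp_s=timestamp,
    )


def write_au_csv(table: VideoAUTable, path: str | Path) -> None:
    """Write a table back out in the OpenFace CSV dialect (unpadded headers)."""
    out = {"frame": table.frame_index}
    if table.timestamp_s is not None:
        out["timestamp"] = table.timestamp_s
    out["confidence"] = np.asarray(table.confidence, dtype=float)
    out["success"] = np.asarray(table.success).astype(int)
    if table.intensity is not None:
        for au in table.intensity.columns:
            out[f"AU{int(au):02d}_r"] = table.intensity[au].to_numpy()
    for au in table.presence.columns:
        out[f"AU{int(au):02d}_c"] = table.presence[au].to_numpy()
    pd.DataFrame(out).to_csv(path, index=False)


def filter_valid_frames(
    table: VideoAUTable, min_confidence: float = 0.0
) -> VideoAUTable:
    """Keep only frames with a detected face and sufficient confidence.

    Keeps frames with ``success`` true and ``confidence >= min_confidence``;
    order and original frame indices are preserved.  An empty result is legal.
    """
    mask = np.asarray(table.success, dtype=bool) & (
        np.asarray(table.confidence, dtype=float) >= min_confidence
    )
    return table.take(np.flatnonzero(mask))
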