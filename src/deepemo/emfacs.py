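"""EMFACS-style rule engine: AU presence sets -> basic-emotion flags.

The Facial Action Coding System (FACS) describes facial behaviour as numbered
action units (AUs).  EMFACS maps AU combinations onto Ekman's six basic
emotions.  This module implements that mapping as a conjunction rule: an
emotion is flagged on a photogram exactly when *all* of its associated AUs are
present.  A photogram showing none of the emotion-related AUs is Neutral; a
photogram with some emotion-related AUs but no complete combination carries no
flag at all (neither emotional nor Neutral).

The default rule set:

=========  =======================
Emotion    Required action units
=========  =======================
Sadness    1, 4
Fear       1, 2, 4, 5, 7, 20, 26
Happiness  6, 12
Anger      4, 5, 7, 23
Surprise   1, 2, 5, 26
Disgust    9, 15, 16
=========  =======================

Because the Fear combination contains both the Sadness and the Surprise
combinations, a frame flagged Fear is always also flagged Sadness and
Surprise: labels are multi-label by design, and all downstream counts treat
each emotion independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import AbstractSet, Iterable, Mapping

import pandas as pd
import yaml

from .au_io import VideoAUTable

EMOTIONS = ("Sadness", "Fear", "Happiness", "Anger", "Surprise", "Disgust")
NEUTRAL = "Neutral"
ALL_LABELS = EMOTIONS + (NEUTRAL,)

_DEFAULT_RULES: dict[str, frozenset[int]] = {
    "Sadness": frozenset({1, 4}),
    "Fear": frozenset({1, 2, 4, 5, 7, 20, 26}),
    "Happiness": frozenset({6, 12}),
    "Anger": frozenset({4, 5, 7, 23}),
    "Surprise": frozenset({1, 2, 5, 26}),
    "Disgust": frozenset({9, 15, 16}),
}


@dataclass(frozen=True)
class EmotionRuleSet:
    """A mapping emotion -> required AU set, plus the derived AU universe.

    ``missing_au_policy`` governs AUs that a rule requires but the input file
    does not report at all (e.g. AU16, absent from standard OpenFace output):

    - ``"absent"`` (default): the unreported AU counts as never present, so a
      rule requiring it can never fire — the conservative reading.
    - ``"drop"``: the unreported AU is removed from the rule for that file.
    """

    rules: Mapping[str, frozenset[int]]
    missing_au_policy: str = "absent"

    def __post_init__(self) -> None:
        if self.missing_au_policy not in ("absent", "drop"):
            raise ValueError("missing_au_policy must be 'absent' or 'drop'")
        object.__setattr__(
            self, "rules", {e: frozenset(a) for e, a in self.rules.items()}
        )
        for emotion, aus in self.rules.items():
            if not aus:
                raise ValueError(f"rule for {emotion!r} is empty")

    @property
    def emotions(self) -> tuple[str, ...]:
        return tuple(self.rules)

    @property
    def emotion_au_universe(self) -> frozenset[int]:
        out: frozenset[int] = frozenset()
        for aus in self.rules.values():
            out |= aus
        return out

    def effective_rule(self, emotion: str, available: AbstractSet[int]) -> frozenset[int] | None:
        """The rule to evaluate against a file reporting only ``available`` AUs.

        Returns None when the rule cannot fire (a required AU is unreported
        under the ``absent`` policy, or the whole rule vanished under ``drop``).
        """
        required = self.rules[emotion]
        if self.missing_au_policy == "absent":
            return required if required <= available else None
        reduced = required & frozenset(available)
        return reduced or None

    @classmethod
    def from_config(cls, path: str | Path, **kwargs) -> "EmotionRuleSet":
        """Load rules from a YAML mapping ``emotion: [au, au, ...]``."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a mapping emotion -> AU list")
        return cls({str(e): frozenset(int(a) for a in aus) for e, aus in raw.items()}, **kwargs)


def default_ruleset() -> EmotionRuleSet:
    """The standard EMFACS emotion/AU table."""
    return EmotionRuleSet(_DEFAULT_RULES)


@dataclass(frozen=True)
class FrameEmotionFlags:
    """Multi-label emotion flags (plus Neutral) for one photogram."""

    flags: Mapping[str, bool]

    @property
    def active(self) -> frozenset[str]:
        return frozenset(k for k, v in self.flags.items() if v)

    def __getitem__(self, label: str) -> bool:
        return self.flags[label]


def classify_frame(
    presence: AbstractSet[int] | Iterable[int], rules: EmotionRuleSet | None = None
) -> FrameEmotionFlags:
    """Classify one photogram from its set of present AU ids.

    Emotion E is flagged iff every AU required by E's rule is present; Neutral
    is flagged iff no emotion-related AU is present at all.  AU ids outside
    the rule universe are ignored.
    """
    if rules is None:
        rules = default_ruleset()
    present = frozenset(presence)
    flags = {e: aus <= present for e, aus in rules.rules.items()}
    flags[NEUTRAL] = not (present & rules.emotion_au_universe)
    return FrameEmotionFlags(flags)


def label_video(
    table: VideoAUTable, rules: EmotionRuleSet | None = None
) -> pd.DataFrame:
    """Label every frame of a (validity-filtered) table.

    Returns a boolean DataFrame with one row per frame (indexed by the
    original ``frame_index``) and one column per emotion plus ``Neutral``.
    """
    if rules is None:
        rules = default_ruleset()
    available = frozenset(table.au_universe)
    n = table.n_frames
    pres = table.presence
    out: dict[str, pd.Series] = {}
    for emotion in rules.emotions:
        required = rules.effective_rule(emotion, available)
        if required is None:
            col = pd.Series(False, index=range(n))
        else:
            col = pres[list(required)].eq(1).all(axis=1)
        out[emotion] = col
    reported_universe = sorted(available & rules.emotion_au_universe)
    if reported_universe:
        out[NEUTRAL] = pres[reported_universe].eq(0).all(axis=1)
    else:
        out[NEUTRAL] = pd.Series(True, index=range(n))
    labels = pd.DataFrame(out)
    labels.index = pd.Index(table.frame_index, name="frame")
    return labels.astype(bool)


def flags_from_row(row: pd.Series) -> FrameEmotionFlags:
    """Convenience: one labeled row back into a :class:`FrameEmotionFlags`."""
    return FrameEmotionFlags({str(k): bool(v) for k, v in row.items()})
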