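"""Frame-agreement statistics between original and fake emotion labelings.

For a given emotion, every original/fake recording pair yields three counts
over its photograms:

- EPC  (alias CO): photograms flagged in *both* channels at the same frame,
- EPOA (alias OR): photograms flagged in the original only,
- EPFA (alias FA): photograms flagged in the fake only.

Percentages normalise to the original channel's emotional photograms:

    %C = 100 * EPC  / (EPC + EPOA)
    %O = 100 * EPOA / (EPC + EPOA)
    %F = 100 * EPFA / (EPC + EPOA)

so %C + %O = 100 while %F may exceed 100 when a performer has many more fake
than original recordings.  When EPC + EPOA = 0 the percentages are undefined;
such rows are routed to the zero-baseline exclusion list, never imputed.

Displayed percentages are rounded half-up to two decimals; internal counts
stay exact integers.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .emfacs import ALL_LABELS, EMOTIONS, NEUTRAL
from .errors import ContractError, ZeroEmotionalBaselineError
from .pairing import DatasetIndex, RecordingPair


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (display convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AgreementCounts:
    """EPC/EPOA/EPFA counts for one emotion (any aggregation scope)."""

    emotion: str
    epc: int
    epoa: int
    epfa: int

    def __post_init__(self) -> None:
        if min(self.epc, self.epoa, self.epfa) < 0:
            raise ValueError("agreement counts must be non-negative")

    def __add__(self, other: "AgreementCounts") -> "AgreementCounts":
        if other.emotion != self.emotion:
            raise ValueError("cannot add counts across emotions")
        return AgreementCounts(
            self.emotion,
            self.epc + other.epc,
            self.epoa + other.epoa,
            self.epfa + other.epfa,
        )

    @property
    def original_total(self) -> int:
        """All emotional photograms in the original channel (EPC + EPOA)."""
        return self.epc + self.epoa


@dataclass(frozen=True)
class PercentTriple:
    """%C/%O/%F at full precision; 2-decimal half-up display on demand."""

    pct_common: float
    pct_original_alone: float
    pct_fake_alone: float

    def display(self) -> tuple[float, float, float]:
        return (
            round_half_up(self.pct_common),
            round_half_up(self.pct_original_alone),
            round_half_up(self.pct_fake_alone),
        )


def percent_triple(counts: AgreementCounts) -> PercentTriple:
    """Normalise counts to the original channel's emotional photograms.

    Raises :class:`ZeroEmotionalBaselineError` when EPC + EPOA = 0 (the
    original showed no such emotion, so a percentage over 0 is undefined).
    """
    denom = counts.original_total
    if denom == 0:
        raise ZeroEmotionalBaselineError(
            f"no emotional photograms in the original channel for "
            f"{counts.emotion}; percentages undefined"
        )
    return PercentTriple(
        pct_common=100.0 * counts.epc / denom,
        pct_original_alone=100.0 * counts.epoa / denom,
        pct_fake_alone=100.0 * counts.epfa / denom,
    )


def _check_labels(pair: RecordingPair, labels_orig: pd.DataFrame, labels_fake: pd.DataFrame) -> None:
    if len(labels_orig) != pair.original.n_frames:
        raise ContractError(
            f"original labels ({len(labels_orig)}) do not match table frames "
            f"({pair.original.n_frames}) for {pair.original.video_id}"
        )
    if len(labels_fake) != pair.fake.n_frames:
        raise ContractError(
            f"fake labels ({len(labels_fake)}) do not match table frames "
            f"({pair.fake.n_frames}) for {pair.fake.video_id}"
        )


def count_agreement(
    pair: RecordingPair,
    labels_orig: pd.DataFrame,
    labels_fake: pd.DataFrame,
    emotion: str,
    *,
    both_channels_only: bool = False,
) -> AgreementCounts:
    """Count EPC/EPOA/EPFA for one emotion over one aligned pair.

    Label frames present in only one channel count toward that channel's
    one-sided tally unless ``both_channels_only`` restricts the scope to
    frames where both channels had a detected face.
    """
    _check_labels(pair, labels_orig, labels_fake)
    o = labels_orig[emotion]
    f = labels_fake[emotion]
    common_idx = pd.Index(pair.aligned_indices[:, 0])
    o_common = o.loc[common_idx].to_numpy()
    f_common = f.loc[pair.aligned_indices[:, 1]].to_numpy()
    epc = int(np.sum(o_common & f_common))
    epoa = int(np.sum(o_common & ~f_common))
    epfa = int(np.sum(~o_common & f_common))
    if not both_channels_only:
        epoa += int(o.loc[~o.index.isin(common_idx)].sum())
        epfa += int(f.loc[~f.index.isin(pair.aligned_indices[:, 1])].sum())
    return AgreementCounts(emotion, epc, epoa, epfa)


def pair_label_counts(
    pair: RecordingPair,
    labels_orig: pd.DataFrame,
    labels_fake: pd.DataFrame,
    *,
    both_channels_only: bool = False,
    labels: Sequence[str] = ALL_LABELS,
) -> dict[str, AgreementCounts]:
    """Agreement counts for every label, plus a distinct-frame ``"_any"``
    entry over the six basic emotions (a frame with several flags counts
    once there, Neutral excluded)."""
    out = {
        label: count_agreement(
            pair, labels_orig, labels_fake, label,
            both_channels_only=both_channels_only,
        )
        for label in labels
    }
    any_o = labels_orig[list(EMOTIONS)].any(axis=1).to_frame("_any")
    any_f = labels_fake[list(EMOTIONS)].any(axis=1).to_frame("_any")
    out["_any"] = count_agreement(
        pair, any_o, any_f, "_any", both_channels_only=both_channels_only
    )
    return out


def sum_counts(groups: Iterable[AgreementCounts], emotion: str) -> AgreementCounts:
    total = AgreementCounts(emotion, 0, 0, 0)
    for c in groups:
        total = total + c
    return total


def aggregate_by_emotion(
    per_pair_counts: Sequence[Mapping[str, AgreementCounts]],
    labels: Sequence[str] = ALL_LABELS,
) -> pd.DataFrame:
    """Global table: counts summed over all pairs, then percentages.

    Columns EPC, EPOA, EPFA, %C, %O, %F; one row per label.  Undefined
    percentage cells are left as NA (the exclusion accounting reports them).
    """
    rows = []
    for label in labels:
        total = sum_counts((pc[label] for pc in per_pair_counts), label)
        row = {"Emotion": label, "EPC": total.epc, "EPOA": total.epoa, "EPFA": total.epfa}
        try:
            pct = percent_triple(total).display()
            row.update({"%C": pct[0], "%O": pct[1], "%F": pct[2]})
        except ZeroEmotionalBaselineError:
            row.update({"%C": pd.NA, "%O": pd.NA, "%F": pd.NA})
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_by_performer(
    index: DatasetIndex,
    per_pair_counts: Sequence[tuple[int, Mapping[str, AgreementCounts]]],
    *,
    totals_mode: str = "multiple",
) -> pd.DataFrame:
    """Per-performer sample and all-emotion agreement summary.

    ``per_pair_counts`` carries (target performer, counts-per-label) for each
    pair.  All-emotion totals sum the six basic emotions and exclude Neutral;
    with ``totals_mode="multiple"`` (default) a frame flagged with several
    emotions counts once per flag, with ``"distinct"`` it counts once.
    Performers with no paired fakes are excluded.
    """
    if totals_mode not in ("multiple", "distinct"):
        raise ValueError("totals_mode must be 'multiple' or 'distinct'")
    rows = []
    for pid in index.performer_ids:
        entry = index.entry(pid)
        mine = [pc for p, pc in per_pair_counts if p == pid]
        if entry.n_fakes == 0 or not mine:
            continue
        if totals_mode == "multiple":
            parts = [sum_counts((pc[e] for pc in mine), e) for e in EMOTIONS]
            co = sum(p.epc for p in parts)
            oa = sum(p.epoa for p in parts)
            fa = sum(p.epfa for p in parts)
        else:
            total = sum_counts((pc["_any"] for pc in mine), "_any")
            co, oa, fa = total.epc, total.epoa, total.epfa
        row = {
            "Id": pid,
            "OR": entry.n_originals,
            "PF": entry.n_donors,
            "FRP": entry.n_fakes,
            "CO": co,
            "OR_alone": oa,
            "FA": fa,
        }
        try:
            pct = percent_triple(AgreementCounts("_all", co, oa, fa)).display()
            row.update({"%CO": pct[0], "%OR": pct[1], "%FA": pct[2]})
        except ZeroEmotionalBaselineError:
            row.update({"%CO": pd.NA, "%OR": pd.NA, "%FA": pd.NA})
        rows.append(row)
    cols = ["Id", "OR", "PF", "FRP", "CO", "OR_alone", "FA", "%CO", "%OR", "%FA"]
    return pd.DataFrame(rows, columns=cols)


def recording_rates(
    index: DatasetIndex,
    fake_labelings: Mapping[str, pd.DataFrame],
    labels: Sequence[str] = ALL_LABELS,
) -> pd.DataFrame:
    """Per performer and label: % of fake recordings with >=1 flagged frame.

    Normalised to FRP, the performer's number of fake recordings (orphan
    fakes included: a fake with no surviving original is still a fake
    recording of the performer); performers with FRP = 0 are omitted.
    """
    rows = []
    for pid in index.performer_ids:
        entry = index.entry(pid)
        frp = entry.n_fakes
        if frp == 0:
            continue
        row: dict[str, object] = {"Id": pid}
        fake_ids = [f.video_id for f in entry.all_fakes]
        for label in labels:
            hits = sum(
                bool(fake_labelings[v][label].any()) for v in fake_ids
            )
            row[label] = round_half_up(100.0 * hits / frp)
        rows.append(row)
    return pd.DataFrame(rows, columns=["Id", *labels])


def zero_baseline_exclusions(
    index: DatasetIndex,
    per_pair_counts: Sequence[tuple[int, Mapping[str, AgreementCounts]]],
    labels: Sequence[str] = ALL_LABELS,
) -> dict[str, list[int]]:
    """Performers whose originals show zero photograms of a label while their
    fakes show some: the percentage increase would be over 0 %, so they are
    excluded from per-performer percentage displays."""
    out: dict[str, list[int]] = {label: [] for label in labels}
    for pid in index.performer_ids:
        mine = [pc for p, pc in per_pair_counts if p == pid]
        if not mine:
            continue
        for label in labels:
            total = sum_counts((pc[label] for pc in mine), label)
            if total.original_total == 0 and total.epfa > 0:
                out[label].append(pid)
    return out
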