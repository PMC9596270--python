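"""Agreement counting, percentage normalisation, and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from deepemo.au_io import parse_video_name
from deepemo.emfacs import ALL_LABELS, label_video
from deepemo.errors import ContractError, ZeroEmotionalBaselineError
from deepemo.metrics import (
    AgreementCounts,
    aggregate_by_emotion,
    aggregate_by_performer,
    count_agreement,
    pair_label_counts,
    percent_triple,
    recording_rates,
    round_half_up,
    sum_counts,
    zero_baseline_exclusions,
)
from deepemo.pairing import RecordingPair, align_frames, index_dataset

from conftest import make_table


def flags_frame(bits, emotion="Happiness", frame_index=None):
    """A label DataFrame with one emotion column driven by a 0/1 list."""
    idx = pd.Index(frame_index if frame_index is not None else range(1, len(bits) + 1))
    data = {label: [False] * len(bits) for label in ALL_LABELS}
    data[emotion] = [bool(b) for b in bits]
    return pd.DataFrame(data, index=idx)


def pair_of_length(n_orig, n_fake, orig_idx=None, fake_idx=None):
    orig = make_table([set()] * n_orig, frame_index=orig_idx)
    fake = make_table(
        [set()] * n_fake, frame_index=fake_idx,
        video_id="id0_id1_0000", donor=1,
    )
    return align_frames(RecordingPair(original=orig, fake=fake))


class TestCountAgreement:
    def test_identical_sequences(self):
        pair = pair_of_length(5, 5)
        labels = flags_frame([1, 1, 0, 1, 0])
        counts = count_agreement(pair, labels, labels, "Happiness")
        assert (counts.epc, counts.epoa, counts.epfa) == (3, 0, 0)

    def test_mixed_sequences(self):
        pair = pair_of_length(5, 5)
        counts = count_agreement(
            pair,
            flags_frame([1, 1, 0, 1, 0]),
            flags_frame([1, 0, 0, 1, 1]),
            "Happiness",
        )
        assert (counts.epc, counts.epoa, counts.epfa) == (2, 1, 1)

    def test_all_false(self):
        pair = pair_of_length(3, 3)
        counts = count_agreement(
            pair, flags_frame([0, 0, 0]), flags_frame([0, 0, 0]), "Happiness"
        )
        assert (counts.epc, counts.epoa, counts.epfa) == (0, 0, 0)

    def test_one_sided_frames_count_to_their_channel(self):
        # original has frames 1-4, fake only 1-2; original flags on 3 and 4
        pair = pair_of_length(4, 2)
        counts = count_agreement(
            pair,
            flags_frame([0, 1, 1, 1]),
            flags_frame([1, 1], frame_index=[1, 2]),
            "Happiness",
        )
        assert (counts.epc, counts.epoa, counts.epfa) == (1, 2, 1)

    def test_both_channels_only_restricts_scope(self):
        pair = pair_of_length(4, 2)
        counts = count_agreement(
            pair,
            flags_frame([0, 1, 1, 1]),
            flags_frame([1, 1], frame_index=[1, 2]),
            "Happiness",
            both_channels_only=True,
        )
        assert (counts.epc, counts.epoa, counts.epfa) == (1, 0, 1)

    def test_length_mismatch_is_contract_error(self):
        pair = pair_of_length(3, 3)
        with pytest.raises(ContractError, match="labels"):
            count_agreement(pair, flags_frame([1, 0]), flags_frame([0, 0, 0]), "Happiness")


class TestPercentTriple:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((6047, 15099, 11827), (28.60, 71.40, 55.93)),
            ((1652, 1871, 3866), (46.89, 53.11, 109.74)),
            ((7, 0, 0), (100.00, 0.00, 0.00)),
        ],
    )
    def test_normalisation(self, counts, expected):
        triple = percent_triple(AgreementCounts("Sadness", *counts))
        assert triple.display() == expected

    def test_common_and_original_sum_to_hundred(self):
        triple = percent_triple(AgreementCounts("Anger", 431, 3029, 2808))
        c, o, _ = triple.display()
        assert abs(c + o - 100.0) <= 0.01

    def test_zero_baseline_raises(self):
        with pytest.raises(ZeroEmotionalBaselineError):
            percent_triple(AgreementCounts("Fear", 0, 0, 12))

    @given(
        st.integers(0, 10**6), st.integers(0, 10**6), st.integers(0, 10**6)
    )
    @settings(max_examples=100, deadline=None)
    def test_sum_invariant_holds_generally(self, epc, epoa, epfa):
        counts = AgreementCounts("x", epc, epoa, epfa)
        if counts.original_total == 0:
            return
        c, o, f = percent_triple(counts).display()
        assert abs(c + o - 100.0) <= 0.01
        assert f >= 0


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [(0.005, 0.01), (109.735, 109.74), (52.004, 52.0), (2.675, 2.68)],
    )
    def test_half_up(self, value, expected):
        assert round_half_up(value) == expected


class TestAggregation:
    def test_singleton_sum(self):
        c = AgreementCounts("Anger", 1, 2, 3)
        assert sum_counts([c], "Anger") == c

    def test_additivity(self):
        a = AgreementCounts("Anger", 1, 2, 3)
        b = AgreementCounts("Anger", 4, 5, 6)
        assert (a + b) == AgreementCounts("Anger", 5, 7, 9)

    def test_aggregate_by_emotion_sums_before_percentages(self):
        per_pair = [
            {"Happiness": AgreementCounts("Happiness", 1, 3, 0)},
            {"Happiness": AgreementCounts("Happiness", 2, 0, 1)},
        ]
        out = aggregate_by_emotion(per_pair, labels=("Happiness",))
        row = out.iloc[0]
        assert (row["EPC"], row["EPOA"], row["EPFA"]) == (3, 3, 1)
        assert row["%C"] == 50.0  # (1+2)/(1+2+3+0), not a mean of ratios

    def test_disjoint_union_equals_concatenation(self):
        rng = np.random.default_rng(3)
        groups = [
            {"Anger": AgreementCounts("Anger", *rng.integers(0, 50, 3))}
            for _ in range(6)
        ]
        whole = aggregate_by_emotion(groups, labels=("Anger",))
        part_a = sum_counts((g["Anger"] for g in groups[:2]), "Anger")
        part_b = sum_counts((g["Anger"] for g in groups[2:]), "Anger")
        merged = part_a + part_b
        assert (merged.epc, merged.epoa, merged.epfa) == tuple(
            whole.iloc[0][["EPC", "EPOA", "EPFA"]]
        )


def _label_dict(epc, epoa, epfa, emotion):
    return {emotion: AgreementCounts(emotion, epc, epoa, epfa)}


class TestAggregateByPerformer:
    def _index(self):
        return index_dataset(
            [parse_video_name(n) for n in ("id0_0000", "id0_id1_0000", "id1_0000")]
        )

    def test_totals_and_percentage(self):
        index = self._index()
        # per-emotion counts for the one pair, summing to CO=10, OA=5, FA=3
        pc = {
            "Sadness": AgreementCounts("Sadness", 6, 2, 1),
            "Fear": AgreementCounts("Fear", 0, 0, 0),
            "Happiness": AgreementCounts("Happiness", 4, 3, 2),
            "Anger": AgreementCounts("Anger", 0, 0, 0),
            "Surprise": AgreementCounts("Surprise", 0, 0, 0),
            "Disgust": AgreementCounts("Disgust", 0, 0, 0),
            "Neutral": AgreementCounts("Neutral", 99, 99, 99),  # excluded
            "_any": AgreementCounts("_any", 9, 4, 3),
        }
        out = aggregate_by_performer(index, [(0, pc)])
        row = out.iloc[0]
        assert (row["CO"], row["OR_alone"], row["FA"]) == (10, 5, 3)
        assert row["%CO"] == 66.67
        assert (row["OR"], row["PF"], row["FRP"]) == (1, 1, 1)

    def test_distinct_mode_uses_any_emotion_counts(self):
        index = self._index()
        pc = {
            **{e: AgreementCounts(e, 0, 0, 0)
               for e in ("Sadness", "Fear", "Happiness", "Anger", "Surprise",
                          "Disgust", "Neutral")},
            "_any": AgreementCounts("_any", 7, 3, 2),
        }
        out = aggregate_by_performer(index, [(0, pc)], totals_mode="distinct")
        assert (out.iloc[0]["CO"], out.iloc[0]["OR_alone"]) == (7, 3)

    def test_performer_without_fakes_excluded(self):
        out = aggregate_by_performer(
            self._index(),
            [(0, _label_dict(1, 1, 1, "_any"))],
            totals_mode="distinct",
        )
        assert 1 not in out["Id"].tolist()


class TestRecordingRates:
    def _setup(self, n_fakes, n_flagged, emotion="Sadness"):
        names = ["id0_0000"] + [f"id0_id{d + 1}_0000" for d in range(n_fakes)]
        index = index_dataset([parse_video_name(n) for n in names])
        labelings = {}
        for i, name in enumerate(names[1:]):
            flagged = i < n_flagged
            labelings[name.rsplit(".", 1)[0]] = flags_frame([1 if flagged else 0], emotion)
        return index, labelings

    def test_table2_normalisation(self):
        # 16 of 114 fake recordings flagged -> 14.04 %
        index, labelings = self._setup(114, 16)
        out = recording_rates(index, labelings, labels=("Sadness",))
        assert out.iloc[0]["Sadness"] == 14.04

    def test_zero_and_full_rates(self):
        index, labelings = self._setup(8, 0)
        assert recording_rates(index, labelings, labels=("Sadness",)).iloc[0]["Sadness"] == 0.00
        index, labelings = self._setup(8, 8)
        assert recording_rates(index, labelings, labels=("Sadness",)).iloc[0]["Sadness"] == 100.00


class TestZeroBaselineExclusions:
    def _index(self):
        return index_dataset(
            [parse_video_name(n)
             for n in ("id0_0000", "id0_id1_0000", "id1_0000", "id1_id0_0000")]
        )

    def test_listed_only_when_originals_silent_and_fakes_not(self):
        per_pair = [
            (0, {"Anger": AgreementCounts("Anger", 0, 0, 5)}),
            (1, {"Anger": AgreementCounts("Anger", 2, 1, 9)}),
        ]
        out = zero_baseline_exclusions(self._index(), per_pair, labels=("Anger",))
        assert out["Anger"] == [0]

    def test_silent_everywhere_not_listed(self):
        per_pair = [(0, {"Anger": AgreementCounts("Anger", 0, 0, 0)})]
        out = zero_baseline_exclusions(self._index(), per_pair, labels=("Anger",))
        assert out["Anger"] == []


class TestPairLabelCounts:
    def test_any_entry_counts_distinct_frames(self):
        # frame 1: Sadness+Surprise in both; frame 2: Happiness in original only
        orig = make_table([{1, 2, 4, 5, 26}, {6, 12}])
        fake = make_table([{1, 2, 4, 5, 26}, set()],
                          video_id="id0_id1_0000", donor=1)
        pair = align_frames(RecordingPair(original=orig, fake=fake))
        counts = pair_label_counts(pair, label_video(orig), label_video(fake))
        assert counts["Sadness"].epc == 1 and counts["Surprise"].epc == 1
        assert counts["_any"].epc == 1  # frame 1 counted once despite two flags
        assert counts["_any"].epoa == 1
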