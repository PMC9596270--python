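"""Match original recordings to the deepfakes derived from them.

Celeb-DF fakes are frame-synchronous re-renderings of an original recording
(only the face is swapped), so a fake ``id<T>_id<D>_<seq>`` corresponds to the
original ``id<T>_<seq>`` and "the corresponding photogram" means the frame
with the same frame number.  Frames dropped by validity filtering in exactly
one channel still contribute to that channel's one-sided emotional counts;
a switch restricts counting to frames present in both channels.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .au_io import VideoAUTable, VideoIdentity
from .errors import DuplicateEntryError


@dataclass
class PerformerEntry:
    """One performer's recordings: originals, fakes grouped by source.

    Fakes whose sequence number has no original are kept in ``orphan_fakes``:
    they still count toward the performer's fake totals (they were made on a
    recording by this performer) but cannot enter pairing.
    """

    performer: int
    originals: list[VideoIdentity] = field(default_factory=list)
    fakes_by_sequence: dict[int, list[VideoIdentity]] = field(
        default_factory=lambda: defaultdict(list)
    )
    orphan_fakes: list[VideoIdentity] = field(default_factory=list)
    donors: set[int] = field(default_factory=set)

    @property
    def n_originals(self) -> int:
        return len(self.originals)

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    @property
    def n_fakes(self) -> int:
        return sum(len(v) for v in self.fakes_by_sequence.values()) + len(
            self.orphan_fakes
        )

    @property
    def all_fakes(self) -> list[VideoIdentity]:
        matched = [f for g in self.fakes_by_sequence.values() for f in g]
        return matched + list(self.orphan_fakes)


@dataclass
class DatasetIndex:
    """Per-performer dataset structure plus unmatched fakes.

    Per performer the counts mirror the study's sample columns: OR = number
    of original recordings, PF = number of distinct donor performers, FRP =
    number of fake recordings made on this performer's originals.
    """

    performers: dict[int, PerformerEntry]
    orphans: list[VideoIdentity]

    @property
    def performer_ids(self) -> list[int]:
        return sorted(self.performers)

    def entry(self, performer: int) -> PerformerEntry:
        return self.performers[performer]


def index_dataset(identities: Iterable[VideoIdentity]) -> DatasetIndex:
    """Group parsed identities by performer; fakes without a matching original
    go to an orphan list rather than being silently dropped."""
    performers: dict[int, PerformerEntry] = {}
    seen: set[str] = set()
    fakes: list[VideoIdentity] = []
    for ident in identities:
        if ident.video_id in seen:
            raise DuplicateEntryError(f"duplicate video identity {ident.video_id!r}")
        seen.add(ident.video_id)
        entry = performers.setdefault(
            ident.target_performer, PerformerEntry(ident.target_performer)
        )
        if ident.is_fake:
            fakes.append(ident)
        else:
            entry.originals.append(ident)
    orphans: list[VideoIdentity] = []
    for ident in fakes:
        entry = performers[ident.target_performer]
        known_seqs = {o.sequence_number for o in entry.originals}
        entry.donors.add(ident.donor_performer)  # type: ignore[arg-type]
        if ident.sequence_number in known_seqs:
            entry.fakes_by_sequence[ident.sequence_number].append(ident)
        else:
            entry.orphan_fakes.append(ident)
            orphans.append(ident)
    for entry in performers.values():
        entry.originals.sort(key=lambda i: i.sequence_number)
        for group in entry.fakes_by_sequence.values():
            group.sort(key=lambda i: (i.donor_performer, i.sequence_number))
    return DatasetIndex(performers=performers, orphans=orphans)


@dataclass
class RecordingPair:
    """One original bound to one fake derived from it, with frame alignment.

    ``aligned_indices`` holds (original frame_index, fake frame_index) pairs,
    strictly increasing in both coordinates; empty until ``align_frames`` runs.
    """

    original: VideoAUTable
    fake: VideoAUTable
    aligned_indices: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=np.int64)
    )

    def __post_init__(self) -> None:
        if self.original.model_variant != self.fake.model_variant:
            raise ValueError("pair must share a model variant")
        if self.fake.target_performer != self.original.target_performer:
            raise ValueError("pair must share the target performer")


def match_pairs(
    index: DatasetIndex, tables: Mapping[str, VideoAUTable]
) -> list[RecordingPair]:
    """One unaligned pair per (original, fake) sharing performer and sequence."""
    pairs: list[RecordingPair] = []
    for pid in index.performer_ids:
        entry = index.entry(pid)
        for orig in entry.originals:
            for fake in entry.fakes_by_sequence.get(orig.sequence_number, []):
                pairs.append(
                    RecordingPair(
                        original=tables[orig.video_id],
                        fake=tables[fake.video_id],
                    )
                )
    return pairs


def align_frames(pair: RecordingPair) -> RecordingPair:
    """Pair frames by equal frame number (in place; also returned).

    Frame indices present in only one channel are excluded from the "common"
    accounting but remain available for that channel's one-sided counts.
    """
    common = np.intersect1d(pair.original.frame_index, pair.fake.frame_index)
    pair.aligned_indices = np.column_stack([common, common]).astype(np.int64)
    return pair
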