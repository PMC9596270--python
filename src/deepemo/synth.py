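"""Synthetic paired original/fake AU streams with tunable transfer fidelity.

The generator emulates the structure of a face-swap deepfake corpus at the
level this pipeline consumes — per-frame binary AU activations — without any
video or face synthesis:

- Each *original* recording is a latent binary state machine over the rule
  universe's AUs: a neutral baseline where each AU fires spontaneously with
  probability ``q_spont`` per frame, interrupted by emotion episodes.  An
  episode starts with probability ``episode_rate`` per idle frame, draws its
  emotion from ``episode_emotion_weights`` (jittered per performer so some
  performers are more expressive in some emotions than others, as real
  interview corpora are), lasts Uniform(min, max) frames, and sets each AU
  required by that emotion with probability ``p_on`` per frame.
- The *static* and *dynamic* label streams of one video are two independent
  observation-noise realisations of the same latent states: each bit is
  flipped with probability ``variant_flip``.
- A *fake* copies its original's per-frame, per-AU observed state with
  probability ``rho`` (the transfer fidelity) and otherwise resamples a
  spontaneous Bernoulli(``q_spont``) bit.  Perturbing AUs rather than whole
  emotions means multi-AU emotions degrade fastest as fidelity drops, the
  same ordering observed in real face-swap corpora.

One root seed drives everything; per-video substreams are derived by hashing
(performer, role, sequence, donor, variant), so adding videos never perturbs
existing ones and datasets are bit-reproducible across platforms.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .au_io import VideoAUTable, write_au_csv
from .emfacs import EMOTIONS, EmotionRuleSet, default_ruleset
from .errors import ConfigError, DegenerateProbeError
from .metrics import AgreementCounts


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator parameters.

    Probabilities are per frame; ``episode_length`` is an inclusive uniform
    frame-count range; ``rho`` is the per-frame per-AU probability that the
    fake channel copies the original's state.
    """

    n_performers: int = 6
    originals_per_performer: int = 2
    fakes_per_original: int = 3
    frames_per_video: int = 300
    episode_rate: float = 0.03
    episode_length: tuple[int, int] = (15, 45)
    episode_emotion_weights: Mapping[str, float] = field(
        default_factory=lambda: {e: 1.0 for e in EMOTIONS}
    )
    p_on: float = 0.9
    q_spont: float = 0.02
    rho: float = 0.7
    variant_flip: float = 0.02
    performer_weight_sigma: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("episode_rate", "p_on", "q_spont", "rho", "variant_flip"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v!r} outside [0, 1]")
        w = self.episode_emotion_weights
        if any(x < 0 for x in w.values()) or not any(x > 0 for x in w.values()):
            raise ConfigError("emotion weights must be non-negative, not all zero")
        lo, hi = self.episode_length
        if not (1 <= lo <= hi):
            raise ConfigError(f"episode_length {self.episode_length!r} invalid")
        for name in (
            "n_performers", "originals_per_performer",
            "fakes_per_original", "frames_per_video",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["episode_emotion_weights"] = dict(self.episode_emotion_weights)
        d["episode_length"] = list(self.episode_length)
        return d


def _substream(seed: int, *key: object) -> np.random.Generator:
    """Deterministic per-video RNG from the root seed and a hashable key."""
    digest = hashlib.sha256(
        ("|".join([str(seed), *map(str, key)])).encode()
    ).digest()
    words = np.frombuffer(digest[:16], dtype=np.uint32)
    return np.random.default_rng(np.random.SeedSequence(list(words)))


@dataclass
class EpisodeLog:
    """Ground-truth emotion episodes of one generated original."""

    video_id: str
    episodes: list[tuple[int, int, str]]  # (start frame, end frame incl., emotion)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.episodes, columns=["start", "end", "emotion"]
        ).assign(video_id=self.video_id)


def _performer_weights(config: SyntheticConfig, performer: int) -> np.ndarray:
    emotions = list(config.episode_emotion_weights)
    base = np.array([config.episode_emotion_weights[e] for e in emotions], float)
    if config.performer_weight_sigma > 0:
        rng = _substream(config.seed, "weights", performer)
        base = base * np.exp(
            rng.normal(0.0, config.performer_weight_sigma, size=base.size)
        )
    return base / base.sum()


def generate_latent(
    config: SyntheticConfig,
    performer: int,
    seq: int,
    rules: EmotionRuleSet | None = None,
) -> tuple[np.ndarray, EpisodeLog]:
    """Latent AU activation matrix (frames x universe AUs) plus episode log."""
    if rules is None:
        rules = default_ruleset()
    config.validate()
    rng = _substream(config.seed, "latent", performer, seq)
    universe = sorted(rules.emotion_au_universe)
    col = {au: j for j, au in enumerate(universe)}
    n, k = config.frames_per_video, len(universe)
    latent = (rng.random((n, k)) < config.q_spont).astype(np.int8)
    emotions = list(config.episode_emotion_weights)
    weights = _performer_weights(config, performer)
    episodes: list[tuple[int, int, str]] = []
    t = 0
    while t < n:
        if rng.random() < config.episode_rate:
            emotion = emotions[rng.choice(len(emotions), p=weights)]
            lo, hi = config.episode_length
            length = int(rng.integers(lo, hi + 1))
            end = min(t + length, n) - 1
            required = [col[a] for a in rules.rules[emotion] if a in col]
            block = (
                rng.random((end - t + 1, len(required))) < config.p_on
            ).astype(np.int8)
            latent[t : end + 1, required] = np.maximum(
                latent[t : end + 1, required], block
            )
            episodes.append((t + 1, end + 1, emotion))  # 1-based frames
            t = end + 1
        else:
            t += 1
    video_id = f"id{performer}_{seq:04d}"
    return latent, EpisodeLog(video_id, episodes)


def _observe(
    latent: np.ndarray, config: SyntheticConfig, key: tuple
) -> np.ndarray:
    rng = _substream(config.seed, "observe", *key)
    if config.variant_flip == 0:
        return latent.copy()
    flips = rng.random(latent.shape) < config.variant_flip
    return np.where(flips, 1 - latent, latent).astype(np.int8)


def _as_table(
    bits: np.ndarray,
    universe: list[int],
    video_id: str,
    target: int,
    donor: int | None,
    variant: str,
) -> VideoAUTable:
    n = bits.shape[0]
    return VideoAUTable(
        video_id=video_id,
        target_performer=target,
        donor_performer=donor,
        model_variant=variant,
        frame_index=np.arange(1, n + 1, dtype=np.int64),
        confidence=np.ones(n),
        success=np.ones(n, dtype=bool),
        presence=pd.DataFrame(bits, columns=universe, dtype=np.int8),
    )


def generate_original(
    config: SyntheticConfig,
    performer: int,
    seq: int,
    variant: str = "dynamic",
    rules: EmotionRuleSet | None = None,
) -> tuple[VideoAUTable, EpisodeLog]:
    """One observed original stream for one model variant."""
    if rules is None:
        rules = default_ruleset()
    latent, log = generate_latent(config, performer, seq, rules)
    bits = _observe(latent, config, ("orig", performer, seq, variant))
    universe = sorted(rules.emotion_au_universe)
    return _as_table(bits, universe, log.video_id, performer, None, variant), log


def derive_fake(
    original: VideoAUTable,
    config: SyntheticConfig,
    donor: int,
    fake_seq: int | None = None,
) -> VideoAUTable:
    """A fake channel: copy each original AU bit with probability ``rho``,
    else resample Bernoulli(``q_spont``).  Frame count and indices preserved;
    works on any parsed table, not only generated ones."""
    config.validate()
    seq = fake_seq if fake_seq is not None else 0
    rng = _substream(
        config.seed, "fake", original.video_id, donor, seq, original.model_variant
    )
    bits = original.presence.to_numpy().astype(np.int8)
    copy = rng.random(bits.shape) < config.rho
    spont = (rng.random(bits.shape) < config.q_spont).astype(np.int8)
    fake_bits = np.where(copy, bits, spont).astype(np.int8)
    video_id = f"id{original.target_performer}_id{donor}_{seq:04d}"
    table = _as_table(
        fake_bits,
        [int(c) for c in original.presence.columns],
        video_id,
        original.target_performer,
        donor,
        original.model_variant,
    )
    table = replace(
        table,
        frame_index=original.frame_index.copy(),
        confidence=np.asarray(original.confidence).copy(),
        success=np.asarray(original.success).copy(),
    )
    return table


@dataclass
class SyntheticDataset:
    """Generated tables per model variant plus the ground-truth episode log."""

    tables: dict[str, dict[str, VideoAUTable]]  # variant -> video_id -> table
    episode_log: pd.DataFrame
    config: SyntheticConfig

    def write(self, outdir: str | Path) -> None:
        """Directory tree of OpenFace-dialect CSVs: <outdir>/<variant>/<id>.csv,
        plus episode_log.csv and the resolved config as YAML."""
        outdir = Path(outdir)
        for variant, tables in self.tables.items():
            vdir = outdir / variant
            vdir.mkdir(parents=True, exist_ok=True)
            for video_id in sorted(tables):
                write_au_csv(tables[video_id], vdir / f"{video_id}.csv")
        self.episode_log.to_csv(outdir / "episode_log.csv", index=False)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=True)


def generate_dataset(
    config: SyntheticConfig, rules: EmotionRuleSet | None = None
) -> SyntheticDataset:
    """Full paired corpus: per performer, ``originals_per_performer``
    originals and ``fakes_per_original`` fakes each (donors cycle over the
    other performers), in both model-variant streams."""
    if rules is None:
        rules = default_ruleset()
    config.validate()
    tables: dict[str, dict[str, VideoAUTable]] = {"static": {}, "dynamic": {}}
    logs: list[pd.DataFrame] = []
    performers = list(range(config.n_performers))
    for performer in performers:
        others = [p for p in performers if p != performer] or [performer]
        for seq in range(config.originals_per_performer):
            for vi, variant in enumerate(("static", "dynamic")):
                orig, log = generate_original(config, performer, seq, variant, rules)
                tables[variant][orig.video_id] = orig
                if vi == 0 and log.episodes:
                    logs.append(log.to_frame())
                for j in range(config.fakes_per_original):
                    donor = others[j % len(others)]
                    fake = derive_fake(orig, config, donor, fake_seq=seq)
                    # distinct donors share the original's sequence number so
                    # pairing groups them under it; a donor repeat would
                    # collide, so cap fakes at the donor pool size
                    if fake.video_id in tables[variant]:
                        continue
                    tables[variant][fake.video_id] = fake
    episode_log = (
        pd.concat(logs, ignore_index=True)
        if logs
        else pd.DataFrame(columns=["start", "end", "emotion", "video_id"])
    )
    return SyntheticDataset(tables=tables, episode_log=episode_log, config=config)


def estimate_fidelity(
    counts: AgreementCounts, q_spont: float
) -> float:
    """Moment estimator of the transfer fidelity from a single-AU probe.

    For an emotion whose rule is a single AU, the per-frame flag of the fake
    given a flagged original is Bernoulli(rho + (1 - rho) * q_spont), so

        rho_hat = (EPC / (EPC + EPOA) - q_spont) / (1 - q_spont).

    Requires the probe to have fired in the original channel; exact in the
    q_spont = 0 limit.
    """
    if not 0.0 <= q_spont < 1.0:
        raise ConfigError(f"q_spont={q_spont!r} outside [0, 1)")
    n1 = counts.original_total
    if n1 == 0:
        raise DegenerateProbeError(
            "probe emotion never fired in the original channel"
        )
    p11 = counts.epc / n1
    return (p11 - q_spont) / (1.0 - q_spont)
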