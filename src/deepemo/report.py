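"""End-to-end analysis driver and table emission.

``run_analysis`` takes a directory of OpenFace-dialect AU CSVs (one per
video, Celeb-DF-style names, optionally split into ``static/`` and
``dynamic/`` subdirectories for the two AU-prediction streams) and produces:

- ``table2.csv`` — per performer and emotion, the percentage of fake
  recordings containing at least one flagged photogram;
- ``table3.csv`` — global EPC/EPOA/EPFA counts and %C/%O/%F per emotion;
- ``table4.csv`` — per-performer sample counts (OR, PF, FRP) and all-emotion
  agreement totals (CO, OR_alone, FA) with percentages;
- ``figure_data_<emotion>.csv`` — per-performer percentage triples, the
  quantities behind the per-performer scatter displays;
- ``exclusions.csv`` — performers excluded from percentage displays because
  their originals showed none of an emotion while their fakes did;
- ``analysis_config.yaml`` — the resolved run configuration, echoed verbatim.

All percentage cells are written with exactly two decimals (half-up);
re-running on the same inputs is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import au_io, metrics, pairing
from .emfacs import ALL_LABELS, EMOTIONS, EmotionRuleSet, default_ruleset, label_video
from .errors import ConfigError, ZeroEmotionalBaselineError

log = logging.getLogger("deepemo")

_KNOWN_KEYS = {
    "input_dir", "output_dir", "model_variant", "rules_path", "min_confidence",
    "donor_first", "both_channels_only", "totals_mode", "presence_threshold",
}


@dataclass
class RunConfig:
    """Resolved analysis configuration (echoed verbatim to the output dir)."""

    input_dir: str
    output_dir: str
    model_variant: str = "both"  # "both" | "static" | "dynamic"
    rules_path: str | None = None
    min_confidence: float = 0.0
    donor_first: bool = False
    both_channels_only: bool = False
    totals_mode: str = "multiple"
    presence_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.model_variant not in ("both", "static", "dynamic"):
            raise ConfigError(f"model_variant {self.model_variant!r} unknown")
        if self.totals_mode not in ("multiple", "distinct"):
            raise ConfigError(f"totals_mode {self.totals_mode!r} unknown")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ConfigError("min_confidence must lie in [0, 1]")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)


@dataclass
class VariantAnalysis:
    """Everything computed for one model-variant stream."""

    variant: str
    index: pairing.DatasetIndex
    pairs: list[pairing.RecordingPair]
    per_pair_counts: list[tuple[int, Mapping[str, metrics.AgreementCounts]]]
    by_emotion: pd.DataFrame
    by_performer: pd.DataFrame
    rates: pd.DataFrame
    exclusions: dict[str, list[int]]


@dataclass
class AnalysisResult:
    variants: dict[str, VariantAnalysis]
    config: RunConfig


def _discover_variants(input_dir: Path, selection: str) -> dict[str, Path]:
    subdirs = {
        v: input_dir / v
        for v in ("static", "dynamic")
        if (input_dir / v).is_dir()
    }
    if subdirs:
        if selection != "both":
            subdirs = {k: v for k, v in subdirs.items() if k == selection}
        return subdirs
    # flat directory: a single stream under the selected (or default) variant
    variant = "dynamic" if selection == "both" else selection
    return {variant: input_dir}


def analyze_variant(
    variant: str,
    csv_dir: Path,
    config: RunConfig,
    rules: EmotionRuleSet,
) -> VariantAnalysis:
    files = sorted(csv_dir.glob("*.csv"))
    files = [f for f in files if f.name != "episode_log.csv"]
    if not files:
        raise ConfigError(f"no AU CSV files found under {csv_dir}")
    tables: dict[str, au_io.VideoAUTable] = {}
    identities = []
    for f in files:
        ident = au_io.parse_video_name(f.name, donor_first=config.donor_first)
        table = au_io.read_au_csv(
            f, variant, identity=ident,
            presence_threshold=config.presence_threshold,
        )
        tables[ident.video_id] = au_io.filter_valid_frames(
            table, config.min_confidence
        )
        identities.append(ident)
    index = pairing.index_dataset(identities)
    if index.orphans:
        log.warning(
            "%s: %d fake(s) without a matching original (kept aside)",
            variant, len(index.orphans),
        )
    pairs = [pairing.align_frames(p) for p in pairing.match_pairs(index, tables)]
    labelings = {vid: label_video(t, rules) for vid, t in tables.items()}
    per_pair_counts = [
        (
            p.original.target_performer,
            metrics.pair_label_counts(
                p,
                labelings[p.original.video_id],
                labelings[p.fake.video_id],
                both_channels_only=config.both_channels_only,
            ),
        )
        for p in pairs
    ]
    fake_labelings = {
        vid: lab for vid, lab in labelings.items() if tables[vid].is_fake
    }
    return VariantAnalysis(
        variant=variant,
        index=index,
        pairs=pairs,
        per_pair_counts=per_pair_counts,
        by_emotion=metrics.aggregate_by_emotion(
            [pc for _, pc in per_pair_counts]
        ),
        by_performer=metrics.aggregate_by_performer(
            index, per_pair_counts, totals_mode=config.totals_mode
        ),
        rates=metrics.recording_rates(index, fake_labelings),
        exclusions=metrics.zero_baseline_exclusions(index, per_pair_counts),
    )


def run_analysis(config: RunConfig) -> AnalysisResult:
    input_dir = Path(config.input_dir)
    if not input_dir.is_dir():
        raise ConfigError(f"input directory {input_dir} does not exist")
    rules = (
        EmotionRuleSet.from_config(config.rules_path)
        if config.rules_path
        else default_ruleset()
    )
    variants = {}
    for variant, csv_dir in _discover_variants(input_dir, config.model_variant).items():
        log.info("analyzing %s stream from %s", variant, csv_dir)
        variants[variant] = analyze_variant(variant, csv_dir, config, rules)
    return AnalysisResult(variants=variants, config=config)


def _fmt_pct(x) -> str:
    return "" if pd.isna(x) else f"{metrics.round_half_up(float(x)):.2f}"


def _format_percent_columns(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        name = str(col)
        bare = name.split("_", 1)[-1]
        if "%" in name or name in ALL_LABELS or bare in ALL_LABELS:
            out[col] = out[col].map(_fmt_pct)
    return out


def _merge_variants(frames: dict[str, pd.DataFrame], on: str) -> pd.DataFrame:
    """Outer-join per-variant tables on a key column, prefixing the rest."""
    merged: pd.DataFrame | None = None
    for variant in ("dynamic", "static"):
        if variant not in frames:
            continue
        df = frames[variant].rename(
            columns={c: f"{variant}_{c}" for c in frames[variant].columns if c != on}
        )
        merged = df if merged is None else merged.merge(df, on=on, how="outer")
    assert merged is not None
    return merged


def write_tables(result: AnalysisResult, outdir: str | Path) -> dict[str, Path]:
    """Emit all output CSVs; returns the mapping name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        _format_percent_columns(df).to_csv(path, index=False)
        written[name] = path

    emit("table2.csv", _merge_variants(
        {v: a.rates for v, a in result.variants.items()}, on="Id"
    ))

    t3 = []
    for variant, analysis in result.variants.items():
        t3.append(analysis.by_emotion.assign(Model=variant))
    emit("table3.csv", pd.concat(t3, ignore_index=True)[
        ["Model", "Emotion", "EPC", "EPOA", "EPFA", "%C", "%O", "%F"]
    ])

    sample_cols = ["Id", "OR", "PF", "FRP"]
    t4_variants = {}
    for variant, analysis in result.variants.items():
        t4_variants[variant] = analysis.by_performer
    if any(len(df) for df in t4_variants.values()):
        sample = next(iter(t4_variants.values()))[sample_cols]
        merged = sample.copy()
        for variant in ("dynamic", "static"):
            if variant not in t4_variants:
                continue
            rest = t4_variants[variant].drop(columns=["OR", "PF", "FRP"])
            rest = rest.rename(
                columns={c: f"{variant}_{c}" for c in rest.columns if c != "Id"}
            )
            merged = merged.merge(rest, on="Id", how="outer")
        emit("table4.csv", merged)
    else:
        emit("table4.csv", pd.DataFrame(columns=sample_cols))

    for emotion in ALL_LABELS:
        rows = []
        for variant, analysis in result.variants.items():
            for pid in analysis.index.performer_ids:
                mine = [
                    pc for p, pc in analysis.per_pair_counts if p == pid
                ]
                if not mine:
                    continue
                total = metrics.sum_counts((pc[emotion] for pc in mine), emotion)
                try:
                    pct = metrics.percent_triple(total)
                except ZeroEmotionalBaselineError:
                    continue  # routed to exclusions.csv
                rows.append({
                    "Model": variant,
                    "Id": pid,
                    "%O": pct.pct_original_alone,
                    "%F": pct.pct_fake_alone,
                    "%C": pct.pct_common,
                })
        emit(
            f"figure_data_{emotion.lower()}.csv",
            pd.DataFrame(rows, columns=["Model", "Id", "%O", "%F", "%C"]),
        )

    excl_rows = [
        {
            "Model": variant,
            "Emotion": emotion,
            "n_performers": len(pids),
            "performers": " ".join(map(str, pids)),
        }
        for variant, analysis in result.variants.items()
        for emotion, pids in analysis.exclusions.items()
    ]
    emit("exclusions.csv", pd.DataFrame(
        excl_rows, columns=["Model", "Emotion", "n_performers", "performers"]
    ))

    with open(outdir / "analysis_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(result.config), fh, sort_keys=True)
    written["analysis_config.yaml"] = outdir / "analysis_config.yaml"
    return written


def summarize(outdir: str | Path) -> str:
    """Human-readable digest of an analysis output directory."""
    outdir = Path(outdir)
    lines = []
    t3 = pd.read_csv(outdir / "table3.csv")
    lines.append("Emotion agreement between originals and fakes (per model):")
    for _, row in t3.iterrows():
        pc = row["%C"]
        pc_txt = "undefined (no emotional originals)" if pd.isna(pc) else f"{pc:.2f}% in common"
        lines.append(
            f"  {row['Model']:>8} {row['Emotion']:<10} "
            f"EPC={row['EPC']:>8} EPOA={row['EPOA']:>8} EPFA={row['EPFA']:>8}  {pc_txt}"
        )
    excl = pd.read_csv(outdir / "exclusions.csv")
    flagged = excl[excl["n_performers"] > 0]
    if len(flagged):
        lines.append("Zero-baseline exclusions (fakes emotional, originals not):")
        for _, row in flagged.iterrows():
            lines.append(
                f"  {row['Model']:>8} {row['Emotion']:<10} {row['n_performers']} performer(s)"
            )
    else:
        lines.append("No zero-baseline exclusions.")
    return "\n".join(lines)
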