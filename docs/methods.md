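# Methods

## Problem and pipeline

Face-swap deepfakes re-render an original video frame-for-frame with another
person's face.  Whether the swap preserves the *emotional expression* of the
original can be asked entirely at the level of facial action units (AUs):
run an AU estimator (e.g. OpenFace) over both videos, label every photogram
with the basic emotions its AU combination implies, and compare the labels
frame by frame.  `deepemo` implements the labeling, pairing and comparison
stages; AU estimation itself is out of scope — the package consumes its CSV
output.

Stages:

1. **I/O** (`au_io`): parse OpenFace-dialect CSVs (columns `frame`,
   `confidence`, `success`, `AU##_c` presence, `AU##_r` intensity;
   whitespace-padded headers accepted).  Presence is read from the binary
   columns; when a file carries only intensities, presence is derived as
   intensity > threshold (default 0).  Frames with `success = 0` are dropped
   before any counting, as only photograms with an analysed face are
   meaningful; the confidence threshold defaults to 0 (no further pruning)
   because AU estimators already gate their `success` flag on tracking
   quality.
2. **Rule engine** (`emfacs`): emotion *E* is flagged iff its full AU set is
   present (conjunction).  The published AU/emotion table lists "involved"
   AUs without an explicit combination logic; conjunction is the reading
   under which the observed rarity of Fear — the emotion with the most AUs —
   follows naturally, and it is the strictest, most reproducible choice.
   Rule sets and the combination policy are overridable from YAML for
   partial-prototype variants.  Neutral means "no emotion-related AU
   present"; frames with some but not all AUs of every rule carry no label
   at all.  Multi-label semantics throughout: downstream counts treat each
   emotion independently.
3. **Pairing** (`pairing`): fakes are matched to originals sharing target
   performer and sequence number; "corresponding photogram" is the same
   frame number, because face-swap synthesis preserves temporal structure.
   Fakes without a surviving original are kept on an orphan list — they
   still count in the performer's fake-recording total (FRP) and in the
   per-recording emotion rates, but cannot enter frame agreement.
4. **Agreement metrics** (`metrics`): per emotion and pair, EPC (flagged in
   both channels), EPOA (original only), EPFA (fake only).  Frames that
   survived validity filtering in only one channel contribute to that
   channel's one-sided count by default (`both_channels_only` restricts the
   scope to frames detected in both).  Percentages normalise to the
   original channel: %C = 100·EPC/(EPC+EPOA), %O its complement, %F =
   100·EPFA/(EPC+EPOA) — unbounded above, since a performer can have far
   more fake than original footage.  Counts aggregate as exact integers and
   are summed *before* percentages are taken.

## Numerical conventions

- Display rounding is half-up to two decimals, applied only at emission;
  `round_half_up` goes through `decimal` on the value's shortest decimal
  representation, so 2.675 → 2.68 rather than the binary-float 2.67.
- A zero denominator (EPC + EPOA = 0 with EPFA > 0) raises an explicit
  signal and routes the performer to the exclusion table; it is never
  imputed as 0 or NaN.  Performers whose originals and fakes are both
  silent for a label simply have no percentage row.
- All-emotion totals (the per-performer CO/OR/FA columns) sum the six basic
  emotions with multiplicity — a frame flagged twice counts twice — and
  exclude Neutral; `totals_mode="distinct"` switches to counting any-emotion
  frames once.  Multiplicity is the default because published per-performer
  totals exceed any single emotion's count.
- Re-running `analyze` on identical inputs is byte-identical: percentage
  cells are formatted to exactly two decimals at write time.

## Synthetic paired corpus

The generator stands in for a real face-swap corpus at the only level the
pipeline sees — binary AU streams:

- **Originals**: a latent state machine over the 13-AU rule universe.  Idle
  frames activate each AU with spontaneous probability `q_spont` (default
  0.02/frame).  With probability `episode_rate` (0.03/frame) an emotion
  episode starts: its emotion is drawn from per-performer weights (global
  weights jittered log-normally, σ = 0.5, so performers differ in
  expressiveness as real interviewees do), it lasts Uniform(15, 45) frames,
  and each required AU switches on with `p_on` = 0.9 per frame — so even
  original episodes only intermittently complete a multi-AU rule, as real
  expressions do.
- **Two model streams**: the "static" and "dynamic" AU-prediction streams
  of one video are two independent observation layers over the same latent
  states, each bit flipped with probability `variant_flip` (0.02).  The
  package does not model the systematic calibration differences between
  real AU predictors, only their disagreement rate.
- **Fakes**: per frame and per AU, the fake copies the original's observed
  state with probability ρ (default 0.7) and otherwise resamples a
  spontaneous Bernoulli(`q_spont`) bit.  Perturbing AUs rather than whole
  emotion labels makes multi-AU rules break progressively — the mechanism
  behind Fear transferring worst.
- **Defaults**: 6 performers × 2 originals × 3 fakes, 300 frames/video
  (10 s at 30 fps) — large enough that every emotion appears, small enough
  that the full suite runs in seconds.
- **Randomness**: one root seed; every video draws its own PCG64 substream
  seeded from SHA-256 of (seed, role, performer, sequence, donor, variant),
  so datasets are bit-reproducible across platforms and extending a corpus
  never perturbs existing videos.  Because the fake's uniform draws depend
  only on that key and not on ρ, fakes generated at increasing ρ from one
  seed are coupled: raising ρ can only move fake bits toward the original,
  which is what makes the %C-monotone-in-ρ check a property rather than a
  statistical accident.

What passing tests on this corpus show: the counting, normalisation,
pairing and exclusion conventions are implemented exactly, and the pipeline
responds to transfer fidelity as derived.  What they do not show: anything
about real AU-estimator error structure (temporal correlation of failures,
intensity miscalibration, identity-dependent bias), which the generator
deliberately omits.

## Fidelity estimation

With a probe rule consisting of a single AU, the per-frame fake flag given a
flagged original is Bernoulli(ρ + (1 − ρ)·q), q = `q_spont`:
the fake either copies the original's 1 (probability ρ) or resamples a
spontaneous 1 (probability (1 − ρ)·q).  Hence the moment estimator

    ρ̂ = (EPC/(EPC+EPOA) − q) / (1 − q),

exact in the q = 0 limit, monotone in EPC at fixed marginals, and undefined
when the probe never fired in the original channel (an explicit error).  Its
standard error is the binomial SE of EPC/(EPC+EPOA) scaled by 1/(1 − q);
recovery tests require agreement within four SEs at 10⁵ frames.  The
estimator is only valid for single-AU probes — multi-AU rules make the flag
a product of correlated bits and ρ̂ would be biased downward.

## Known limitations

- Conjunction-only rule logic; graded/partial prototype scoring and
  intensity weighting are out of scope.
- Frame-number alignment assumes frame-synchronous fakes; no content-based
  or time-warped alignment.
- The AU16 problem: the Disgust rule requires an AU that common AU
  estimators do not emit.  Default behaviour treats unreported AUs as never
  present (Disgust then cannot fire on such files); the `drop` policy
  evaluates the rule over the reported subset instead.  Neither choice can
  be validated against the original study, which does not state its
  handling.
- Statistical testing between models or emotions is deliberately absent;
  the pipeline reports descriptive agreement statistics only.
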