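"""Adaptive psychoacoustic procedures: Békésy tracking, gap detection,
sentence-in-noise (HINT) and triple-digit (TDT) tests.

Each procedure drives a :class:`~audcog.listeners.PsychometricListener`
through its staircase rules and returns a :class:`Track`: the ordered trial
records (stimulus level, response, reversal flags) plus the threshold
estimate defined by that procedure's estimator rule.

All stimulus levels are quantized to a 0.1-unit grid (0.1 dB, 0.1 ms for
gaps) so that a run is bit-stable and can be compared exactly against an
independent trace.  Every stochastic procedure takes an explicit
``numpy.random.Generator``; identical (seed, config, listener) triples give
identical tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .listeners import PsychometricListener, respond, respond_triplet

__all__ = [
    "TrialRecord",
    "Track",
    "BekesyConfig",
    "GapConfig",
    "HintConfig",
    "TdtConfig",
    "run_bekesy",
    "run_gap_staircase",
    "run_hint_condition",
    "hint_composite",
    "run_tdt",
    "tracks_to_frame",
]

HINT_CONDITIONS = ("noise_front", "noise_right", "noise_left", "quiet")


def quantize(x: float, grid: float = 0.1) -> float:
    """Snap a level to the 0.1-unit grid (bit-stable oracle comparisons)."""
    return round(x / grid) * grid


@dataclass(frozen=True)
class TrialRecord:
    index: int
    level: float
    response: int  # bool-like for yes/no tests; digits correct (0..3) for TDT
    is_reversal: bool = False
    phase: str = "none"  # positive/negative masker phase (TDT only)
    condition: str = "none"
    in_estimate: bool = True  # False for TDT practice presentations


@dataclass
class Track:
    """One adaptive run: ordered trials plus the procedure's estimate."""

    test: str
    trials: list[TrialRecord]
    estimate: float
    estimator_rule: str
    converged: bool = True
    condition: str = "none"

    @property
    def levels(self) -> list[float]:
        return [t.level for t in self.trials]

    @property
    def reversal_levels(self) -> list[float]:
        return [t.level for t in self.trials if t.is_reversal]

    def to_frame(self, subject_id: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "test": self.test,
                "condition": [t.condition for t in self.trials],
                "trial_index": [t.index for t in self.trials],
                "level": [t.level for t in self.trials],
                "response": [t.response for t in self.trials],
                "is_reversal": [t.is_reversal for t in self.trials],
                "phase": [t.phase for t in self.trials],
                "estimate": self.estimate,
            }
        )
        if subject_id is not None:
            df.insert(0, "subject_id", subject_id)
        return df


def tracks_to_frame(items: Iterable[tuple[str, Track]]) -> pd.DataFrame:
    """Long trial table for many (subject_id, track) pairs."""
    return pd.concat(
        [tr.to_frame(sid) for sid, tr in items], ignore_index=True
    )


# ---------------------------------------------------------------------------
# Békésy-like audiometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BekesyConfig:
    """Pulsed-tone tracking audiometry.

    Tones of 250 ms (20 ms rise/fall, 500 ms inter-stimulus interval) descend
    in ``big_step`` (4 dB) steps while the subject holds the button, switching
    to ``small_step`` (2 dB) after the first reversal; unheard tones ascend in
    ``small_step`` steps.  The threshold is the mean level of
    ``reversals_required`` good reversals (all reversals after the first).
    """

    start_level: float = 40.0
    big_step: float = 4.0
    small_step: float = 2.0
    reversals_required: int = 6
    tone_duration_ms: float = 250.0
    rise_fall_ms: float = 20.0
    isi_ms: float = 500.0
    min_level: float = -10.0
    max_level: float = 110.0
    max_trials: int = 400

    def __post_init__(self) -> None:
        if not (self.big_step > self.small_step > 0):
            raise ValueError("require big_step > small_step > 0")
        if self.reversals_required < 2:
            raise ValueError("reversals_required must be >= 2")


def run_bekesy(
    listener: PsychometricListener,
    config: BekesyConfig = BekesyConfig(),
    rng: np.random.Generator | None = None,
) -> Track:
    """Simulate one Békésy-like audiometric track at a single frequency.

    The listener's "response" is whether the tone was heard (button held).
    Good reversals are every reversal after the first: the first direction
    change still reflects the large-step descent and is excluded from the
    estimate, which is the mean of the good-reversal levels.
    """
    rng = np.random.default_rng() if rng is None else rng
    cfg = config
    level = quantize(cfg.start_level)
    trials: list[TrialRecord] = []
    directions: list[int] = []  # -1 descend after heard, +1 ascend after miss
    reversal_idx: list[int] = []
    good_levels: list[float] = []
    had_first_reversal = False
    pinned = 0

    for i in range(cfg.max_trials):
        heard = respond(listener, level, rng)
        direction = -1 if heard else +1
        is_rev = bool(directions) and direction != directions[-1]
        trials.append(TrialRecord(i, level, int(heard), is_rev))
        directions.append(direction)
        if is_rev:
            if had_first_reversal:
                good_levels.append(level)
            had_first_reversal = True
            reversal_idx.append(i)
        if len(good_levels) >= cfg.reversals_required:
            est = quantize(float(np.mean(good_levels)))
            return Track("bekesy", trials, est, "mean_good_reversals")
        down = cfg.big_step if not had_first_reversal else cfg.small_step
        nxt = level - down if heard else level + cfg.small_step
        nxt = quantize(min(max(nxt, cfg.min_level), cfg.max_level))
        pinned = pinned + 1 if nxt == level and level in (cfg.min_level, cfg.max_level) else 0
        if pinned >= 10:
            break
        level = nxt

    return Track("bekesy", trials, math.nan, "mean_good_reversals", converged=False)


# ---------------------------------------------------------------------------
# Adaptive gap detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GapConfig:
    """Single-staircase gap-detection procedure.

    The gap shortens after two consecutive correct identifications and
    lengthens (a reversal of the track) after two consecutive misses or a
    third cumulative miss; the step halves at every reversal down to
    ``min_step``.  Each lengthening consumes the accumulated misses so the
    cumulative rule re-arms; ``miss_counter_scope`` selects whether that
    counter additionally resets at each reversal (default) or only when it
    triggers, counting over the whole track.
    """

    start_gap: float = 20.0
    initial_step: float = 4.0
    min_step: float = 1.0
    max_gap: float = 100.0
    min_gap: float = 1.0
    stop_reversals: int = 6
    estimator_reversals: int = 4
    miss_counter_scope: str = "since_reversal"  # or "whole_run"
    max_trials: int = 300

    def __post_init__(self) -> None:
        if self.min_gap <= 0:
            raise ValueError("min_gap must be positive")
        if self.start_gap > self.max_gap:
            raise ValueError("start_gap must be <= max_gap")
        if self.estimator_reversals > self.stop_reversals:
            raise ValueError("estimator_reversals must be <= stop_reversals")
        if self.miss_counter_scope not in ("since_reversal", "whole_run"):
            raise ValueError("miss_counter_scope: since_reversal|whole_run")


def run_gap_staircase(
    listener: PsychometricListener,
    config: GapConfig = GapConfig(),
    rng: np.random.Generator | None = None,
) -> Track:
    """Simulate the adaptive gap-detection staircase.

    The listener is queried on the log2(gap ms) axis (Weber-like temporal
    thresholds; see :func:`audcog.listeners.make_gap_listener`), while the
    track itself is recorded in ms.  The estimate is the mean gap length at
    the last ``estimator_reversals`` reversals.
    """
    rng = np.random.default_rng() if rng is None else rng
    cfg = config
    gap = quantize(cfg.start_gap)
    step = cfg.initial_step
    trials: list[TrialRecord] = []
    consec_correct = consec_miss = cum_miss = 0
    last_move = 0  # -1 down (harder), +1 up (easier)
    reversal_levels: list[float] = []
    pinned = 0

    for i in range(cfg.max_trials):
        correct = respond(listener, math.log2(gap), rng)
        rec = TrialRecord(i, gap, int(correct))
        if correct:
            consec_correct += 1
            consec_miss = 0
        else:
            consec_miss += 1
            consec_correct = 0
            cum_miss += 1

        move = 0
        if consec_correct >= 2:
            move = -1
        elif consec_miss >= 2 or cum_miss >= 3:
            move = +1

        if move != 0:
            consec_correct = consec_miss = 0
            if move > 0:
                cum_miss = 0  # the lengthening consumes the miss budget
            is_rev = last_move != 0 and move != last_move
            if is_rev:
                rec = TrialRecord(i, gap, int(correct), is_reversal=True)
                reversal_levels.append(gap)
                step = max(step / 2.0, cfg.min_step)
                if cfg.miss_counter_scope == "since_reversal":
                    cum_miss = 0
            last_move = move
            trials.append(rec)
            if len(reversal_levels) >= cfg.stop_reversals:
                est = float(np.mean(reversal_levels[-cfg.estimator_reversals :]))
                return Track("gap", trials, est, "mean_last_reversals")
            nxt = quantize(
                min(max(gap + move * step, cfg.min_gap), cfg.max_gap)
            )
            pinned = pinned + 1 if nxt == gap and gap in (cfg.min_gap, cfg.max_gap) else 0
            if pinned >= 10:
                break
            gap = nxt
        else:
            trials.append(rec)

    return Track("gap", trials, math.nan, "mean_last_reversals", converged=False)


# ---------------------------------------------------------------------------
# Hearing-in-noise sentence test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HintConfig:
    """Adaptive sentence-in-noise test, one 20-sentence list per condition.

    The masking noise is fixed at 65 dB(A); the sentence level moves down
    after a correctly repeated sentence and up after an incorrect one, by
    ``step_first_four`` (4 dB) for the first four sentences and ``step_rest``
    (2 dB) thereafter.  The speech reception threshold (SRT) is the mean
    presentation level of all sentences after the first four, expressed as
    SNR re the noise.
    """

    n_sentences: int = 20
    noise_level_dba: float = 65.0
    step_first_four: float = 4.0
    step_rest: float = 2.0
    start_snr: float = 0.0

    def __post_init__(self) -> None:
        if self.n_sentences < 5:
            raise ValueError("n_sentences must be >= 5")


def run_hint_condition(
    listener: PsychometricListener,
    config: HintConfig = HintConfig(),
    condition: str = "noise_front",
    rng: np.random.Generator | None = None,
) -> Track:
    """Simulate one HINT condition and return its SRT track (levels in dB SNR)."""
    if condition not in HINT_CONDITIONS:
        raise ValueError(f"condition must be one of {HINT_CONDITIONS}")
    rng = np.random.default_rng() if rng is None else rng
    cfg = config
    snr = quantize(cfg.start_snr)
    trials: list[TrialRecord] = []
    responses: list[bool] = []
    for i in range(cfg.n_sentences):
        correct = respond(listener, snr, rng)
        is_rev = bool(responses) and correct != responses[-1]
        trials.append(
            TrialRecord(i, snr, int(correct), is_rev, condition=condition,
                        in_estimate=i >= 4)
        )
        responses.append(correct)
        step = cfg.step_first_four if i < 4 else cfg.step_rest
        snr = quantize(snr - step if correct else snr + step)
    srt = float(np.mean([t.level for t in trials[4:]]))
    return Track("hint", trials, srt, "mean_levels_after_first_four",
                 condition=condition)


def hint_composite(
    srt_front: float, srt_right: float, srt_left: float
) -> float:
    """Composite SNR: unweighted mean of the three noise-condition SRTs.

    Any missing condition propagates as a missing composite (NaN); the quiet
    condition never enters the composite.
    """
    vals = [srt_front, srt_right, srt_left]
    if any(v is None or not math.isfinite(v) for v in vals):
        return math.nan
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Triple-digit test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TdtConfig:
    """Digit-triplet recognition in paired positive/negative-phase maskers.

    Presentations come in pairs at identical SNR, masker phase order
    randomized within each pair, with the masker fixed at 75 dB SPL.  After
    each pair the target level moves by ``step_per_digit`` (1.5 dB) per digit
    — down for each correct digit, up for each incorrect digit — scored on
    the pair's positive-phase presentation only.  Six practice presentations
    (3 pairs) precede 30 test presentations (15 pairs); the SRT is the mean
    SNR of the last ``srt_last_k_positive`` (14) positive-phase test
    presentations.
    """

    n_practice_presentations: int = 6
    n_test_presentations: int = 30
    start_snr: float = 0.0
    masker_level_db_spl: float = 75.0
    step_per_digit: float = 1.5
    srt_last_k_positive: int = 14

    def __post_init__(self) -> None:
        if self.n_practice_presentations % 2 or self.n_test_presentations % 2:
            raise ValueError("presentations are delivered in pairs")
        if self.srt_last_k_positive > self.n_test_presentations // 2:
            raise ValueError(
                "srt_last_k_positive exceeds the number of positive-phase "
                "test presentations"
            )


def run_tdt(
    listener: PsychometricListener,
    config: TdtConfig = TdtConfig(),
    rng: np.random.Generator | None = None,
) -> Track:
    """Simulate one TDT run; response per presentation is digits correct (0-3).

    Negative-phase responses are recorded but drive neither the level update
    nor the SRT.
    """
    rng = np.random.default_rng() if rng is None else rng
    cfg = config
    snr = quantize(cfg.start_snr)
    trials: list[TrialRecord] = []
    n_practice_pairs = cfg.n_practice_presentations // 2
    n_test_pairs = cfg.n_test_presentations // 2
    positive_test_snrs: list[float] = []
    idx = 0
    for pair in range(n_practice_pairs + n_test_pairs):
        is_test = pair >= n_practice_pairs
        positive_first = bool(rng.random() < 0.5)
        phases = ("positive", "negative") if positive_first else ("negative", "positive")
        n_correct_positive = 0
        for phase in phases:
            k = respond_triplet(listener, snr, rng)
            if phase == "positive":
                n_correct_positive = k
                if is_test:
                    positive_test_snrs.append(snr)
            trials.append(
                TrialRecord(idx, snr, k, phase=phase, in_estimate=is_test)
            )
            idx += 1
        delta = cfg.step_per_digit * ((3 - n_correct_positive) - n_correct_positive)
        snr = quantize(snr + delta)
    srt = float(np.mean(positive_test_snrs[-cfg.srt_last_k_positive :]))
    return Track("tdt", trials, srt, "mean_last_positive_phase_snrs")
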