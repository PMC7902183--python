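"""Virtual listeners with logistic psychometric functions.

Every adaptive-test simulation in this package is driven by a
:class:`PsychometricListener`: a latent description of one subject's ability on
one test, parameterised by a threshold (the stimulus level of 50 %-corrected
performance), a slope, and guess/lapse asymptotes.  Listeners answer individual
trials; the staircase procedures in :mod:`audcog.adaptive_tests` only ever see
those answers, exactly as a real test instrument only sees button presses.

Level conventions follow the "higher is better" direction: dB SNR for speech
tests, dB HL for tone audibility (a louder tone is more audible), and
``log2(gap in ms)`` for gap detection, where a longer gap is easier to hear.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "PsychometricListener",
    "p_correct",
    "respond",
    "respond_triplet",
    "make_gap_listener",
    "load_listeners",
    "dump_listeners",
]


@dataclass(frozen=True)
class PsychometricListener:
    """Latent auditory ability of one subject on one test.

    Parameters
    ----------
    threshold : float
        Level of 50 %-corrected performance, in the test's stimulus units
        (dB SNR, dB HL, or log2 gap-ms).
    slope : float
        Steepness of the logistic psychometric function, in 1/units.
    guess_rate : float
        Lower asymptote (chance performance), in [0, 1).
    lapse_rate : float
        1 minus the upper asymptote, in [0, 0.5).
    mode : str
        ``"stochastic"`` for Bernoulli responses, ``"deterministic_step"``
        for an ideal step-function observer (correct iff the stimulus is
        at-or-better-than threshold) used as an exact oracle.
    """

    threshold: float
    slope: float = 1.0
    guess_rate: float = 0.0
    lapse_rate: float = 0.0
    mode: str = "stochastic"
    test: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.guess_rate < 1.0 - self.lapse_rate <= 1.0):
            raise ValueError(
                f"require 0 <= guess_rate < 1 - lapse_rate <= 1, got "
                f"guess={self.guess_rate}, lapse={self.lapse_rate}"
            )
        if self.lapse_rate >= 0.5:
            raise ValueError("lapse_rate must be < 0.5")
        if self.mode not in ("stochastic", "deterministic_step"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "stochastic" and self.slope <= 0:
            raise ValueError("slope must be positive for a stochastic listener")


def p_correct(listener: PsychometricListener, level: float) -> float:
    """Probability of a correct response at ``level``.

    ``guess + (1 - guess - lapse) * F(slope * (level - threshold))`` with F the
    cumulative logistic; monotone nondecreasing in level.  In
    ``deterministic_step`` mode returns exactly 0.0 or 1.0.
    """
    if not math.isfinite(level):
        raise ValueError(f"stimulus level must be finite, got {level}")
    if listener.mode == "deterministic_step":
        return 1.0 if level >= listener.threshold else 0.0
    x = listener.slope * (level - listener.threshold)
    f = 0.5 * (1.0 + math.tanh(x / 2.0))  # stable logistic
    return listener.guess_rate + (1.0 - listener.guess_rate - listener.lapse_rate) * f


def respond(
    listener: PsychometricListener, level: float, rng: np.random.Generator
) -> bool:
    """One Bernoulli trial at ``level``; deterministic_step mode ignores rng."""
    p = p_correct(listener, level)
    if listener.mode == "deterministic_step":
        return p >= 0.5
    return bool(rng.random() < p)


def respond_triplet(
    listener: PsychometricListener, snr: float, rng: np.random.Generator
) -> int:
    """Number of digits (0..3) identified in a spoken digit triplet.

    Each of the three digits is an independent Bernoulli trial at the same
    SNR, which models a closed-set triple-digit presentation.
    """
    return sum(respond(listener, snr, rng) for _ in range(3))


def make_gap_listener(
    threshold_ms: float,
    slope_per_octave: float = 4.0,
    guess_rate: float = 0.0,
    lapse_rate: float = 0.0,
    mode: str = "stochastic",
) -> PsychometricListener:
    """Listener for the gap-detection task on the log2(gap ms) axis.

    Temporal thresholds behave Weber-like, so the psychometric function lives
    on log2(gap): a doubling of the gap is one unit of the level axis.  The
    staircase passes ``log2(gap_ms)`` as the level, so a deterministic-step
    listener built here is correct exactly when ``gap >= threshold_ms``.
    """
    if threshold_ms <= 0:
        raise ValueError("gap threshold must be positive ms")
    return PsychometricListener(
        threshold=math.log2(threshold_ms),
        slope=slope_per_octave,
        guess_rate=guess_rate,
        lapse_rate=lapse_rate,
        mode=mode,
        test="gap",
    )


# -- listener parameter files -------------------------------------------------

_FIELDS = ("test", "threshold", "slope", "guess_rate", "lapse_rate", "mode")


def load_listeners(path: str | Path) -> dict[str, dict[str, PsychometricListener]]:
    """Read a JSON listener-parameter file.

    The file holds one record per subject per test with keys
    ``{subject_id, test, threshold, slope, guess_rate, lapse_rate, mode}``;
    returns ``{subject_id: {test: listener}}``.
    """
    records = json.loads(Path(path).read_text())
    out: dict[str, dict[str, PsychometricListener]] = {}
    for rec in records:
        sid = str(rec["subject_id"])
        kwargs = {k: rec[k] for k in _FIELDS if k in rec}
        out.setdefault(sid, {})[rec["test"]] = PsychometricListener(**kwargs)
    return out


def dump_listeners(
    listeners: dict[str, dict[str, PsychometricListener]], path: str | Path
) -> None:
    """Write the inverse of :func:`load_listeners`."""
    records = []
    for sid, by_test in listeners.items():
        for test, lst in by_test.items():
            records.append(
                {
                    "subject_id": sid,
                    "test": test or lst.test,
                    "threshold": lst.threshold,
                    "slope": lst.slope,
                    "guess_rate": lst.guess_rate,
                    "lapse_rate": lst.lapse_rate,
                    "mode": lst.mode,
                }
            )
    Path(path).write_text(json.dumps(records, indent=1))
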