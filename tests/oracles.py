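"""Independent brute-force traces of the adaptive procedures.

These are hand-coded, trial-by-trial re-derivations of each staircase rule
for ideal step-function listeners (correct iff the stimulus is
at-or-better-than threshold).  They share no code with the package and are
deliberately written in the most literal style possible; the package's
tracks must match them bit-for-bit on the 0.1-unit level grid.
"""

from __future__ import annotations

import math


def r1(x: float) -> float:
    return round(x * 10.0) / 10.0


def bekesy_trace(threshold, start=40.0, big=4.0, small=2.0, n_good=6,
                 max_trials=400):
    """(levels, heard flags, estimate) for a step-function button presser."""
    level = r1(start)
    levels, heard_seq, dirs = [], [], []
    good = []
    saw_first_reversal = False
    for _ in range(max_trials):
        heard = level >= threshold
        levels.append(level)
        heard_seq.append(heard)
        d = -1 if heard else +1
        if dirs and d != dirs[-1]:
            if saw_first_reversal:
                good.append(level)
            saw_first_reversal = True
        dirs.append(d)
        if len(good) >= n_good:
            return levels, heard_seq, r1(sum(good) / len(good))
        down = big if not saw_first_reversal else small
        level = r1(level - down if heard else level + small)
    return levels, heard_seq, math.nan


def gap_trace(threshold_ms, start=20.0, step=4.0, min_step=1.0,
              stop_reversals=6, estimator_reversals=4, min_gap=1.0,
              max_gap=100.0, max_trials=300):
    """(gaps, correct flags, estimate) for the 2-down / 2-or-3-miss-up rule."""
    gap = r1(start)
    gaps, corrects = [], []
    cc = cm = cum = 0
    last_move = 0
    reversals = []
    for _ in range(max_trials):
        correct = gap >= threshold_ms
        gaps.append(gap)
        corrects.append(correct)
        if correct:
            cc += 1
            cm = 0
        else:
            cm += 1
            cc = 0
            cum += 1
        move = 0
        if cc >= 2:
            move = -1
        elif cm >= 2 or cum >= 3:
            move = +1
        if move:
            cc = cm = 0
            if move > 0:
                cum = 0
            if last_move and move != last_move:
                reversals.append(gap)
                step = step / 2.0 if step / 2.0 >= min_step else min_step
                cum = 0
            last_move = move
            if len(reversals) >= stop_reversals:
                tail = reversals[-estimator_reversals:]
                return gaps, corrects, sum(tail) / len(tail)
            gap = r1(max(min(gap + move * step, max_gap), min_gap))
    return gaps, corrects, math.nan


def hint_trace(threshold_snr, start=0.0, step14=4.0, step_rest=2.0, n=20):
    """(levels, correct flags, SRT) for the 1-down/1-up sentence track."""
    snr = r1(start)
    levels, corrects = [], []
    for i in range(n):
        correct = snr >= threshold_snr
        levels.append(snr)
        corrects.append(correct)
        step = step14 if i < 4 else step_rest
        snr = r1(snr - step if correct else snr + step)
    tail = levels[4:]
    return levels, corrects, sum(tail) / len(tail)


def tdt_trace(threshold_snr, start=0.0, step=1.5, n_practice_pairs=3,
              n_test_pairs=15, last_k=14):
    """(pair SNRs, positive-phase test SNRs, SRT) for the paired-masker track.

    For a step-function listener all three digits are correct at-or-above
    threshold and all are wrong below, so each pair moves the level by
    3*step in one direction; the phase order within the pair is irrelevant
    to the level sequence.
    """
    snr = r1(start)
    pair_snrs, positive_test = [], []
    for pair in range(n_practice_pairs + n_test_pairs):
        pair_snrs.append(snr)
        if pair >= n_practice_pairs:
            positive_test.append(snr)
        n_correct = 3 if snr >= threshold_snr else 0
        snr = r1(snr + step * ((3 - n_correct) - n_correct))
    tail = positive_test[-last_k:]
    return pair_snrs, positive_test, sum(tail) / len(tail)
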