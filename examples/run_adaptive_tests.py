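"""Simulate the four adaptive auditory procedures for one virtual listener.

Builds a listener with known thresholds on each test, runs the Békésy
audiometric track, the gap-detection staircase, the three-condition
sentence-in-noise test, and the triple-digit test, and prints each
procedure's threshold estimate next to the truth it should recover.
"""

import numpy as np

from audcog import (BekesyConfig, GapConfig, HintConfig, TdtConfig,
                    PsychometricListener, hint_composite, make_gap_listener,
                    run_bekesy, run_gap_staircase, run_hint_condition,
                    run_tdt)

rng = np.random.default_rng(7)

# tone audibility: true threshold 12 dB HL, moderately steep function
tone = PsychometricListener(threshold=12.0, slope=1.0)
track = run_bekesy(tone, BekesyConfig(start_level=40.0), rng)
print(f"Bekesy audiometry : estimate {track.estimate:6.2f} dB HL "
      f"(truth 12.0, {len(track.trials)} presentations)")

# gap detection: true threshold 6 ms on the log2(gap) axis
gap = make_gap_listener(6.0, slope_per_octave=4.0)
track = run_gap_staircase(gap, GapConfig(), rng)
print(f"Gap detection     : estimate {track.estimate:6.2f} ms     "
      f"(truth  6.0, {len(track.trials)} trials)")

# sentence-in-noise: three noise conditions, composite of the three SRTs
speech = PsychometricListener(threshold=-4.0, slope=1.5)
srts = {}
for cond in ("noise_front", "noise_right", "noise_left"):
    srts[cond] = run_hint_condition(speech, HintConfig(), cond, rng).estimate
composite = hint_composite(srts["noise_front"], srts["noise_right"],
                           srts["noise_left"])
print(f"HINT composite    : estimate {composite:6.2f} dB SNR "
      f"(truth -4.0; per-condition {[round(v, 1) for v in srts.values()]})")

# digit triplets in paired-phase maskers: closed set of 10 digits
digits = PsychometricListener(threshold=-8.0, slope=0.8, guess_rate=0.1)
track = run_tdt(digits, TdtConfig(), rng)
print(f"TDT               : estimate {track.estimate:6.2f} dB SNR "
      f"(truth -8.0, SRT over last 14 positive-phase presentations)")

print("\nEach estimate should sit within roughly one step size of the "
      "listener's true threshold; larger gaps would indicate a broken "
      "staircase rule.")
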