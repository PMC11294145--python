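"""Run the classical signal-processing J-peak detector on a synthetic night.

The chain (bandpass, cube, low-pass, second derivative, absolute value,
low-pass, adaptive peak picking) is both the comparison baseline and the
source of the preliminary J-peaks used to align reference events to the BCG.
"""

import numpy as np

from bcgbeat import (SubjectParams, derive_jpeaks, detect_jpeaks_dsp,
                     simulate_heartbeats, synthesize_bcg)

params = SubjectParams()            # default noise: imperfect but functional
r = simulate_heartbeats(params, 300.0, seed=7)
j = derive_jpeaks(r, params)
rec = synthesize_bcg(j, params, fs=64.0, duration=300.0, seed=8)

detected = detect_jpeaks_dsp(rec)
dist = np.abs(j.times[:, None] - detected.times[None, :])
recall = (dist.min(axis=1) <= 0.1).mean()
precision = (dist.min(axis=0) <= 0.1).mean()
print(f"true beats: {len(j)}, detected: {len(detected)}")
print(f"recall {recall:.2f}, precision {precision:.2f} (100 ms tolerance)")

# At the generator's default noise the baseline finds most beats but misses
# some and adds spurious ones — the imperfection the learned detector improves.
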