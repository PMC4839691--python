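"""Compute the 54x81 cochleogram that feeds the classification image.

The stimulus is passed through 54 ERB-spaced gammatone filters
(100-8000 Hz), envelopes are extracted and averaged into 81 time
frames, and band energies are log-compressed.  The flattened map is
the 4374-dimensional predictor vector of the GLM.
"""

import numpy as np

from acimage import (build_filterbank, compute_cochleogram, flatten,
                     synthesize_targets)

targets = synthesize_targets()
fb = build_filterbank()
c = compute_cochleogram(targets.waveforms["alga"], fb)

print(f"cochleogram shape: {c.shape} (channels x frames)")
print(f"center frequencies: {c.center_frequencies[0]:.0f} .. "
      f"{c.center_frequencies[-1]:.0f} Hz (ERB-spaced)")
print(f"frame times: {c.frame_times[0]:.1f} .. {c.frame_times[-1]:.1f} ms")
print(f"floor (60 dB below max): {c.floor:.1f} dB")
print(f"predictor vector length: {flatten(c).size}")

# sanity check: a 1 kHz pure tone excites the channel nearest 1 kHz
tone = np.sin(2 * np.pi * 1000.0 * np.arange(32_640) / 48_000)
ct = compute_cochleogram(tone, fb)
best = np.argmax(ct.values.mean(axis=1))
print(f"\n1 kHz tone peaks in channel {best} "
      f"(center {fb.center_frequencies[best]:.0f} Hz)")
# Expected: shape (54, 81), 4374 predictors, and the tone peak at the
# channel whose center frequency is nearest 1000 Hz (~1023 Hz).
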