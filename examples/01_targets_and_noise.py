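"""Build the four /aCCa/ targets, draw trial noise, and mix at an SNR.

The four targets (alda, alga, aRda, aRga) are formant-synthesized
680 ms nonwords at 48 kHz; each trial adds a unique white-noise token
at the staircase-controlled SNR and re-normalizes the mixture to unit
RMS.
"""

import numpy as np

from acimage import generate_noise, mix_at_snr, synthesize_targets, write_wav

targets = synthesize_targets()
print("targets:", ", ".join(targets.labels))
for lab in targets.labels:
    w = targets.waveforms[lab]
    print(f"  {lab}: {len(w)} samples "
          f"({len(w) / targets.sample_rate * 1000:.0f} ms), "
          f"RMS = {np.sqrt(np.mean(w ** 2)):.9f}")

noise = generate_noise(seed=42)
mix = mix_at_snr(targets.waveforms["alda"], noise, snr_db=-10.0)
print(f"\nmixture at -10 dB SNR: RMS = {np.sqrt(np.mean(mix ** 2)):.9f} "
      "(power-normalized, so level carries no information)")

write_wav("/tmp/alda_minus10db.wav", mix, targets.sample_rate)
print("wrote /tmp/alda_minus10db.wav")
# Expected: all 4 targets are 32640 samples with RMS exactly 1; the
# mixture is unit-RMS as well.  The seed fully determines the noise, so
# a trial can be reconstructed from (target label, seed, SNR) alone.
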