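"""Denoise a noisy PPG with SSA bit-plane suppression.

The record is decomposed into 32 SSA components; each component is
quantised to 13 bits, its estimated noise bit-planes are zeroed, and the
sum is decomposed again, keeping the leading component.
"""

import numpy as np

from glucoppg import SynthConfig, denoise_ppg, generate_ppg_record
from glucoppg.synth import clean_config, generate_beat_intervals

cfg = clean_config(SynthConfig(duration_s=20.0, fs_fast=250.0))
rng = np.random.default_rng(0)
intervals = generate_beat_intervals(cfg, 20.0, glucose=6.0, rng=rng)
clean = generate_ppg_record(intervals, 880, 250.0, 20.0, 6.0, cfg, seed=1).samples

noise = rng.normal(0.0, 0.08, size=clean.size)
noisy = clean + noise
denoised = denoise_ppg(noisy)

def snr_db(signal, residual):
    return 10 * np.log10(np.var(signal) / np.var(residual))

print(f"input SNR : {snr_db(clean, noisy - clean):6.2f} dB")
print(f"output SNR: {snr_db(clean, denoised - clean):6.2f} dB")
print(f"waveform correlation with the clean pulse train: "
      f"{np.corrcoef(clean, denoised)[0, 1]:.4f}")
# A positive SNR gain with correlation near 1 means the pulse morphology
# (systolic peak + dicrotic bump) survives while broadband noise is removed.
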