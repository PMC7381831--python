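"""Segmentation failure vs channel SNR: coherence vs amplitude beamforming.

Gaussian noise is added to clean reference recordings as a surrogate for
lowering the laser energy; segmentations of the noisy images are compared
with the reference segmentations.  SLSC (which images spatial coherence,
not amplitude) keeps segmenting at channel SNRs where DAS has failed.
"""

import numpy as np

import paslsc as P

geometry = P.ArrayGeometry(num_elements=64, pitch_mm=0.3,
                           sampling_frequency_mhz=40.0)
frames = [
    P.simulate_channel_data(geometry, P.SourceSpec(x_mm=float(x), depth_mm=30.0),
                            depth_mm=40.0, noise_snr_db=5.0, seed=100 + i)
    for i, x in enumerate(np.linspace(-2.0, 2.0, 10))
]
table = P.failed_segmentation_experiment(
    frames, snr_grid_db=[-36, -33, -30, -27, -24, -21], seed=7,
)
print(table.pivot(index="snrc_db", columns="method",
                  values="mean_pct_failed").to_string())
print()
print("Rows are the channel SNR of the added noise (dB); values are the "
      "mean % of failed segmentations over the 35-66% threshold sweep. "
      "Failures rise as SNR falls, and SLSC fails less than DAS in the "
      "low-SNR regime.")
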