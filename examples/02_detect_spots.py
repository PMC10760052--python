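"""Detect single-molecule spots in a simulated TIRF field.

Renders 100 diffraction-limited spots at peak SNR 5 on a photon-noise
background, detects them, and scores recall/precision against the
ground-truth positions.
"""

import math

import numpy as np
from scipy.spatial import cKDTree

import smassay as sm

fp = sm.FieldParams(rows=512, cols=512, psf_sigma_px=1.5, spot_density=100,
                    min_separation_px=10, edge_margin_px=10)
bg = 100.0
noise_sd = math.sqrt(bg + 2.0 ** 2)
pp = sm.PhotophysicsParams(copies_n=1, p_mature=1.0, bleach_rate=1e-9,
                           unit_intensity=5.0 * noise_sd,
                           background_level=bg, read_noise_sd=2.0,
                           n_frames=2, frame_interval_s=0.1)

stack, truth = sm.simulate_field(fp, pp, seed=0)
spots = sm.detect_spots(stack.data[0], approx_size_px=4, snr_threshold=5.0)

tree = cKDTree(truth.spots[["x", "y"]].to_numpy())
d, j = tree.query(spots.positions, distance_upper_bound=2.0)
hits = np.isfinite(d)
print(f"detected {len(spots)} spots of {len(truth.spots)} true")
print(f"recall    {len(set(j[hits])) / len(truth.spots):.2f}")
print(f"precision {hits.sum() / len(spots):.2f}")
print(f"median localization error {np.median(d[hits]):.2f} px")
# At peak SNR 5 the band-pass detection statistic sits well above the
# threshold, so both rates are at or near 1.0 on these fields.
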