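"""Full image-based stoichiometry: movie -> spots -> traces -> (n, p).

Renders a photobleaching movie of dimeric complexes, detects spots on
the first frame, extracts aperture-photometry traces, fits steps and
infers the copy number and per-copy visibility.
"""

import smassay as sm
from smassay.errors import EdgeError

fp = sm.FieldParams(rows=320, cols=320, psf_sigma_px=1.3, spot_density=100,
                    min_separation_px=10, edge_margin_px=10)
pp = sm.PhotophysicsParams(copies_n=2, p_mature=0.8, bleach_rate=1 / 30,
                           unit_intensity=400.0, background_level=20.0,
                           read_noise_sd=2.0, frame_interval_s=0.25,
                           n_frames=480)

fits = []
for field in range(3):
    stack, truth = sm.simulate_field(fp, pp, seed=field)
    spots = sm.detect_spots(stack.data[0])
    for i in range(len(spots)):
        try:
            trace = sm.extract_trace(stack, spots[i])
        except EdgeError:
            continue
        fits.append(sm.fit_steps(trace))

hist = sm.classify_and_histogram(fits)
result = sm.fit_stoichiometry(hist)
print(f"{len(fits)} traces, histogram {hist.counts.tolist()}, "
      f"rejected {hist.n_rejected} ({hist.reject_reasons})")
bic = {n: round(b, 1) for n, b in result.bic.items()}
print(f"n = {result.n_hat}, p = {result.p_hat:.3f}  (BIC per n: {bic})")
print(f"goodness-of-fit p-value: {result.gof_p_value:.2f}")
# 200 spots/movie across three movies mirrors the scale at which a
# photobleaching experiment distinguishes dimer from monomer or trimer.
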