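"""Two-color colocalization with a chance-coincidence control.

Simulates complexes that always carry a channel-A label and carry a
channel-B label 62% of the time, matches the two channels, and compares
the matched fraction with the chance floor from random translations.
"""

import smassay as sm

fp = sm.FieldParams(rows=1024, cols=1024, spot_density=0,
                    min_separation_px=5, edge_margin_px=10)
tc = sm.TwoChannelParams(n_complexes=1000, p_label_A=1.0, p_label_B=0.62,
                         independent_fraction=0.1, jitter_px=0.25)

set_a, set_b, truth = sm.two_channel_truth_spotsets(tc, fp, seed=2)
pairing = sm.match_spots(set_a, set_b, max_distance_px=4.0)
result = sm.colocalization_fraction(pairing, len(set_a), len(set_b))
chance = sm.estimate_chance(set_a, set_b, max_distance_px=4.0,
                            n_randomizations=20, seed=3)

print(f"channel A spots: {result.n_a}, channel B spots: {result.n_b}, "
      f"pairs: {result.n_pairs}")
print(f"fraction of A colocalized with B: {result.fraction_a_with_b:.3f}")
print(f"fraction of B colocalized with A: {result.fraction_b_with_a:.3f}")
print(f"chance coincidence fraction:      {chance:.3f}")
# A-with-B tracks p_label_B (0.62) diluted by the 10% free molecules;
# B-with-A is higher because nearly every labeled B sits in a complex
# whose A label is always present. Chance stays near zero on a sparse
# field, so the measured colocalization is genuine.
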