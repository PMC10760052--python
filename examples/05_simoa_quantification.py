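"""Digital ELISA: standard curve, limit of detection, organ abundance.

Simulates a 6-point bead-count standard series plus a cochlea-like
unknown at 2.75 pM, fits the AEB-vs-concentration curve, estimates the
LOD (blank + 3 SD) and converts the unknown into attomoles per organ
given 20 uL of lysate.
"""

import smassay as sm

levels = [(0.0, [sm.simulate_simoa(
    sm.SimoaSimParams(concentration_molar=0.0), seed=s)[0]
    for s in range(3)])]
seed = 100
for conc in (1e-14, 3e-14, 1e-13, 3e-13, 1e-12, 3e-12):
    reps = []
    for _ in range(3):
        run, _ = sm.simulate_simoa(
            sm.SimoaSimParams(concentration_molar=conc), seed=seed)
        seed += 1
        reps.append(run)
    levels.append((conc, reps))

curve = sm.fit_standard_curve(levels)
lod = sm.estimate_lod(curve)
print(f"curve: AEB = {curve.slope:.3g} * C + {curve.intercept:.3g}, "
      f"R^2 = {curve.r_squared:.4f}")
print(f"LOD = {lod * 1e15:.2f} fM "
      f"({sm.attomoles(lod, 25e-6):.2f} amol in the 25 uL assay)")

truth_conc = 2.75e-12
quants = []
for rep in range(2):  # samples run in duplicate
    run, _ = sm.simulate_simoa(
        sm.SimoaSimParams(concentration_molar=truth_conc), seed=900 + rep)
    run.sample_label, run.replicate_id = "cochlea", str(rep)
    quants.append(sm.quantify_organ(run, curve, lysate_volume_L=20e-6))

print(sm.summarize_replicates(quants).to_string(index=False))
print(f"truth: {sm.attomoles(truth_conc, 20e-6):.1f} amol per cochlea")
# The back-calculated mean lands within a few percent of 55 amol; the
# CV reflects pure bead-counting (binomial) noise at ~25k beads/array.
# The simulator has no non-specific binding, so its blanks are truly
# dark and the blank+3SD LOD collapses toward zero; real assays have a
# nonzero blank AEB and correspondingly higher LODs.
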