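# smassay

Analysis tools for coverslip single-molecule immunoassays of very
low-abundance protein complexes — the regime of the inner-ear
mechanotransduction machinery, where a whole mouse cochlea holds only
tens of attomoles of a subunit such as protocadherin-15 (PCDH15) or
LHFPL5. Two assay families are covered:

- **SiMPull** (single-molecule pull-down): complexes immunocaptured on a
  passivated coverslip are imaged by TIRF microscopy. The package
  detects diffraction-limited spots, measures two-color colocalization
  with a chance-coincidence control, extracts per-spot photobleaching
  traces, counts bleaching steps by change-point fitting, and infers
  subunit stoichiometry.
- **SiMoA** (single-molecule array, digital ELISA): antibody-coated
  beads are isolated one-per-well in femtoliter arrays and read out
  on/off. The package converts on/off counts to average enzymes per bead
  (AEB), fits standard curves, estimates limits of detection, and
  back-calculates attomoles per organ.

Every analysis stage has a matching simulator that generates data with
known ground truth (spot positions, per-spot fluorophore counts and
bleach times, per-complex channel pairings, per-bead enzyme counts), so
the whole pipeline is testable without experimental data.

## The two core models

**Stoichiometry from photobleaching.** A complex with `n` fluorophore
sites, each independently visible with probability `p` (chromophore
maturation × labeling × photoactivity), shows `k` bleaching steps with
the zero-truncated binomial probability

    P(k | detected) = C(n,k) p^k (1-p)^(n-k) / (1 - (1-p)^n),  k = 1..n,

because fully dark complexes never appear as spots. For a dimer this
gives the closed forms `f2 = p/(2-p)` and `p = 2 f2/(1+f2)`: at p = 0.8,
two-thirds of detectable spots bleach in two steps. Steps are counted by
recursive binary segmentation with an RSS-reduction penalty, a
level-tracking noise model (shot noise makes bright segments noisier),
and refine/prune passes; `fit_stoichiometry` maximizes the multinomial
likelihood over `p` for each candidate `n` and selects `n` by BIC.

**Digital counting.** Enzyme labels land on beads as a Poisson process,
so the fraction of "on" wells obeys `f_on = 1 - exp(-AEB)` and
`AEB = -ln(1 - f_on)` is linear in concentration in the digital range
(`f_on < 0.7`). The limit of detection is the blank mean + 3 SD mapped
through the standard curve, and abundance per organ is
`concentration × lysate volume × dilution × 1e18` attomoles.

## Worked example

`examples/01_simulate_and_count_steps.py` simulates 600 detectable
photobleaching traces of a dimer at 80% per-copy visibility and runs the
step-counting and inference pipeline:

```
step histogram (1..4+ steps): [188, 388, 0, 0], accepted 576, rejected 24
two-step fraction: 0.674 (model prediction at p=0.8: 0.667)
inferred stoichiometry: n = 2, p = 0.805 (truth: n = 2, p = 0.8)
```

The histogram splits close to 1/3 : 2/3 one-step : two-step, the
rejected traces are those that never fully bleach within the movie, and
the maximum-likelihood fit recovers the generating copy number and
visibility. The other examples cover spot detection scoring
(`02`), colocalization with the chance control (`03`), the full
image-to-stoichiometry pipeline (`04`), SiMoA calibration and
attomole-per-cochlea quantification (`05`), and the config-driven
orchestrated run (`06`).

A thin CLI mirrors the pipeline stages for shell use:

```
smassay run-all --config cfg.yaml
smassay simulate | detect | colocalize | bleach | stoich | simoa-curve | simoa-quant
```

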