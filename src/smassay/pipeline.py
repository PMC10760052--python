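"""End-to-end orchestration of the SiMPull and SiMoA analyses.

``run_simpull`` executes simulate (optional) -> detect -> register ->
colocalize -> extract traces -> fit steps -> histogram -> stoichiometry;
``run_simoa`` executes simulate (optional) -> standard curve -> LOD ->
per-sample quantification. Every stage draws its randomness from a seed
derived deterministically from the single global seed and the stage name
(via ``numpy.random.SeedSequence``), so any stage can be rerun in
isolation and full runs are reproducible file-for-file.

All artifacts are written under ``out_dir`` together with a provenance
record (config hash, global seed, package version, per-stage seeds).
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass
from dataclasses import field as dc_field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as smio
from .bleach import (StepFit, StepHistogram, StoichiometryFit,
                     classify_and_histogram, extract_trace, fit_steps,
                     fit_stoichiometry, fits_to_dataframe)
from .colocalize import (ColocalizationResult, colocalization_fraction,
                         estimate_chance, match_spots)
from .detect import SpotSet, detect_spots
from .errors import InputError
from .params import (FieldParams, PhotophysicsParams, SimoaSimParams,
                     TwoChannelParams)
from .simoa import (OrganQuantification, SimoaRun, StandardCurve, estimate_lod,
                    fit_standard_curve, quantify_organ, summarize_replicates)
from .simulate import simulate_simoa, simulate_two_channel

__version__ = "0.1.0"


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31.

    Spawned from ``SeedSequence([global_seed, crc32(stage)])`` so stages
    are independent streams yet individually reproducible.
    """
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class DetectionConfig:
    approx_size_px: int = 4
    snr_threshold: float = 5.0
    frame: int = 0


@dataclass
class MatchingConfig:
    max_distance_px: float = 4.0
    correct_offset: bool = True
    n_randomizations: int = 10
    chance_control: bool = True


@dataclass
class BleachConfig:
    aperture_radius_px: float = 3.0
    annulus_radii_px: Tuple[float, float] = (5.0, 8.0)
    penalty: Optional[float] = None
    min_dwell_frames: int = 1
    k_max: int = 4
    n_candidates: Tuple[int, ...] = (1, 2, 3, 4)

    def __post_init__(self) -> None:
        self.annulus_radii_px = tuple(self.annulus_radii_px)
        self.n_candidates = tuple(self.n_candidates)


@dataclass
class SimoaConfig:
    sim: SimoaSimParams = dc_field(default_factory=SimoaSimParams)
    standard_concentrations: Tuple[float, ...] = (
        0.0, 1e-14, 3e-14, 1e-13, 3e-13, 1e-12, 3e-12)
    n_replicates: int = 3
    sample_concentrations: Dict[str, float] = dc_field(default_factory=dict)
    lysate_volume_L: float = 20e-6
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        self.standard_concentrations = tuple(self.standard_concentrations)


@dataclass
class RunConfig:
    """Complete, serializable description of one pipeline run."""

    seed: int = 0
    out_dir: str = "smassay_out"
    n_fields: int = 1
    field: FieldParams = dc_field(default_factory=FieldParams)
    photophysics: PhotophysicsParams = dc_field(default_factory=PhotophysicsParams)
    photophysics_b: Optional[PhotophysicsParams] = None
    two_channel: Optional[TwoChannelParams] = dc_field(
        default_factory=TwoChannelParams)
    detection: DetectionConfig = dc_field(default_factory=DetectionConfig)
    matching: MatchingConfig = dc_field(default_factory=MatchingConfig)
    bleach: BleachConfig = dc_field(default_factory=BleachConfig)
    simoa: SimoaConfig = dc_field(default_factory=SimoaConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("field", FieldParams),
                         ("photophysics", PhotophysicsParams),
                         ("photophysics_b", PhotophysicsParams),
                         ("two_channel", TwoChannelParams)):
            if isinstance(d.get(key), dict):
                d[key] = typ.from_dict(d[key])
        for key, typ in (("detection", DetectionConfig),
                         ("matching", MatchingConfig),
                         ("bleach", BleachConfig)):
            if isinstance(d.get(key), dict):
                d[key] = typ(**d[key])
        if isinstance(d.get("simoa"), dict):
            sd = dict(d["simoa"])
            if isinstance(sd.get("sim"), dict):
                sd["sim"] = SimoaSimParams.from_dict(sd["sim"])
            d["simoa"] = SimoaConfig(**sd)
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where results land is not scientific state
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SimpullResults:
    spots_a: List[SpotSet]
    spots_b: List[SpotSet]
    colocalization: Optional[ColocalizationResult]
    step_fits: List[StepFit]
    histogram: Optional[StepHistogram]
    stoichiometry: Optional[StoichiometryFit]
    warnings_count: int
    out_dir: Path


@dataclass
class SimoaResults:
    curve: StandardCurve
    lod: float
    quantifications: List[OrganQuantification]
    summary: pd.DataFrame
    out_dir: Path


def _provenance(config: RunConfig, stages: Sequence[str]) -> dict:
    return {"config_hash": config.hash(), "seed": config.seed,
            "version": __version__,
            "stage_seeds": {s: stage_seed(config.seed, s) for s in stages}}


def run_simpull(config: RunConfig,
                input_stacks: Optional[Sequence[Tuple]] = None
                ) -> SimpullResults:
    """Run the full SiMPull analysis from a config.

    Without ``input_stacks``, two-channel movies are synthesized from the
    config's generative parameters; otherwise pass ``(stack_a, stack_b)``
    tuples (``stack_b`` may be None for single-channel stoichiometry).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_warnings = 0
    pp_a = config.photophysics
    pp_b = config.photophysics_b or pp_a

    fields = []
    if input_stacks is None:
        sim_seed = stage_seed(config.seed, "simulate")
        for k in range(config.n_fields):
            if config.two_channel is not None:
                sa, sb, truth = simulate_two_channel(
                    config.two_channel, config.field, pp_a, pp_b,
                    seed=sim_seed + k, field_id=str(k))
            else:
                from .simulate import simulate_field
                sa, truth = simulate_field(config.field, pp_a,
                                           seed=sim_seed + k, field_id=str(k))
                sb = None
            smio.write_stack(sa, smio.stack_path(out, str(k), "chA"))
            if sb is not None:
                smio.write_stack(sb, smio.stack_path(out, str(k), "chB"))
            truth.to_csv_dir(out / f"truth_field{k}")
            fields.append((sa, sb))
    else:
        fields = [(a, b) for a, b in input_stacks]

    det = config.detection
    spots_a, spots_b = [], []
    for k, (sa, sb) in enumerate(fields):
        img_a = np.asarray(sa.data)[det.frame]
        set_a = detect_spots(img_a, det.approx_size_px, det.snr_threshold,
                             field_id=str(k), channel="chA")
        set_a.to_csv(out / f"spots_field{k}_chA.csv", asdict(det))
        spots_a.append(set_a)
        if sb is not None:
            img_b = np.asarray(sb.data)[det.frame]
            set_b = detect_spots(img_b, det.approx_size_px, det.snr_threshold,
                                 field_id=str(k), channel="chB")
            set_b.to_csv(out / f"spots_field{k}_chB.csv", asdict(det))
            spots_b.append(set_b)

    coloc = None
    if spots_b:
        match = config.matching
        total_pairs = total_a = total_b = 0
        pair_rows = []
        chance_vals = []
        for k, (set_a, set_b) in enumerate(zip(spots_a, spots_b)):
            if len(set_a) == 0 or len(set_b) == 0:
                n_warnings += 1
                continue
            pairing = match_spots(set_a, set_b, match.max_distance_px,
                                  correct_offset=match.correct_offset)
            total_pairs += pairing.n_pairs
            total_a += len(set_a)
            total_b += len(set_b)
            df = pairing.to_dataframe()
            df.insert(0, "field_id", k)
            pair_rows.append(df)
            if match.chance_control:
                chance_vals.append(estimate_chance(
                    set_a, set_b, match.max_distance_px,
                    match.n_randomizations,
                    seed=stage_seed(config.seed, f"chance{k}")))
        if total_a and total_b:
            coloc = ColocalizationResult(
                total_pairs / total_a, total_pairs / total_b,
                total_a, total_b, total_pairs,
                chance_fraction=(float(np.mean(chance_vals))
                                 if chance_vals else None))
            coloc.to_json(out / "colocalization.json")
            pd.concat(pair_rows).to_csv(out / "pairs.csv", index=False)
        else:
            n_warnings += 1

    bl = config.bleach
    step_fits: List[StepFit] = []
    trace_rows = []
    for k, (sa, _) in enumerate(fields):
        for set_a in [spots_a[k]]:
            for i in range(len(set_a)):
                spot = set_a[i]
                try:
                    tr = extract_trace(sa, spot, bl.aperture_radius_px,
                                       bl.annulus_radii_px)
                except InputError:
                    n_warnings += 1
                    continue
                except Exception:
                    n_warnings += 1
                    continue
                step_fits.append(fit_steps(tr, bl.penalty, bl.min_dwell_frames))
                trace_rows.append(pd.DataFrame({
                    "field_id": k, "spot_index": i,
                    "frame": np.arange(len(tr)),
                    "intensity": tr.intensities}))
    if trace_rows:
        pd.concat(trace_rows).to_csv(out / "traces.csv", index=False)
        fits_to_dataframe(step_fits).to_csv(out / "step_fits.csv", index=False)

    histogram = stoich = None
    if step_fits:
        histogram = classify_and_histogram(step_fits, bl.k_max)
        histogram.to_json(out / "step_histogram.json")
        if histogram.n_accepted >= 20:
            stoich = fit_stoichiometry(histogram, bl.n_candidates)
            stoich.to_json(out / "stoichiometry.json")
        else:
            n_warnings += 1
    else:
        n_warnings += 1

    prov = _provenance(config, ["simulate", "detect", "colocalize", "bleach"])
    prov["warnings_count"] = n_warnings
    smio.write_json(prov, out / "provenance.json")
    config.to_yaml(out / "config.yaml")
    return SimpullResults(spots_a, spots_b, coloc, step_fits, histogram,
                          stoich, n_warnings, out)


def run_simoa(config: RunConfig,
              runs: Optional[Sequence[SimoaRun]] = None) -> SimoaResults:
    """Run the digital-ELISA branch: standards, curve, LOD, samples.

    Without ``runs``, a synthetic standard series plus the configured
    samples are simulated from ``config.simoa``; with ``runs``, blanks
    are the runs labeled ``"blank"``, standards are labeled
    ``"std:<concentration>"`` and everything else is quantified.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sc = config.simoa
    seed = stage_seed(config.seed, "simoa")

    levels: List[Tuple[float, List[SimoaRun]]] = []
    samples: List[SimoaRun] = []
    if runs is None:
        base = sc.sim.to_dict()
        base.pop("concentration_molar")
        base.pop("seed")
        counter = 0
        for conc in sc.standard_concentrations:
            reps = []
            for r in range(sc.n_replicates):
                sp = SimoaSimParams(concentration_molar=conc, **base)
                run, _ = simulate_simoa(sp, seed=seed + counter)
                counter += 1
                run.sample_label = f"std:{conc:g}"
                run.replicate_id = str(r)
                reps.append(run)
            levels.append((conc, reps))
        for label, conc in sc.sample_concentrations.items():
            for r in range(2):  # samples run in duplicate
                sp = SimoaSimParams(concentration_molar=conc, **base)
                run, _ = simulate_simoa(sp, seed=seed + counter)
                counter += 1
                run.sample_label = label
                run.replicate_id = str(r)
                samples.append(run)
    else:
        by_level: Dict[float, List[SimoaRun]] = {}
        for run in runs:
            if run.sample_label == "blank":
                by_level.setdefault(0.0, []).append(run)
            elif run.sample_label.startswith("std:"):
                by_level.setdefault(float(run.sample_label[4:]), []).append(run)
            else:
                samples.append(run)
        levels = sorted(by_level.items())

    curve = fit_standard_curve(levels)
    curve.to_json(out / "standard_curve.json")
    lod = estimate_lod(curve)
    quants = [quantify_organ(run, curve, sc.lysate_volume_L,
                             sc.dilution_factor, lod_concentration=lod)
              for run in samples]
    rows = []
    for q in quants:
        rows.append({
            "sample_label": q.sample_label, "replicate_id": q.replicate_id,
            "aeb": q.aeb, "concentration_molar": q.concentration_molar,
            "attomoles_per_organ": ("< LOD" if q.below_lod
                                    else f"{q.attomoles_per_organ:.6g}"),
            "below_lod": q.below_lod})
    pd.DataFrame(rows).to_csv(out / "quantification.csv", index=False)
    summary = summarize_replicates(quants) if quants else pd.DataFrame()
    if len(summary):
        summary.to_csv(out / "quantification_summary.csv", index=False)
    prov = _provenance(config, ["simoa"])
    prov["lod_concentration_molar"] = lod
    smio.write_json(prov, out / "provenance.json")
    config.to_yaml(out / "config.yaml")
    return SimoaResults(curve, lod, quants, summary, out)
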