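"""Digital-ELISA (SiMoA) quantification.

Beads carrying an enzyme-labeled immunocomplex are isolated one-per-well
in a femtoliter array and read out as on/off. Because enzymes land on
beads as a Poisson process, the fraction of "on" wells relates to the
average number of enzymes per bead (AEB) through the zero class:

    f_on = 1 - exp(-AEB)   =>   AEB = -ln(1 - f_on)

AEB is linear in analyte concentration in the digital regime (f_on
below ~0.7), so a weighted linear standard curve maps AEB to
concentration, the limit of detection is the blank mean + 3 SD
back-calculated through the curve, and organ abundance follows from the
lysate volume and dilution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import CurveError, InputError, SaturationError

#: f_on ceiling of the digital (Poisson-countable) range.
DIGITAL_F_ON_MAX = 0.7

AMOL_PER_MOL = 1e18


def compute_aeb(beads_analyzed: int, beads_on: int) -> float:
    """Average enzymes per bead from on/off counts, -ln(1 - f_on)."""
    if beads_analyzed <= 0:
        raise InputError("beads_analyzed must be > 0")
    if not (0 <= beads_on <= beads_analyzed):
        raise InputError("beads_on must be in [0, beads_analyzed]")
    if beads_on == beads_analyzed:
        raise SaturationError(
            "all beads on: the Poisson zero class is empty and AEB diverges")
    return -math.log(1.0 - beads_on / beads_analyzed)


@dataclass
class SimoaRun:
    """On/off counts from one bead array measurement."""

    beads_analyzed: int
    beads_on: int
    replicate_id: str = ""
    sample_label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.beads_on <= self.beads_analyzed):
            raise InputError("beads_on must be in [0, beads_analyzed]")

    @property
    def f_on(self) -> float:
        return self.beads_on / self.beads_analyzed

    @property
    def aeb(self) -> float:
        return compute_aeb(self.beads_analyzed, self.beads_on)


@dataclass
class StandardCurve:
    """Linear AEB-vs-concentration calibration over the digital range."""

    concentrations: np.ndarray        # non-blank levels used in the fit
    mean_aeb: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    blank_mean: float
    blank_sd: float
    n_blank: int
    unit: str = "M"
    flags: List[str] = field(default_factory=list)

    def concentration_from_aeb(self, aeb: float) -> float:
        if self.slope <= 0:
            raise CurveError("curve slope is not positive; cannot invert")
        return (aeb - self.intercept) / self.slope

    def to_json(self, path) -> None:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in self.__dict__.items()}
        Path(path).write_text(json.dumps(d, indent=2))


@dataclass
class OrganQuantification:
    """Back-calculated abundance of one sample, in attomoles per organ."""

    sample_label: str
    replicate_id: str
    aeb: float
    concentration_molar: float
    lysate_volume_L: float
    dilution_factor: float
    attomoles_per_organ: float
    below_lod: bool
    lod_concentration: Optional[float] = None


LevelInput = Union["SimoaRun", float]


def _level_aebs(replicates: Sequence[LevelInput]) -> Tuple[np.ndarray, Optional[np.ndarray], Optional[np.ndarray]]:
    """AEBs plus (f_on, beads) when replicates are runs, else (None, None)."""
    if all(isinstance(r, SimoaRun) for r in replicates):
        aebs = np.array([r.aeb for r in replicates])
        f = np.array([r.f_on for r in replicates])
        n = np.array([r.beads_analyzed for r in replicates])
        return aebs, f, n
    return np.asarray([float(r) for r in replicates], dtype=float), None, None


def fit_standard_curve(levels: Sequence[Tuple[float, Sequence[LevelInput]]],
                       unit: str = "M") -> StandardCurve:
    """Fit a weighted linear standard curve from replicate measurements.

    ``levels`` is a list of ``(concentration, replicates)`` pairs where
    each replicate is a :class:`SimoaRun` (preferred: bead counts give
    analytic weights) or a bare AEB value (unweighted fit). Exactly the
    levels with ``concentration == 0`` form the blank. Levels whose mean
    f_on exceeds the digital ceiling (0.7) are excluded from the fit as
    saturated.
    """
    blanks: List[float] = []
    concs, means, weights = [], [], []
    flags: List[str] = []
    for conc, reps in levels:
        if len(reps) == 0:
            continue
        aebs, f, nbeads = _level_aebs(list(reps))
        if conc == 0:
            blanks.extend(aebs.tolist())
            continue
        if len(aebs) < 2:
            raise InputError(
                f"level at concentration {conc} has fewer than 2 replicates")
        if f is not None and float(np.mean(f)) > DIGITAL_F_ON_MAX:
            flags.append(f"level-{conc}-saturated-excluded")
            continue
        if f is None and float(np.mean(aebs)) > -math.log(1 - DIGITAL_F_ON_MAX):
            flags.append(f"level-{conc}-saturated-excluded")
            continue
        concs.append(float(conc))
        means.append(float(np.mean(aebs)))
        if f is not None:
            # var(AEB) per replicate = f / ((1 - f) n) by the delta method
            # on the binomial proportion; the level mean averages replicates.
            var_rep = np.clip(f, 1e-12, None) / ((1.0 - f) * nbeads)
            weights.append(len(aebs) / float(np.mean(var_rep)))
        else:
            weights.append(1.0)
    if len(blanks) == 0:
        raise InputError("a blank (concentration 0) level is required")
    if len(concs) < 3:
        raise InputError("need >= 3 non-blank, non-saturated levels")

    order = np.argsort(concs)
    x = np.asarray(concs)[order]
    y = np.asarray(means)[order]
    w = np.asarray(weights)[order]
    if np.any(np.diff(y) <= 0):
        flags.append("non-monotone-aeb")
    sw = np.sqrt(w)
    A = np.column_stack([x * sw, sw])
    coef, *_ = np.linalg.lstsq(A, y * sw, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = y - (slope * x + intercept)
    ybar = float(np.average(y, weights=w))
    ss_res = float(np.sum(w * resid ** 2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(
        concentrations=x, mean_aeb=y, slope=slope, intercept=intercept,
        r_squared=r2, blank_mean=float(np.mean(blanks)),
        blank_sd=float(np.std(blanks, ddof=1)) if len(blanks) > 1 else 0.0,
        n_blank=len(blanks), unit=unit, flags=flags)


def estimate_lod(curve: StandardCurve, n_sd: float = 3.0) -> float:
    """Limit of detection: blank mean + ``n_sd`` blank SDs through the curve."""
    if curve.n_blank < 3:
        raise InputError("LOD requires >= 3 blank replicates")
    if curve.slope <= 0:
        raise CurveError("LOD undefined for a non-positive slope")
    lod = (curve.blank_mean + n_sd * curve.blank_sd - curve.intercept) / curve.slope
    return max(lod, 0.0)


def attomoles(concentration_molar: float, volume_L: float,
              dilution_factor: float = 1.0) -> float:
    """Amount in attomoles of analyte in ``volume_L`` at the given dilution."""
    return concentration_molar * volume_L * dilution_factor * AMOL_PER_MOL


def quantify_organ(run: SimoaRun, curve: StandardCurve,
                   lysate_volume_L: float, dilution_factor: float = 1.0,
                   lod_concentration: Optional[float] = None,
                   ) -> OrganQuantification:
    """Convert one sample reading into attomoles per organ via the curve.

    Readings below the limit of detection are still converted but flagged
    ``below_lod`` so reports can print "< LOD" instead of a number.
    """
    aeb = run.aeb
    conc = curve.concentration_from_aeb(aeb)
    if lod_concentration is None and curve.n_blank >= 3:
        lod_concentration = estimate_lod(curve)
    below = bool(lod_concentration is not None and conc < lod_concentration)
    return OrganQuantification(
        sample_label=run.sample_label, replicate_id=run.replicate_id,
        aeb=aeb, concentration_molar=conc, lysate_volume_L=lysate_volume_L,
        dilution_factor=dilution_factor,
        attomoles_per_organ=attomoles(conc, lysate_volume_L, dilution_factor),
        below_lod=below, lod_concentration=lod_concentration)


def summarize_replicates(quants: Sequence[OrganQuantification]) -> pd.DataFrame:
    """Per-sample mean, SD and CV of attomoles per organ across replicates."""
    if not quants:
        raise InputError("no quantifications to summarize")
    df = pd.DataFrame({
        "sample_label": [q.sample_label for q in quants],
        "attomoles_per_organ": [q.attomoles_per_organ for q in quants],
        "below_lod": [q.below_lod for q in quants],
    })
    rows = []
    for label, g in df.groupby("sample_label", sort=False):
        vals = g["attomoles_per_organ"].to_numpy()
        mean = float(np.mean(vals))
        if len(vals) >= 2:
            sd = float(np.std(vals, ddof=1))
            cv = sd / mean if mean != 0 else math.nan
            flag = ""
        else:
            sd, cv, flag = math.nan, math.nan, "single-replicate"
        rows.append({"sample_label": label, "n_replicates": len(vals),
                     "mean_amol": mean, "sd_amol": sd, "cv": cv,
                     "any_below_lod": bool(g["below_lod"].any()),
                     "flags": flag})
    return pd.DataFrame(rows)


def read_runs_csv(path) -> List[SimoaRun]:
    """Read runs from a CSV of (sample_label, replicate_id, beads_analyzed, beads_on)."""
    df = pd.read_csv(path)
    required = {"sample_label", "replicate_id", "beads_analyzed", "beads_on"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"run CSV is missing columns {sorted(missing)}")
    runs = []
    for i, row in df.iterrows():
        try:
            runs.append(SimoaRun(int(row.beads_analyzed), int(row.beads_on),
                                 replicate_id=str(row.replicate_id),
                                 sample_label=str(row.sample_label)))
        except (ValueError, InputError) as exc:
            raise InputError(f"malformed run CSV at row {i}: {exc}") from exc
    return runs
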