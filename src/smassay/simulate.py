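"""Ground-truth-annotated simulation of single-molecule data.

Four generators cover the statistical structure the analyses assume:

``simulate_traces``
    Photobleaching intensity traces. Each complex has ``copies_n``
    fluorophore sites; each site is visible with probability ``p_mature``
    (absorbing chromophore maturation, Fab occupancy and photoactivity),
    so the visible count is Binomial(copies_n, p_mature). Visible
    fluorophores bleach at independent exponential times, producing a
    staircase of unit-intensity drops. Complexes with zero visible
    fluorophores are flagged undetectable: dark complexes never appear as
    spots, which is why downstream stoichiometry fits condition on k >= 1.

``simulate_field``
    Renders traces as 2-D Gaussian spots (the PSF) on a noisy background,
    one movie per field, with Poisson shot noise and Gaussian read noise.

``simulate_two_channel``
    Two-color complex fields: each complex is labeled in channel A/B with
    independent probabilities, plus optional unpaired free molecules, a
    constant registration offset and localization jitter.

``simulate_simoa``
    Digital-ELISA bead populations: captured enzyme labels are scattered
    uniformly over beads (Poisson per bead in the large-number limit);
    beads loaded into wells read "on" iff they carry >= 1 enzyme.

Every generator returns a :class:`GroundTruth` whose tables have exactly
one record per simulated observable, and is bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .detect import SpotSet
from .errors import ParameterError, PlacementError
from .params import FieldParams, PhotophysicsParams, SimoaSimParams, TwoChannelParams
from .simoa import SimoaRun


@dataclass
class TirfStack:
    """A frames x rows x cols intensity movie with physical metadata."""

    data: np.ndarray
    pixel_size_um: float = 0.16
    frame_interval_s: float = 0.1
    channel: str = ""
    field_id: str = ""

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape


@dataclass
class TraceSet:
    """Simulated per-complex intensity time series."""

    intensities: np.ndarray           # (n_traces, n_frames)
    frame_interval_s: float
    detectable: np.ndarray            # (n_traces,) bool; True iff >=1 visible fluor

    def __len__(self) -> int:
        return self.intensities.shape[0]


@dataclass
class GroundTruth:
    """One table per simulated observable class; ``meta`` holds scalars."""

    spots: Optional[pd.DataFrame] = None       # one row per complex/spot
    traces: Optional[pd.DataFrame] = None      # one row per trace
    steps: Optional[pd.DataFrame] = None       # one row per bleach event
    pairs: Optional[pd.DataFrame] = None       # one row per two-channel complex
    beads: Optional[pd.DataFrame] = None       # one row per bead
    meta: dict = field(default_factory=dict)

    def to_csv_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("spots", "traces", "steps", "pairs", "beads"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(outdir / f"truth_{name}.csv", index=False)
        (outdir / "truth_meta.json").write_text(
            json.dumps(self.meta, indent=2, default=str))


def _bleach_schedule(pp: PhotophysicsParams, n: int, rng: np.random.Generator):
    """Visible counts and bleach times for n complexes.

    Draws copies_n exponential times per complex and masks by the matured
    count so streams are reproducible regardless of m.
    """
    m = rng.binomial(pp.copies_n, pp.p_mature, size=n)
    times = rng.exponential(1.0 / pp.bleach_rate, size=(n, pp.copies_n))
    visible = np.arange(pp.copies_n)[None, :] < m[:, None]
    return m, times, visible


def _active_counts(pp: PhotophysicsParams, times, visible) -> np.ndarray:
    """(n, n_frames) count of still-fluorescent fluorophores at frame start."""
    t_grid = np.arange(pp.n_frames) * pp.frame_interval_s
    alive = times[:, :, None] > t_grid[None, None, :]
    return (alive & visible[:, :, None]).sum(axis=1)


def _steps_table(pp: PhotophysicsParams, times, visible) -> pd.DataFrame:
    idx, fl = np.nonzero(visible)
    t = times[idx, fl]
    return pd.DataFrame({
        "trace_id": idx,
        "fluor_index": fl,
        "bleach_time_s": t,
        "bleach_frame": np.ceil(t / pp.frame_interval_s).astype(int),
        "in_movie": t < pp.n_frames * pp.frame_interval_s,
    })


def simulate_traces(pp: PhotophysicsParams, n_traces: int,
                    seed: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None
                    ) -> Tuple[TraceSet, GroundTruth]:
    """Simulate photobleaching traces with per-trace ground truth.

    Trace values are ``unit_intensity * active_count + background`` plus
    Poisson shot noise (if ``pp.shot_noise``) and Gaussian read noise.
    """
    if n_traces < 1:
        raise ParameterError("n_traces must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    m, times, visible = _bleach_schedule(pp, n_traces, rng)
    active = _active_counts(pp, times, visible)
    signal = pp.unit_intensity * active + pp.background_level
    vals = rng.poisson(signal).astype(float) if pp.shot_noise else signal.astype(float)
    if pp.read_noise_sd > 0:
        vals = vals + rng.normal(0.0, pp.read_noise_sd, size=vals.shape)
    truth_traces = pd.DataFrame({
        "trace_id": np.arange(n_traces),
        "n_fluor_visible": m,
        "detectable": m > 0,
        "n_steps_in_movie": (
            (times < pp.n_frames * pp.frame_interval_s) & visible).sum(axis=1),
    })
    truth = GroundTruth(traces=truth_traces,
                        steps=_steps_table(pp, times, visible),
                        meta={"params": pp.to_dict(), "n_traces": n_traces})
    return TraceSet(vals, pp.frame_interval_s, m > 0), truth


def _place_positions(rng: np.random.Generator, n: int, fp: FieldParams
                     ) -> np.ndarray:
    """Rejection-sample n (x, y) positions with a minimum separation."""
    lo_x, hi_x = fp.edge_margin_px, fp.cols - fp.edge_margin_px
    lo_y, hi_y = fp.edge_margin_px, fp.rows - fp.edge_margin_px
    if hi_x <= lo_x or hi_y <= lo_y:
        raise PlacementError("field too small for the requested edge margin")
    area = (hi_x - lo_x) * (hi_y - lo_y)
    if n * math.pi * fp.min_separation_px ** 2 >= 0.5 * area:
        raise PlacementError(
            "spot density too high for the requested minimum separation")
    pos = np.empty((n, 2))
    placed = 0
    attempts = 0
    max_attempts = 1000 * max(n, 1)
    min_sq = fp.min_separation_px ** 2
    while placed < n:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {n} spots with min separation "
                f"{fp.min_separation_px} px after {max_attempts} attempts")
        attempts += 1
        cand = np.array([rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)])
        if placed and (np.sum((pos[:placed] - cand) ** 2, axis=1) < min_sq).any():
            continue
        pos[placed] = cand
        placed += 1
    return pos


def _render(fp: FieldParams, pp: PhotophysicsParams, positions: np.ndarray,
            amplitudes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Render spots (rows given by amplitudes, (n_spots, n_frames)) into a movie.

    Gaussians use the amplitude convention A*exp(-r^2 / (2 sigma^2)); the
    integrated intensity of one spot is therefore 2*pi*sigma^2*A up to
    window truncation at 4.5 sigma (relative loss < 4e-5).
    """
    n_frames = amplitudes.shape[1] if amplitudes.size else pp.n_frames
    stack = np.zeros((n_frames, fp.rows, fp.cols), dtype=float)
    half = int(math.ceil(4.5 * fp.psf_sigma_px))
    for (x, y), amp in zip(positions, amplitudes):
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(cx - half, 0), min(cx + half + 1, fp.cols)
        y0, y1 = max(cy - half, 0), min(cy + half + 1, fp.rows)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        psf = np.exp(-((xx - x) ** 2 + (yy - y) ** 2)
                     / (2.0 * fp.psf_sigma_px ** 2))
        stack[:, y0:y1, x0:x1] += amp[:, None, None] * psf[None, :, :]
    stack += pp.background_level
    if pp.shot_noise:
        stack = rng.poisson(stack).astype(float)
    if pp.read_noise_sd > 0:
        stack = stack + rng.normal(0.0, pp.read_noise_sd, size=stack.shape)
    return stack


def simulate_field(fp: FieldParams, pp: PhotophysicsParams,
                   seed: Optional[int] = None,
                   rng: Optional[np.random.Generator] = None,
                   field_id: str = "0", channel: str = "chA",
                   ) -> Tuple[TirfStack, GroundTruth]:
    """Simulate one TIRF movie of photobleaching complexes with truth."""
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else fp.seed)
    n = int(fp.spot_density)
    positions = _place_positions(rng, n, fp) if n else np.empty((0, 2))
    if n:
        m, times, visible = _bleach_schedule(pp, n, rng)
        active = _active_counts(pp, times, visible)
        steps = _steps_table(pp, times, visible)
    else:
        m = np.empty(0, dtype=int)
        active = np.empty((0, pp.n_frames), dtype=int)
        steps = None
    det = m > 0
    amplitudes = pp.unit_intensity * active[det]
    stack = _render(fp, pp, positions[det], amplitudes, rng)
    truth_spots = pd.DataFrame({
        "spot_id": np.arange(n),
        "x": positions[:, 0] if n else np.empty(0),
        "y": positions[:, 1] if n else np.empty(0),
        "n_fluor_visible": m,
        "detectable": det,
        "channel": channel,
        "field_id": field_id,
    })
    truth = GroundTruth(spots=truth_spots, steps=steps,
                        meta={"field": fp.to_dict(), "photophysics": pp.to_dict(),
                              "field_id": field_id, "channel": channel})
    return TirfStack(stack, fp.pixel_size_um, pp.frame_interval_s,
                     channel=channel, field_id=field_id), truth


def _two_channel_truth(tc: TwoChannelParams, fp: FieldParams,
                       rng: np.random.Generator) -> pd.DataFrame:
    base = _place_positions(rng, tc.n_complexes, fp)
    in_a = rng.random(tc.n_complexes) < tc.p_label_A
    in_b = rng.random(tc.n_complexes) < tc.p_label_B
    dx, dy = tc.registration_offset_px
    jit = tc.jitter_px
    ja = rng.normal(0.0, jit, size=base.shape) if jit > 0 else 0.0
    jb = rng.normal(0.0, jit, size=base.shape) if jit > 0 else 0.0
    pos_a = base + ja
    pos_b = base + np.array([dx, dy]) + jb
    return pd.DataFrame({
        "complex_id": np.arange(tc.n_complexes),
        "x": base[:, 0], "y": base[:, 1],
        "in_A": in_a, "in_B": in_b,
        "x_A": pos_a[:, 0], "y_A": pos_a[:, 1],
        "x_B": pos_b[:, 0], "y_B": pos_b[:, 1],
    })


def _free_positions(tc: TwoChannelParams, fp: FieldParams,
                    rng: np.random.Generator) -> np.ndarray:
    n_free = int(math.floor(tc.independent_fraction * tc.n_complexes))
    if n_free == 0:
        return np.empty((0, 2))
    x = rng.uniform(fp.edge_margin_px, fp.cols - fp.edge_margin_px, n_free)
    y = rng.uniform(fp.edge_margin_px, fp.rows - fp.edge_margin_px, n_free)
    return np.column_stack([x, y])


def two_channel_truth_spotsets(tc: TwoChannelParams, fp: FieldParams,
                               seed: Optional[int] = None,
                               field_id: str = "0",
                               ) -> Tuple[SpotSet, SpotSet, GroundTruth]:
    """Ground-truth spot lists for both channels, without image rendering.

    Useful for testing the matching stage at large n where rendering and
    re-detecting every spot would only add localization noise that
    ``jitter_px`` already models.
    """
    rng = np.random.default_rng(seed)
    pairs = _two_channel_truth(tc, fp, rng)
    free_a = _free_positions(tc, fp, rng)
    free_b = _free_positions(tc, fp, rng)
    xa = np.concatenate([pairs.loc[pairs.in_A, "x_A"].to_numpy(), free_a[:, 0]])
    ya = np.concatenate([pairs.loc[pairs.in_A, "y_A"].to_numpy(), free_a[:, 1]])
    xb = np.concatenate([pairs.loc[pairs.in_B, "x_B"].to_numpy(), free_b[:, 0]])
    yb = np.concatenate([pairs.loc[pairs.in_B, "y_B"].to_numpy(), free_b[:, 1]])
    shape = (fp.rows, fp.cols)
    set_a = SpotSet.from_positions(xa, ya, field_id=field_id, channel="chA",
                                   field_shape=shape)
    set_b = SpotSet.from_positions(xb, yb, field_id=field_id, channel="chB",
                                   field_shape=shape)
    truth = GroundTruth(pairs=pairs,
                        meta={"two_channel": tc.to_dict(), "field": fp.to_dict(),
                              "n_free_per_channel": len(free_a)})
    return set_a, set_b, truth


def simulate_two_channel(tc: TwoChannelParams, fp: FieldParams,
                         pp_a: PhotophysicsParams, pp_b: PhotophysicsParams,
                         seed: Optional[int] = None, field_id: str = "0",
                         ) -> Tuple[TirfStack, TirfStack, GroundTruth]:
    """Render a two-color complex field into one movie per channel."""
    rng = np.random.default_rng(seed)
    pairs = _two_channel_truth(tc, fp, rng)
    free_a = _free_positions(tc, fp, rng)
    free_b = _free_positions(tc, fp, rng)
    stacks = []
    for ch, pp, col, free in (("chA", pp_a, ("x_A", "y_A"), free_a),
                              ("chB", pp_b, ("x_B", "y_B"), free_b)):
        lab = pairs["in_A" if ch == "chA" else "in_B"].to_numpy()
        pos = np.vstack([pairs.loc[lab, list(col)].to_numpy(), free])
        n = len(pos)
        if n:
            m, times, visible = _bleach_schedule(pp, n, rng)
            active = _active_counts(pp, times, visible)
            det = m > 0
            amp = pp.unit_intensity * active[det]
            data = _render(fp, pp, pos[det], amp, rng)
        else:
            data = _render(fp, pp, np.empty((0, 2)),
                           np.empty((0, pp.n_frames)), rng)
        stacks.append(TirfStack(data, fp.pixel_size_um, pp.frame_interval_s,
                                channel=ch, field_id=field_id))
    truth = GroundTruth(pairs=pairs,
                        meta={"two_channel": tc.to_dict(), "field": fp.to_dict(),
                              "n_free_per_channel": len(free_a),
                              "field_id": field_id})
    return stacks[0], stacks[1], truth


def simulate_simoa(sp: SimoaSimParams, seed: Optional[int] = None,
                   ) -> Tuple[SimoaRun, GroundTruth]:
    """Simulate one digital-ELISA bead measurement with per-bead truth."""
    if sp.concentration_molar < 0:
        raise ParameterError("concentration must be >= 0")
    rng = np.random.default_rng(seed if seed is not None else sp.seed)
    from .params import AVOGADRO
    molecules = int(round(sp.concentration_molar * sp.sample_volume_L * AVOGADRO))
    eff = sp.capture_efficiency * sp.detect_label_efficiency
    labels = int(rng.binomial(molecules, eff)) if molecules and eff > 0 else 0
    # Uniform scatter of labels over beads; per-bead counts are multinomial,
    # Poisson(labels / n_beads) in the large-n limit.
    enzymes = rng.multinomial(labels, np.full(sp.n_beads, 1.0 / sp.n_beads))
    n_loaded = min(int(rng.binomial(sp.n_beads, sp.bead_load_fraction)), sp.n_wells)
    # Beads are exchangeable, so the loaded subset is the first n_loaded.
    loaded = np.zeros(sp.n_beads, dtype=bool)
    loaded[:n_loaded] = True
    on = enzymes[:n_loaded] >= 1
    run = SimoaRun(beads_analyzed=n_loaded, beads_on=int(on.sum()))
    truth = GroundTruth(
        beads=pd.DataFrame({"bead_id": np.arange(sp.n_beads),
                            "enzymes": enzymes, "loaded": loaded}),
        meta={"params": sp.to_dict(), "total_labels": labels,
              "mean_enzymes_per_bead": labels / sp.n_beads,
              "expected_mean_enzymes_per_bead":
                  sp.expected_mean_enzymes_per_bead})
    return run, truth
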