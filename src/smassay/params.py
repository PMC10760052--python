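"""Parameter containers for simulation and analysis.

All containers are plain dataclasses that validate their invariants on
construction and round-trip losslessly through ``to_dict``/``from_dict``
(and hence through YAML/JSON configs).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Optional, Tuple

from .errors import ParameterError

#: Avogadro constant (exact, 2019 SI), molecules per mole.
AVOGADRO = 6.02214076e23


class _Validated:
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict):
        names = {f.name for f in fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ParameterError(f"{cls.__name__}: unknown fields {sorted(unknown)}")
        return cls(**d)


@dataclass
class PhotophysicsParams(_Validated):
    """Photophysics of one labeled complex.

    A complex carries ``copies_n`` fluorophore sites; each is independently
    visible (matured, labeled, photoactive) with probability ``p_mature``.
    Visible fluorophores bleach independently with a constant hazard
    ``bleach_rate`` (s^-1). The defaults describe a GFP-tagged dimer imaged
    for a two-minute movie, with the mean bleach time at one quarter of the
    movie so that nearly all steps complete in-movie.
    """

    copies_n: int = 2
    p_mature: float = 0.8
    bleach_rate: float = 1.0 / 30.0  # s^-1; mean bleach time 30 s
    unit_intensity: float = 400.0    # photons per frame per active fluorophore
    background_level: float = 20.0   # photons per pixel per frame
    read_noise_sd: float = 2.0       # counts, additive Gaussian
    frame_interval_s: float = 0.1
    n_frames: int = 1200
    shot_noise: bool = True          # Poisson noise on signal+background

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_mature <= 1.0):
            raise ParameterError(f"p_mature must be in [0, 1], got {self.p_mature}")
        if self.copies_n < 1:
            raise ParameterError(f"copies_n must be >= 1, got {self.copies_n}")
        if self.bleach_rate <= 0:
            raise ParameterError(f"bleach_rate must be > 0, got {self.bleach_rate}")
        if self.n_frames < 2:
            raise ParameterError(f"n_frames must be >= 2, got {self.n_frames}")
        for name in ("unit_intensity", "background_level", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.frame_interval_s <= 0:
            raise ParameterError("frame_interval_s must be > 0")


@dataclass
class FieldParams(_Validated):
    """Geometry of one simulated TIRF field of view."""

    rows: int = 256
    cols: int = 256
    pixel_size_um: float = 0.16
    psf_sigma_px: float = 1.3
    spot_density: int = 60           # complexes per field
    min_separation_px: float = 10.0
    edge_margin_px: float = 10.0     # keep truth away from borders
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.psf_sigma_px <= 0:
            raise ParameterError("psf_sigma_px must be > 0")
        if self.spot_density < 0:
            raise ParameterError("spot_density must be >= 0")
        if self.min_separation_px < 0:
            raise ParameterError("min_separation_px must be >= 0")
        if self.rows < 1 or self.cols < 1:
            raise ParameterError("rows and cols must be >= 1")


@dataclass
class TwoChannelParams(_Validated):
    """Generative model for two-color complex fields.

    Each of ``n_complexes`` carries a detectable label in channel A with
    probability ``p_label_A`` and in channel B with probability
    ``p_label_B``, independently; the label probabilities absorb antibody
    occupancy, fluorophore labeling efficiency and complex dissociation.
    ``independent_fraction`` adds unpaired free molecules per channel.
    """

    n_complexes: int = 60
    p_label_A: float = 1.0
    p_label_B: float = 0.62
    registration_offset_px: Tuple[float, float] = (0.0, 0.0)
    independent_fraction: float = 0.0
    jitter_px: float = 0.25          # per-channel localization jitter (SD, px)

    def __post_init__(self) -> None:
        for name in ("p_label_A", "p_label_B", "independent_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.n_complexes < 0:
            raise ParameterError("n_complexes must be >= 0")
        if self.jitter_px < 0:
            raise ParameterError("jitter_px must be >= 0")
        self.registration_offset_px = tuple(self.registration_offset_px)


@dataclass
class SimoaSimParams(_Validated):
    """Digital-ELISA bead population simulation.

    Target molecules in ``sample_volume_L`` at ``concentration_molar`` are
    captured and enzyme-labeled with the combined efficiency
    ``capture_efficiency * detect_label_efficiency`` and distributed
    uniformly over ``n_beads``, so enzymes per bead are Poisson in the
    large-number limit. A fraction ``bead_load_fraction`` of beads lands in
    the femtoliter well array (one bead per well) and is analyzed.
    """

    concentration_molar: float = 1e-13
    sample_volume_L: float = 25e-6
    n_beads: int = 500_000
    capture_efficiency: float = 0.1
    detect_label_efficiency: float = 0.1
    n_wells: int = 216_000
    bead_load_fraction: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.concentration_molar < 0:
            raise ParameterError("concentration_molar must be >= 0")
        if self.n_beads <= 0:
            raise ParameterError("n_beads must be > 0")
        for name in ("capture_efficiency", "detect_label_efficiency",
                     "bead_load_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.sample_volume_L <= 0:
            raise ParameterError("sample_volume_L must be > 0")

    @property
    def expected_mean_enzymes_per_bead(self) -> float:
        """Expected Poisson mean (enzymes per bead) implied by the inputs."""
        molecules = self.concentration_molar * self.sample_volume_L * AVOGADRO
        eff = self.capture_efficiency * self.detect_label_efficiency
        return molecules * eff / self.n_beads

    @classmethod
    def from_mean_enzymes_per_bead(cls, lam: float, **kwargs) -> "SimoaSimParams":
        """Build params whose expected enzymes-per-bead equals ``lam``.

        Solves for the concentration given the other (possibly overridden)
        fields; convenient for pinning the Poisson regime in tests.
        """
        if lam < 0:
            raise ParameterError("mean enzymes per bead must be >= 0")
        base = cls(concentration_molar=0.0, **kwargs)
        eff = base.capture_efficiency * base.detect_label_efficiency
        if lam > 0 and eff == 0:
            raise ParameterError("cannot reach a positive mean with zero efficiency")
        conc = 0.0
        if lam > 0:
            conc = lam * base.n_beads / (base.sample_volume_L * AVOGADRO * eff)
        kwargs = dict(kwargs)
        kwargs["concentration_molar"] = conc
        return cls(**kwargs)
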