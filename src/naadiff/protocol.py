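"""Acquisition protocol and diffusion-condition descriptions.

The default protocol reproduces a cardiac-gated diffusion-weighted PRESS
acquisition of the corpus callosum at 3 T: TE 110 ms, 1024 complex points at
1500 Hz spectral width, bipolar diffusion gradients (delta 22 ms, Delta 55 ms,
20 ms bipolar gap), two gradient directions expressed in the VOI frame --
[1,0,0] roughly parallel to the callosal fibers and [0,-1,1] perpendicular to
them -- each with four b-values, 48 transients per condition and an extra 48
at the strongest gradient of each direction.

Unit conventions used package-wide:

* b-values in s/mm^2, diffusivities in um^2/ms; the attenuation exponent is
  ``b * D * 1e-3``.
* Frequencies are stored in Hz relative to the carrier, which sits on the
  NAA singlet at 2.0 ppm; ``ppm = carrier_ppm + f_Hz / proton_freq_MHz``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DiffusionCondition",
    "AcquisitionProtocol",
    "default_protocol",
    "PARALLEL_B_VALUES",
    "PERPENDICULAR_B_VALUES",
]

#: b-values (s/mm^2) applied along the fiber-parallel direction [1,0,0].
PARALLEL_B_VALUES = (290.0, 890.0, 1750.0, 2860.0)
#: b-values (s/mm^2) applied along the fiber-perpendicular direction [0,-1,1].
PERPENDICULAR_B_VALUES = (650.0, 1760.0, 3460.0, 5730.0)


@dataclass(frozen=True)
class DiffusionCondition:
    """One diffusion-weighting condition: a unit gradient direction (VOI frame)
    and a b-value in s/mm^2."""

    direction: tuple[float, float, float]
    b_value: float
    role_label: str = "parallel"  # {"parallel", "perpendicular"}

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if n <= 0:
            raise ValueError("diffusion gradient direction must be nonzero")
        if abs(n - 1.0) > 1e-9:
            object.__setattr__(self, "direction", tuple(d / n))
        if self.b_value < 0:
            raise ValueError("b-value must be nonnegative")
        if self.role_label not in ("parallel", "perpendicular"):
            raise ValueError(f"unknown role label {self.role_label!r}")

    @property
    def direction_array(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing, sampling, and diffusion-weighting parameters of one DW-MRS scan."""

    echo_time_ms: float = 110.0
    n_points: int = 1024
    spectral_width_hz: float = 1500.0
    carrier_ppm: float = 2.0
    field_strength_t: float = 3.0
    proton_freq_mhz: float = 127.74
    gradient_duration_delta_ms: float = 22.0
    diffusion_time_delta_ms: float = 55.0
    bipolar_gap_ms: float = 20.0
    conditions: tuple[DiffusionCondition, ...] = ()
    n_transients_per_condition: int = 48
    extra_transients_at_max_b: int = 48

    def __post_init__(self) -> None:
        if self.n_points <= 0:
            raise ValueError("n_points must be positive")
        if self.spectral_width_hz <= 0:
            raise ValueError("spectral width must be positive")

    @property
    def dwell_time_s(self) -> float:
        return 1.0 / self.spectral_width_hz

    @property
    def time_axis_s(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dwell_time_s

    def ppm_to_hz(self, ppm: float) -> float:
        """Carrier-relative frequency (Hz) of a resonance at chemical shift `ppm`."""
        return (ppm - self.carrier_ppm) * self.proton_freq_mhz

    def hz_to_ppm(self, f_hz: float) -> float:
        return self.carrier_ppm + f_hz / self.proton_freq_mhz

    def max_b_condition_indices(self) -> list[int]:
        """Indices of the highest-b condition within each gradient direction."""
        best: dict[tuple[float, ...], int] = {}
        for i, c in enumerate(self.conditions):
            key = tuple(np.round(c.direction_array, 6))
            if key not in best or c.b_value > self.conditions[best[key]].b_value:
                best[key] = i
        return sorted(best.values())

    def transient_count(self, condition_index: int) -> int:
        n = self.n_transients_per_condition
        if condition_index in self.max_b_condition_indices():
            n += self.extra_transients_at_max_b
        return n

    def with_conditions(self, conditions) -> "AcquisitionProtocol":
        return replace(self, conditions=tuple(conditions))


def default_protocol() -> AcquisitionProtocol:
    """The 2-direction x 4-b-value corpus-callosum protocol with study defaults."""
    par = (1.0, 0.0, 0.0)
    perp = (0.0, -1.0, 1.0)  # normalized by DiffusionCondition
    conditions = tuple(
        [DiffusionCondition(par, b, "parallel") for b in PARALLEL_B_VALUES]
        + [DiffusionCondition(perp, b, "perpendicular") for b in PERPENDICULAR_B_VALUES]
    )
    return AcquisitionProtocol(conditions=conditions)
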