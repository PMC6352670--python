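"""UV-Vis and IR curve synthesis from transition and mode lists.

TD-DFT stick spectra become UV-Vis curves by keeping transitions below a
5.6 eV cutoff, broadening each with a Gaussian of 0.25 eV full width at
half maximum in the energy domain, and evaluating on a wavelength grid via
E(λ) = 1239.842/λ.  Following common quantum-chemistry visualization
practice no Jacobian factor is applied in the conversion (switchable).

Harmonic modes become IR curves by scaling each frequency by 0.9547 and
broadening with a 20 cm⁻¹ FWHM Gaussian on a wavenumber grid.

Amplitudes are in arbitrary units proportional to oscillator strength or
IR intensity; vibronic structure is not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EV_NM",
    "SpectrumCurve",
    "uv_spectrum",
    "ir_spectrum",
]

#: eV <-> nm conversion constant: E[eV] = EV_NM / lambda[nm].
EV_NM = 1239.842

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class SpectrumCurve:
    """A broadened intensity curve on an explicit axis grid.

    ``axis`` is strictly monotone (nm for UV-Vis, cm⁻¹ for IR);
    ``intensity`` is nonnegative and aligned to it; ``metadata`` records
    the exact broadening parameters applied.
    """

    axis: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if axis.ndim != 1 or axis.size == 0:
            raise ValueError("axis must be a nonempty 1-D grid")
        diffs = np.diff(axis)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("axis must be strictly monotone")
        if intensity.shape != axis.shape:
            raise ValueError("intensity must align with axis")
        if np.any(intensity < 0):
            raise ValueError("intensity must be nonnegative")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)

    def peak_position(self) -> float:
        """Axis value of the global intensity maximum."""
        return float(self.axis[int(np.argmax(self.intensity))])


def _gaussian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm * _FWHM_TO_SIGMA
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def uv_spectrum(
    transitions: Sequence[tuple[float, float]],
    cutoff_ev: float = 5.6,
    width_ev: float = 0.25,
    grid_nm: np.ndarray | None = None,
    jacobian: bool = False,
) -> SpectrumCurve:
    """UV-Vis curve from (excitation energy eV, oscillator strength) lines.

    Transitions at or above ``cutoff_ev`` are excluded.  Each retained line
    contributes a Gaussian in the energy domain with amplitude proportional
    to its oscillator strength, evaluated at E(λ); with ``jacobian=True``
    the E²/EV_NM wavelength-density factor is applied instead.

    Default grid: 200-1400 nm in 1 nm steps.
    """
    for energy, strength in transitions:
        if strength < 0:
            raise ValueError(f"negative oscillator strength {strength} at {energy} eV")
    axis = np.arange(200.0, 1400.0 + 0.5, 1.0) if grid_nm is None else np.asarray(grid_nm, float)
    if axis.size == 0:
        raise ValueError("empty wavelength grid")
    energy_axis = EV_NM / axis
    intensity = np.zeros_like(axis)
    kept = [(e, f) for e, f in transitions if e < cutoff_ev]
    for energy, strength in kept:
        contrib = strength * _gaussian(energy_axis, energy, width_ev)
        if jacobian:
            contrib = contrib * energy_axis**2 / EV_NM
        intensity += contrib
    return SpectrumCurve(
        axis=axis,
        intensity=intensity,
        metadata={
            "kind": "uv-vis",
            "cutoff_ev": cutoff_ev,
            "width_ev_fwhm": width_ev,
            "jacobian": jacobian,
            "n_lines_used": len(kept),
        },
    )


def ir_spectrum(
    modes: Sequence[tuple[float, float]],
    scale: float = 0.9547,
    width_cm: float = 20.0,
    grid_cm: np.ndarray | None = None,
) -> SpectrumCurve:
    """IR curve from (harmonic frequency cm⁻¹, intensity) modes.

    Each frequency is multiplied by ``scale`` (default 0.9547, the
    empirical harmonic-frequency correction) and broadened with a Gaussian
    of ``width_cm`` FWHM.  Default grid: 400-2000 cm⁻¹ in 1 cm⁻¹ steps.
    """
    for freq, inten in modes:
        if inten < 0:
            raise ValueError(f"negative IR intensity {inten} at {freq} cm^-1")
    axis = np.arange(400.0, 2000.0 + 0.5, 1.0) if grid_cm is None else np.asarray(grid_cm, float)
    if axis.size == 0:
        raise ValueError("empty wavenumber grid")
    intensity = np.zeros_like(axis)
    for freq, inten in modes:
        intensity += inten * _gaussian(axis, scale * freq, width_cm)
    return SpectrumCurve(
        axis=axis,
        intensity=intensity,
        metadata={
            "kind": "ir",
            "scale": scale,
            "width_cm_fwhm": width_cm,
            "n_modes": len(modes),
        },
    )
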