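"""Static photoelectron spectra from Dyson norms and state energies.

Each ionization channel i -> alpha contributes a stick at its binding energy
dE = V_alpha - V_i with amplitude W = dE * (Dyson norm), the oscillator-
strength-like measure of the channel yield.  Sticks are broadened with
unit-area Gaussians of a given FWHM, components (tautomers) are mixed with
normalised weights, and ensembles of sampled geometries are averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .wavefunctions import CIState

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: default binding-energy axis: 0-14 eV in 0.01 eV steps
DEFAULT_GRID = (0.0, 14.0, 0.01)


class GridMismatchError(ValueError):
    """Spectra on different grids cannot be combined without resampling."""


@dataclass
class IonizationChannel:
    """One ionization channel with binding energy and amplitude."""

    source: str
    ion: str
    binding_energy: float  # eV, V_alpha - V_i
    dyson_norm: float
    amplitude: float
    closed: bool


@dataclass
class SpectrumGrid:
    """Intensity on a uniform energy axis (binding or kinetic energy)."""

    energies: np.ndarray
    intensity: np.ndarray
    axis_kind: str = "binding"  # or "kinetic"
    metadata: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.energies.shape != self.intensity.shape:
            raise ValueError("energy and intensity shapes differ")
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite intensity")

    def normalized(self) -> "SpectrumGrid":
        """Copy scaled to maximum height 1 (presentation option)."""
        peak = float(self.intensity.max())
        scale = 1.0 / peak if peak > 0 else 1.0
        return SpectrumGrid(
            energies=self.energies.copy(),
            intensity=self.intensity * scale,
            axis_kind=self.axis_kind,
            metadata={**self.metadata, "normalized": True},
            warnings=list(self.warnings),
        )


def energy_grid(spec=DEFAULT_GRID) -> np.ndarray:
    """Uniform energy axis from an (emin, emax, step) triple or an array."""
    if isinstance(spec, np.ndarray):
        return np.asarray(spec, dtype=float)
    emin, emax, step = spec
    n = int(round((emax - emin) / step)) + 1
    return emin + step * np.arange(n)


def channel_amplitude(norm: float, dE: float) -> float:
    """Channel amplitude W = dE * norm; closed channels (dE < 0) give 0."""
    if norm < 0:
        raise ValueError("Dyson norm must be non-negative")
    if dE < 0:
        return 0.0
    return dE * norm


def make_channel(source: CIState, ion: CIState, norm: float) -> IonizationChannel:
    dE = ion.energy - source.energy
    return IonizationChannel(
        source=source.label,
        ion=ion.label,
        binding_energy=dE,
        dyson_norm=norm,
        amplitude=channel_amplitude(norm, dE),
        closed=dE < 0,
    )


def stick_spectrum(
    source: CIState,
    ions: list[CIState],
    norms: dict[str, float],
    shift: float = 0.0,
) -> list[tuple[float, float]]:
    """Sticks (binding energy, amplitude) for all open channels of a source.

    ``norms`` maps ion labels to Dyson norms; every requested ion state must
    be present.  ``shift`` is a global additive binding-energy correction
    (eV) applied to the stick positions.  Closed channels (ion below source)
    are omitted.
    """
    missing = [ion.label for ion in ions if ion.label not in norms]
    if missing:
        raise KeyError(f"missing Dyson norms for channels: {missing}")
    sticks = []
    for ion in ions:
        ch = make_channel(source, ion, norms[ion.label])
        if ch.closed:
            continue
        sticks.append((ch.binding_energy + shift, ch.amplitude))
    return sticks


def broaden(
    sticks: list[tuple[float, float]],
    grid=DEFAULT_GRID,
    fwhm: float = 0.2,
    axis_kind: str = "binding",
) -> SpectrumGrid:
    """Convolve a stick spectrum with unit-area Gaussians of the given FWHM.

    The trapezoid-integrated intensity equals the summed stick heights when
    the grid covers every stick by at least five standard deviations; a
    warning is attached otherwise.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    e = energy_grid(grid)
    sigma = fwhm * FWHM_TO_SIGMA
    intensity = np.zeros_like(e)
    warnings = []
    for pos, height in sticks:
        if pos - 5 * sigma < e[0] or pos + 5 * sigma > e[-1]:
            warnings.append(
                f"stick at {pos:.3f} eV not covered by grid within 5 sigma"
            )
        intensity += height * np.exp(-0.5 * ((e - pos) / sigma) ** 2)
    intensity /= sigma * math.sqrt(2.0 * math.pi)
    return SpectrumGrid(
        energies=e,
        intensity=intensity,
        axis_kind=axis_kind,
        metadata={"fwhm": fwhm, "n_sticks": len(sticks)},
        warnings=warnings,
    )


def mix_components(
    spectra: list[SpectrumGrid],
    weights: list[float],
    labels: list[str] | None = None,
) -> SpectrumGrid:
    """Weighted mixture of component spectra on a common grid.

    Weights are normalised to unit sum; the raw weights are recorded in the
    result metadata.  Grids must agree exactly -- no silent resampling.
    """
    if len(spectra) != len(weights):
        raise ValueError("one weight per spectrum required")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be non-negative")
    total = sum(weights)
    if total == 0:
        raise ValueError("weights must not all be zero")
    ref = spectra[0]
    for s in spectra[1:]:
        if s.energies.shape != ref.energies.shape or not np.array_equal(
            s.energies, ref.energies
        ):
            raise GridMismatchError("component spectra are on different grids")
    intensity = np.zeros_like(ref.intensity)
    for s, w in zip(spectra, weights):
        intensity += (w / total) * s.intensity
    return SpectrumGrid(
        energies=ref.energies.copy(),
        intensity=intensity,
        axis_kind=ref.axis_kind,
        metadata={
            "raw_weights": list(weights),
            "labels": labels,
            "fractions": [w / total for w in weights],
        },
    )


def classify_bright_dark(
    states: list[CIState],
    dipole_norms: list[float],
    rel_tol: float = 0.05,
) -> dict:
    """Assign bright/dark character from transition dipole norms to S0.

    The candidate with the largest transition-dipole norm is labelled
    ``"pipi*"`` (bright), the other considered state ``"npi*"`` (dark).  If
    the two largest norms agree within ``rel_tol`` relative, the lower state
    index is taken as bright and a ``mixed`` flag is set.
    """
    if len(states) < 2 or len(dipole_norms) != len(states):
        raise ValueError("need >= 2 candidate states with one dipole norm each")
    order = sorted(range(len(states)), key=lambda i: (-dipole_norms[i], i))
    top, second = order[0], order[1]
    mixed = False
    if dipole_norms[top] > 0 and (
        (dipole_norms[top] - dipole_norms[second]) / dipole_norms[top] <= rel_tol
    ):
        mixed = True
        bright = min(top, second)
    else:
        bright = top
    dark = second if bright == top else top
    return {
        "pipi*": states[bright].label,
        "npi*": states[dark].label,
        "mixed": mixed,
    }


def ensemble_spectrum(
    stick_lists: list[list[tuple[float, float]]],
    grid=DEFAULT_GRID,
    fwhm: float = 0.2,
) -> SpectrumGrid:
    """Average spectrum over sampled geometries.

    Sticks are pooled with weight 1/N_geometries and broadened once; by
    linearity this equals the mean of the per-geometry broadened spectra.
    """
    if not stick_lists:
        raise ValueError("need at least one geometry")
    n = len(stick_lists)
    pooled = [(pos, h / n) for sticks in stick_lists for pos, h in sticks]
    out = broaden(pooled, grid=grid, fwhm=fwhm)
    out.metadata["n_geometries"] = n
    return out


def write_spectrum(path: str, spectrum: SpectrumGrid, delimiter: str = "\t") -> None:
    """Two-column text (energy eV, intensity) with a JSON metadata sidecar."""
    import json

    np.savetxt(
        path,
        np.column_stack([spectrum.energies, spectrum.intensity]),
        delimiter=delimiter,
        header=f"{spectrum.axis_kind}_energy_eV{delimiter}intensity",
    )
    sidecar = {
        "axis_kind": spectrum.axis_kind,
        "metadata": spectrum.metadata,
        "warnings": spectrum.warnings,
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
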