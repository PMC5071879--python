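"""Harmonic ground-state Wigner sampling of nuclear geometries and momenta.

The vibrational ground state of a harmonic mode has the Wigner function
W(q, p) = (1/pi) exp(-q^2 - p^2) in dimensionless normal coordinates, i.e.
q and p are independent zero-mean Gaussians with variance 1/2.  Sampled
dimensionless coordinates are mapped back to Cartesian displacements via the
mass-weighted normal modes; the characteristic length of mode k is
sqrt(hbar / omega_k) in mass-weighted coordinates.

Zero-point symmetry implies <q^2> = <p^2> = 1/2, so each mode carries on
average hbar*omega/2 of energy, split evenly between potential and kinetic
parts (virial).  Only 0 K sampling is provided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

# physical constants (SI)
_HBAR = 1.054571817e-34  # J s
_AMU = 1.66053906660e-27  # kg
_C_CM = 2.99792458e10  # cm / s
_M_TO_ANG = 1e10

#: modes below this wavenumber are treated as translations/rotations
ZERO_MODE_THRESHOLD_CM1 = 10.0


class ModeExclusionError(ValueError):
    """A mode with imaginary/near-zero frequency was requested for sampling."""


@dataclass
class HarmonicModel:
    """Harmonic vibrational model of a molecule.

    Parameters
    ----------
    geometry:
        Equilibrium Cartesian coordinates, shape (n_atoms, 3), Angstrom.
    masses:
        Atomic masses, shape (n_atoms,), amu.
    frequencies:
        Harmonic wavenumbers, shape (n_modes,), cm^-1.
    modes:
        Mass-weighted normal-mode displacement vectors, shape
        (n_modes, n_atoms, 3), orthonormal in mass-weighted coordinates.
    symbols:
        Optional element symbols for XYZ output.
    """

    geometry: np.ndarray
    masses: np.ndarray
    frequencies: np.ndarray
    modes: np.ndarray
    symbols: list[str] | None = None

    def __post_init__(self) -> None:
        self.geometry = np.asarray(self.geometry, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.modes = np.asarray(self.modes, dtype=float)
        n_atoms = self.geometry.shape[0]
        if self.geometry.shape != (n_atoms, 3):
            raise ValueError("geometry must be (n_atoms, 3)")
        if self.masses.shape != (n_atoms,):
            raise ValueError("one mass per atom required")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.modes.shape != (len(self.frequencies), n_atoms, 3):
            raise ValueError("modes must be (n_modes, n_atoms, 3)")
        flat = self.modes.reshape(len(self.frequencies), -1)
        gram = flat @ flat.T
        if len(self.frequencies) and not np.allclose(
            gram, np.eye(len(self.frequencies)), atol=1e-6
        ):
            raise ValueError("modes must be orthonormal in mass-weighted coordinates")

    @property
    def n_atoms(self) -> int:
        return self.geometry.shape[0]


def _mode_length_angstrom(freq_cm1: np.ndarray) -> np.ndarray:
    """sqrt(hbar / omega) per mode, in Angstrom * sqrt(amu)."""
    omega = 2.0 * np.pi * _C_CM * freq_cm1  # s^-1
    return np.sqrt(_HBAR / (_AMU * omega)) * _M_TO_ANG


def wigner_sample(
    model: HarmonicModel,
    n: int,
    seed: int,
    include_momenta: bool = True,
    zero_mode_threshold: float = ZERO_MODE_THRESHOLD_CM1,
    skip_low_modes: bool = False,
) -> dict:
    """Draw geometries (and momenta) from the ground-state Wigner function.

    Per mode, the dimensionless coordinate Q and conjugate momentum P are
    independent N(0, 1/2) variables; Cartesian displacements follow from the
    mass-weighted modes.  Results are reproducible per seed.

    Returns a dict with keys ``geometries`` (n, n_atoms, 3) in Angstrom,
    ``momenta`` (n, n_atoms, 3) in amu * Angstrom / fs (or None),
    ``Q``/``P`` the dimensionless samples (n, n_modes), and ``modes_used``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    freqs = model.frequencies
    low = freqs <= zero_mode_threshold
    if np.any(low) and not skip_low_modes:
        bad = np.where(low)[0].tolist()
        raise ModeExclusionError(
            f"modes {bad} have wavenumbers <= {zero_mode_threshold} cm^-1; "
            "pass skip_low_modes=True to exclude them"
        )
    used = ~low
    freqs_used = freqs[used]
    modes_used = model.modes[used]
    k = len(freqs_used)

    rng = np.random.default_rng(seed)
    sigma = np.sqrt(0.5)
    q = rng.normal(0.0, sigma, size=(n, k))
    p = rng.normal(0.0, sigma, size=(n, k))

    # Cartesian displacement: dx_i = sum_k L_{k,i} * Q_k * sqrt(hbar/omega_k) / sqrt(m_i)
    length = _mode_length_angstrom(freqs_used)  # Angstrom sqrt(amu)
    inv_sqrt_m = 1.0 / np.sqrt(model.masses)[None, :, None]
    disp_basis = modes_used * length[:, None, None] * inv_sqrt_m  # (k, atoms, 3)
    geometries = model.geometry[None] + np.einsum("nk,kij->nij", q, disp_basis)

    momenta = None
    if include_momenta:
        # Cartesian momentum: p_i = sum_k sqrt(m_i) L_{k,i} P_k sqrt(hbar*omega_k)
        omega = 2.0 * np.pi * _C_CM * freqs_used  # s^-1
        p_scale = np.sqrt(_HBAR * _AMU * omega)  # kg m/s per sqrt(amu)
        # convert kg m/s -> amu Angstrom / fs:  / (amu) * 1e10 * 1e-15
        p_scale_amu = p_scale / _AMU * _M_TO_ANG * 1e-15
        sqrt_m = np.sqrt(model.masses)[None, :, None]
        mom_basis = modes_used * p_scale_amu[:, None, None] * sqrt_m
        momenta = np.einsum("nk,kij->nij", p, mom_basis)

    return {
        "geometries": geometries,
        "momenta": momenta,
        "Q": q,
        "P": p,
        "modes_used": np.where(used)[0],
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_harmonic_model(path: str) -> HarmonicModel:
    """Read a harmonic model from its JSON schema.

    Keys: ``geometry`` [[x,y,z]...] (Angstrom), ``masses`` (amu),
    ``frequencies`` (cm^-1), ``modes`` (n_modes x n_atoms x 3, mass-weighted
    orthonormal), optional ``symbols``.
    """
    with open(path) as fh:
        payload = json.load(fh)
    return HarmonicModel(
        geometry=np.array(payload["geometry"], dtype=float),
        masses=np.array(payload["masses"], dtype=float),
        frequencies=np.array(payload["frequencies"], dtype=float),
        modes=np.array(payload["modes"], dtype=float),
        symbols=payload.get("symbols"),
    )


def write_xyz(path: str, model: HarmonicModel, geometries: np.ndarray) -> None:
    """Multi-structure XYZ file of sampled geometries."""
    symbols = model.symbols or ["X"] * model.n_atoms
    with open(path, "w") as fh:
        for idx, geom in enumerate(geometries):
            fh.write(f"{model.n_atoms}\n")
            fh.write(f"wigner sample {idx}\n")
            for sym, (x, y, z) in zip(symbols, geom):
                fh.write(f"{sym} {x:.8f} {y:.8f} {z:.8f}\n")


def write_momenta(path: str, momenta: np.ndarray, delimiter: str = "\t") -> None:
    """Momenta (amu * Angstrom / fs) as delimiter-separated text, one row per
    (sample, atom)."""
    n, n_atoms, _ = momenta.shape
    with open(path, "w") as fh:
        fh.write(f"sample{delimiter}atom{delimiter}px{delimiter}py{delimiter}pz\n")
        for i in range(n):
            for a in range(n_atoms):
                px, py, pz = momenta[i, a]
                fh.write(
                    f"{i}{delimiter}{a}{delimiter}{px:.10e}{delimiter}"
                    f"{py:.10e}{delimiter}{pz:.10e}\n"
                )
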