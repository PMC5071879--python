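"""Synthetic fixtures: toy CI systems and trajectory ensembles.

Everything the other modules consume can be generated here without external
data: random CI wavefunction pairs (n and n-1 electrons) in one of three
orbital-overlap regimes, complete ionic determinant families for sum-rule
checks, small harmonic models, and surface-hopping-like trajectory ensembles
whose pathway populations decay with known exponential lifetimes.

The ensemble generator emulates the structure of a non-adiabatic dynamics
trajectory set: each trajectory starts in the bright pipi* state, hops to
the dark npi* state after an exponentially distributed delay, and leaves the
excited manifold at a terminal event time drawn from the exponential of its
pathway lifetime, after which only closed channels remain (binding energy
above the probe) and the trajectory stops contributing signal.  By default
event times are drawn by stratified inverse-CDF sampling (marginals remain
exponential; ensemble-level fluctuations shrink), which keeps small demo
ensembles statistically stable; plain i.i.d. draws are a switch away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .dyson import OrbitalOverlap, build_orbital_overlap
from .trpes import ChannelSeries, TrajectoryRecord
from .wavefunctions import CIState, Determinant, SpinOrbitalBasis

OVERLAP_REGIMES = ("identical-orbitals", "rotated-orbitals", "random-SPD-AO")


@dataclass
class ToySystemSpec:
    """Specification of a random toy CI system for Dyson-norm tests."""

    n_spatial: int
    n_electrons: int
    n_source_terms: int = 4
    n_ion_states: int = 3
    n_ion_terms: int = 4
    full_ci_ion: bool = False
    overlap_regime: str = "identical-orbitals"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_electrons < 1 or self.n_electrons > 2 * self.n_spatial:
            raise ValueError("infeasible electron count")
        if self.n_electrons - 1 > 2 * self.n_spatial:
            raise ValueError("ion occupation infeasible")
        if self.n_source_terms < 1 or self.n_ion_terms < 1 or self.n_ion_states < 1:
            raise ValueError("expansion sizes must be >= 1")
        if self.overlap_regime not in OVERLAP_REGIMES:
            raise ValueError(f"unknown overlap regime {self.overlap_regime!r}")


def _determinant_sector(n_spatial: int, n_electrons: int, ms2: int) -> list[tuple[int, ...]]:
    """All normal-form determinants with a given 2*M_S."""
    n_alpha2 = n_electrons + ms2
    if n_alpha2 % 2:
        return []
    n_alpha = n_alpha2 // 2
    n_beta = n_electrons - n_alpha
    if not (0 <= n_alpha <= n_spatial and 0 <= n_beta <= n_spatial):
        return []
    out = []
    for alpha in combinations(range(n_spatial), n_alpha):
        for beta in combinations(range(n_spatial), n_beta):
            out.append(tuple(alpha) + tuple(n_spatial + b for b in beta))
    return out


def _random_state(
    rng: np.random.Generator,
    basis: SpinOrbitalBasis,
    pool: list[tuple[int, ...]],
    n_terms: int,
    energy: float,
    label: str,
) -> CIState:
    n_terms = min(n_terms, len(pool))
    chosen = rng.choice(len(pool), size=n_terms, replace=False)
    coeffs = rng.normal(size=n_terms)
    coeffs /= np.linalg.norm(coeffs)
    terms = sorted(
        ((Determinant(pool[i]), float(c)) for i, c in zip(chosen, coeffs)),
        key=lambda t: t[0].occupied,
    )
    n_el = len(pool[0])
    mult = (n_el % 2) + 1
    return CIState(
        basis=basis,
        n_electrons=n_el,
        multiplicity=mult,
        energy=energy,
        terms=terms,
        label=label,
    )


def _orthonormalize(c: np.ndarray, metric: np.ndarray) -> np.ndarray:
    """Loewdin orthonormalisation of MO columns under an AO metric."""
    g = c.T @ metric @ c
    vals, vecs = np.linalg.eigh(g)
    inv_sqrt = vecs @ np.diag(vals**-0.5) @ vecs.T
    return c @ inv_sqrt


def make_toy_system(spec: ToySystemSpec) -> tuple[CIState, list[CIState], OrbitalOverlap]:
    """Random normalized source state, ionic state family, and MO overlap.

    With ``full_ci_ion`` the ionic family is the complete orthonormal
    determinant basis of the (n-1)-electron space (every M_S sector), which
    enables the completeness sum-rule check Sum_alpha ||phi^D||^2 = n.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.n_spatial
    n = spec.n_electrons
    src_basis = SpinOrbitalBasis("toy-source", m)
    ion_basis = SpinOrbitalBasis("toy-ion", m)

    if spec.overlap_regime == "identical-orbitals":
        overlap = OrbitalOverlap(np.eye(m), src_basis, ion_basis)
    elif spec.overlap_regime == "rotated-orbitals":
        q, _ = np.linalg.qr(rng.normal(size=(m, m)))
        overlap = OrbitalOverlap(q, src_basis, ion_basis)
    else:  # random-SPD-AO
        b = rng.normal(size=(m, m))
        s_ao = b @ b.T + 0.5 * np.eye(m)
        c_src = _orthonormalize(rng.normal(size=(m, m)), s_ao)
        c_ion = _orthonormalize(rng.normal(size=(m, m)), s_ao)
        overlap = build_orbital_overlap(c_src, c_ion, s_ao, src_basis, ion_basis)

    ms2_src = n % 2
    src_pool = _determinant_sector(m, n, ms2_src)
    source = _random_state(rng, src_basis, src_pool, spec.n_source_terms, 0.0, "S")

    ions: list[CIState] = []
    if spec.full_ci_ion:
        idx = 0
        for ms2 in range(-(n - 1), n, 2):
            for occ in _determinant_sector(m, n - 1, ms2):
                ions.append(
                    CIState(
                        basis=ion_basis,
                        n_electrons=n - 1,
                        multiplicity=n % 2 + 1,
                        energy=8.0 + 0.2 * idx,
                        terms=[(Determinant(occ), 1.0)],
                        label=f"D{idx}",
                    )
                )
                idx += 1
    else:
        sectors = [ms2 for ms2 in (ms2_src - 1, ms2_src + 1)
                   if _determinant_sector(m, n - 1, ms2)]
        for k in range(spec.n_ion_states):
            pool = _determinant_sector(m, n - 1, sectors[k % len(sectors)])
            ions.append(
                _random_state(rng, ion_basis, pool, spec.n_ion_terms, 8.0 + 0.8 * k, f"D{k}")
            )
    return source, ions, overlap


# ---------------------------------------------------------------------------
# harmonic models
# ---------------------------------------------------------------------------

def make_harmonic_model(n_atoms: int = 3, seed: int = 0):
    """Random small harmonic model for exercising the Wigner sampler.

    Geometry, masses and 3N-6 orthonormal mass-weighted modes with
    wavenumbers in the 300-3000 cm^-1 range typical of molecular vibrations.
    """
    from .wigner import HarmonicModel

    rng = np.random.default_rng(seed)
    n_modes = max(1, 3 * n_atoms - 6)
    geometry = rng.normal(scale=1.2, size=(n_atoms, 3))
    masses = rng.choice([1.008, 12.011, 14.007, 15.999], size=n_atoms)
    q, _ = np.linalg.qr(rng.normal(size=(3 * n_atoms, 3 * n_atoms)))
    modes = q[:, :n_modes].T.reshape(n_modes, n_atoms, 3)
    frequencies = np.sort(rng.uniform(300.0, 3000.0, size=n_modes))
    return HarmonicModel(
        geometry=geometry,
        masses=masses,
        frequencies=frequencies,
        modes=modes,
        symbols=["X"] * n_atoms,
    )


# ---------------------------------------------------------------------------
# trajectory ensembles
# ---------------------------------------------------------------------------

@dataclass
class PathwaySpec:
    """One deactivation pathway: label, lifetime and population fraction."""

    label: str
    tau_fs: float
    fraction: float

    def __post_init__(self) -> None:
        if self.tau_fs <= 0:
            raise ValueError("pathway lifetime must be positive")
        if self.fraction < 0:
            raise ValueError("pathway fraction must be non-negative")


@dataclass
class EnsembleSpec:
    """Specification of a synthetic trajectory ensemble.

    The default electronic template has three neutral states -- the bright
    pipi* (V = 4.6 eV), the dark npi* (V = 4.3 eV) and the ground state
    (V = 0) -- and a single ionic state D0 at 8.6 eV, so that the excited
    states ionize with binding energies of 4.0 / 4.3 eV (open at a 5.4 eV
    probe) while the ground state's 8.6 eV channel is closed, emulating the
    loss of signal after internal conversion.
    """

    pathways: list[PathwaySpec]
    n_trajectories: int
    dt_fs: float = 5.0
    t_total_fs: float = 1400.0
    tautomer: str = "enol"
    seed: int = 0
    hop_tau_fs: float = 40.0
    mixing_ramp_fs: float = 0.0
    stratified: bool = True
    state_energies: dict[str, float] = field(
        default_factory=lambda: {"S0": 0.0, "pipi*": 4.6, "npi*": 4.3}
    )
    channels: list[tuple[str, str, float, float]] = field(
        default_factory=lambda: [
            ("pipi*", "D0", 8.6, 0.8),
            ("npi*", "D0", 8.6, 0.7),
            ("S0", "D0", 8.6, 0.9),
        ]
    )

    def __post_init__(self) -> None:
        total = sum(p.fraction for p in self.pathways)
        if not self.pathways or total <= 0:
            raise ValueError("pathway fractions must sum to a positive value")
        if abs(total - 1.0) > 1e-9:
            raise ValueError("pathway fractions must sum to 1")
        if self.n_trajectories < 1:
            raise ValueError("need at least one trajectory")
        n_steps = self.t_total_fs / self.dt_fs
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("stride must divide the total time")


def _allocate(fractions: list[float], n: int) -> list[int]:
    """Largest-remainder allocation of n trajectories to pathway fractions."""
    raw = [f * n for f in fractions]
    counts = [int(math.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _draw_exponential(
    rng: np.random.Generator, tau: float, size: int, stratified: bool
) -> np.ndarray:
    if not stratified:
        return rng.exponential(tau, size=size)
    u = (rng.permutation(size) + rng.uniform(size=size)) / size
    return -tau * np.log1p(-u)


def _crossfade(t: np.ndarray, t_switch: float, ramp: float) -> np.ndarray:
    """Weight of the post-switch state: step or linear ramp of width ramp."""
    if ramp <= 0:
        return (t >= t_switch).astype(float)
    return np.clip((t - (t_switch - ramp / 2)) / ramp, 0.0, 1.0)


def simulate_ensemble(spec: EnsembleSpec) -> list[TrajectoryRecord]:
    """Generate a trajectory ensemble with known pathway lifetimes.

    Each trajectory is assigned a pathway (deterministic largest-remainder
    allocation by fraction), a pipi* -> npi* hop time ~ Exp(hop_tau), and a
    terminal excited-state event time ~ Exp(tau_pathway) measured from t=0,
    so the pathway's excited-state survival -- and hence its ionization
    yield -- decays exponentially with exactly the specified lifetime.
    After the terminal event the trajectory sits in the ground state, whose
    only channel is closed.
    """
    rng = np.random.default_rng(spec.seed)
    n_steps = int(round(spec.t_total_fs / spec.dt_fs)) + 1
    times = spec.dt_fs * np.arange(n_steps)

    counts = _allocate([p.fraction for p in spec.pathways], spec.n_trajectories)
    records: list[TrajectoryRecord] = []
    traj_no = 0
    for pathway, count in zip(spec.pathways, counts):
        if count == 0:
            continue
        terminal = _draw_exponential(rng, pathway.tau_fs, count, spec.stratified)
        hops = rng.exponential(spec.hop_tau_fs, size=count)
        for j in range(count):
            t_term = float(terminal[j])
            t_hop = min(float(hops[j]), t_term)
            ground = _crossfade(times, t_term, spec.mixing_ramp_fs)
            hopped = _crossfade(times, t_hop, spec.mixing_ramp_fs)
            w_s0 = ground
            w_npi = (1.0 - ground) * hopped
            w_pipi = (1.0 - ground) * (1.0 - hopped)
            weights = {"S0": w_s0, "npi*": w_npi, "pipi*": w_pipi}
            energies = {
                s: np.full(n_steps, v) for s, v in spec.state_energies.items()
            }
            channels = [
                ChannelSeries(
                    source=src,
                    ion=ion,
                    v_ion=np.full(n_steps, v_ion),
                    norm=np.full(n_steps, norm),
                )
                for src, ion, v_ion, norm in spec.channels
            ]
            records.append(
                TrajectoryRecord(
                    traj_id=f"{spec.tautomer}-{pathway.label}-{traj_no:04d}",
                    tautomer=spec.tautomer,
                    pathway=pathway.label,
                    times=times.copy(),
                    weights=weights,
                    energies=energies,
                    channels=channels,
                )
            )
            traj_no += 1
    return records


def demo_ensemble_spec(
    n_per_pathway: int = 100, seed: int = 0, tautomer: str = "enol"
) -> EnsembleSpec:
    """The shipped demo ensemble: three pathways with well-separated
    lifetimes spanning tens of femtoseconds to ~1.3 ps."""
    pathways = [
        PathwaySpec("CI-fast", 60.0, 1 / 3),
        PathwaySpec("CI-mid", 300.0, 1 / 3),
        PathwaySpec("ISC-slow", 1300.0, 1 / 3),
    ]
    return EnsembleSpec(
        pathways=pathways,
        n_trajectories=3 * n_per_pathway,
        seed=seed,
        tautomer=tautomer,
    )
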