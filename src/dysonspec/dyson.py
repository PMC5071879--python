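"""Dyson orbitals and norms between CI states in non-orthogonal MO sets.

The Dyson orbital of an ionization channel i -> alpha is the one-electron
overlap between an n-electron source state and an (n-1)-electron ionic
state, expressed here in the spin-orbital basis of the source MO set.  Its
squared norm (the "Dyson norm") is the sudden-approximation proxy for the
relative single-photon ionization probability of the channel.

Because the neutral and ionic states typically come from separate orbital
optimisations, the two MO sets are non-orthogonal; the inter-set overlap is
carried by :class:`OrbitalOverlap` (spatial orbitals only -- opposite spins
never overlap, so the spin-orbital overlap is block diagonal and every
determinant overlap factorises into an alpha and a beta sub-determinant).

The main path computes, per determinant pair, one (n-1)x(n-1) minor per
occupied source spin orbital with the annihilation phase (-1)**p counted in
the module-wide spatial-major phase convention (spatial orbitals ascending,
alpha before beta).  ``dyson_orbital_bruteforce`` re-derives the same
quantity by explicit permutation sums without spin factorisation or
screening and serves as the independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .wavefunctions import (
    CIState,
    Determinant,
    SpinOrbitalBasis,
    _permutation_parity,
    spatial_major_order,
)


class ChannelError(ValueError):
    """Electron counts of source and ion are not n and n-1."""


@dataclass
class OrbitalOverlap:
    """Spatial-orbital overlaps <source p | ion q> between two MO sets."""

    matrix: np.ndarray
    source_basis: SpinOrbitalBasis
    ion_basis: SpinOrbitalBasis

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        expected = (self.source_basis.n_spatial, self.ion_basis.n_spatial)
        if self.matrix.shape != expected:
            raise ValueError(
                f"overlap shape {self.matrix.shape} does not match bases {expected}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("overlap entries must be finite")

    def spin_orbital_matrix(self) -> np.ndarray:
        """Full spin-orbital overlap (block diagonal in spin)."""
        ms, mi = self.matrix.shape
        full = np.zeros((2 * ms, 2 * mi))
        full[:ms, :mi] = self.matrix
        full[ms:, mi:] = self.matrix
        return full


@dataclass
class DysonResult:
    """Dyson orbital coefficients over source spin orbitals, and its norm."""

    coefficients: np.ndarray
    norm: float
    channel: tuple[str, str]
    screening_threshold: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.norm < -1e-12:
            raise ValueError("negative Dyson norm")


def build_orbital_overlap(
    source_mo: np.ndarray,
    ion_mo: np.ndarray,
    ao_overlap: np.ndarray,
    source_basis: SpinOrbitalBasis | None = None,
    ion_basis: SpinOrbitalBasis | None = None,
) -> OrbitalOverlap:
    """Inter-set MO overlap  C_source^T . S_AO . C_ion.

    MO coefficient matrices are (n_AO, n_MO) with one column per spatial
    orbital; the AO overlap must be symmetric positive semi-definite.
    """
    source_mo = np.asarray(source_mo, dtype=float)
    ion_mo = np.asarray(ion_mo, dtype=float)
    s = np.asarray(ao_overlap, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("AO overlap must be square")
    if not np.allclose(s, s.T, atol=1e-10):
        raise ValueError("AO overlap must be symmetric")
    if source_mo.shape[0] != s.shape[0] or ion_mo.shape[0] != s.shape[0]:
        raise ValueError("MO coefficient rows must match AO dimension")
    matrix = source_mo.T @ s @ ion_mo
    if source_basis is None:
        source_basis = SpinOrbitalBasis("source", source_mo.shape[1])
    if ion_basis is None:
        ion_basis = SpinOrbitalBasis("ion", ion_mo.shape[1])
    return OrbitalOverlap(matrix=matrix, source_basis=source_basis, ion_basis=ion_basis)


def _block_minor_det(
    alpha_rows: list[int],
    beta_rows: list[int],
    ion_alpha: tuple[int, ...],
    ion_beta: tuple[int, ...],
    spatial: np.ndarray,
) -> float:
    """Determinant of the spin-factorised (n-1)x(n-1) overlap minor."""
    if len(alpha_rows) != len(ion_alpha) or len(beta_rows) != len(ion_beta):
        return 0.0
    det = 1.0
    if alpha_rows:
        det *= np.linalg.det(spatial[np.ix_(alpha_rows, list(ion_alpha))])
    if beta_rows:
        det *= np.linalg.det(spatial[np.ix_(beta_rows, list(ion_beta))])
    return float(det)


def determinant_pair_dyson(
    source_det: Determinant, ion_det: Determinant, overlap: OrbitalOverlap
) -> np.ndarray:
    """Dyson contribution of one determinant pair.

    Returns a vector over the source spin orbitals: for each occupied source
    spin orbital s, ``(-1)**p(s) * det(M_s)`` where p(s) counts occupied
    spin orbitals preceding s in the spatial-major phase order and M_s is the
    overlap minor between the source determinant with s removed and the ion
    determinant (rows and columns taken in that same order).  The minor
    factorises into alpha and beta sub-determinants because opposite spins do
    not overlap; the reordering parities into the spin blocks are applied
    explicitly.
    """
    if source_det.n_electrons != ion_det.n_electrons + 1:
        raise ChannelError(
            f"source has {source_det.n_electrons} electrons, ion "
            f"{ion_det.n_electrons}; expected a difference of one"
        )
    m_src = overlap.source_basis.n_spatial
    m_ion = overlap.ion_basis.n_spatial
    ion_alpha, ion_beta = ion_det.alpha_beta_split(m_ion)
    # parity bringing the ion's spatial-major column order into spin blocks
    ion_parity = _permutation_parity(ion_det.spatial_major(m_ion))
    spatial = overlap.matrix

    out = np.zeros(2 * m_src)
    sm = source_det.spatial_major(m_src)
    alpha_all = [i for i in source_det.occupied if i < m_src]
    beta_all = [i - m_src for i in source_det.occupied if i >= m_src]
    for pos, s in enumerate(sm):
        if s < m_src:
            rows_a = [i for i in alpha_all if i != s]
            rows_b = beta_all
        else:
            rows_a = alpha_all
            rows_b = [i for i in beta_all if i != s - m_src]
        row_parity = _permutation_parity(tuple(r for r in sm if r != s))
        det = _block_minor_det(rows_a, rows_b, ion_alpha, ion_beta, spatial)
        sign = (-1.0 if pos % 2 else 1.0) * row_parity * ion_parity
        out[s] = sign * det
    return out


def dyson_orbital(
    source: CIState,
    ion: CIState,
    overlap: OrbitalOverlap,
    pair_threshold: float = 1e-4,
) -> DysonResult:
    """Dyson orbital of the channel source -> ion.

    Sums ``c_a * d_b * determinant_pair_dyson(a, b)`` over all determinant
    pairs whose CI-coefficient product satisfies ``|c_a * d_b| >
    pair_threshold`` (strict).  The returned norm is the squared length of
    the coefficient vector.
    """
    if source.n_electrons != ion.n_electrons + 1:
        raise ChannelError(
            f"states {source.label!r} ({source.n_electrons} e) and {ion.label!r} "
            f"({ion.n_electrons} e) do not form an ionization channel"
        )
    if source.basis.n_spatial != overlap.source_basis.n_spatial:
        raise ValueError("source basis does not match overlap")
    if ion.basis.n_spatial != overlap.ion_basis.n_spatial:
        raise ValueError("ion basis does not match overlap")

    phi = np.zeros(2 * source.basis.n_spatial)
    for det_a, c_a in source.terms:
        if abs(c_a) * max(
            (abs(d_b) for _, d_b in ion.terms), default=0.0
        ) <= pair_threshold:
            continue
        for det_b, d_b in ion.terms:
            if not abs(c_a * d_b) > pair_threshold:
                continue
            phi += c_a * d_b * determinant_pair_dyson(det_a, det_b, overlap)
    norm = float(phi @ phi)
    return DysonResult(
        coefficients=phi,
        norm=norm,
        channel=(source.label, ion.label),
        screening_threshold=pair_threshold,
    )


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def _permsum_overlap(
    ion_occ: tuple[int, ...], src_occ: tuple[int, ...], so_overlap: np.ndarray
) -> float:
    """<ion determinant | source determinant> by explicit permutation sum.

    Leibniz expansion over all permutations; no LU factorisation and no spin
    factorisation, deliberately distinct from the main path.
    """
    n = len(src_occ)
    if len(ion_occ) != n:
        return 0.0
    if n == 0:
        return 1.0
    total = 0.0
    for perm in permutations(range(n)):
        inversions = sum(
            1 for i in range(n) for j in range(i + 1, n) if perm[i] > perm[j]
        )
        sign = -1.0 if inversions % 2 else 1.0
        prod = 1.0
        for i in range(n):
            prod *= so_overlap[src_occ[perm[i]], ion_occ[i]]
            if prod == 0.0:
                break
        total += sign * prod
    return total


def _annihilate_sm(
    occupied: tuple[int, ...], s: int, n_spatial: int
) -> tuple[tuple[int, ...], int] | None:
    """Apply a_s with the spatial-major phase: (reduced sm sequence, sign)."""
    sm = spatial_major_order(occupied, n_spatial)
    if s not in sm:
        return None
    pos = sm.index(s)
    sign = -1 if pos % 2 else 1
    return sm[:pos] + sm[pos + 1:], sign


def dyson_orbital_bruteforce(
    source: CIState,
    ion: CIState,
    overlap: OrbitalOverlap,
    max_spin_orbitals: int = 12,
) -> DysonResult:
    """Unscreened Dyson orbital by direct expansion (test oracle).

    Applies the annihilation operator explicitly to every source determinant
    and evaluates every inter-determinant overlap as a permutation sum over
    the full spin-orbital overlap matrix.  Refuses systems above
    ``max_spin_orbitals`` spin orbitals (factorial cost).
    """
    n_so = max(source.basis.n_spin_orbitals, ion.basis.n_spin_orbitals)
    if n_so > max_spin_orbitals:
        raise ValueError(
            f"{n_so} spin orbitals exceed the brute-force bound "
            f"{max_spin_orbitals}; use dyson_orbital instead"
        )
    if source.n_electrons != ion.n_electrons + 1:
        raise ChannelError("electron counts must differ by exactly one")

    so = overlap.spin_orbital_matrix()
    m_src = source.basis.n_spatial
    m_ion = ion.basis.n_spatial
    phi = np.zeros(2 * m_src)
    for s in range(2 * m_src):
        acc = 0.0
        for det_a, c_a in source.terms:
            ann = _annihilate_sm(det_a.occupied, s, m_src)
            if ann is None:
                continue
            reduced, sign = ann
            for det_b, d_b in ion.terms:
                ion_sm = spatial_major_order(det_b.occupied, m_ion)
                acc += c_a * d_b * sign * _permsum_overlap(ion_sm, reduced, so)
        phi[s] = acc
    return DysonResult(
        coefficients=phi,
        norm=float(phi @ phi),
        channel=(source.label, ion.label),
        screening_threshold=0.0,
    )
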