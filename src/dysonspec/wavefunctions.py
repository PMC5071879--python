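"""CI-type electronic wavefunctions over Slater determinants.

This module provides the bookkeeping layer for configuration-interaction
states: a fixed spin-orbital ordering convention, Slater determinants in a
phase normal form, spin-adapted configuration state functions (CSFs) with
genealogical (Yamanouchi-Kotani) coupling, and the expansion of CSF-based CI
vectors into determinant-based :class:`CIState` objects with coefficient
screening.

Conventions
-----------
Spin orbitals are indexed ``0 .. 2*n_spatial - 1``: the alpha block occupies
indices ``0 .. n_spatial - 1`` (ascending spatial index), the beta block
``n_spatial .. 2*n_spatial - 1``.  A determinant is stored as a strictly
increasing tuple of occupied spin-orbital indices.  Its *phase* refers to the
antisymmetrised product taken in spatial-major order -- spatial orbitals
ascending, alpha before beta within one spatial orbital -- so a closed-shell
determinant carries coefficient +1 and fermionic-operator phases count
occupied spin orbitals preceding in that spatial-major sequence.  Every
module shares this single convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


class CouplingError(ValueError):
    """Raised for genealogical spin-coupling vectors that are not valid."""


class SpinProjectionError(ValueError):
    """Raised when the requested M_S cannot be reached by the coupling."""


# ---------------------------------------------------------------------------
# basis and determinants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpinOrbitalBasis:
    """A named set of spatial molecular orbitals with the fixed spin ordering.

    Parameters
    ----------
    mo_set_id:
        Identifier of the MO set (e.g. ``"neutral-casscf"``); states computed
        in different MO sets must reference different ids.
    n_spatial:
        Number of spatial orbitals.  Spin orbitals number ``2 * n_spatial``.
    """

    mo_set_id: str
    n_spatial: int

    def __post_init__(self) -> None:
        if self.n_spatial < 1:
            raise ValueError("n_spatial must be >= 1")

    @property
    def n_spin_orbitals(self) -> int:
        return 2 * self.n_spatial

    def alpha(self, p: int) -> int:
        """Spin-orbital index of the alpha spin orbital on spatial orbital p."""
        self._check_spatial(p)
        return p

    def beta(self, p: int) -> int:
        """Spin-orbital index of the beta spin orbital on spatial orbital p."""
        self._check_spatial(p)
        return self.n_spatial + p

    def is_alpha(self, so: int) -> bool:
        return so < self.n_spatial

    def spatial(self, so: int) -> int:
        """Spatial orbital index of spin orbital ``so``."""
        return so if so < self.n_spatial else so - self.n_spatial

    def _check_spatial(self, p: int) -> None:
        if not 0 <= p < self.n_spatial:
            raise IndexError(f"spatial orbital {p} outside basis of {self.n_spatial}")


@dataclass(frozen=True)
class Determinant:
    """A Slater determinant in phase normal form.

    ``occupied`` is a strictly increasing tuple of spin-orbital indices in the
    module's alpha-block/beta-block ordering.
    """

    occupied: tuple[int, ...]

    def __post_init__(self) -> None:
        occ = tuple(self.occupied)
        object.__setattr__(self, "occupied", occ)
        if any(b <= a for a, b in zip(occ, occ[1:])):
            raise ValueError(f"occupied list must be strictly increasing, got {occ}")
        if occ and occ[0] < 0:
            raise ValueError("negative spin-orbital index")

    @property
    def n_electrons(self) -> int:
        return len(self.occupied)

    def alpha_beta_split(self, n_spatial: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """Occupied spatial indices of the alpha and beta blocks."""
        alpha = tuple(i for i in self.occupied if i < n_spatial)
        beta = tuple(i - n_spatial for i in self.occupied if i >= n_spatial)
        return alpha, beta

    def spatial_major(self, n_spatial: int) -> tuple[int, ...]:
        """Occupied spin orbitals in the phase-defining spatial-major order."""
        return spatial_major_order(self.occupied, n_spatial)


def spatial_major_order(occupied: Iterable[int], n_spatial: int) -> tuple[int, ...]:
    """Sort spin-orbital indices by (spatial orbital, spin), alpha first."""
    return tuple(
        sorted(occupied, key=lambda so: (so - n_spatial, 1) if so >= n_spatial else (so, 0))
    )


def _permutation_parity(seq: Sequence[int]) -> int:
    """Parity (+1/-1) of the permutation sorting ``seq`` ascending."""
    inversions = sum(
        1
        for i in range(len(seq))
        for j in range(i + 1, len(seq))
        if seq[i] > seq[j]
    )
    return -1 if inversions % 2 else 1


# ---------------------------------------------------------------------------
# CSFs and genealogical expansion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CSF:
    """A spin-adapted configuration state function.

    Parameters
    ----------
    spatial_occ:
        Tuple of ``(spatial orbital, occupancy)`` with occupancy in
        ``{1, 2}``; unoccupied orbitals are simply absent.  Orbitals must be
        distinct and are kept in ascending order.
    coupling:
        Genealogical coupling vector over the singly occupied orbitals in
        ascending orbital order: ``+1`` couples the next unpaired electron to
        raise the intermediate total spin by 1/2, ``-1`` to lower it.
    ms:
        Spin projection M_S of the expanded function (multiple of 1/2).
    """

    spatial_occ: tuple[tuple[int, int], ...]
    coupling: tuple[int, ...]
    ms: float

    def __post_init__(self) -> None:
        occ = tuple(sorted((int(p), int(o)) for p, o in self.spatial_occ))
        object.__setattr__(self, "spatial_occ", occ)
        object.__setattr__(self, "coupling", tuple(int(c) for c in self.coupling))
        orbitals = [p for p, _ in occ]
        if len(set(orbitals)) != len(orbitals):
            raise ValueError("repeated spatial orbital in CSF occupation")
        if any(o not in (1, 2) for _, o in occ):
            raise ValueError("occupancies must be 1 or 2")
        singly = self.singly_occupied
        if len(self.coupling) != len(singly):
            raise CouplingError(
                f"coupling vector length {len(self.coupling)} != number of "
                f"singly occupied orbitals {len(singly)}"
            )
        if any(c not in (+1, -1) for c in self.coupling):
            raise CouplingError("coupling steps must be +1 or -1")
        # intermediate spins must stay non-negative
        s2 = 0  # running 2*S
        for c in self.coupling:
            s2 += c
            if s2 < 0:
                raise CouplingError("intermediate spin dropped below zero")
        if abs(round(2 * self.ms) - 2 * self.ms) > 1e-12:
            raise SpinProjectionError("M_S must be a multiple of 1/2")
        if abs(2 * self.ms) > s2 + 1e-12 or (round(2 * self.ms) - s2) % 2 != 0:
            raise SpinProjectionError(
                f"M_S={self.ms} unreachable for total spin S={s2 / 2}"
            )

    @property
    def singly_occupied(self) -> tuple[int, ...]:
        return tuple(p for p, o in self.spatial_occ if o == 1)

    @property
    def doubly_occupied(self) -> tuple[int, ...]:
        return tuple(p for p, o in self.spatial_occ if o == 2)

    @property
    def n_electrons(self) -> int:
        return sum(o for _, o in self.spatial_occ)

    @property
    def total_spin(self) -> float:
        return sum(self.coupling) / 2.0


def _cg_half(s_prev2: int, m_prev2: int, m2: int, step: int) -> float:
    """Clebsch-Gordan coefficient <S' M'; 1/2 m | S M> for S = S' +- 1/2.

    All spin arguments are twice their physical value (integers).  ``step``
    is +1 for S = S' + 1/2 and -1 for S = S' - 1/2; ``m2`` is +-1.
    """
    m_tot2 = m_prev2 + m2
    if step == +1:
        if m2 == +1:
            num = s_prev2 + m_tot2 + 1
        else:
            num = s_prev2 - m_tot2 + 1
        return math.sqrt(num / (2 * (s_prev2 + 1)))
    # step == -1
    if m2 == +1:
        return -math.sqrt((s_prev2 - m_tot2 + 1) / (2 * (s_prev2 + 1)))
    return math.sqrt((s_prev2 + m_tot2 + 1) / (2 * (s_prev2 + 1)))


def expand_csf(
    csf: CSF, basis: SpinOrbitalBasis
) -> list[tuple[Determinant, float]]:
    """Expand a genealogically coupled CSF into Slater determinants.

    The expansion coefficients are products of Clebsch-Gordan coefficients
    along the coupling chain, multiplied by the parity bringing the
    spatial-major product order into the stored normal form.  The squared
    coefficients sum to one.
    """
    singly = csf.singly_occupied
    doubly = csf.doubly_occupied
    k = len(singly)
    ms2_target = round(2 * csf.ms)

    out: list[tuple[Determinant, float]] = []
    # enumerate spin assignments m_i = +-1/2 over the k open shells
    for pattern in range(1 << k) if k else (0,):
        ms = [(+1 if pattern >> i & 1 else -1) for i in range(k)]
        if sum(ms) != ms2_target:
            continue
        coeff = 1.0
        s2 = 0
        m2 = 0
        for m, step in zip(ms, csf.coupling):
            coeff *= _cg_half(s2, m2, m, step)
            s2 += step
            m2 += m
        if coeff == 0.0:
            continue
        # the genealogical product is built in spatial-major order, which is
        # exactly the phase-defining order: no reordering parity arises
        product_order: list[int] = []
        for p, occ in csf.spatial_occ:
            if occ == 2:
                product_order.append(basis.alpha(p))
                product_order.append(basis.beta(p))
            else:
                m = ms[singly.index(p)]
                product_order.append(basis.alpha(p) if m == +1 else basis.beta(p))
        det = Determinant(tuple(sorted(product_order)))
        out.append((det, coeff))

    if not out and (k or doubly):
        raise SpinProjectionError("no determinant reaches the requested M_S")
    out.sort(key=lambda t: t[0].occupied)
    return out


# ---------------------------------------------------------------------------
# CI states
# ---------------------------------------------------------------------------

@dataclass
class CIState:
    """An electronic state as a CI expansion over Slater determinants.

    ``terms`` maps determinants to real CI coefficients.  The squared norm
    may be below one after coefficient screening; screened states are never
    renormalised.
    """

    basis: SpinOrbitalBasis
    n_electrons: int
    multiplicity: int
    energy: float  # eV
    terms: list[tuple[Determinant, float]]
    label: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for det, _ in self.terms:
            if det.n_electrons != self.n_electrons:
                raise ValueError(
                    f"determinant {det.occupied} has {det.n_electrons} electrons, "
                    f"state {self.label!r} expects {self.n_electrons}"
                )
            if det.occupied and det.occupied[-1] >= self.basis.n_spin_orbitals:
                raise ValueError("determinant index outside basis")
        norm2 = self.squared_norm
        if norm2 > 1.0 + 1e-8:
            raise ValueError(f"CI squared norm {norm2} exceeds 1")

    @property
    def squared_norm(self) -> float:
        return sum(c * c for _, c in self.terms)


def decompose_ci_state(
    csf_terms: Sequence[tuple[CSF, float]],
    basis: SpinOrbitalBasis,
    energy: float,
    multiplicity: int,
    label: str = "",
    csf_threshold: float = 1e-4,
    keep_threshold: float = 0.0,
    screen_mode: str = "abs",
) -> CIState:
    """Expand a CSF-based CI vector into a determinant-based state.

    CSFs whose coefficient magnitude is not strictly above ``csf_threshold``
    are dropped before expansion; determinant terms not strictly above
    ``keep_threshold`` are dropped afterwards.  No renormalisation is applied,
    so the squared norm of the result may be below one.  ``screen_mode``
    selects whether thresholds compare against ``|c|`` (``"abs"``, default) or
    ``c**2`` (``"square"``).
    """
    if csf_threshold < 0 or keep_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    if screen_mode not in ("abs", "square"):
        raise ValueError("screen_mode must be 'abs' or 'square'")

    def measure(c: float) -> float:
        return abs(c) if screen_mode == "abs" else c * c

    n_el = None
    acc: dict[tuple[int, ...], float] = {}
    for csf, coeff in csf_terms:
        if not math.isfinite(coeff):
            raise ValueError("non-finite CSF coefficient")
        if n_el is None:
            n_el = csf.n_electrons
        elif csf.n_electrons != n_el:
            raise ValueError("CSFs with inconsistent electron counts")
        if not measure(coeff) > csf_threshold:
            continue
        for det, c in expand_csf(csf, basis):
            acc[det.occupied] = acc.get(det.occupied, 0.0) + coeff * c

    terms = [
        (Determinant(occ), c)
        for occ, c in sorted(acc.items())
        if measure(c) > keep_threshold
    ]
    warnings = []
    if not terms:
        warnings.append("degenerate-state: no determinant survived screening")
    return CIState(
        basis=basis,
        n_electrons=n_el if n_el is not None else 0,
        multiplicity=multiplicity,
        energy=energy,
        terms=terms,
        label=label,
        warnings=warnings,
    )


def validate_state(state: CIState) -> dict:
    """Diagnostics report for a CI state; never mutates its input."""
    report: dict = {"label": state.label, "checks": {}, "ok": True}
    checks = report["checks"]

    counts_ok = all(d.n_electrons == state.n_electrons for d, _ in state.terms)
    checks["electron_count_consistent"] = counts_ok

    in_basis = all(
        (not d.occupied) or d.occupied[-1] < state.basis.n_spin_orbitals
        for d, _ in state.terms
    )
    checks["within_basis"] = in_basis

    occ_lists = [d.occupied for d, _ in state.terms]
    checks["no_duplicate_determinants"] = len(set(occ_lists)) == len(occ_lists)

    norm2 = state.squared_norm
    checks["norm_at_most_one"] = norm2 <= 1.0 + 1e-8
    report["squared_norm"] = norm2
    report["ok"] = all(checks.values())
    return report


# ---------------------------------------------------------------------------
# spin diagnostics (used as a convention-independent oracle in tests)
# ---------------------------------------------------------------------------

def _sm_key(so: int, n_spatial: int) -> tuple[int, int]:
    return (so - n_spatial, 1) if so >= n_spatial else (so, 0)


def _apply_excitation(
    occupied: tuple[int, ...], create: int, annihilate: int, n_spatial: int
) -> tuple[tuple[int, ...], int] | None:
    """Apply a+_create a_annihilate to a determinant (spatial-major phases).

    Returns the resulting occupied tuple and fermionic sign, or None if the
    result vanishes.
    """
    if annihilate not in occupied:
        return None
    sm = spatial_major_order(occupied, n_spatial)
    pos = sm.index(annihilate)
    sign = -1 if pos % 2 else 1
    reduced = tuple(o for o in occupied if o != annihilate)
    if create in reduced:
        return None
    key_c = _sm_key(create, n_spatial)
    n_before = sum(1 for o in reduced if _sm_key(o, n_spatial) < key_c)
    sign *= -1 if n_before % 2 else 1
    return tuple(sorted(reduced + (create,))), sign


def s_squared_expectation(
    terms: Iterable[tuple[Determinant, float]], basis: SpinOrbitalBasis
) -> float:
    """<S^2> of a determinant expansion, via S^2 = S-S+ + Sz(Sz + 1).

    Works directly on occupation lists with explicit fermionic phases, making
    it independent of any CSF coupling machinery.
    """
    vec: dict[tuple[int, ...], float] = {}
    for det, c in terms:
        vec[det.occupied] = vec.get(det.occupied, 0.0) + c
    norm2 = sum(c * c for c in vec.values())
    if norm2 == 0.0:
        raise ValueError("zero vector")

    M = basis.n_spatial
    total = 0.0
    for occ, c in vec.items():
        n_alpha = sum(1 for o in occ if o < M)
        n_beta = len(occ) - n_alpha
        sz = (n_alpha - n_beta) / 2.0
        total += c * c * sz * (sz + 1.0)
        # S- S+ term: sum_pq a+_{p beta} a_{p alpha} a+_{q alpha} a_{q beta}
        for q in range(M):
            up = _apply_excitation(
                occ, create=basis.alpha(q), annihilate=basis.beta(q), n_spatial=M
            )
            if up is None:
                continue
            mid, sign_up = up
            for p in range(M):
                down = _apply_excitation(
                    mid, create=basis.beta(p), annihilate=basis.alpha(p), n_spatial=M
                )
                if down is None:
                    continue
                final, sign_down = down
                c_final = vec.get(final)
                if c_final is not None:
                    total += c_final * c * sign_up * sign_down
    return total / norm2


# ---------------------------------------------------------------------------
# wavefunction container I/O (JSON and HDF5)
# ---------------------------------------------------------------------------

_SCHEMA_VERSION = 1


def _state_payload(state: CIState) -> dict:
    return {
        "n_electrons": state.n_electrons,
        "multiplicity": state.multiplicity,
        "energy": state.energy,
        "terms": [[list(d.occupied), c] for d, c in state.terms],
    }


def save_wavefunctions(path: str, basis: SpinOrbitalBasis, states: Sequence[CIState]) -> None:
    """Write a wavefunction container (format chosen by file extension).

    ``.json`` produces the plain-text container; ``.h5``/``.hdf5`` the HDF5
    layout with groups ``/basis`` and ``/states/<label>``.
    """
    if path.endswith(".json"):
        payload = {
            "schema_version": _SCHEMA_VERSION,
            "basis": {"mo_set_id": basis.mo_set_id, "n_spatial": basis.n_spatial},
            "states": {s.label: _state_payload(s) for s in states},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return
    if path.endswith((".h5", ".hdf5")):
        import h5py
        import numpy as np

        with h5py.File(path, "w") as fh:
            fh.attrs["schema_version"] = _SCHEMA_VERSION
            g = fh.create_group("basis")
            g.attrs["mo_set_id"] = basis.mo_set_id
            g.attrs["n_spatial"] = basis.n_spatial
            gs = fh.create_group("states")
            for s in states:
                gst = gs.create_group(s.label)
                gst.attrs["n_electrons"] = s.n_electrons
                gst.attrs["multiplicity"] = s.multiplicity
                gst.attrs["energy"] = s.energy
                occ = np.array([d.occupied for d, _ in s.terms], dtype=np.int64)
                coeff = np.array([c for _, c in s.terms], dtype=float)
                gst.create_dataset("terms/occupied", data=occ)
                gst.create_dataset("terms/coefficients", data=coeff)
        return
    raise ValueError(f"unrecognised container extension: {path}")


def load_wavefunctions(path: str) -> tuple[SpinOrbitalBasis, dict[str, CIState]]:
    """Read a wavefunction container written by :func:`save_wavefunctions`."""
    if path.endswith(".json"):
        with open(path) as fh:
            payload = json.load(fh)
        basis = SpinOrbitalBasis(**payload["basis"])
        states = {}
        for label, st in payload["states"].items():
            if "csf_terms" in st:
                # CSF-based input: [[spatial_occ, coupling, ms], coefficient]
                csf_terms = [
                    (CSF(tuple((p, o) for p, o in occ), tuple(coup), ms), c)
                    for (occ, coup, ms), c in st["csf_terms"]
                ]
                states[label] = decompose_ci_state(
                    csf_terms,
                    basis,
                    energy=st["energy"],
                    multiplicity=st["multiplicity"],
                    label=label,
                    csf_threshold=st.get("csf_threshold", 1e-4),
                    keep_threshold=st.get("keep_threshold", 0.0),
                )
                continue
            terms = [(Determinant(tuple(occ)), c) for occ, c in st["terms"]]
            states[label] = CIState(
                basis=basis,
                n_electrons=st["n_electrons"],
                multiplicity=st["multiplicity"],
                energy=st["energy"],
                terms=terms,
                label=label,
            )
        return basis, states
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as fh:
            basis = SpinOrbitalBasis(
                mo_set_id=str(fh["basis"].attrs["mo_set_id"]),
                n_spatial=int(fh["basis"].attrs["n_spatial"]),
            )
            states = {}
            for label, gst in fh["states"].items():
                occ = gst["terms/occupied"][...]
                coeff = gst["terms/coefficients"][...]
                terms = [
                    (Determinant(tuple(int(i) for i in row)), float(c))
                    for row, c in zip(occ, coeff)
                ]
                states[label] = CIState(
                    basis=basis,
                    n_electrons=int(gst.attrs["n_electrons"]),
                    multiplicity=int(gst.attrs["multiplicity"]),
                    energy=float(gst.attrs["energy"]),
                    terms=terms,
                    label=label,
                )
        return basis, states
    raise ValueError(f"unrecognised container extension: {path}")
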