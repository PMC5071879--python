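"""Dyson orbitals/norms against brute-force oracles and exact limits."""

import numpy as np
import pytest

from dysonspec import (
    CIState,
    Determinant,
    OrbitalOverlap,
    SpinOrbitalBasis,
    ToySystemSpec,
    build_orbital_overlap,
    determinant_pair_dyson,
    dyson_orbital,
    dyson_orbital_bruteforce,
    make_toy_system,
)
from dysonspec.dyson import ChannelError


def _single_det_state(basis, occupied, label="S", energy=0.0):
    return CIState(
        basis, len(occupied), 1 + len(occupied) % 2, energy,
        [(Determinant(tuple(occupied)), 1.0)], label,
    )


class TestBuildOrbitalOverlap:
    def test_identity_case(self):
        c = np.eye(3)
        ov = build_orbital_overlap(c, c, np.eye(3))
        np.testing.assert_allclose(ov.matrix, np.eye(3), atol=1e-14)

    def test_column_swap_gives_permutation(self):
        c = np.eye(4)
        swapped = c[:, [1, 0, 2, 3]]
        ov = build_orbital_overlap(c, swapped, np.eye(4))
        np.testing.assert_allclose(ov.matrix, np.eye(4)[:, [1, 0, 2, 3]], atol=1e-14)

    def test_matches_elementwise_triple_product(self, rng):
        a = rng.normal(size=(4, 4))
        s = a @ a.T + 0.5 * np.eye(4)
        q1, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        q2, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        ov = build_orbital_overlap(q1, q2, s)
        expected = np.array(
            [[q1[:, i] @ s @ q2[:, j] for j in range(4)] for i in range(4)]
        )
        np.testing.assert_allclose(ov.matrix, expected, atol=1e-12)

    def test_asymmetric_ao_overlap_rejected(self):
        with pytest.raises(ValueError):
            build_orbital_overlap(np.eye(2), np.eye(2), np.array([[1.0, 0.2], [0.0, 1.0]]))


class TestDeterminantPairDyson:
    def test_koopmans_minor(self):
        # source |1a 1b 2a|, ion |1a 1b| -> +1 at spin orbital 2-alpha
        bs, bi = SpinOrbitalBasis("s", 2), SpinOrbitalBasis("i", 2)
        ov = OrbitalOverlap(np.eye(2), bs, bi)
        vec = determinant_pair_dyson(Determinant((0, 1, 2)), Determinant((0, 2)), ov)
        np.testing.assert_allclose(vec, [0.0, 1.0, 0.0, 0.0], atol=1e-14)

    def test_orthogonal_ion_vanishes(self):
        bs, bi = SpinOrbitalBasis("s", 2), SpinOrbitalBasis("i", 2)
        # <1|2'> = 0: overlap column for the ion orbital is zero
        ov = OrbitalOverlap(np.array([[0.0, 1.0], [0.0, 0.0]]), bs, bi)
        vec = determinant_pair_dyson(Determinant((0, 2)), Determinant((0,)), ov)
        np.testing.assert_allclose(vec, 0.0, atol=1e-14)

    def test_wrong_electron_count_raises(self):
        bs, bi = SpinOrbitalBasis("s", 2), SpinOrbitalBasis("i", 2)
        ov = OrbitalOverlap(np.eye(2), bs, bi)
        with pytest.raises(ChannelError):
            determinant_pair_dyson(Determinant((0, 1)), Determinant((0, 1)), ov)

    def test_matches_bruteforce_on_random_overlaps(self, rng):
        bs, bi = SpinOrbitalBasis("s", 3), SpinOrbitalBasis("i", 3)
        for _ in range(25):
            m = rng.normal(size=(3, 3))
            ov = OrbitalOverlap(m, bs, bi)
            src = _single_det_state(bs, (0, 2, 4))
            ion = _single_det_state(bi, (1, 4), "D")
            vec = determinant_pair_dyson(src.terms[0][0], ion.terms[0][0], ov)
            oracle = dyson_orbital_bruteforce(src, ion, ov)
            np.testing.assert_allclose(vec, oracle.coefficients, atol=1e-12)


class TestDysonOrbital:
    def test_koopmans_limit_every_removable_orbital(self):
        bs, bi = SpinOrbitalBasis("s", 3), SpinOrbitalBasis("i", 3)
        ov = OrbitalOverlap(np.eye(3), bs, bi)
        occ = (0, 2, 4)
        src = _single_det_state(bs, occ)
        for s in occ:
            ion = _single_det_state(bi, tuple(o for o in occ if o != s), "D")
            res = dyson_orbital(src, ion, ov, 0.0)
            assert res.norm == pytest.approx(1.0, abs=1e-12)
            assert abs(res.coefficients[s]) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_ion_norm_zero(self):
        bs, bi = SpinOrbitalBasis("s", 2), SpinOrbitalBasis("i", 2)
        ov = OrbitalOverlap(np.array([[0.0, 1.0], [0.0, 0.0]]), bs, bi)
        src = _single_det_state(bs, (0, 2))
        ion = _single_det_state(bi, (0,), "D")
        assert dyson_orbital(src, ion, ov, 0.0).norm == pytest.approx(0.0, abs=1e-14)

    def test_hand_computed_two_electron_minors(self):
        """2e -> 1e toy: phi(s) follows from 1x1 minors of the overlap."""
        bs, bi = SpinOrbitalBasis("s", 2), SpinOrbitalBasis("i", 2)
        m = np.array([[0.9, 0.1], [0.2, 0.8]])
        ov = OrbitalOverlap(m, bs, bi)
        # source |1a 2b|, ion |1a|: only the beta electron can be removed and
        # a_{2b}|1a 2b> = -|1a>, so phi(2b) = -<1|1'> = -0.9
        src = _single_det_state(bs, (0, 3))
        ion = _single_det_state(bi, (0,), "D")
        res = dyson_orbital(src, ion, ov, 0.0)
        np.testing.assert_allclose(res.coefficients, [0.0, 0.0, 0.0, -0.9], atol=1e-14)
        assert res.norm == pytest.approx(0.81)
        # ion |2a|: the remaining alpha overlaps 2' -> phi(2b) = -<1|2'> = -0.1
        ion2 = _single_det_state(bi, (1,), "D")
        res2 = dyson_orbital(src, ion2, ov, 0.0)
        np.testing.assert_allclose(res2.coefficients, [0.0, 0.0, 0.0, -0.1], atol=1e-14)

    @pytest.mark.parametrize("regime", ["identical-orbitals", "rotated-orbitals", "random-SPD-AO"])
    def test_oracle_agreement_full_ci_pair(self, regime):
        spec = ToySystemSpec(
            n_spatial=3, n_electrons=3, seed=11, overlap_regime=regime,
            n_source_terms=9, n_ion_terms=9, n_ion_states=3,
        )
        source, ions, overlap = make_toy_system(spec)
        for ion in ions:
            fast = dyson_orbital(source, ion, overlap, 0.0)
            slow = dyson_orbital_bruteforce(source, ion, overlap)
            np.testing.assert_allclose(fast.coefficients, slow.coefficients, atol=1e-10)
            assert fast.norm == pytest.approx(slow.norm, abs=1e-10)

    def test_screening_changes_norm_below_one_percent(self):
        spec = ToySystemSpec(
            n_spatial=4, n_electrons=3, seed=2, overlap_regime="random-SPD-AO",
            n_source_terms=12, n_ion_terms=12, n_ion_states=3,
        )
        source, ions, overlap = make_toy_system(spec)
        for ion in ions:
            tight = dyson_orbital(source, ion, overlap, 1e-7).norm
            loose = dyson_orbital(source, ion, overlap, 1e-4).norm
            if tight > 1e-12:
                assert abs(loose - tight) / tight < 1e-2

    def test_bruteforce_refuses_large_systems(self):
        bs = SpinOrbitalBasis("s", 8)
        bi = SpinOrbitalBasis("i", 8)
        ov = OrbitalOverlap(np.eye(8), bs, bi)
        src = _single_det_state(bs, (0, 1))
        ion = _single_det_state(bi, (0,), "D")
        with pytest.raises(ValueError, match="brute-force"):
            dyson_orbital_bruteforce(src, ion, ov)


class TestInvariants:
    def test_norm_bounds(self, toy_system):
        source, ions, overlap = toy_system
        for ion in ions:
            norm = dyson_orbital(source, ion, overlap, 0.0).norm
            assert -1e-12 <= norm <= source.n_electrons + 1e-12

    def test_completeness_sum_rule(self):
        for n in (2, 3, 4):
            spec = ToySystemSpec(
                n_spatial=3, n_electrons=n, seed=5, full_ci_ion=True,
                n_source_terms=6,
            )
            source, ions, overlap = make_toy_system(spec)
            total = sum(dyson_orbital(source, ion, overlap, 0.0).norm for ion in ions)
            assert total == pytest.approx(n, abs=1e-8)

    def test_norm_invariant_under_common_unitary_rotation(self, rng):
        spec = ToySystemSpec(
            n_spatial=3, n_electrons=3, seed=9, overlap_regime="rotated-orbitals",
            n_source_terms=4, n_ion_terms=4, n_ion_states=2,
        )
        source, ions, overlap = make_toy_system(spec)
        # rotating the source MO set by Q changes the overlap to Q^T M, and
        # the CI vector must be re-expressed; a norm-preserving special case
        # is a permutation of the source spatial orbitals.
        perm = rng.permutation(3)
        m_perm = overlap.matrix[perm, :]
        overlap_perm = OrbitalOverlap(m_perm, overlap.source_basis, overlap.ion_basis)

        def permute_det(det):
            mapping = {int(old): new for new, old in enumerate(perm)}
            new_occ = []
            for so in det.occupied:
                if so < 3:
                    new_occ.append(mapping[so])
                else:
                    new_occ.append(3 + mapping[so - 3])
            return tuple(sorted(new_occ))

        from dysonspec.wavefunctions import spatial_major_order
        from dysonspec.wavefunctions import _permutation_parity

        new_terms = []
        for det, c in source.terms:
            new_occ = permute_det(det)
            # phase: parity of the permuted spatial-major sequence relative
            # to the re-sorted one
            old_sm = spatial_major_order(det.occupied, 3)
            moved = tuple(
                (perm.tolist().index(so) if so < 3 else 3 + perm.tolist().index(so - 3))
                for so in old_sm
            )
            # moved is the image sequence in old sm order; its parity to the
            # new sm order is the phase the coefficient picks up
            new_sm = spatial_major_order(moved, 3)
            sign = 1.0
            seq = list(moved)
            for i, target in enumerate(new_sm):
                j = seq.index(target, i)
                if j != i:
                    seq[i], seq[j] = seq[j], seq[i]
                    sign = -sign
            new_terms.append((Determinant(new_occ), sign * c))
        rotated = CIState(source.basis, 3, 2, 0.0, new_terms, "Srot")
        for ion in ions:
            n0 = dyson_orbital(source, ion, overlap, 0.0).norm
            n1 = dyson_orbital(rotated, ion, overlap_perm, 0.0).norm
            assert n1 == pytest.approx(n0, abs=1e-10)

    def test_spin_mirror_symmetry(self, toy_system):
        """Swapping every alpha and beta label leaves all norms unchanged."""
        source, ions, overlap = toy_system
        m = 3

        def mirror(state):
            # swapping alpha<->beta flips the spatial-major order within each
            # doubly occupied orbital: phase (-1)**n_doubly per determinant
            terms = []
            for det, c in state.terms:
                alpha = {so for so in det.occupied if so < m}
                beta = {so - m for so in det.occupied if so >= m}
                n_doubly = len(alpha & beta)
                occ = tuple(sorted((so + m) % (2 * m) for so in det.occupied))
                terms.append((Determinant(occ), c * (-1.0) ** n_doubly))
            return CIState(state.basis, state.n_electrons, state.multiplicity,
                           state.energy, terms, state.label + "-mir")

        for ion in ions:
            n0 = dyson_orbital(source, ion, overlap, 0.0).norm
            n1 = dyson_orbital(mirror(source), mirror(ion), overlap, 0.0).norm
            assert n1 == pytest.approx(n0, abs=1e-10)
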