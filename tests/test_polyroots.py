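from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quasimodes.networks import jacobian, random_stable_system
from quasimodes.polyroots import (Poly, count_modes_of_poly,
                                  count_positive_roots, count_resonant_modes,
                                  derivative, descartes_bound,
                                  n3_resonance_condition, r_polynomial,
                                  sign_changes_at, sturm_chain)

coeff_ints = st.integers(min_value=-9, max_value=9)


def _random_int_poly(rng, deg):
    c = rng.integers(-9, 10, size=deg + 1)
    while c[0] == 0:
        c[0] = rng.integers(-9, 10)
    return Poly([int(v) for v in c])


def _companion_positive_roots(p: Poly) -> int:
    """Independent oracle: distinct positive real roots via eigenvalues of
    the companion matrix (numpy.roots)."""
    roots = np.roots([float(c) for c in p.coeffs])
    scale = max(1.0, np.max(np.abs(roots))) if len(roots) else 1.0
    real_pos = sorted(r.real for r in roots
                      if abs(r.imag) < 1e-9 * scale and r.real > 1e-9)
    distinct = []
    for r in real_pos:
        if not distinct or r - distinct[-1] > 1e-6 * max(1.0, abs(r)):
            distinct.append(r)
    return len(distinct)


class TestDerivative:
    def test_cubic(self):
        p = Poly([1, 4, -2, 7])
        assert derivative(p).coeffs == (3, 8, -2)

    def test_constant_gives_zero(self):
        assert derivative(Poly([5])).is_zero()

    @given(st.lists(coeff_ints, min_size=2, max_size=9))
    @settings(derandomize=True, max_examples=50)
    def test_degree_drops_by_one(self, coeffs):
        p = Poly(coeffs)
        if p.degree >= 1:
            assert derivative(p).degree == p.degree - 1


class TestRPolynomial:
    def test_2x2_closed_form(self):
        # for n = 2, det(xI + A) = x^2 + Tr(A) x + det(A) with A = J^2
        J = np.array([[-1, 2], [-2, -1]])
        A = J @ J
        R = r_polynomial(J)
        assert [float(c) for c in R.coeffs] == pytest.approx(
            [1.0, np.trace(A), np.linalg.det(A)])
        assert R.coeffs == (1, -6, 25)  # x^2 - 6x + 25

    def test_constant_term_is_det_squared(self, rng):
        for _ in range(50):
            J = rng.standard_normal((4, 4))
            R = r_polynomial(J)
            detJ = np.linalg.det(J)
            assert np.isclose(float(R.coeffs[-1]), detJ**2, rtol=1e-8)
            assert float(R.coeffs[-1]) >= 0

    def test_monic_of_degree_n(self, J5):
        R = r_polynomial(J5)
        assert R.degree == 5
        assert float(R.coeffs[0]) == 1.0

    def test_exact_equals_float(self, spec3):
        Rf = r_polynomial(jacobian(spec3))
        Re = r_polynomial(jacobian(spec3, exact=True))
        assert Re.exact
        assert np.allclose([float(c) for c in Re.coeffs],
                           [float(c) for c in Rf.coeffs], rtol=1e-10)

    def test_nonsquare_rejected(self):
        with pytest.raises(ValueError):
            r_polynomial(np.ones((2, 3)))


class TestSturmChain:
    def test_hand_chain(self):
        chain = sturm_chain(Poly([1, 0, -1]))  # x^2 - 1
        assert [p.coeffs for p in chain.polys] == [(1, 0, -1), (2, 0), (1,)]

    def test_repeated_root_counted_once(self):
        p = Poly([1, -2, 1])  # (x - 1)^2
        chain = sturm_chain(p)
        assert chain.polys[-1].degree >= 1  # terminates at the gcd
        assert count_positive_roots(p) == 1

    @given(st.lists(coeff_ints, min_size=2, max_size=9))
    @settings(derandomize=True, max_examples=100)
    def test_chain_length_bound(self, coeffs):
        p = Poly(coeffs)
        if not p.is_zero() and p.degree >= 1:
            assert len(sturm_chain(p)) <= p.degree + 1


class TestSignChanges:
    def test_x2_minus_1(self):
        chain = sturm_chain(Poly([1, 0, -1]))
        assert sign_changes_at(chain, "zero") - sign_changes_at(
            chain, "infinity") == 1

    def test_x2_plus_1(self):
        chain = sturm_chain(Poly([1, 0, 1]))
        assert sign_changes_at(chain, "zero") == sign_changes_at(
            chain, "infinity")

    def test_invariant_under_positive_scaling(self):
        from quasimodes.polyroots import SturmChain
        chain = sturm_chain(Poly([1, 1, -6]))
        scaled = SturmChain(tuple(
            Poly([7 * c for c in p.coeffs]) if i == 1 else p
            for i, p in enumerate(chain.polys)))
        for pt in ("zero", "infinity", 1, 5):
            assert sign_changes_at(chain, pt) == sign_changes_at(scaled, pt)


class TestCountPositiveRoots:
    @pytest.mark.parametrize("roots, expected", [
        ((1, 2, -3), 2),
        ((-1, -2, -3), 0),
        ((5,), 1),
    ])
    def test_factored_construction(self, roots, expected):
        coeffs = [1]
        for r in roots:
            coeffs = [a - r * b for a, b in
                      zip(coeffs + [0], [0] + coeffs)]
        assert count_positive_roots(Poly(coeffs)) == expected

    def test_no_real_roots(self):
        assert count_positive_roots(Poly([1, 0, 1])) == 0

    def test_zero_poly_rejected(self):
        with pytest.raises(ValueError):
            count_positive_roots(Poly([0]))

    def test_root_at_origin_not_counted(self):
        # x(x - 2) has one root in (0, inf)
        assert count_positive_roots(Poly([1, -2, 0])) == 1

    def test_against_companion_oracle_500(self, rng):
        """Exact Sturm counts equal companion-matrix eigenvalue counts on
        500 random integer polynomials of degrees 2-8 (zero mismatches)."""
        mismatches = 0
        for _ in range(500):
            p = _random_int_poly(rng, int(rng.integers(2, 9)))
            if count_positive_roots(p) != _companion_positive_roots(p):
                mismatches += 1
        assert mismatches == 0


class TestDescartes:
    @pytest.mark.parametrize("coeffs, expected", [
        ([1, -3, 2], 2),
        ([1, 1, 1], 0),
        ([1, 0, -1], 1),
    ])
    def test_examples(self, coeffs, expected):
        assert descartes_bound(Poly(coeffs)) == expected

    def test_bounds_sturm_count_with_equal_parity(self, rng):
        for _ in range(500):
            p = _random_int_poly(rng, int(rng.integers(2, 9)))
            bound = descartes_bound(p)
            exact = count_positive_roots(p)
            # the bound counts a root at 0 never, multiplicities as distinct
            assert bound >= exact
            if p.coeffs[-1] != 0:  # parity statement needs p(0) != 0
                assert (bound - _companion_multiplicity_count(p)) % 2 == 0


def _companion_multiplicity_count(p: Poly) -> int:
    roots = np.roots([float(c) for c in p.coeffs])
    scale = max(1.0, np.max(np.abs(roots))) if len(roots) else 1.0
    return sum(1 for r in roots
               if abs(r.imag) < 1e-9 * scale and r.real > 1e-9)


class TestModeCounting:
    def test_2x2_single_mode(self):
        # R = x^2 - 6x + 25, R' = 2x - 6: one minimum at x = 3
        res = count_resonant_modes(np.array([[-1, 2], [-2, -1]]))
        assert res.n_modes == 1
        (cp,) = res.critical_points
        assert cp.kind == "minimum"
        assert cp.x == pytest.approx(3.0, abs=1e-8)
        assert res.resonant_frequencies[0] == pytest.approx(np.sqrt(3.0))

    def test_n3_single_mode_vs_grid_minimization(self, J3):
        res = count_resonant_modes(J3)
        assert res.n_modes == 1
        # independent oracle: R evaluated by determinants on a dense grid
        # has a unique interior local minimum (the resonance is local; R(0)
        # itself is smaller, so a global argmin would be wrong here)
        A = J3 @ J3
        xs = np.linspace(1e-4, 10.0, 40001)
        rv = np.array([np.linalg.det(A + x * np.eye(3)) for x in xs])
        local_min = np.flatnonzero((rv[1:-1] < rv[:-2]) & (rv[1:-1] < rv[2:]))
        assert len(local_min) == 1
        assert res.critical_points[-1].x == pytest.approx(
            xs[local_min[0] + 1], abs=1e-3)

    def test_n5_two_modes(self, J5):
        res = count_resonant_modes(J5)
        assert res.n_modes == 2
        kinds = [cp.kind for cp in res.critical_points]
        assert kinds == ["maximum", "minimum", "maximum", "minimum"]

    def test_modes_bounded_by_half_n(self):
        for seed in range(30):
            sys_ = random_stable_system(6, seed=seed)
            res = count_resonant_modes(sys_.jacobian)
            assert 0 <= res.n_modes <= 3
            # minima/maxima alternate and the last critical point is a minimum
            kinds = [cp.kind for cp in res.critical_points
                     if cp.kind != "inflection"]
            if kinds:
                assert kinds[-1] == "minimum"
                assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_report_dict_shape(self, J3):
        d = count_resonant_modes(J3).to_dict()
        assert d["method"] == "sturm"
        assert d["n_species"] == 3
        assert {"x", "omega", "kind"} <= set(d["critical_points"][0])


class TestN3ResonanceCondition:
    def test_no_positive_critical_point(self):
        assert n3_resonance_condition(0, 1) == "no_resonance"

    def test_resonance_by_quadratic_formula(self):
        # R' = 3x^2 - 6x + 1 has its larger root positive
        assert n3_resonance_condition(-3, 1) == "resonance"

    def test_agrees_with_mode_count_on_grid(self):
        """(a1, a2) grid with a3 = 1 fixed: the closed-form inequality route
        and the full classification route must coincide."""
        a1s = np.linspace(-5, 5, 100)
        a2s = np.linspace(-5, 5, 100)
        for a1 in a1s:
            for a2 in a2s:
                cond = n3_resonance_condition(float(a1), float(a2))
                res = count_modes_of_poly(Poly([1.0, a1, a2, 1.0]),
                                          n_species=3)
                assert (cond == "resonance") == (res.n_modes >= 1), (a1, a2)

    def test_agrees_on_random_stable_jacobians(self):
        for seed in range(1000):
            J = random_stable_system(3, seed=seed).jacobian
            R = r_polynomial(J)
            cond = n3_resonance_condition(float(R.coeffs[1]),
                                          float(R.coeffs[2]))
            modes = count_resonant_modes(J).n_modes
            assert (cond == "resonance") == (modes >= 1), seed


def test_exact_pipeline_uses_rationals(spec3):
    Je = jacobian(spec3, exact=True)
    R = r_polynomial(Je)
    assert all(isinstance(c, Fraction) for c in R.coeffs)
    chain = sturm_chain(derivative(R))
    assert all(p.exact for p in chain.polys)
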