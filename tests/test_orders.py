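"""Rationalization, characteristic determinants, roots and the wedge test."""

import math

import mpmath
import numpy as np
import pytest

from fracstab import (
    DegenerateRootError,
    IncommensurateLinearization,
    RationalOrder,
    SparsePolynomial,
    all_roots,
    characteristic_polynomial,
    common_multiple,
    min_arg,
    rationalize,
    stability_report,
)


class TestRationalize:
    @pytest.mark.parametrize(
        "alpha, convention, expected",
        [
            (0.97, "fixed_denominator", (97, 100)),
            (0.98, "fixed_denominator", (98, 100)),
            (1.0, "reduced", (1, 1)),
            (0.98, "reduced", (49, 50)),
            (0.75, "reduced", (3, 4)),
        ],
    )
    def test_conventions(self, alpha, convention, expected):
        order = rationalize(alpha, convention)
        assert (order.numerator, order.denominator) == expected
        assert abs(order.numerator / order.denominator - alpha) < 1e-12

    def test_reduced_flag_enforces_coprimality(self):
        assert rationalize(0.98, "reduced").reduced
        assert not rationalize(0.98, "fixed_denominator").reduced
        with pytest.raises(ValueError):
            RationalOrder(0.98, 98, 100, reduced=True)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_out_of_range_order_rejected(self, bad):
        with pytest.raises(ValueError):
            rationalize(bad)

    def test_non_representable_alpha_rejected(self):
        with pytest.raises(ValueError):
            rationalize(0.975, "fixed_denominator", denominator=100)
        # but representable under a finer lattice
        assert rationalize(0.975, "fixed_denominator", 1000).numerator == 975


class TestCommonMultiple:
    @pytest.mark.parametrize(
        "pairs, expected",
        [
            ([(97, 100), (1, 1)], 100),
            ([(1, 2), (1, 3)], 6),
            ([(98, 100), (1, 1)], 100),
            ([(49, 50), (1, 1)], 50),
        ],
    )
    def test_lcm_of_denominators(self, pairs, expected):
        orders = [RationalOrder(v / u, v, u, reduced=math.gcd(v, u) == 1)
                  for v, u in pairs]
        assert common_multiple(orders) == expected

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            common_multiple([])


def _lin(jac, alphas, M):
    orders = tuple(
        rationalize(a, "fixed_denominator", M) if a < 1 else rationalize(1.0, "reduced")
        for a in alphas
    )
    return IncommensurateLinearization(np.asarray(jac, float), orders, M)


class TestCharacteristicPolynomial:
    def test_positive_equilibrium_determinant(self):
        # 2x2 chain-model Jacobian at the positive equilibrium, a = rho = 4.5
        p = characteristic_polynomial(
            _lin([[4.5, -2 * 4.5 * 4.5], [1.0, -4.5]], (0.97, 1.0), 100)
        )
        assert p.terms == ((197, 1.0), (100, -4.5), (97, 4.5), (0, 20.25))

    def test_trivial_equilibrium_determinant(self):
        p = characteristic_polynomial(
            _lin([[4.5, 0.0], [1.0, -4.5]], (0.97, 1.0), 100)
        )
        assert p.terms == ((197, 1.0), (100, -4.5), (97, 4.5), (0, -20.25))

    def test_scalar_system_is_pure_monomial(self):
        p = characteristic_polynomial(_lin([[0.0]], (1.0,), 1))
        assert p.terms == ((1, 1.0),)

    def test_non_square_jacobian_rejected(self):
        with pytest.raises(ValueError):
            IncommensurateLinearization(
                np.zeros((2, 3)), (rationalize(0.5, "reduced"),) * 2, 2
            )

    def test_indivisible_M_rejected(self):
        with pytest.raises(ValueError):
            _lin([[1.0, 0.0], [0.0, 1.0]], (0.97, 1.0), 50)


class TestAllRoots:
    def test_quadratic_unit_roots(self):
        roots = sorted(all_roots(SparsePolynomial(((2, 1.0), (0, 1.0)))),
                       key=lambda z: z.imag)
        assert roots == pytest.approx([-1j, 1j])

    def test_cube_roots_of_eight(self):
        roots = all_roots(SparsePolynomial(((3, 1.0), (0, -8.0))))
        assert sorted(abs(r) for r in roots) == pytest.approx([2.0, 2.0, 2.0])
        args = sorted(np.angle(roots))
        assert args == pytest.approx([-2 * np.pi / 3, 0.0, 2 * np.pi / 3])

    def test_degree_zero_rejected(self):
        with pytest.raises(ValueError):
            all_roots(SparsePolynomial(((0, 3.0),)))

    def test_root_count_matches_degree(self):
        p = SparsePolynomial(((197, 1.0), (100, -4.5), (97, 4.6), (0, 20.7)))
        assert len(all_roots(p)) == 197


class TestMinArg:
    def test_conjugate_imaginary_pair(self):
        assert min_arg([1j, -1j]) == pytest.approx(np.pi / 2)

    def test_positive_real_root_gives_zero(self):
        # sign change on the positive real axis forces a real root: the
        # trivial-equilibrium polynomial has p(0) < 0 and p -> +inf
        p = SparsePolynomial(((197, 1.0), (100, -4.5), (97, 4.5), (0, -20.25)))
        assert min_arg(all_roots(p)) == pytest.approx(0.0, abs=1e-8)

    def test_zero_root_is_degenerate(self):
        with pytest.raises(DegenerateRootError):
            min_arg([0.0 + 0.0j, 1.0 + 1.0j])


class TestStabilityReport:
    def test_stable_case(self):
        p = SparsePolynomial(((197, 1.0), (100, -4.5), (97, 5.0), (0, 22.5)))
        rep = stability_report(p, 100)
        assert rep.verdict == "stable"
        assert rep.min_arg == pytest.approx(0.0162375, abs=5e-6)
        assert rep.imfos == pytest.approx(rep.threshold - rep.min_arg)

    def test_marginal_case_flags_hopf_band(self):
        p = SparsePolynomial(((197, 1.0), (100, -4.5), (97, 4.5), (0, 20.25)))
        rep = stability_report(p, 100)
        assert rep.verdict == "marginal"
        assert abs(rep.imfos) < rep.tol

    def test_trivial_equilibrium_always_unstable(self):
        p = SparsePolynomial(((197, 1.0), (100, -4.5), (97, 4.5), (0, -20.25)))
        rep = stability_report(p, 100)
        assert rep.verdict == "unstable"
        assert rep.min_arg == pytest.approx(0.0, abs=1e-8)
        assert rep.imfos == pytest.approx(np.pi / 200)

    def test_zero_constant_term_is_degenerate(self):
        with pytest.raises(DegenerateRootError):
            stability_report(SparsePolynomial(((2, 1.0), (1, 1.0))), 1)


def _chain_poly(alpha1, rho, a, M):
    ma = round(M * alpha1)
    return SparsePolynomial(
        ((M + ma, 1.0), (M, -rho), (ma, a), (0, a * rho))
    )


class TestInvariants:
    @pytest.mark.parametrize("k", [2, 3])
    def test_M_rescaling_preserves_verdict(self, k, parameter_triples):
        """Replacing M by kM divides min_arg and threshold by exactly k."""
        for alpha1, rho, a in parameter_triples[:6]:
            rep1 = stability_report(_chain_poly(alpha1, rho, a, 100), 100)
            repk = stability_report(_chain_poly(alpha1, rho, a, 100 * k), 100 * k)
            assert repk.min_arg == pytest.approx(rep1.min_arg / k, rel=1e-6, abs=1e-12)
            assert repk.threshold == pytest.approx(rep1.threshold / k)
            if rep1.verdict != "marginal":
                assert repk.verdict == rep1.verdict

    def test_roots_closed_under_conjugation(self, parameter_triples):
        for alpha1, rho, a in parameter_triples[:5]:
            roots = all_roots(_chain_poly(alpha1, rho, a, 100))
            as_set = sorted(roots, key=lambda z: (round(z.real, 9), round(z.imag, 9)))
            conj = sorted(np.conj(roots),
                          key=lambda z: (round(z.real, 9), round(z.imag, 9)))
            np.testing.assert_allclose(as_set, conj, atol=1e-9)

    def test_root_count_is_M_times_order_sum(self, parameter_triples):
        for alpha1, rho, a in parameter_triples[:5]:
            roots = all_roots(_chain_poly(alpha1, rho, a, 100))
            assert len(roots) == round(100 * (alpha1 + 1))

    def test_companion_roots_match_multiprecision_isolation(self):
        """Independent oracle: mpmath polyroots at 40 digits, small M."""
        for alpha1, rho, a, M in [(0.75, 4.5, 4.6, 4), (0.5, 2.0, 3.0, 2),
                                  (0.75, 14.0, 15.0, 12)]:
            p = _chain_poly(alpha1, rho, a, M)
            mine = min_arg(all_roots(p))
            with mpmath.workdps(40):
                coeffs = [mpmath.mpf(c) for c in p.dense_coefficients()[::-1]]
                oracle_roots = mpmath.polyroots(coeffs, maxsteps=200,
                                                extraprec=80, asc=True)
                oracle = min(abs(mpmath.arg(r)) for r in oracle_roots)
            assert mine == pytest.approx(float(oracle), abs=1e-10)

    def test_refined_root_residuals_are_small(self):
        for alpha1, rho, a in [(0.97, 4.5, 4.5), (0.95, 22.91, 25.0)]:
            p = _chain_poly(alpha1, rho, a, 100)
            roots = all_roots(p, refine=True)
            max_coeff = max(abs(c) for _, c in p.terms)
            assert max(abs(p(r)) for r in roots) <= 1e-8 * max_coeff
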