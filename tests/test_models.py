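import cmath

import numpy as np
import pytest

from fracz import (
    CPEParams,
    Element,
    ElementParams,
    FrequencyGrid,
    MaclaurinCoeffs,
    ModelSpec,
    dc_limit,
    eval_cole,
    eval_cpe,
    eval_gc1,
    eval_ggc1,
    eval_serial,
    gcpe_scaling,
    solve_p,
    table_fixture,
)
from fracz.errors import (
    DomainError,
    InvalidParameterError,
    InvalidSpecError,
    NoSolutionError,
)

from conftest import oracle_factor, oracle_serial, random_cole_params


class TestFrequencyGrid:
    def test_omega_is_derived(self):
        g = FrequencyGrid(np.array([1.0, 10.0]))
        assert np.allclose(g.omega, 2 * np.pi * g.f)

    def test_zero_frequency_rejected(self):
        with pytest.raises(InvalidParameterError, match="positive"):
            FrequencyGrid(np.array([0.0, 1.0]))

    def test_non_increasing_rejected(self):
        with pytest.raises(InvalidParameterError, match="increasing"):
            FrequencyGrid(np.array([1.0, 1.0, 2.0]))

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidParameterError):
            FrequencyGrid(np.array([1.0, np.inf]))


class TestCPE:
    def test_alpha_zero_is_resistance(self, grid61):
        z = eval_cpe(CPEParams(c_alpha=2.0, alpha=0.0), grid61)
        assert np.allclose(z, 0.5 + 0.0j, rtol=0, atol=1e-15)

    def test_alpha_one_is_ideal_capacitor(self):
        # omega = 1 rad/s
        g = FrequencyGrid(np.array([1.0 / (2 * np.pi)]))
        z = eval_cpe(CPEParams(c_alpha=1.0, alpha=1.0), g)
        assert z[0] == pytest.approx(-1j, abs=1e-15)

    def test_half_order_polar_form(self):
        # independent polar-form oracle: 1/e^{j pi/4} = e^{-j pi/4}
        g = FrequencyGrid(np.array([1.0 / (2 * np.pi)]))
        z = eval_cpe(CPEParams(c_alpha=1.0, alpha=0.5), g)
        expected = cmath.exp(-1j * cmath.pi / 4)
        assert abs(z[0] - expected) < 1e-14
        assert z[0].real == pytest.approx(0.7071067811865476, abs=1e-12)

    def test_phase_constant_over_grid(self, grid61):
        for alpha in (0.2, 0.5, 0.85, 1.0):
            z = eval_cpe(CPEParams(c_alpha=3.3e-6, alpha=alpha), grid61)
            phases = np.angle(z)
            assert np.max(np.abs(phases - (-alpha * np.pi / 2))) < 1e-12

    def test_invalid_params(self):
        with pytest.raises(InvalidParameterError):
            CPEParams(c_alpha=-1.0, alpha=0.5)
        with pytest.raises(InvalidParameterError):
            CPEParams(c_alpha=1.0, alpha=1.2)


class TestCole:
    def test_dc_limit_reaches_r0(self):
        g = FrequencyGrid(np.array([1e-12]))
        z = eval_cole(1e6, 2e3, 0.77, 0.5, g)
        assert z[0].real == pytest.approx(1e6, rel=1e-6)

    def test_alpha_one_at_unit_omega_tau(self):
        tau = 0.25
        g = FrequencyGrid(np.array([1.0 / (2 * np.pi * tau)]))  # omega*tau = 1
        r0, r_inf = 5e5, 1e3
        z = eval_cole(r0, r_inf, 1.0, tau, g)
        expected = r_inf + (r0 - r_inf) * (1 - 1j) / 2  # direct arithmetic
        assert abs(z[0] - expected) < 1e-9 * abs(expected)

    def test_alpha_one_exact_semicircle(self):
        # Debye limit: locus lies on the circle centred at ((r0+rinf)/2, 0)
        r0, r_inf, tau = 1e6, 1e3, 0.1
        g = FrequencyGrid(np.geomspace(1e-3, 1e5, 101))
        z = eval_cole(r0, r_inf, 1.0, tau, g)
        centre = (r0 + r_inf) / 2
        radius = (r0 - r_inf) / 2
        dist = np.hypot(z.real - centre, z.imag)
        assert np.max(np.abs(dist - radius)) < 1e-6 * radius

    def test_hf_limit(self):
        g = FrequencyGrid(np.array([1e12]))
        z = eval_cole(1e6, 2e3, 0.9, 0.5, g)
        assert z[0].real == pytest.approx(2e3, rel=1e-3)

    def test_r0_not_above_rinf_rejected(self):
        with pytest.raises(InvalidParameterError, match="r0"):
            eval_cole(1e3, 1e6, 0.8, 0.5, FrequencyGrid(np.array([1.0])))


class TestSolveP:
    def test_beta_zero_linear_scaling(self):
        # memoryless case: no log correction, p = 1 exactly
        assert solve_p(0.8, 0.0, 1.0) == 1.0
        assert solve_p(0.3, 0.0, 17.0) == 1.0

    @pytest.mark.parametrize(
        "alpha,beta,tau",
        [
            (0.819, -0.015, 0.240),
            (0.805, 0.074, 2.883),
            (0.532, 0.024, 1.900),
            (0.940, -0.043233, 0.281),
            (0.707, 0.010132, 0.604),
        ],
    )
    def test_fixed_point_residual(self, alpha, beta, tau):
        p = solve_p(alpha, beta, tau)
        assert p >= 0.0
        residual = abs(p - np.exp(-(beta / alpha) * np.log(p * tau) ** 2))
        assert residual < 1e-10

    def test_against_bisection_oracle(self):
        alpha, beta, tau = 0.8, 0.05, 1.0
        p = solve_p(alpha, beta, tau)

        # dense bracketed bisection on p in [0, 10], independent of brentq
        def relation(q):
            return q - np.exp(-(beta / alpha) * np.log(q * tau) ** 2)

        qs = np.linspace(1e-9, 10.0, 200001)
        vals = relation(qs)
        roots = []
        for i in np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]:
            lo, hi = qs[i], qs[i + 1]
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if np.sign(relation(mid)) == np.sign(relation(lo)):
                    lo = mid
                else:
                    hi = mid
            roots.append(0.5 * (lo + hi))
        assert roots, "bisection oracle found no root"
        assert min(abs(p - r) for r in roots) < 1e-8

    def test_no_root_raises_with_bracket(self):
        # strongly negative beta with tau > 1 pushes the relation away from 0
        with pytest.raises(NoSolutionError) as err:
            solve_p(0.1, -0.9, 20.0)
        assert err.value.bracket == (1e-12, 10.0)
        assert np.isfinite(err.value.residual)


class TestGcpeScaling:
    def test_beta_zero_reduces_to_cole_factor(self):
        w = 2 * np.pi * np.geomspace(0.1, 1e5, 61)
        alpha, tau = 0.7, 1.0 / (2 * np.pi)
        for p in (0.2, 1.0, 5.0):
            fac = gcpe_scaling(w, alpha, 0.0, tau, p)
            assert np.allclose(fac, (1j * w * tau) ** alpha, rtol=1e-14, atol=0)

    def test_beta_zero_unit_omega_tau(self):
        # factor = j^0.7 = e^{j 0.35 pi}
        fac = gcpe_scaling(np.array([1.0]), 0.7, 0.0, 1.0, 1.0)
        assert abs(fac[0] - cmath.exp(0.35j * cmath.pi)) < 1e-14

    def test_beta_zero_modulus_linear(self, grid61):
        w = grid61.omega
        fac = gcpe_scaling(w, 0.9, 0.0, 0.05, 3.0)
        assert np.allclose(np.abs(fac), (w * 0.05) ** 0.9, rtol=1e-13, atol=0)

    def test_high_precision_oracle_table_values(self):
        # GC2 element-2 generators at 1 Hz; frozen 50-digit evaluation
        fac = gcpe_scaling(
            np.array([2 * np.pi * 1.0]), 0.805, 0.074, 2.883, 0.655
        )[0]
        frozen = 2.758763673274475 + 9.766639567264344j
        assert abs(fac - frozen) / abs(frozen) < 1e-10

    def test_scalar_oracle_agreement(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            f = float(np.exp(rng.uniform(np.log(0.1), np.log(1e5))))
            alpha = float(rng.uniform(0.3, 1.0))
            beta = float(rng.uniform(-0.1, 0.1))
            tau = float(np.exp(rng.uniform(-2, 1)))
            p = float(np.exp(rng.uniform(-1, 1)))
            got = gcpe_scaling(np.array([2 * np.pi * f]), alpha, beta, tau, p)[0]
            want = oracle_factor(f, alpha, beta, tau, p)
            assert abs(got - want) <= 1e-10 * abs(want)

    def test_zero_frequency_is_domain_error(self):
        with pytest.raises(DomainError):
            gcpe_scaling(np.array([0.0]), 0.8, 0.05, 1.0, 1.0)

    def test_zero_p_with_beta_is_domain_error(self):
        with pytest.raises(DomainError):
            gcpe_scaling(np.array([1.0]), 0.8, 0.05, 1.0, 0.0)


def _circle_fit_max_deviation(z: np.ndarray) -> float:
    """Algebraic least-squares circle through the locus; max orthogonal residual."""
    x, y = z.real, -z.imag
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = coef[0] / 2, coef[1] / 2
    r = np.sqrt(coef[2] + cx**2 + cy**2)
    return float(np.max(np.abs(np.hypot(x - cx, y - cy) - r)))


class TestGC1:
    def test_beta_zero_equals_cole(self, grid61):
        params = ElementParams(dr=0.0, alpha=0.82, tau=0.4, p=0.7, beta=0.0)
        z_gc1 = eval_gc1(params, 1.1e6, 1.5e3, grid61)
        z_cole = eval_cole(1.1e6, 1.5e3, 0.82, 0.4, grid61)
        assert np.max(np.abs(z_gc1 - z_cole) / np.abs(z_cole)) < 1e-12

    def test_beta_bends_locus_off_the_arc(self, grid61):
        base = dict(dr=0.0, alpha=0.82, tau=0.4, p=1.0)
        z0 = eval_gc1(ElementParams(beta=0.0, **base), 1.1e6, 1.5e3, grid61)
        z1 = eval_gc1(ElementParams(beta=0.08, **base), 1.1e6, 1.5e3, grid61)
        dev0 = _circle_fit_max_deviation(z0)
        dev1 = _circle_fit_max_deviation(z1)
        assert dev0 < 1e-4 * 1.1e6  # depressed arc is circular
        assert dev1 > 10 * max(dev0, 1.0)  # memory term bends it measurably

    def test_independent_term_evaluation(self, grid61):
        # GGC1 (d = 2.0 cm) base parameters with the Maclaurin tail removed
        params = ElementParams(dr=0.0, alpha=0.707, tau=0.604, p=1.0, beta=0.010132)
        z = eval_gc1(params, 1.461e6, 2.53e3, grid61)
        for i in (0, 17, 44, 60):
            f = grid61.f[i]
            fac = oracle_factor(f, 0.707, 0.010132, 0.604, 1.0)
            want = 2.53e3 + (1.461e6 - 2.53e3) / (1.0 + fac)
            assert abs(z[i] - want) <= 1e-10 * abs(want)


class TestSerial:
    def test_single_classic_equals_cole(self, grid61):
        prm = ElementParams(dr=9.5e5, alpha=0.78, tau=0.31)
        spec = ModelSpec("C1", 2.2e3, (Element("cole", prm),))
        z = eval_serial(spec, grid61)
        z_cole = eval_cole(2.2e3 + 9.5e5, 2.2e3, 0.78, 0.31, grid61)
        assert np.allclose(z, z_cole, rtol=1e-14, atol=0)

    def test_permutation_commutes(self, grid61):
        cole = Element("cole", ElementParams(dr=4e5, alpha=0.9, tau=1.2))
        gen = Element(
            "gencole", ElementParams(dr=6e5, alpha=0.6, tau=0.2, p=0.8, beta=0.03)
        )
        z_cg = eval_serial(ModelSpec("C1GC1", 1e3, (cole, gen)), grid61)
        z_gc = eval_serial(ModelSpec("GC1C1", 1e3, (gen, cole)), grid61)
        assert np.array_equal(z_cg, z_gc)

    def test_series_additivity_exact(self, grid61):
        from fracz.models import element_impedance

        spec = table_fixture("GC2-d025")
        z = eval_serial(spec, grid61)
        parts = sum(element_impedance(el, grid61) for el in spec.elements)
        assert np.allclose(z, spec.r_inf + parts, rtol=0, atol=0) or np.max(
            np.abs(z - (spec.r_inf + parts)) / np.abs(z)
        ) < 1e-15

    def test_c2_table_column_frozen_oracle(self):
        # two-term evaluation at 1 Hz, frozen from a 50-digit computation
        spec = table_fixture("C2-d025")
        g = FrequencyGrid(np.array([1.0]))
        z = eval_serial(spec, g)[0]
        frozen = 237728.08465473072 - 252569.54738911593j
        assert abs(z - frozen) <= 1e-10 * abs(frozen)

    def test_c2_scalar_oracle(self, grid61):
        spec = table_fixture("C2-d20")
        z = eval_serial(spec, grid61)
        for i in (0, 30, 60):
            want = oracle_serial(spec, grid61.f[i])
            assert abs(z[i] - want) <= 1e-12 * abs(want)

    def test_empty_elements_rejected(self):
        with pytest.raises(InvalidSpecError):
            ModelSpec("C1", 1e3, ())


class TestGGC1:
    _base = dict(dr=0.0, alpha=0.73, tau=0.45, p=1.0)

    def test_truncation_to_gc1(self, grid61):
        prm = ElementParams(
            beta=0.02, maclaurin=MaclaurinCoeffs(0, 0, 0, 0), **self._base
        )
        z = eval_ggc1(prm, 1e6, 1e3, grid61)
        z_gc1 = eval_gc1(
            ElementParams(beta=0.02, **self._base), 1e6, 1e3, grid61
        )
        assert np.max(np.abs(z - z_gc1) / np.abs(z_gc1)) < 1e-12

    def test_full_reduction_to_cole(self, grid61):
        prm = ElementParams(
            beta=0.0, maclaurin=MaclaurinCoeffs(0, 0, 0, 0), **self._base
        )
        z = eval_ggc1(prm, 1e6, 1e3, grid61)
        z_cole = eval_cole(1e6, 1e3, 0.73, 0.45, grid61)
        assert np.max(np.abs(z - z_cole) / np.abs(z_cole)) < 1e-13

    def test_table_column_frozen_oracle(self):
        spec = table_fixture("GGC1-d20")
        g = FrequencyGrid(np.array([10.0]))
        prm = spec.elements[0].params
        z = eval_ggc1(prm, spec.r_inf + prm.dr, spec.r_inf, g)[0]
        frozen = 56170.237001348716 - 93042.79455348376j
        assert abs(z - frozen) <= 1e-10 * abs(frozen)

    def test_requires_maclaurin(self, grid61):
        with pytest.raises(InvalidParameterError):
            eval_ggc1(ElementParams(beta=0.1, **self._base), 1e6, 1e3, grid61)


class TestReductionChain:
    def test_hundred_random_draws(self, grid61):
        rng = np.random.default_rng(42)
        for _ in range(100):
            r0, r_inf, alpha, tau = random_cole_params(rng)
            p = float(np.exp(rng.uniform(-1, 1)))
            base = ElementParams(dr=0.0, alpha=alpha, tau=tau, p=p, beta=0.0)
            z_cole = eval_cole(r0, r_inf, alpha, tau, grid61)
            z_gc1 = eval_gc1(base, r0, r_inf, grid61)
            prm = ElementParams(
                dr=0.0, alpha=alpha, tau=tau, p=p, beta=0.0,
                maclaurin=MaclaurinCoeffs(0, 0, 0, 0),
            )
            z_ggc1 = eval_ggc1(prm, r0, r_inf, grid61)
            assert np.max(np.abs(z_ggc1 - z_gc1) / np.abs(z_gc1)) < 1e-12
            assert np.max(np.abs(z_gc1 - z_cole) / np.abs(z_cole)) < 1e-12


class TestClassicShapeInvariants:
    def test_re_monotone_and_capacitive(self, grid61):
        rng = np.random.default_rng(5)
        for _ in range(100):
            r0, r_inf, alpha, tau = random_cole_params(rng)
            z = eval_cole(r0, r_inf, alpha, tau, grid61)
            assert np.all(np.diff(z.real) <= 1e-12 * r0)
            assert np.all(-z.imag >= -1e-12 * r0)


class TestOracleEquivalence:
    def test_thousand_random_pairs(self):
        rng = np.random.default_rng(2024)
        kinds = ["cole", "gencole", "ggc"]
        for _ in range(1000):
            kind = kinds[int(rng.integers(3))]
            prm = ElementParams(
                dr=float(rng.uniform(1e4, 2e6)),
                alpha=float(rng.uniform(0.3, 0.99)),
                tau=float(np.exp(rng.uniform(-2, 1.5))),
                p=float(np.exp(rng.uniform(-1, 1))),
                beta=float(rng.uniform(-0.1, 0.1)) if kind != "cole" else 0.0,
                maclaurin=(
                    MaclaurinCoeffs(*rng.uniform(-0.05, 0.05, size=4))
                    if kind == "ggc"
                    else None
                ),
            )
            f = float(np.exp(rng.uniform(np.log(0.1), np.log(1e5))))
            from fracz.models import element_impedance

            got = element_impedance(Element(kind, prm), FrequencyGrid(np.array([f])))[0]
            want = __import__("conftest").oracle_element(kind, prm, f)
            assert abs(got - want) <= 1e-10 * max(abs(want), 1e-30)


class TestDCLimit:
    def test_classic_dc_limit_matches_r0(self):
        spec = table_fixture("C2-d025")
        z = dc_limit(spec)
        assert z.real == pytest.approx(spec.r0_classic, rel=1e-4)

    def test_generalized_dc_reported_numerically(self):
        spec = table_fixture("GC2-d025")
        z = dc_limit(spec)
        assert np.isfinite(z.real) and np.isfinite(z.imag)


class TestModelSpecValidation:
    def test_label_kind_mismatch(self):
        prm = ElementParams(dr=1e5, alpha=0.8, tau=0.5)
        with pytest.raises(InvalidSpecError, match="requires element kinds"):
            ModelSpec("GC1", 1e3, (Element("cole", prm),))

    def test_ggc_requires_maclaurin(self):
        with pytest.raises(InvalidSpecError, match="maclaurin"):
            Element("ggc", ElementParams(dr=1e5, alpha=0.8, tau=0.5))

    def test_maclaurin_implies_ggc(self):
        prm = ElementParams(
            dr=1e5, alpha=0.8, tau=0.5, maclaurin=MaclaurinCoeffs(0.01, 0, 0, 0)
        )
        with pytest.raises(InvalidSpecError):
            Element("gencole", prm)

    def test_r0_classic_total(self):
        spec = table_fixture("C2-d025")
        total = spec.r_inf + sum(e.params.dr for e in spec.elements)
        assert spec.r0_classic == total
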