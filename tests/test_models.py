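"""Forward model evaluation, activity coefficients, SLE closure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import terpsol as ts
from terpsol.models import ModelError, sle_solve_x_grid

TM = ts.DEHYDROABIETIC_ACID.Tm
R = ts.R_GAS


class TestClosedFormModels:
    def test_apelblat_printed_parameters(self):
        # fitted parameters for the α-pinene system, evaluated at 299.45 K
        p = ts.ApelblatParams(A=-48.47524, B=521.07863, C=7.78171)
        assert ts.apelblat_x(p, 299.45) == pytest.approx(0.09402, abs=2e-4)

    def test_apelblat_limits(self):
        assert ts.apelblat_x(ts.ApelblatParams(0.0, 0.0, 0.0), 321.0) == 1.0
        # C = 0 collapses to the van't Hoff form
        a = ts.apelblat_x(ts.ApelblatParams(2.0, -800.0, 0.0), 310.0)
        v = ts.vanthoff_x(ts.VantHoffParams(2.0, -800.0), 310.0)
        assert a == pytest.approx(v, rel=1e-15)
        with pytest.raises(ModelError):
            ts.apelblat_x(ts.ApelblatParams(0, 0, 0), -1.0)

    def test_vanthoff_evaluation(self):
        p = ts.VantHoffParams(A=4.14712, B=-1952.44054)
        assert ts.vanthoff_x(p, 299.45) == pytest.approx(
            np.exp(4.14712 - 1952.44054 / 299.45), rel=1e-12
        )
        assert ts.vanthoff_x(ts.VantHoffParams(0.0, 0.0), 300.0) == 1.0

    def test_lambda_h_limits(self):
        p = ts.LambdaHParams(lam=0.63102, h=2847.00662)
        assert ts.lambda_h_x(p, TM, TM) == pytest.approx(1.0, rel=1e-14)
        # λ = 1 is the ideal van't Hoff-in-(1/T − 1/Tm) form
        one = ts.LambdaHParams(lam=1.0, h=2000.0)
        T = 310.0
        assert ts.lambda_h_x(one, T, TM) == pytest.approx(
            np.exp(-2000.0 * (1 / T - 1 / TM)), rel=1e-12
        )
        with pytest.raises(ModelError):
            ts.lambda_h_x(p, TM + 1.0, TM)
        with pytest.raises(ModelError):
            ts.LambdaHParams(lam=-0.5, h=100.0)

    @given(
        lam=st.floats(0.05, 5.0),
        h=st.floats(100.0, 8000.0),
        T=st.floats(280.0, 440.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_lambda_h_inverts_defining_relation(self, lam, h, T):
        """The closed form substituted back into ln(1 + λ(1−x)/x) must
        reproduce λh(1/T − 1/Tm) to near machine precision."""
        x = float(ts.lambda_h_x(ts.LambdaHParams(lam, h), T, TM))
        assert 0 < x <= 1
        lhs = np.log1p(lam * (1 - x) / x)
        rhs = lam * h * (1 / T - 1 / TM)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_lambda_h_matches_numeric_root(self):
        p = ts.LambdaHParams(lam=0.63102, h=2847.00662)
        T = 299.45
        f = lambda x: np.log1p(p.lam * (1 - x) / x) - p.lam * p.h * (1 / T - 1 / TM)
        x_root = brentq(f, 1e-9, 1 - 1e-9, xtol=1e-15)
        x_closed = float(ts.lambda_h_x(p, T, TM))
        assert x_closed == pytest.approx(x_root, rel=1e-10)
        assert x_closed == pytest.approx(0.09516, abs=2e-5)

    def test_ideal_solubility(self, solute):
        assert ts.ideal_solubility(TM, solute) == pytest.approx(1.0, rel=1e-14)
        assert ts.ideal_solubility(299.45, solute) == pytest.approx(0.1065, abs=2e-4)
        T = np.linspace(280.0, TM, 50)
        assert np.all(np.diff(ts.ideal_solubility(T, solute)) > 0)


def _numeric_dlngamma(gamma_pair, x1, eps=1e-6):
    g_hi = [np.log(g) for g in gamma_pair(x1 + eps)]
    g_lo = [np.log(g) for g in gamma_pair(x1 - eps)]
    return [(h - l) / (2 * eps) for h, l in zip(g_hi, g_lo)]


class TestNRTL:
    def test_ideal_limit(self):
        g1, g2 = ts.nrtl_gamma(0.3, 310.0, ts.NRTLParams(0.0, 0.0))
        assert g1 == pytest.approx(1.0, rel=1e-14)
        assert g2 == pytest.approx(1.0, rel=1e-14)

    def test_infinite_dilution_closed_form(self):
        p = ts.NRTLParams(4616.96557, -2402.45933)
        T = 299.45
        t12 = p.dg12 / (R * T)
        t21 = p.dg21 / (R * T)
        expected = t21 + t12 * np.exp(-p.alpha * t12)
        g1, _ = ts.nrtl_gamma(1e-9, T, p)
        assert np.log(g1) == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("dg12, dg21", [(4616.97, -2402.46), (-1500.0, 2500.0)])
    def test_gamma_matches_excess_energy_derivative(self, dg12, dg21):
        """ln γi must equal ∂(n·gE/RT)/∂ni of the NRTL excess Gibbs energy."""
        p = ts.NRTLParams(dg12, dg21)
        T = 310.0

        def nGE(n1, n2):
            n = n1 + n2
            x1, x2 = n1 / n, n2 / n
            t12, t21 = p.dg12 / (R * T), p.dg21 / (R * T)
            G12, G21 = np.exp(-p.alpha * t12), np.exp(-p.alpha * t21)
            return n * x1 * x2 * (
                t21 * G21 / (x1 + x2 * G21) + t12 * G12 / (x2 + x1 * G12)
            )

        x1 = 0.3
        eps = 1e-7
        ln_g1 = (nGE(x1 + eps, 1 - x1) - nGE(x1 - eps, 1 - x1)) / (2 * eps)
        ln_g2 = (nGE(x1, 1 - x1 + eps) - nGE(x1, 1 - x1 - eps)) / (2 * eps)
        g1, g2 = ts.nrtl_gamma(x1, T, p)
        assert np.log(g1) == pytest.approx(ln_g1, abs=1e-6)
        assert np.log(g2) == pytest.approx(ln_g2, abs=1e-6)

    def test_gibbs_duhem(self):
        p = ts.NRTLParams(3000.0, -1200.0)
        T = 315.0
        x1 = 0.3
        d1, d2 = _numeric_dlngamma(lambda x: ts.nrtl_gamma(x, T, p), x1)
        assert x1 * d1 + (1 - x1) * d2 == pytest.approx(0.0, abs=1e-5)


class TestUNIQUAC:
    def test_identical_molecules_ideal(self):
        s = ts.UNIQUACStructure(r=(2.5, 2.5), q=(2.0, 2.0))
        g1, g2 = ts.uniquac_gamma(0.4, 310.0, ts.UNIQUACParams(0.0, 0.0), s)
        assert g1 == pytest.approx(1.0, rel=1e-12)
        assert g2 == pytest.approx(1.0, rel=1e-12)

    def test_gibbs_duhem(self):
        s = ts.structure_for("dehydroabietic acid", ("(-)-alpha-pinene",))
        p = ts.UNIQUACParams(2789.63759, -1207.90976)
        T = 310.0
        x1 = 0.3
        d1, d2 = _numeric_dlngamma(lambda x: ts.uniquac_gamma(x, T, p, s), x1)
        assert x1 * d1 + (1 - x1) * d2 == pytest.approx(0.0, abs=1e-5)

    def test_component_swap_symmetry(self):
        s = ts.UNIQUACStructure(r=(12.3, 6.054), q=(9.332, 4.756))
        s_swapped = ts.UNIQUACStructure(r=(6.054, 12.3), q=(4.756, 9.332))
        p = ts.UNIQUACParams(1500.0, -900.0)
        p_swapped = ts.UNIQUACParams(-900.0, 1500.0)
        g1, g2 = ts.uniquac_gamma(0.3, 320.0, p, s)
        h2, h1 = ts.uniquac_gamma(0.7, 320.0, p_swapped, s_swapped)
        assert g1 == pytest.approx(h1, rel=1e-12)
        assert g2 == pytest.approx(h2, rel=1e-12)

    def test_structure_from_groups(self):
        r, q = ts.uniquac_structure_from_groups({"CH3": 1}, {"CH3": (1.0, 1.0)})
        assert (r, q) == (1.0, 1.0)
        base = ts.uniquac_structure_from_groups({"CH3": 2, "CH2": 4})
        double = ts.uniquac_structure_from_groups({"CH3": 4, "CH2": 8})
        assert double == pytest.approx(tuple(2 * v for v in base), rel=1e-14)
        # n-hexane from the shipped subgroup constants
        assert base[0] == pytest.approx(4.4998, abs=1e-4)
        assert base[1] == pytest.approx(3.856, abs=1e-3)
        with pytest.raises(KeyError):
            ts.uniquac_structure_from_groups({"XYZ": 1})


class TestSLEClosure:
    def test_ideal_gamma_returns_ideal(self, solute):
        x = ts.sle_solve_x(lambda x1, T: 1.0, 310.0, solute)
        assert x == pytest.approx(float(ts.ideal_solubility(310.0, solute)), rel=1e-9)

    def test_constant_gamma_scales(self, solute):
        x = ts.sle_solve_x(lambda x1, T: 2.0, 310.0, solute)
        assert x == pytest.approx(float(ts.ideal_solubility(310.0, solute)) / 2, rel=1e-9)

    def test_against_bisection_oracle(self, solute):
        """Fixed-point solve must agree with brute-force root bracketing for
        randomly drawn NRTL parameter sets."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            p = ts.NRTLParams(*rng.uniform(-5000.0, 5000.0, size=2))
            T = rng.uniform(295.0, 340.0)
            x_id = float(ts.ideal_solubility(T, solute))
            g1 = lambda x, T=T: float(ts.nrtl_gamma(x, T, p)[0])
            f = lambda x: x * g1(x) - x_id
            x_ref = brentq(f, 1e-12, 1 - 1e-9, xtol=1e-14)
            x_fp = ts.sle_solve_x(g1, T, solute)
            assert x_fp == pytest.approx(x_ref, abs=1e-8)

    def test_printed_nrtl_parameters(self, solute):
        # α-pinene interaction energies; tolerance reflects the rounded
        # printed parameters and the unstated closure of the source fit
        p = ts.NRTLParams(4616.96557, -2402.45933)
        x = ts.sle_solve_x(lambda x1, T: float(ts.nrtl_gamma(x1, T, p)[0]), 299.45, solute)
        assert x == pytest.approx(0.09319, abs=2e-3)

    def test_grid_solver_matches_scalar(self, solute):
        p = ts.NRTLParams(3000.0, -1000.0)
        T = np.array([300.0, 320.0, 340.0])
        xs = sle_solve_x_grid(lambda x, T: ts.nrtl_gamma(x, T, p)[0], T, solute)
        for Ti, xi in zip(T, xs):
            scalar = ts.sle_solve_x(
                lambda x, T: float(ts.nrtl_gamma(x, T, p)[0]), float(Ti), solute
            )
            assert xi == pytest.approx(scalar, abs=1e-9)


class TestWilsonRules:
    def test_pure_solvent_boundaries(self):
        p = ts.WilsonParams(lam12=-1.3, lam21=0.7)
        assert ts.modified_wilson_xm(p, 1.0, 0.2, 0.1) == pytest.approx(0.2, rel=1e-12)
        assert ts.modified_wilson_xm(p, 0.0, 0.2, 0.1) == pytest.approx(0.1, rel=1e-12)

    def test_unit_parameters_identity(self):
        # λ12 = λ21 = 1 with equal pure solubilities returns that solubility
        p = ts.WilsonParams(1.0, 1.0)
        assert ts.modified_wilson_xm(p, 0.5, 0.15, 0.15) == pytest.approx(0.15, rel=1e-12)

    def test_vanthoff_variant_consistency(self):
        vh = ts.WilsonVantHoffParams(
            lam12=0.8, lam21=1.4, A1=4.147, B1=-1952.4, A2=3.853, B2=-1859.7
        )
        T = 315.0
        x1 = np.exp(vh.A1 + vh.B1 / T)
        x2 = np.exp(vh.A2 + vh.B2 / T)
        direct = ts.wilson_vanthoff_xm(vh, 0.4, T)
        via_pure = ts.modified_wilson_xm(ts.WilsonParams(0.8, 1.4), 0.4, x1, x2)
        assert direct == pytest.approx(via_pure, rel=1e-12)
        # boundary reduces to the pure van't Hoff curve
        assert ts.wilson_vanthoff_xm(vh, 1.0, T) == pytest.approx(x1, rel=1e-12)

    def test_singular_denominator(self):
        with pytest.raises(ModelError):
            ts.modified_wilson_xm(ts.WilsonParams(-1.0, 0.5), 0.5, 0.2, 0.1)


class TestMonotoneInTemperature:
    """Every fitted model's x(T) rises with T over the measured range."""

    def test_fitted_curves_increase(self, solute):
        T = np.linspace(295.0, 340.0, 40)
        curves = [
            ts.apelblat_x(ts.ApelblatParams(-48.47524, 521.07863, 7.78171), T),
            ts.lambda_h_x(ts.LambdaHParams(0.63102, 2847.00662), T, TM),
            ts.vanthoff_x(ts.VantHoffParams(4.14712, -1952.44054), T),
        ]
        p = ts.NRTLParams(4616.96557, -2402.45933)
        curves.append(
            sle_solve_x_grid(lambda x, T: ts.nrtl_gamma(x, T, p)[0], T, solute)
        )
        for xc in curves:
            assert np.all(np.diff(xc) > 0)
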