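import numpy as np
import pandas as pd
import pytest
import sympy as sp

from hepatodyn import ratelaws as rl
from hepatodyn.boundary import BoundaryProfile
from hepatodyn.functions import demo_registry
from hepatodyn.model import (Compartment, KineticModel, Parameter, Reaction,
                             Species)
from hepatodyn.sensitivity import (UndefinedCoefficientError, dynamic_mca,
                                   finite_response, infinitesimal_response,
                                   monte_carlo_envelope, normalize_signed,
                                   pi_elasticity, relative_difference_D,
                                   threshold_census, time_averaged_response)
from hepatodyn.simulate import compile_model


def mm_model(vm=2.0, km=1.0):
    m = KineticModel(id="mm1")
    m.compartments["c"] = Compartment("c", 1.0)
    m.species["S"] = Species("S", "c", "internal", 1.0)
    m.species["P"] = Species("P", "c", "internal", 0.0)
    m.parameters["vm"] = Parameter("vm", vm, "VMAX")
    m.parameters["km"] = Parameter("km", km, "KM")
    m.reactions["R"] = Reaction("R", {"S": -1, "P": 1},
                                rl.reversible_mm("vm", {"S": "km"}))
    m.validate()
    return m


class TestPiElasticity:
    def test_vmax_prefactor_is_exactly_one(self):
        m = mm_model()
        state = {"S": 0.37, "P": 0.1}
        sym = pi_elasticity(m, "R", "vm", state, method="symbolic")
        num = pi_elasticity(m, "R", "vm", state, method="numeric")
        assert sym == 1.0
        assert abs(num - 1.0) < 1e-8

    def test_km_elasticity_at_half_saturation(self):
        # v = vm S/(km+S): pi wrt km at S=km is -1/2
        m = mm_model(km=0.8)
        val = pi_elasticity(m, "R", "km", {"S": 0.8, "P": 0.0})
        assert val == pytest.approx(-0.5, abs=1e-12)

    def test_hill_exponent_elasticity_matches_symbolic_oracle(self):
        m = KineticModel(id="hill")
        m.compartments["c"] = Compartment("c", 1.0)
        m.species["S"] = Species("S", "c", "internal", 1.0)
        m.species["P"] = Species("P", "c", "internal", 0.0)
        m.parameters["vm"] = Parameter("vm", 3.0, "VMAX")
        m.parameters["k"] = Parameter("k", 2.0, "KM")
        m.parameters["n"] = Parameter("n", 2.5, "N")
        m.reactions["H"] = Reaction("H", {"S": -1, "P": 1},
                                    rl.hill("vm", "S", "k", "n"))
        m.validate()
        # independent oracle: differentiate a hand-written expression
        S, k, n = sp.symbols("S k n", positive=True)
        v = S**n / (k**n + S**n)
        expected = float((n / v * sp.diff(v, n)).subs({S: 1.3, k: 2.0, n: 2.5}))
        got = pi_elasticity(m, "H", "n", {"S": 1.3, "P": 0.0})
        assert got == pytest.approx(expected, rel=1e-10)

    def test_symbolic_and_numeric_agree(self):
        m = mm_model()
        state = {"S": 2.3, "P": 0.4}
        for pid in ("vm", "km"):
            s = pi_elasticity(m, "R", pid, state, method="symbolic")
            n = pi_elasticity(m, "R", pid, state, method="numeric")
            assert abs(s - n) <= 1e-6 * max(1.0, abs(s))

    def test_inactive_reaction_is_undefined(self):
        m = mm_model()
        with pytest.raises(UndefinedCoefficientError, match="not operative"):
            pi_elasticity(m, "R", "vm", {"S": 0.0, "P": 0.0})


def linear_source_sink():
    """Steady state S* = k_in/k_out: linear in k_in, 1/p in k_out."""
    m = KineticModel(id="lin")
    m.compartments["e"] = Compartment("e", 1.0)
    m.compartments["c"] = Compartment("c", 1.0)
    m.species["X_ext"] = Species("X_ext", "e", "external", 1.0)
    m.species["S"] = Species("S", "c", "internal", 0.5)
    m.parameters["k_in"] = Parameter("k_in", 2.0)
    m.parameters["k_out"] = Parameter("k_out", 4.0)
    m.reactions["IN"] = Reaction("IN", {"X_ext": -1, "S": 1},
                                 rl.mass_action("k_in", {"X_ext": 1}))
    m.reactions["OUT"] = Reaction("OUT", {"S": -1, "X_ext": 1},
                                  rl.mass_action("k_out", {"S": 1}))
    m.validate()
    return m


class TestResponseCoefficients:
    BND = {"X_ext": 1.0}

    @pytest.mark.parametrize("lam", [0.5, 1.5, 2.0])
    def test_linear_variable_has_unit_response_for_any_lambda(self, lam):
        rec = finite_response(linear_source_sink(), self.BND, "conc:S",
                              "k_in", lam)
        assert rec.value == pytest.approx(1.0, abs=1e-6)

    def test_independent_variable_has_zero_response(self):
        # the flux through IN does not depend on k_out
        rec = finite_response(linear_source_sink(), self.BND, "flux:IN",
                              "k_out", 1.5)
        assert rec.value == pytest.approx(0.0, abs=1e-8)

    def test_reciprocal_variable_closed_form(self):
        # S* = c/p in k_out: R(lambda) = (1/lambda - 1)/(lambda - 1) = -1/lambda
        lam = 2.0
        rec = finite_response(linear_source_sink(), self.BND, "conc:S",
                              "k_out", lam)
        assert rec.value == pytest.approx(-1.0 / lam, abs=1e-6)

    def test_infinitesimal_power_law_exponent(self):
        # S* = k_in / k_out: log-derivatives are +1 and -1
        m = linear_source_sink()
        r_in = infinitesimal_response(m, self.BND, "conc:S", "k_in")
        r_out = infinitesimal_response(m, self.BND, "conc:S", "k_out")
        assert r_in.value == pytest.approx(1.0, abs=1e-6)
        assert r_out.value == pytest.approx(-1.0, abs=1e-6)

    def test_finite_converges_to_infinitesimal(self):
        m = mm_model_with_sink()
        inf = infinitesimal_response(m, {"X_ext": 1.0}, "conc:S", "vm").value
        gaps = []
        for lam in (1.5, 1.25, 1.1, 1.05):
            fin = finite_response(m, {"X_ext": 1.0}, "conc:S", "vm", lam).value
            gaps.append(abs(fin - inf))
        assert all(a >= b - 1e-10 for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] < gaps[0] / 3.0

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            finite_response(linear_source_sink(), self.BND, "conc:S", "k_in", 1.0)


def mm_model_with_sink():
    """Nonlinear steady state: constant source, MM sink with Vmax vm."""
    m = KineticModel(id="mm-sink")
    m.compartments["e"] = Compartment("e", 1.0)
    m.compartments["c"] = Compartment("c", 1.0)
    m.species["X_ext"] = Species("X_ext", "e", "external", 1.0)
    m.species["S"] = Species("S", "c", "internal", 0.5)
    m.parameters["k"] = Parameter("k", 0.5)
    m.parameters["vm"] = Parameter("vm", 1.5, "VMAX")
    m.parameters["km"] = Parameter("km", 1.0, "KM")
    m.reactions["IN"] = Reaction("IN", {"X_ext": -1, "S": 1},
                                 rl.mass_action("k", {"X_ext": 1}))
    m.reactions["OUT"] = Reaction("OUT", {"S": -1, "X_ext": 1},
                                  rl.reversible_mm("vm", {"S": "km"}))
    m.validate()
    return m


class TestDemoResponse:
    def test_glucokinase_control_of_glucose_flux(self, demo_model,
                                                 demo_compiled, demo_mean):
        """R̃ of the glucose transport flux to glucokinase Vmax agrees with
        the extrapolated one-sided finite-response sequence (λ → 1)."""
        inf = infinitesimal_response(demo_model, demo_mean, "flux:GLUT2",
                                     "v_gk", compiled=demo_compiled)
        fins = [finite_response(demo_model, demo_mean, "flux:GLUT2", "v_gk",
                                lam, compiled=demo_compiled).value
                for lam in (1.04, 1.02)]
        # Richardson extrapolation of the one-sided sequence to lambda = 1
        extrapolated = 2 * fins[1] - fins[0]
        assert inf.value == pytest.approx(extrapolated, abs=1e-3)
        assert abs(inf.value) > 0.01  # glucokinase does control this flux


class TestRelativeDifferenceD:
    def test_zero_when_equal(self):
        assert relative_difference_D(1.0, 1.0) == 0.0

    def test_twenty_percent(self):
        assert relative_difference_D(1.2, 1.0) == pytest.approx(20.0)

    def test_linear_system_has_zero_D_at_both_lambdas(self):
        m = linear_source_sink()
        inf = infinitesimal_response(m, {"X_ext": 1.0}, "conc:S", "k_in").value
        for lam in (0.5, 1.5):
            fin = finite_response(m, {"X_ext": 1.0}, "conc:S", "k_in", lam).value
            assert abs(relative_difference_D(inf, fin)) < 1e-3

    def test_undefined_for_zero_reference(self):
        with pytest.raises(UndefinedCoefficientError):
            relative_difference_D(1.0, 0.0)


class TestThresholdCensus:
    def test_all_zero_matrix(self):
        mat = pd.DataFrame(np.zeros((5, 24)))
        cen = threshold_census(mat, 0.1)
        assert cen["n_affecting_any"] == 0
        assert cen["frequency"] == {}

    def test_identity_like_matrix(self):
        mat = pd.DataFrame(np.eye(24))
        cen = threshold_census(mat, 1.0)
        assert cen["n_affecting_any"] == 24
        assert cen["frequency"] == {1: 24}

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(0, 0.6, size=(50, 24))
        vals[rng.random(vals.shape) < 0.05] = np.nan  # tagged undefined
        mat = pd.DataFrame(vals)
        for r_star in (0.1, 0.5, 1.0):
            cen = threshold_census(mat, r_star)
            # brute force, element by element
            counts = []
            for i in range(50):
                c = sum(1 for j in range(24)
                        if np.isfinite(vals[i, j]) and abs(vals[i, j]) >= r_star)
                counts.append(c)
            assert list(cen["per_parameter"]) == counts
            for k, n in cen["frequency"].items():
                assert n == sum(1 for c in counts if c == k)
        assert cen["n_undefined"] == int(np.isnan(vals).sum())


class TestTimeAveragedResponse:
    T = np.linspace(0, 24, 97)

    def test_identical_trajectories_score_zero(self):
        y = np.sin(self.T) + 2
        assert time_averaged_response(y, y, self.T) == 0.0

    def test_constant_relative_offset(self):
        y = np.sin(self.T) + 2
        assert time_averaged_response(y, 1.1 * y, self.T) == pytest.approx(0.1)

    def test_piecewise_linear_hand_quadrature(self):
        t = np.array([0.0, 1.0, 2.0])
        y_ref = np.array([1.0, 1.0, 1.0])
        y_pert = np.array([1.0, 2.0, 1.0])
        # integral |diff| = 2 * (1/2 * 1 * 1) = 1; integral |ref| = 2
        assert time_averaged_response(y_ref, y_pert, t) == pytest.approx(0.5)

    def test_invariant_under_y_rescaling(self):
        y = np.cos(self.T) + 3
        yp = y + 0.2 * np.sin(2 * self.T)
        a = time_averaged_response(y, yp, self.T)
        b = time_averaged_response(-7 * y, -7 * yp, self.T)
        assert a == pytest.approx(b, rel=1e-12)

    def test_grid_refinement_stability(self):
        t2 = np.linspace(0, 24, 193)
        y = lambda t: np.cos(2 * np.pi * t / 24) + 3
        yp = lambda t: y(t) + 0.3 * np.sin(2 * np.pi * t / 12)
        a = time_averaged_response(y(self.T), yp(self.T), self.T)
        b = time_averaged_response(y(t2), yp(t2), t2)
        assert abs(a - b) < 1e-4

    def test_zero_reference_undefined(self):
        with pytest.raises(UndefinedCoefficientError):
            time_averaged_response(np.zeros_like(self.T),
                                   np.ones_like(self.T), self.T)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            time_averaged_response(np.ones(5), np.ones(4), np.arange(5))


class TestNormalization:
    def test_signed_matrix_maps_into_unit_interval(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(0, 2, (10, 6)))
        norm = normalize_signed(df)
        assert np.nanmax(norm.to_numpy()) == pytest.approx(1.0)
        assert np.nanmin(norm.to_numpy()) == pytest.approx(-1.0)
        assert ((norm.to_numpy() >= -1 - 1e-12)
                & (norm.to_numpy() <= 1 + 1e-12)).all()

    def test_per_function_option(self):
        df = pd.DataFrame([[1.0, 10.0], [0.5, 5.0]])
        norm = normalize_signed(df, per_function=True)
        assert norm.iloc[0, 0] == 1.0 and norm.iloc[0, 1] == 1.0


def two_reaction_forced_model():
    """Small forced model for dynamic-MCA mechanics tests."""
    m = KineticModel(id="forced")
    m.compartments["e"] = Compartment("e", 1.0)
    m.compartments["c"] = Compartment("c", 1.0)
    m.species["X_ext"] = Species("X_ext", "e", "external", 1.0)
    m.species["S"] = Species("S", "c", "internal", 1.0)
    m.parameters["v_in"] = Parameter("v_in", 2.0, "VMAX")
    m.parameters["km_in"] = Parameter("km_in", 1.0, "KM")
    m.parameters["v_out"] = Parameter("v_out", 3.0, "VMAX")
    m.parameters["km_out"] = Parameter("km_out", 1.0, "KM")
    m.reactions["IN"] = Reaction("IN", {"X_ext": -1, "S": 1},
                                 rl.reversible_mm("v_in", {"X_ext": "km_in"}))
    m.reactions["OUT"] = Reaction("OUT", {"S": -1, "X_ext": 1},
                                  rl.reversible_mm("v_out", {"S": "km_out"}))
    m.validate()
    return m


def small_registry():
    from hepatodyn.functions import MetabolicFunction, MetabolicFunctionRegistry
    return MetabolicFunctionRegistry([
        MetabolicFunction(1, "substrate", "conc:S"),
        MetabolicFunction(2, "uptake", "uptake:X_ext"),
    ])


def forced_boundary():
    t = np.linspace(0, 24, 49)
    y = 1.0 + 0.3 * np.cos(2 * np.pi * (t - 12) / 24)
    y[-1] = y[0]
    return BoundaryProfile(t, {"X_ext": y}, periodic=True)


class TestDynamicMCA:
    def test_zero_delta_gives_zero_matrix(self):
        res = dynamic_mca(two_reaction_forced_model(), forced_boundary(),
                          small_registry(), delta=0.0, run_in_days=1)
        assert np.allclose(res.raw.to_numpy(float), 0.0, atol=1e-9)

    def test_normalized_entries_bounded_with_max_attained(self):
        res = dynamic_mca(two_reaction_forced_model(), forced_boundary(),
                          small_registry(), delta=0.1, run_in_days=1)
        vals = res.normalized.to_numpy(float)
        assert np.nanmin(vals) >= -1 - 1e-12
        assert np.nanmax(vals) <= 1 + 1e-12
        if np.any(vals > 0):
            assert np.nanmax(vals) == pytest.approx(1.0)
        assert not res.failed

    def test_raw_matrix_nonnegative(self):
        res = dynamic_mca(two_reaction_forced_model(), forced_boundary(),
                          small_registry(), delta=0.1, run_in_days=1)
        assert (res.raw.to_numpy(float) >= 0).all()


class TestMonteCarlo:
    def test_zero_variation_collapses_onto_reference(self):
        env = monte_carlo_envelope(two_reaction_forced_model(),
                                   forced_boundary(), small_registry(),
                                   n=5, variation=0.0, seed=1, run_in_days=1)
        for idx in (1, 2):
            assert np.allclose(env.lower[idx], env.reference[idx], atol=1e-12)
            assert np.allclose(env.upper[idx], env.reference[idx], atol=1e-12)

    def test_bitwise_reproducible_under_seed(self):
        kw = dict(n=8, variation=0.1, seed=123, run_in_days=1)
        a = monte_carlo_envelope(two_reaction_forced_model(),
                                 forced_boundary(), small_registry(), **kw)
        b = monte_carlo_envelope(two_reaction_forced_model(),
                                 forced_boundary(), small_registry(), **kw)
        assert np.array_equal(a.lower[1], b.lower[1])
        assert np.array_equal(a.upper[2], b.upper[2])

    def test_two_replicates_band_is_min_max(self):
        env = monte_carlo_envelope(two_reaction_forced_model(),
                                   forced_boundary(), small_registry(),
                                   n=2, variation=0.1, seed=5, run_in_days=1,
                                   quantiles=(0.0, 100.0))
        assert (env.lower[1] <= env.upper[1]).all()

    def test_envelope_width_scales_linearly_for_linear_model(self):
        """First-order exchange: the trajectory is linear in the rate
        constants, so doubling the Vmax variation doubles the band width."""
        m = KineticModel(id="lin2")
        m.compartments["e"] = Compartment("e", 1.0)
        m.compartments["c"] = Compartment("c", 1.0)
        m.species["X_ext"] = Species("X_ext", "e", "external", 1.0)
        m.species["S"] = Species("S", "c", "internal", 0.0)
        m.parameters["k_in"] = Parameter("k_in", 1.0, "VMAX")
        m.reactions["IN"] = Reaction("IN", {"X_ext": -1, "S": 1},
                                     rl.mass_action("k_in", {"X_ext": 1}))
        # S grows linearly with k_in; band width at fixed t scales with it
        m.validate()
        reg = small_registry()
        kw = dict(n=40, seed=9, run_in_days=0)
        env1 = monte_carlo_envelope(m, forced_boundary(), reg, variation=0.05, **kw)
        env2 = monte_carlo_envelope(m, forced_boundary(), reg, variation=0.10, **kw)
        w1 = (env1.upper[1] - env1.lower[1])[-1]
        w2 = (env2.upper[1] - env2.lower[1])[-1]
        assert w2 == pytest.approx(2 * w1, rel=0.15)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_envelope(two_reaction_forced_model(),
                                 forced_boundary(), small_registry(), n=1)


class TestDemoRegistry:
    def test_indices_and_order_stable(self):
        reg = demo_registry()
        assert len(reg) == 24
        assert [f.index for f in reg] == list(range(1, 25))
        assert reg[1].name == "glucose exchange rate"
        assert reg[24].name == "NADP/NADPH ratio (cytosolic)"

    def test_every_function_defined_on_demo_trajectory(self, diurnal_traj):
        vals = demo_registry().evaluate(diurnal_traj)
        for idx, series in vals.items():
            assert np.all(np.isfinite(series)), f"function {idx} not finite"
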