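import numpy as np
import pandas as pd
import pytest

from hepatodyn.scenarios import (DrugInhibition, DrugTarget, EnzymeVariant,
                                 InfusionProfile, ProteomeScaling,
                                 ScenarioConfigurationError, apply_drug,
                                 apply_proteome_scaling, compare_galactosemia,
                                 ethanol_bolus, galactosemia_run, hypoxia_scan,
                                 read_proteome_table, vpa_scenario,
                                 default_vpa_inhibition)
from hepatodyn.simulate import compile_model, find_steady_state, simulate
from hepatodyn.units import po2_mmhg_to_mm


class TestInfusionProfile:
    def test_negative_rates_rejected(self):
        with pytest.raises(ScenarioConfigurationError):
            InfusionProfile("x", [0, 1], [-1.0, 0.0])

    def test_bolus_has_finite_support(self):
        inf = InfusionProfile.bolus("x", 50.0, 2.0, 3.0)
        assert inf.rate_at(1.0) == 0.0
        assert inf.rate_at(3.5) == pytest.approx(50.0)
        assert inf.rate_at(10.0) == 0.0

    def test_gamma_appearance_integrates_to_total(self):
        inf = InfusionProfile.gamma_appearance("x", total=120.0, start=2.0)
        area = np.trapezoid(inf.rates, inf.times)
        assert area == pytest.approx(120.0, rel=1e-3)
        assert np.all(inf.rates[inf.times < 2.0] == 0.0)


class TestHypoxiaScan:
    @pytest.fixture()
    def scan(self, hypoxia_table):
        return hypoxia_table

    def test_normoxic_point_self_normalizes(self, scan):
        top = scan.iloc[-1]
        assert top["rel_glucose_production"] == pytest.approx(1.0, abs=0.01)
        assert top["rel_urea_production"] == pytest.approx(1.0, abs=0.01)

    def test_productions_monotone_in_po2(self, scan):
        assert scan["converged"].all()
        glc = scan["rel_glucose_production"].to_numpy()
        urea = scan["rel_urea_production"].to_numpy()
        assert np.all(np.diff(glc) >= -1e-6)   # sorted ascending in pO2
        assert np.all(np.diff(urea) >= -1e-6)

    def test_anoxia_collapses_production(self, scan):
        low = scan.iloc[0]
        assert low["rel_glucose_production"] < 0.20
        assert low["rel_urea_production"] < 0.20

    def test_transition_centered_below_25_mmhg(self, scan):
        half = scan[scan["rel_urea_production"] <= 0.5]
        assert half["po2_mmhg"].max() < 25.0

    def test_midgrid_point_equals_direct_steady_state(self, demo_model,
                                                      demo_compiled,
                                                      demo_mean, scan):
        row = scan[scan["po2_mmhg"] == 15].iloc[0]
        clamp = dict(demo_mean)
        clamp["o2_ext"] = po2_mmhg_to_mm(15.0)
        ss = find_steady_state(demo_model, clamp, compiled=demo_compiled)
        assert row["urea_production"] == pytest.approx(ss.flux("UREA_EXP"),
                                                       rel=1e-5)

    def test_negative_grid_rejected(self, demo_model, demo_mean):
        with pytest.raises(ScenarioConfigurationError):
            hypoxia_scan(demo_model, [-5.0], demo_mean)


class TestEthanol:
    @pytest.fixture()
    def bolus_run(self, ethanol_run):
        return ethanol_run

    def test_zero_infusion_identical_to_reference(self, demo_model,
                                                  demo_boundary, warm_state):
        res = ethanol_bolus(demo_model, demo_boundary,
                            InfusionProfile.zero("etoh_ext"), x0=warm_state,
                            t_span=(0.0, 6.0))
        assert np.array_equal(res.trajectory.state, res.reference.state)

    def test_plasma_ethanol_rises_and_clears(self, bolus_run):
        pe = bolus_run.panels["plasma_ethanol_mM"].to_numpy()
        assert pe.max() > 5.0
        assert pe[-1] < 0.05 * pe.max()

    def test_clearance_saturation_makes_rise_superlinear(self, demo_model,
                                                         demo_boundary,
                                                         warm_state):
        peaks = []
        for rate in (40.0, 120.0):
            inf = InfusionProfile.bolus("etoh_ext", rate, 2.0, 3.0)
            res = ethanol_bolus(demo_model, demo_boundary, inf, x0=warm_state,
                                t_span=(0.0, 8.0))
            peaks.append(res.panels["plasma_ethanol_mM"].max())
        assert peaks[1] > 3.0 * peaks[0] / (120.0 / 40.0) * 1.0  # superlinear
        assert peaks[1] / peaks[0] > 120.0 / 40.0

    def test_triglyceride_excursion_reverses_within_six_hours(self, bolus_run):
        p = bolus_run.panels
        # by bolus-end (5 h) + 6 h the triglyceride excursion has decayed
        at11 = p[(p["time_h"] >= 11.0) & (p["time_h"] <= 13.0)]
        rel = np.abs(at11["tg_mM"] - at11["tg_reference_mM"]) \
            / at11["tg_reference_mM"]
        assert rel.max() < 0.05

    def test_acetaldehyde_transient(self, bolus_run):
        ac = bolus_run.panels["acetaldehyde_mM"].to_numpy()
        assert ac.max() > 0
        assert ac[-1] < 0.1 * ac.max()

    def test_wrong_substance_rejected(self, demo_model, demo_boundary):
        with pytest.raises(ScenarioConfigurationError):
            ethanol_bolus(demo_model, demo_boundary,
                          InfusionProfile.zero("gal_ext"))


class TestDrugInhibition:
    def test_zero_drug_restores_rates_bitwise(self, demo_model, demo_compiled):
        drugged = apply_drug(demo_model, default_vpa_inhibition())
        cm = compile_model(drugged)
        x = cm.x0
        ext = np.array([drugged.species[s].initial_concentration
                        for s in cm.ext_ids])
        ext[cm.ext_ids.index("vpa_ext")] = 0.0
        v_drugged = cm.rates(0.0, x, ext, cm.param_values(drugged))
        ext0 = np.array([demo_model.species[s].initial_concentration
                         for s in demo_compiled.ext_ids])
        v_ref = demo_compiled.rates(0.0, demo_compiled.x0, ext0,
                                    demo_compiled.param_values(demo_model))
        for rid in demo_compiled.reaction_ids:
            i = demo_compiled.reaction_ids.index(rid)
            j = cm.reaction_ids.index(rid)
            assert v_drugged[j] == v_ref[i], rid

    def test_apparent_km_doubles_at_ki(self, demo_model):
        """At [drug] = Ki the competitive mechanism must double the
        apparent KM: the inhibited rate at S equals the reference rate
        evaluated with km -> 2 km."""
        inh = DrugInhibition(
            drug="vpa_ext",
            targets=[DrugTarget("ALDH", "competitive", ki=0.3,
                                km_param="km_aldh_acald")])
        drugged = apply_drug(demo_model, inh)
        import sympy as sp
        law_ref = demo_model.reactions["ALDH"].rate_law.expr
        law_drug = drugged.reactions["ALDH"].rate_law.expr
        subs = {"v_aldh": 140.0, "km_aldh_acald": 0.005, "km_aldh_nad": 0.05,
                "acald": 0.02, "nad_c": 0.5, "vpa_ext": 0.3}
        subs_sym = {sp.Symbol(k, real=True): v for k, v in subs.items()}
        v_drug = float(law_drug.subs(subs_sym))
        subs["km_aldh_acald"] = 0.010  # doubled by hand
        subs_sym = {sp.Symbol(k, real=True): v for k, v in subs.items()}
        v_ref = float(law_ref.subs(subs_sym))
        assert v_drug == pytest.approx(v_ref, rel=1e-12)

    def test_vmax_scaling_mechanism(self, demo_model):
        inh = DrugInhibition(drug="d_ext",
                             targets=[DrugTarget("ALDH", "vmax_scaling",
                                                 factor=0.25)])
        drugged = apply_drug(demo_model, inh)
        assert drugged.parameters["v_aldh"].value == pytest.approx(
            0.25 * demo_model.parameters["v_aldh"].value)

    def test_unknown_target_rejected(self, demo_model):
        inh = DrugInhibition(drug="d_ext",
                             targets=[DrugTarget("NOPE", "competitive", ki=1.0,
                                                 km_param="km_gk")])
        with pytest.raises(ScenarioConfigurationError):
            apply_drug(demo_model, inh)

    def test_vpa_reduces_urea_during_exposure_but_not_daily_mean(
            self, vpa_run):
        res = vpa_run
        drug_mean, ref_mean = res.urea_mean_window
        assert drug_mean < ref_mean           # suppressed while VPA is high
        rel = abs(res.urea_mean_drug - res.urea_mean_reference) \
            / res.urea_mean_reference
        assert rel < 0.02                     # daily nitrogen balance holds
        # cholesterol synthesis is transiently reduced as well
        ratio = (res.panels["cholesterol_synthesis"]
                 / res.panels["cholesterol_synthesis_reference"])
        assert ratio.min() < 1.0


class TestGalactosemia:
    @pytest.fixture()
    def auc_table(self, galactosemia_table):
        return galactosemia_table

    def test_no_challenge_matches_baseline(self, demo_model, demo_boundary,
                                           warm_state):
        res = galactosemia_run(demo_model, demo_boundary,
                               EnzymeVariant(label="normal"),
                               challenge=InfusionProfile.zero("gal_ext"),
                               t_span=(0.0, 4.0), x0=warm_state)
        base = galactosemia_run(demo_model, demo_boundary,
                                EnzymeVariant(label="normal"),
                                challenge=InfusionProfile.zero("gal_ext"),
                                t_span=(0.0, 4.0), x0=warm_state)
        assert res.auc_gal1p == base.auc_gal1p
        assert res.auc_galactitol == base.auc_galactitol

    def test_galt_deficiency_maximizes_gal1p_burden(self, auc_table):
        t = auc_table.set_index("variant")
        galt = t.loc["GALT-null", "auc_gal1p"]
        others = t.drop("GALT-null")["auc_gal1p"]
        assert (galt > others).all()
        assert galt > 2 * others.max()

    def test_galk_deficiency_blocks_leloir_entry(self, demo_model,
                                                 demo_boundary, warm_state,
                                                 auc_table):
        res = galactosemia_run(demo_model, demo_boundary,
                               EnzymeVariant("GALK", 0.0, label="GALK-null"),
                               x0=warm_state)
        assert np.allclose(res.trajectory.flux("GALK"), 0.0, atol=1e-12)
        t = auc_table.set_index("variant")
        assert t.loc["GALK-null", "auc_galactitol"] \
            > t.loc["normal", "auc_galactitol"]

    def test_unknown_variant_enzyme_rejected(self, demo_model, demo_boundary):
        with pytest.raises(ScenarioConfigurationError):
            galactosemia_run(demo_model, demo_boundary,
                             EnzymeVariant("NOPE", 0.0))


class TestProteomeScaling:
    def test_all_ones_reproduces_reference_bitwise(self, demo_model,
                                                   demo_compiled,
                                                   demo_boundary):
        ratios = {rid: 1.0 for rid, r in demo_model.reactions.items()
                  if r.vmax_params}
        scaled, report = apply_proteome_scaling(demo_model,
                                                ProteomeScaling(ratios))
        t_eval = np.linspace(0, 4, 21)
        a = simulate(demo_model, demo_boundary, (0, 4), t_eval=t_eval,
                     compiled=demo_compiled)
        b = simulate(scaled, demo_boundary, (0, 4), t_eval=t_eval)
        assert np.array_equal(a.state, b.state)
        assert report["coverage"] == 1.0

    def test_single_ratio_scales_one_vmax_only(self, demo_model):
        scaled, _ = apply_proteome_scaling(demo_model,
                                           ProteomeScaling({"GK": 2.0}))
        assert scaled.parameters["v_gk"].value == pytest.approx(
            2 * demo_model.parameters["v_gk"].value)
        for pid, p in scaled.parameters.items():
            if pid != "v_gk":
                assert p.value == demo_model.parameters[pid].value

    def test_scaling_composes_multiplicatively(self, demo_model):
        s1, _ = apply_proteome_scaling(demo_model, ProteomeScaling({"GK": 2.0}))
        s2, _ = apply_proteome_scaling(s1, ProteomeScaling({"GK": 3.0}))
        direct, _ = apply_proteome_scaling(demo_model,
                                           ProteomeScaling({"GK": 6.0}))
        assert s2.parameters["v_gk"].value == pytest.approx(
            direct.parameters["v_gk"].value)

    def test_coverage_report_lists_unmapped_half(self, demo_model):
        mapped = [rid for rid, r in demo_model.reactions.items()
                  if r.vmax_params]
        half = mapped[: len(mapped) // 2]
        _, report = apply_proteome_scaling(
            demo_model, ProteomeScaling({rid: 1.5 for rid in half}))
        assert sorted(report["unmapped_enzymes"]) == sorted(
            set(mapped) - set(half))

    def test_unknown_enzyme_skipped_and_recorded(self, demo_model):
        _, report = apply_proteome_scaling(
            demo_model, ProteomeScaling({"GK": 1.5, "NOT_AN_ENZYME": 2.0}))
        assert report["unknown_entries"] == ["NOT_AN_ENZYME"]

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ScenarioConfigurationError):
            ProteomeScaling({"GK": 0.0})

    def test_table_reader(self, tmp_path):
        path = tmp_path / "ratios.tsv"
        path.write_text("enzyme_id\tratio\nGK\t0.5\nFAS\t2.0\n")
        scaling = read_proteome_table(path)
        assert scaling.ratios == {"GK": 0.5, "FAS": 2.0}
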