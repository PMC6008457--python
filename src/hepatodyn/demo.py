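"""Bundled reduced hepatocyte model and synthetic diurnal plasma profiles.

The demo model instantiates the textbook liver pathway map at coarse
granularity: glycogen metabolism, the Leloir pathway of galactose with the
aldose-reductase and galactose-dehydrogenase side branches, glycolysis and
gluconeogenesis, the oxidative pentose phosphate shunt, fatty-acid
synthesis/esterification/VLDL export, β-oxidation behind the
malonyl-CoA-inhibited carnitine shuttle, a lumped TCA cycle, a respiratory
chain with cytochrome c in the inter-membrane space and a lumped
proton-motive potential, ketogenesis, the N-acetylglutamate-activated urea
cycle, ethanol detoxification through ADH/ALDH, and alanine / serine /
glutamine / ammonia nitrogen feeds.  Multi-step pathways are single lumped
reactions; the four compartments are extracellular space, cytosol,
mitochondrial matrix, and the inner-membrane space.

Every kinetic constant here is synthetic — chosen so the network behaves
like a liver qualitatively (fed/fasted glycogen cycling, inverse regulation
of fatty-acid synthesis against fatty-acid uptake, hypoxia-sensitive
gluconeogenesis and ureagenesis) — and is not an experimentally measured
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from . import ratelaws as rl
from .boundary import BoundaryProfile
from .model import (Compartment, KineticModel, MembranePotential, Parameter,
                    PhosphoFunction, Reaction, Species)

PATHWAYS = ("glycolysis", "glycogen", "galactose", "lipid", "tca", "oxphos",
            "beta_oxidation", "ketone", "urea", "ethanol", "amino")

#: pathway prerequisites: disabling the prerequisite while enabling the
#: dependent pathway is a configuration error (the dependent pathway's
#: carbon source would vanish silently).
_REQUIRES = {"galactose": ("glycogen",), "ketone": ("tca", "beta_oxidation")}


class DemoConfigurationError(ValueError):
    pass


@dataclass
class DemoModelSpec:
    """Pathway switches and parameter overrides for the demo model.

    Disabling a pathway zeroes the maximal activities of exactly that
    pathway's reactions and nothing else.
    """
    pathways: dict = field(default_factory=dict)  # name -> bool (default True)
    parameter_overrides: dict = field(default_factory=dict)

    def enabled(self, name: str) -> bool:
        return bool(self.pathways.get(name, True))

    def validate(self):
        unknown = set(self.pathways) - set(PATHWAYS)
        if unknown:
            raise DemoConfigurationError(f"unknown pathway switches: {sorted(unknown)}")
        for dep, reqs in _REQUIRES.items():
            if self.enabled(dep):
                for req in reqs:
                    if not self.enabled(req):
                        raise DemoConfigurationError(
                            f"pathway {dep!r} requires {req!r} to be enabled")


def build_demo_model(spec: DemoModelSpec | None = None) -> KineticModel:
    spec = spec or DemoModelSpec()
    spec.validate()
    m = KineticModel(id="liver-demo",
                     notes="reduced hepatocyte network; all parameters synthetic")

    for cid, frac, name in [("ext", 15.0, "extracellular space"),
                            ("cyt", 0.70, "cytosol"),
                            ("mit", 0.20, "mitochondrial matrix"),
                            ("ims", 0.02, "inner-membrane space")]:
        m.compartments[cid] = Compartment(cid, frac, name)

    def ext(sid, c0=0.0):
        m.species[sid] = Species(sid, "ext", "external", c0)

    def sp_(sid, comp, c0, bounds=None):
        m.species[sid] = Species(sid, comp, "internal", c0, bounds=bounds)

    # ---- external / boundary species (plasma) ------------------------------
    for sid, c0 in [("glc_ext", 6.5), ("lac_ext", 1.2), ("pyr_ext", 0.12),
                    ("glyc_ext", 0.15), ("ffa_ext", 0.55), ("acac_ext", 0.15),
                    ("bhb_ext", 0.30), ("o2_ext", 0.07), ("nh4_ext", 0.03),
                    ("gln_ext", 0.55), ("glu_ext", 0.10), ("ser_ext", 0.15),
                    ("ala_ext", 0.35), ("ins_ext", 1.2), ("gcg_ext", 0.05),
                    ("etoh_ext", 0.0), ("ac_ext", 0.10), ("gal_ext", 0.08),
                    ("urea_ext", 4.0), ("galtol_ext", 0.0), ("galn_ext", 0.0),
                    ("vldl_ext", 0.0), ("chol_ext", 0.0)]:
        ext(sid, c0)

    # ---- internal species --------------------------------------------------
    cyt = [("glc_c", 6.0), ("g6p", 0.2), ("glycogen", 250.0), ("pyr_c", 0.10),
           ("lac_c", 1.0), ("accoa_c", 0.06), ("malcoa", 0.004),
           ("ffa_c", 0.08), ("tg", 50.0), ("chol", 5.0),
           ("nad_c", 0.55), ("nadh_c", 0.0008),
           ("nadp_c", 0.012), ("nadph_c", 0.30),
           ("atp_c", 2.8), ("adp_c", 0.7),
           ("nh4_c", 0.25), ("glu_c", 5.0), ("nag", 0.06), ("urea_c", 4.0),
           ("etoh_c", 0.0), ("acald", 0.0), ("ac_c", 0.10),
           ("gal_c", 0.05), ("gal1p", 0.02), ("udpglc", 0.30),
           ("udpgal", 0.10), ("galtol_c", 0.002),
           ("o2_c", 0.05), ("acac_c", 0.15), ("bhb_c", 0.30)]
    for sid, c0 in cyt:
        sp_(sid, "cyt", c0)
    for sid, c0 in [("accoa_m", 0.05), ("nad_m", 0.8), ("nadh_m", 0.2)]:
        sp_(sid, "mit", c0)
    for sid, c0 in [("cytc_ox", 0.30), ("cytc_red", 0.10)]:
        sp_(sid, "ims", c0)

    m.membrane_potential = MembranePotential(capacitance=1.0, initial_mv=160.0)

    # ---- parameters --------------------------------------------------------
    def P(pid, value, category, reaction=None):
        m.parameters[pid] = Parameter(pid, value, category, reaction=reaction,
                                      note="synthetic - not an experimental value")
        return pid

    # ---- phosphorylation state: fraction phosphorylated falls with glucose
    m.phospho_functions["glc_phospho"] = PhosphoFunction(
        "glc_phospho", half_saturation=6.5, steepness=8.0,
        direction="falling", glucose_species="glc_ext")
    gamma = rl.phospho_fraction_expr(sp.Symbol("glc_ext", real=True),
                                     6.5, 8.0, "falling")

    reactions = []

    def R(rid, pathway, stoich, law, charge=0.0, name=""):
        reactions.append(Reaction(rid, stoich, law, charge_transfer=charge,
                                  pathway=pathway, name=name))

    # ================= glucose core =========================================
    R("GLUT2", "glycolysis", {"glc_ext": -1, "glc_c": 1},
      rl.reversible_mm(P("v_glut2", 300.0, "VMAX"), {"glc_ext": P("km_glut2_e", 17.0, "KM")},
                       {"glc_c": P("km_glut2_c", 17.0, "KM")}, P("keq_glut2", 1.0, "OTHER")),
      name="glucose transporter (near-equilibrium)")
    R("GK", "glycolysis", {"glc_c": -1, "atp_c": -1, "g6p": 1, "adp_c": 1},
      rl.with_modifiers(
          rl.hill(P("v_gk", 32.0, "VMAX"), "glc_c", P("km_gk", 9.0, "KM"),
                  P("n_gk", 1.7, "N")),
          activators=[("atp_c", P("ka_gk_atp", 0.40, "KA"))]),
      name="glucokinase")
    R("G6PASE", "glycolysis", {"g6p": -1, "glc_c": 1},
      rl.reversible_mm(P("v_g6pase", 65.0, "VMAX"), {"g6p": P("km_g6pase", 0.25, "KM")}),
      name="glucose-6-phosphatase")
    # lower glycolysis: dephosphorylated (fed) state active
    R("GLYCOLYSIS", "glycolysis",
      {"g6p": -1, "adp_c": -2, "nad_c": -2, "pyr_c": 2, "atp_c": 2, "nadh_c": 2},
      rl.phospho_interpolated(
          gamma,
          rl.reversible_mm(P("v_glyc_p", 3.0, "VMAX"),
                           {"g6p": P("km_glyc_g6p", 0.15, "KM"),
                            "adp_c": P("km_glyc_adp", 0.15, "KM"),
                            "nad_c": P("km_glyc_nad", 0.05, "KM")}),
          rl.reversible_mm(P("v_glyc_d", 55.0, "VMAX"),
                           {"g6p": "km_glyc_g6p", "adp_c": "km_glyc_adp",
                            "nad_c": "km_glyc_nad"})),
      name="lower glycolysis (PFK1..PK lump)")
    # gluconeogenesis: phosphorylated (fasted) state active; ATP-gated
    R("GNG", "glycolysis",
      {"pyr_c": -2, "atp_c": -4, "nadh_c": -2, "g6p": 1, "adp_c": 4, "nad_c": 2},
      rl.phospho_interpolated(
          gamma,
          rl.with_modifiers(
              rl.reversible_mm(P("v_gng_p", 48.0, "VMAX"),
                               {"pyr_c": P("km_gng_pyr", 0.05, "KM"),
                                "nadh_c": P("km_gng_nadh", 0.0005, "KM")}),
              activators=[("atp_c", P("ka_gng_atp", 2.0, "KA"),
                           P("n_gng_atp", 3.0, "N"))]),
          rl.with_modifiers(
              rl.reversible_mm(P("v_gng_d", 4.0, "VMAX"),
                               {"pyr_c": "km_gng_pyr", "nadh_c": "km_gng_nadh"}),
              activators=[("atp_c", "ka_gng_atp", "n_gng_atp")])),
      name="gluconeogenesis (PC..FBPase lump)")
    R("LDH", "glycolysis",
      {"pyr_c": -1, "nadh_c": -1, "lac_c": 1, "nad_c": 1},
      rl.reversible_mm(P("v_ldh", 800.0, "VMAX"),
                       {"pyr_c": P("km_ldh_pyr", 0.30, "KM"),
                        "nadh_c": P("km_ldh_nadh", 0.002, "KM")},
                       {"lac_c": P("km_ldh_lac", 1.7, "KM"),
                        "nad_c": P("km_ldh_nad", 0.05, "KM")},
                       P("keq_ldh", 9000.0, "OTHER")),
      name="lactate dehydrogenase")
    R("MCT_LAC", "glycolysis", {"lac_ext": -1, "lac_c": 1},
      rl.reversible_mm(P("v_mct_lac", 150.0, "VMAX"),
                       {"lac_ext": P("km_mct_lac_e", 1.5, "KM")},
                       {"lac_c": P("km_mct_lac_c", 1.5, "KM")},
                       P("keq_mct_lac", 1.0, "OTHER")),
      name="monocarboxylate transporter (lactate)")
    R("MCT_PYR", "glycolysis", {"pyr_ext": -1, "pyr_c": 1},
      rl.reversible_mm(P("v_mct_pyr", 30.0, "VMAX"),
                       {"pyr_ext": P("km_mct_pyr_e", 0.15, "KM")},
                       {"pyr_c": P("km_mct_pyr_c", 0.15, "KM")},
                       P("keq_mct_pyr", 1.0, "OTHER")),
      name="monocarboxylate transporter (pyruvate)")
    R("GLYC_UP", "glycolysis",
      {"glyc_ext": -1, "atp_c": -1, "nad_c": -1, "g6p": 0.5, "adp_c": 1, "nadh_c": 1},
      rl.reversible_mm(P("v_glyc_up", 6.0, "VMAX"),
                       {"glyc_ext": P("km_glyc_up", 0.10, "KM"),
                        "atp_c": P("km_glyc_up_atp", 0.5, "KM"),
                        "nad_c": P("km_glyc_up_nad", 0.05, "KM")}),
      name="glycerol uptake and utilization")
    R("PPP", "glycolysis",
      {"g6p": -1, "nadp_c": -2, "nadph_c": 2, "pyr_c": 1},
      rl.reversible_mm(P("v_ppp", 12.0, "VMAX"),
                       {"g6p": P("km_ppp_g6p", 0.20, "KM"),
                        "nadp_c": P("km_ppp_nadp", 0.005, "KM")}),
      name="oxidative pentose phosphate shunt (lump)")
    R("NOX", "glycolysis", {"nadph_c": -1, "nadp_c": 1},
      rl.mass_action(P("k_nox", 0.5, "OTHER"), {"nadph_c": 1}),
      name="basal NADPH consumption")

    # ================= glycogen =============================================
    gs_core_d = rl.with_modifiers(
        rl.reversible_mm(P("v_gs_d", 20.0, "VMAX"),
                         {"udpglc": P("km_gs_udpglc", 0.20, "KM")}),
        inhibitors=[("glycogen", P("ka_gs_cap", 300.0, "KA"),
                     P("n_gs_cap", 4.0, "N"))])
    gs_core_p = rl.with_modifiers(
        rl.reversible_mm(P("v_gs_p", 1.0, "VMAX"), {"udpglc": "km_gs_udpglc"}),
        inhibitors=[("glycogen", "ka_gs_cap", "n_gs_cap")])
    R("GS", "glycogen", {"udpglc": -1, "glycogen": 1},
      rl.phospho_interpolated(gamma, gs_core_p, gs_core_d),
      name="glycogen synthase (dephospho-active)")
    R("GP", "glycogen", {"glycogen": -1, "g6p": 1},
      rl.phospho_interpolated(
          gamma,
          rl.reversible_mm(P("v_gp_p", 40.0, "VMAX"),
                           {"glycogen": P("km_gp", 150.0, "KM")}),
          rl.reversible_mm(P("v_gp_d", 1.5, "VMAX"), {"glycogen": "km_gp"})),
      name="glycogen phosphorylase (phospho-active)")
    R("UGP", "glycogen", {"g6p": -1, "atp_c": -1, "udpglc": 1, "adp_c": 1},
      rl.with_modifiers(
          rl.reversible_mm(P("v_ugp", 55.0, "VMAX"),
                           {"g6p": P("km_ugp_g6p", 0.12, "KM"),
                            "atp_c": P("km_ugp_atp", 0.30, "KM")}),
          inhibitors=[("udpglc", P("ka_ugp_udpglc", 1.00, "KA"))]),
      name="UDP-glucose pyrophosphorylase (PGM+UGP lump)")

    # ================= galactose (Leloir + branches) ========================
    R("GAL_UP", "galactose", {"gal_ext": -1, "gal_c": 1},
      rl.reversible_mm(P("v_gal_up", 60.0, "VMAX"),
                       {"gal_ext": P("km_gal_up_e", 20.0, "KM")},
                       {"gal_c": P("km_gal_up_c", 20.0, "KM")},
                       P("keq_gal_up", 1.0, "OTHER")),
      name="galactose transporter")
    R("GALK", "galactose", {"gal_c": -1, "atp_c": -1, "gal1p": 1, "adp_c": 1},
      rl.reversible_mm(P("v_galk", 8.0, "VMAX"),
                       {"gal_c": P("km_galk_gal", 0.50, "KM"),
                        "atp_c": P("km_galk_atp", 0.15, "KM")}),
      name="galactokinase")
    R("GALT", "galactose", {"gal1p": -1, "udpglc": -1, "udpgal": 1, "g6p": 1},
      rl.reversible_mm(P("v_galt", 10.0, "VMAX"),
                       {"gal1p": P("km_galt_gal1p", 0.35, "KM"),
                        "udpglc": P("km_galt_udpglc", 0.15, "KM")}),
      name="galactose-1-phosphate uridylyltransferase")
    R("GALE", "galactose", {"udpgal": -1, "udpglc": 1},
      rl.reversible_mm(P("v_gale", 8.0, "VMAX"),
                       {"udpgal": P("km_gale_udpgal", 0.10, "KM")},
                       {"udpglc": P("km_gale_udpglc", 0.30, "KM")},
                       P("keq_gale", 3.0, "OTHER")),
      name="UDP-galactose 4-epimerase")
    R("ALDR", "galactose", {"gal_c": -1, "nadph_c": -1, "galtol_c": 1, "nadp_c": 1},
      rl.reversible_mm(P("v_aldr", 2.0, "VMAX"),
                       {"gal_c": P("km_aldr_gal", 12.0, "KM"),
                        "nadph_c": P("km_aldr_nadph", 0.05, "KM")}),
      name="aldose reductase (galactose -> galactitol)")
    R("GALDH", "galactose", {"gal_c": -1, "nad_c": -1, "galn_ext": 1, "nadh_c": 1},
      rl.reversible_mm(P("v_galdh", 1.5, "VMAX"),
                       {"gal_c": P("km_galdh_gal", 8.0, "KM"),
                        "nad_c": P("km_galdh_nad", 0.05, "KM")}),
      name="galactose dehydrogenase (galactonate release lump)")
    R("GALTOL_EXP", "galactose", {"galtol_c": -1, "galtol_ext": 1},
      rl.reversible_mm(P("v_galtol_exp", 4.0, "VMAX"),
                       {"galtol_c": P("km_galtol_exp", 0.50, "KM")}),
      name="galactitol release")

    # ================= lipid ================================================
    R("FFA_UP", "lipid", {"ffa_ext": -1, "ffa_c": 1},
      rl.reversible_mm(P("v_ffa_up", 30.0, "VMAX"),
                       {"ffa_ext": P("km_ffa_up_e", 0.40, "KM")},
                       {"ffa_c": P("km_ffa_up_c", 0.40, "KM")},
                       P("keq_ffa_up", 1.0, "OTHER")),
      name="fatty acid exchange (bidirectional)")
    R("CITSHUTTLE", "lipid", {"accoa_m": -1, "atp_c": -1, "accoa_c": 1, "adp_c": 1},
      rl.reversible_mm(P("v_citshuttle", 2.5, "VMAX"),
                       {"accoa_m": P("km_cits_accoa", 0.05, "KM"),
                        "atp_c": P("km_cits_atp", 0.50, "KM")}),
      name="citrate shuttle (acetyl-CoA export lump)")
    # acetyl-CoA carboxylase: dephospho-active, fatty-acid inhibited
    acc_d = rl.with_modifiers(
        rl.reversible_mm(P("v_acc_d", 12.0, "VMAX"),
                         {"accoa_c": P("km_acc_accoa", 0.03, "KM"),
                          "atp_c": P("km_acc_atp", 0.50, "KM")}),
        inhibitors=[("ffa_c", P("ka_acc_ffa", 0.50, "KA"))])
    acc_p = rl.with_modifiers(
        rl.reversible_mm(P("v_acc_p", 0.3, "VMAX"),
                         {"accoa_c": "km_acc_accoa", "atp_c": "km_acc_atp"}),
        inhibitors=[("ffa_c", "ka_acc_ffa")])
    R("ACC", "lipid", {"accoa_c": -1, "atp_c": -1, "malcoa": 1, "adp_c": 1},
      rl.phospho_interpolated(gamma, acc_p, acc_d),
      name="acetyl-CoA carboxylase (phospho + allosteric control)")
    R("FAS", "lipid",
      {"malcoa": -1, "nadph_c": -2, "ffa_c": 0.125, "nadp_c": 2},
      rl.reversible_mm(P("v_fas", 30.0, "VMAX"),
                       {"malcoa": P("km_fas_malcoa", 0.03, "KM"),
                        "nadph_c": P("km_fas_nadph", 0.05, "KM")}),
      name="fatty acid synthase (C16 lump)")
    R("TGSYN", "lipid",
      {"ffa_c": -3, "g6p": -0.5, "atp_c": -1, "tg": 1, "adp_c": 1},
      rl.reversible_mm(P("v_tgsyn", 3.0, "VMAX"),
                       {"ffa_c": P("km_tgsyn_ffa", 0.03, "KM"),
                        "g6p": P("km_tgsyn_g6p", 0.30, "KM"),
                        "atp_c": P("km_tgsyn_atp", 0.50, "KM")}),
      name="triglyceride synthesis (GPAT lump)")
    R("LIPOLYSIS", "lipid", {"tg": -1, "ffa_c": 3, "glyc_ext": 1},
      rl.reversible_mm(P("v_lipolysis", 0.6, "VMAX"),
                       {"tg": P("km_lipolysis", 60.0, "KM")}),
      name="lipid droplet lipolysis")
    R("VLDL_EXP", "lipid", {"tg": -1, "atp_c": -1, "vldl_ext": 1, "adp_c": 1},
      rl.with_modifiers(
          rl.reversible_mm(P("v_vldl", 1.2, "VMAX"),
                           {"tg": P("km_vldl_tg", 60.0, "KM"),
                            "atp_c": P("km_vldl_atp", 0.50, "KM")}),
          inhibitors=[("ins_ext", P("ka_vldl_ins", 1.0, "KA"),
                       P("n_vldl_ins", 2.0, "N"))]),
      name="VLDL assembly and export (apoB-limited, insulin-inhibited)")
    R("CHOLSYN", "lipid",
      {"accoa_c": -1.5, "nadph_c": -2, "chol": 1, "nadp_c": 2},
      rl.reversible_mm(P("v_cholsyn", 0.8, "VMAX"),
                       {"accoa_c": P("km_chol_accoa", 0.50, "KM"),
                        "nadph_c": P("km_chol_nadph", 0.05, "KM")}),
      name="cholesterol synthesis (HMGCR lump)")
    R("CHOL_EXP", "lipid", {"chol": -1, "chol_ext": 1},
      rl.reversible_mm(P("v_chol_exp", 2.0, "VMAX"),
                       {"chol": P("km_chol_exp", 5.0, "KM")}),
      name="cholesterol export (bile + VLDL lump)")

    # ================= TCA ==================================================
    R("PDH", "tca", {"pyr_c": -1, "nad_m": -1, "accoa_m": 1, "nadh_m": 1},
      rl.reversible_mm(P("v_pdh", 45.0, "VMAX"),
                       {"pyr_c": P("km_pdh_pyr", 0.06, "KM"),
                        "nad_m": P("km_pdh_nad", 0.20, "KM")}),
      name="pyruvate dehydrogenase")
    R("TCA", "tca",
      {"accoa_m": -1, "nad_m": -4, "adp_c": -1, "nadh_m": 4, "atp_c": 1},
      rl.reversible_mm(P("v_tca", 60.0, "VMAX"),
                       {"accoa_m": P("km_tca_accoa", 0.03, "KM"),
                        "nad_m": P("km_tca_nad", 0.20, "KM"),
                        "adp_c": P("km_tca_adp", 0.15, "KM")}),
      name="citric acid cycle (lump)")

    # ================= respiratory chain / oxphos ===========================
    R("O2_T", "oxphos", {"o2_ext": -1, "o2_c": 1},
      rl.mass_action(P("k_o2t", 3000.0, "OTHER"), {"o2_ext": 1}, {"o2_c": 1},
                     P("keq_o2t", 1.0, "OTHER")),
      name="oxygen diffusion")
    R("CI_CIII", "oxphos",
      {"nadh_m": -1, "cytc_ox": -2, "nad_m": 1, "cytc_red": 2},
      rl.with_modifiers(
          rl.reversible_mm(P("v_ci", 300.0, "VMAX"),
                           {"nadh_m": P("km_ci_nadh", 0.05, "KM"),
                            "cytc_ox": P("km_ci_cytc", 0.05, "KM")}),
          inhibitors=[("dpsi", P("ka_ci_dpsi", 185.0, "KA"),
                       P("n_ci_dpsi", 8.0, "N"))]),
      charge=6.0, name="complexes I+III (proton pumping)")
    R("CIV", "oxphos",
      {"cytc_red": -2, "o2_c": -0.5, "cytc_ox": 2},
      rl.with_modifiers(
          rl.reversible_mm(P("v_civ", 300.0, "VMAX"),
                           {"cytc_red": P("km_civ_cytc", 0.05, "KM"),
                            "o2_c": P("km_civ_o2", 0.005, "KM")}),
          inhibitors=[("dpsi", P("ka_civ_dpsi", 185.0, "KA"),
                       P("n_civ_dpsi", 8.0, "N"))]),
      charge=4.0, name="complex IV (O2-limited under hypoxia)")
    R("ATPSYN", "oxphos", {"adp_c": -1, "atp_c": 1},
      rl.with_modifiers(
          rl.reversible_mm(P("v_atpsyn", 900.0, "VMAX"),
                           {"adp_c": P("km_atpsyn_adp", 0.60, "KM")}),
          activators=[("dpsi", P("ka_atpsyn_dpsi", 150.0, "KA"),
                       P("n_atpsyn_dpsi", 6.0, "N"))]),
      charge=-4.0, name="F0F1 ATP synthase + adenine nucleotide translocase")
    R("LEAK", "oxphos", {},  # pure charge movement: proton leak / UCP
      rl.ghk_ion(P("p_leak", 1.3e5, "OTHER"), 1,
                 P("h_matrix", 1.0e-4, "OTHER"), P("h_ims", 2.0e-4, "OTHER"),
                 orientation=-1),
      charge=1.0, name="proton leak (GHK, UCP lump)")
    R("MAS", "oxphos",
      {"nadh_c": -1, "nad_m": -1, "nad_c": 1, "nadh_m": 1},
      rl.reversible_mm(P("v_mas", 60.0, "VMAX"),
                       {"nadh_c": P("km_mas_nadhc", 0.002, "KM"),
                        "nad_m": P("km_mas_nadm", 0.15, "KM")},
                       {"nad_c": P("km_mas_nadc", 0.05, "KM"),
                        "nadh_m": P("km_mas_nadhm", 0.05, "KM")},
                       P("keq_mas", 50.0, "OTHER")),
      name="malate-aspartate shuttle (lump)")
    R("ATPASE", "oxphos", {"atp_c": -1, "adp_c": 1},
      rl.reversible_mm(P("v_atpase", 300.0, "VMAX"),
                       {"atp_c": P("km_atpase", 1.20, "KM")}),
      name="housekeeping ATP demand")

    # ================= beta oxidation =======================================
    R("CPT_BOX", "beta_oxidation",
      {"ffa_c": -1, "nad_m": -7, "accoa_m": 8, "nadh_m": 7},
      rl.with_modifiers(
          rl.reversible_mm(P("v_cpt", 4.5, "VMAX"),
                           {"ffa_c": P("km_cpt_ffa", 0.04, "KM"),
                            "nad_m": P("km_cpt_nad", 0.10, "KM")}),
          competitive=[("malcoa", P("ki_cpt_malcoa", 0.001, "KA"), "km_cpt_ffa")]),
      name="CPT1 + beta-oxidation (malonyl-CoA inhibited)")

    # ================= ketone bodies ========================================
    R("KETO", "ketone", {"accoa_m": -2, "acac_c": 1},
      rl.reversible_mm(P("v_keto", 12.0, "VMAX"),
                       {"accoa_m": P("km_keto_accoa", 0.08, "KM")}),
      name="ketogenesis (HMG-CoA lump)")
    R("BDH", "ketone",
      {"acac_c": -1, "nadh_m": -1, "bhb_c": 1, "nad_m": 1},
      rl.reversible_mm(P("v_bdh", 30.0, "VMAX"),
                       {"acac_c": P("km_bdh_acac", 0.10, "KM"),
                        "nadh_m": P("km_bdh_nadh", 0.02, "KM")},
                       {"bhb_c": P("km_bdh_bhb", 0.10, "KM"),
                        "nad_m": P("km_bdh_nad", 0.50, "KM")},
                       P("keq_bdh", 20.0, "OTHER")),
      name="beta-hydroxybutyrate dehydrogenase")
    R("ACAC_EXP", "ketone", {"acac_c": -1, "acac_ext": 1},
      rl.reversible_mm(P("v_acac_exp", 50.0, "VMAX"),
                       {"acac_c": P("km_acac_exp_c", 0.30, "KM")},
                       {"acac_ext": P("km_acac_exp_e", 0.30, "KM")},
                       P("keq_acac_exp", 1.0, "OTHER")),
      name="acetoacetate exporter (near-equilibrium)")
    R("BHB_EXP", "ketone", {"bhb_c": -1, "bhb_ext": 1},
      rl.reversible_mm(P("v_bhb_exp", 50.0, "VMAX"),
                       {"bhb_c": P("km_bhb_exp_c", 0.30, "KM")},
                       {"bhb_ext": P("km_bhb_exp_e", 0.30, "KM")},
                       P("keq_bhb_exp", 1.0, "OTHER")),
      name="beta-hydroxybutyrate exporter (near-equilibrium)")

    # ================= urea cycle ===========================================
    R("NH4_UP", "urea", {"nh4_ext": -1, "nh4_c": 1},
      rl.reversible_mm(P("v_nh4_up", 8.0, "VMAX"),
                       {"nh4_ext": P("km_nh4_up_e", 0.05, "KM")},
                       {"nh4_c": P("km_nh4_up_c", 2.00, "KM")},
                       P("keq_nh4_up", 1.0, "OTHER")),
      name="ammonia exchange (bidirectional)")
    R("AGS", "urea", {"accoa_m": -1, "glu_c": -1, "nag": 1},
      rl.reversible_mm(P("v_ags", 1.2, "VMAX"),
                       {"glu_c": P("km_ags_glu", 2.5, "KM"),
                        "accoa_m": P("km_ags_accoa", 0.02, "KM")}),
      name="N-acetylglutamate synthetase")
    R("NAGDEG", "urea", {"nag": -1, "glu_c": 1},
      rl.mass_action(P("k_nagdeg", 12.0, "OTHER"), {"nag": 1}),
      name="N-acetylglutamate degradation")
    R("UREA_CYCLE", "urea",
      {"nh4_c": -2, "atp_c": -2, "urea_c": 1, "adp_c": 2},
      rl.with_modifiers(
          rl.reversible_mm(P("v_urea", 30.0, "VMAX"),
                           {"nh4_c": P("km_urea_nh4", 0.08, "KM")}),
          activators=[("nag", P("ka_urea_nag", 0.02, "KA")),
                      ("atp_c", P("ka_urea_atp", 2.0, "KA"),
                       P("n_urea_atp", 3.0, "N"))]),
      name="urea cycle (CPS1..ARG1 lump, NAG-activated, ATP-gated)")
    R("UREA_EXP", "urea", {"urea_c": -1, "urea_ext": 1},
      rl.reversible_mm(P("v_urea_exp", 40.0, "VMAX"),
                       {"urea_c": P("km_urea_exp", 2.0, "KM")}),
      name="urea release")

    # ================= ethanol ==============================================
    R("ETOH_T", "ethanol", {"etoh_ext": -1, "etoh_c": 1},
      rl.reversible_mm(P("v_etoh_t", 400.0, "VMAX"),
                       {"etoh_ext": P("km_etoh_t_e", 10.0, "KM")},
                       {"etoh_c": P("km_etoh_t_c", 10.0, "KM")},
                       P("keq_etoh_t", 1.0, "OTHER")),
      name="ethanol diffusion (near-equilibrium)")
    R("ADH", "ethanol", {"etoh_c": -1, "nad_c": -1, "acald": 1, "nadh_c": 1},
      rl.reversible_mm(P("v_adh", 110.0, "VMAX"),
                       {"etoh_c": P("km_adh_etoh", 1.2, "KM"),
                        "nad_c": P("km_adh_nad", 0.05, "KM")},
                       {"acald": P("km_adh_acald", 0.01, "KM"),
                        "nadh_c": P("km_adh_nadh", 0.005, "KM")},
                       P("keq_adh", 1.0e-4, "OTHER")),
      name="alcohol dehydrogenase")
    R("ALDH", "ethanol", {"acald": -1, "nad_c": -1, "ac_c": 1, "nadh_c": 1},
      rl.reversible_mm(P("v_aldh", 140.0, "VMAX"),
                       {"acald": P("km_aldh_acald", 0.005, "KM"),
                        "nad_c": P("km_aldh_nad", 0.05, "KM")}),
      name="acetaldehyde dehydrogenase")
    R("ACS", "ethanol", {"ac_c": -1, "atp_c": -2, "accoa_c": 1, "adp_c": 2},
      rl.reversible_mm(P("v_acs", 3.0, "VMAX"),
                       {"ac_c": P("km_acs_ac", 0.30, "KM"),
                        "atp_c": P("km_acs_atp", 0.50, "KM")}),
      name="acetyl-CoA synthetase")
    R("AC_EXP", "ethanol", {"ac_c": -1, "ac_ext": 1},
      rl.reversible_mm(P("v_ac_exp", 60.0, "VMAX"),
                       {"ac_c": P("km_ac_exp_c", 0.30, "KM")},
                       {"ac_ext": P("km_ac_exp_e", 0.30, "KM")},
                       P("keq_ac_exp", 1.0, "OTHER")),
      name="acetate exchange (near-equilibrium)")

    # ================= amino acids / nitrogen ===============================
    R("GLN_UP", "amino", {"gln_ext": -1, "glu_c": 1, "nh4_c": 1},
      rl.reversible_mm(P("v_gln_up", 7.0, "VMAX"),
                       {"gln_ext": P("km_gln_up", 0.80, "KM")}),
      name="glutamine uptake + glutaminase")
    R("GDH", "amino", {"glu_c": -1, "nad_c": -1, "nh4_c": 1, "nadh_c": 1},
      rl.reversible_mm(P("v_gdh", 12.0, "VMAX"),
                       {"glu_c": P("km_gdh_glu", 3.0, "KM"),
                        "nad_c": P("km_gdh_nad", 0.05, "KM")},
                       {"nh4_c": P("km_gdh_nh4", 0.30, "KM"),
                        "nadh_c": P("km_gdh_nadh", 0.005, "KM")},
                       P("keq_gdh", 1.0e-4, "OTHER")),
      name="glutamate dehydrogenase (2-oxoglutarate lumped)")
    R("GLU_EXP", "amino", {"glu_c": -1, "glu_ext": 1},
      rl.reversible_mm(P("v_glu_exp", 12.0, "VMAX"),
                       {"glu_c": P("km_glu_exp_c", 3.0, "KM")},
                       {"glu_ext": P("km_glu_exp_e", 0.50, "KM")},
                       P("keq_glu_exp", 1.0, "OTHER")),
      name="glutamate exchange")
    R("SER_UP", "amino", {"ser_ext": -1, "pyr_c": 1, "nh4_c": 1},
      rl.reversible_mm(P("v_ser_up", 4.0, "VMAX"),
                       {"ser_ext": P("km_ser_up", 0.30, "KM")}),
      name="serine uptake + dehydratase")
    R("ALA_UP", "amino",
      {"ala_ext": -1, "nad_c": -1, "pyr_c": 1, "nh4_c": 1, "nadh_c": 1},
      rl.reversible_mm(P("v_ala_up", 9.0, "VMAX"),
                       {"ala_ext": P("km_ala_up", 0.40, "KM")}),
      name="alanine uptake + transamination (GDH-coupled lump)")

    for r in reactions:
        m.reactions[r.id] = r

    # pathway switches: zero the maximal activities of disabled pathways
    for r in reactions:
        if not spec.enabled(r.pathway):
            for pid in r.vmax_params:
                p = m.parameters[pid]
                m.parameters[pid] = Parameter(p.id, 0.0, "OTHER", p.unit,
                                              p.reaction, p.note + " (disabled)")

    for pid, value in spec.parameter_overrides.items():
        m.set_parameter(pid, value)

    m.validate()
    return m


# =========================== diurnal profile ================================

#: the 15 plasma panels driving the model: metabolites, O2, ammonia, amino
#: acids and the two counter-regulatory hormones.
PROFILE_SPECIES = ("glc_ext", "lac_ext", "pyr_ext", "glyc_ext", "ffa_ext",
                   "acac_ext", "bhb_ext", "o2_ext", "nh4_ext", "gln_ext",
                   "glu_ext", "ser_ext", "ala_ext", "ins_ext", "gcg_ext")


@dataclass
class Waveform:
    mean: float
    amplitude: float = 0.0
    peak_h: float = 12.0
    amplitude2: float = 0.0
    peak2_h: float = 0.0

    def __call__(self, t):
        t = np.asarray(t, float)
        y = (self.mean
             + self.amplitude * np.cos(2 * np.pi * (t - self.peak_h) / 24.0)
             + self.amplitude2 * np.cos(4 * np.pi * (t - self.peak2_h) / 24.0))
        return y


def _default_waveforms() -> dict:
    # fed phase mid-day (glucose/insulin peak ~10 h), counter-regulatory
    # fatty acids / glucagon / ketones peak overnight
    return {
        "glc_ext": Waveform(6.5, 2.0, 10.0),
        "lac_ext": Waveform(1.2, 0.30, 13.0),
        "pyr_ext": Waveform(0.12, 0.03, 13.0),
        "glyc_ext": Waveform(0.15, 0.06, 2.0),
        "ffa_ext": Waveform(0.55, 0.30, 3.0),
        "acac_ext": Waveform(0.15, 0.07, 4.0),
        "bhb_ext": Waveform(0.30, 0.15, 4.0),
        "o2_ext": Waveform(0.07, 0.003, 12.0),
        "nh4_ext": Waveform(0.03, 0.008, 12.0),
        "gln_ext": Waveform(0.55, 0.10, 12.0),
        "glu_ext": Waveform(0.10, 0.02, 12.0),
        "ser_ext": Waveform(0.15, 0.04, 12.0),
        "ala_ext": Waveform(0.35, 0.10, 12.0),
        "ins_ext": Waveform(1.2, 0.80, 10.0),
        "gcg_ext": Waveform(0.05, 0.02, 2.0),
    }


#: constant plasma levels of species only relevant to perturbation scenarios
CONSTANT_SPECIES = {"etoh_ext": 0.0, "ac_ext": 0.10, "gal_ext": 0.08,
                    "urea_ext": 4.0}


@dataclass
class DiurnalProfileSpec:
    """Per-species waveform spec for the 24 h plasma profile generator."""
    waveforms: dict = field(default_factory=_default_waveforms)
    constants: dict = field(default_factory=lambda: dict(CONSTANT_SPECIES))
    step_h: float = 0.5
    jitter: float = 0.0  # fractional log-normal perturbation of the means

    def validate(self):
        for sid, w in self.waveforms.items():
            if abs(w.amplitude) + abs(w.amplitude2) >= w.mean:
                raise ValueError(
                    f"species {sid!r}: amplitudes must stay below the mean "
                    f"(profile would go negative)")


def generate_diurnal_profile(spec: DiurnalProfileSpec | None = None,
                             seed: int | None = None) -> BoundaryProfile:
    """Synthesize a strictly positive, 24 h-periodic plasma profile.

    With ``jitter > 0`` the per-species means are perturbed log-normally
    under the given seed (inter-individual variability); the default is the
    deterministic reference profile.
    """
    spec = spec or DiurnalProfileSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 24.0 + spec.step_h / 2, spec.step_h)
    values = {}
    for sid, w in spec.waveforms.items():
        y = w(t)
        if spec.jitter > 0:
            y = y * float(rng.lognormal(0.0, spec.jitter))
        y[-1] = y[0]
        values[sid] = y
    for sid, c in spec.constants.items():
        values[sid] = np.full_like(t, float(c))
    return BoundaryProfile(t, values, periodic=True, period=24.0)


def default_demo_boundary() -> BoundaryProfile:
    return generate_diurnal_profile()


def mean_boundary(profile: BoundaryProfile | None = None) -> dict:
    """24 h mean plasma concentrations — the reference clamp for
    steady-state sensitivity analysis."""
    profile = profile or default_demo_boundary()
    return profile.mean_values()
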