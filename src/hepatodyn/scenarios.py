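"""Pre-packaged perturbation experiments on a hepatocyte model.

Every scenario is a pure function of (model, boundary, configuration,
seed): hypoxia steady-state scans, an ethanol bolus with a one-pool plasma
mass balance, drug inhibition with a time-varying plasma profile
(valproate fixture), galactose challenges on Leloir-pathway enzyme
variants, and proteomics-based rescaling of maximal activities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sympy as sp

from .boundary import BoundaryProfile
from .model import KineticModel, Parameter, Species
from .ratelaws import RateLaw, custom
from .simulate import (CompiledModel, SteadyStateError, Trajectory,
                       compile_model, find_steady_state, simulate)
from .units import convert_units, po2_mmhg_to_mm  # noqa: F401  (re-export)


class ScenarioConfigurationError(ValueError):
    pass


# ----------------------------------------------------------------- infusion

@dataclass
class InfusionProfile:
    """Substance appearance in the plasma: either an explicit rate series
    (µmol/g/h against hours) or a rectangular bolus, or a gamma-shaped
    appearance curve mimicking delayed intestinal absorption."""
    substance: str
    times: np.ndarray | None = None
    rates: np.ndarray | None = None

    def __post_init__(self):
        if self.times is not None:
            self.times = np.asarray(self.times, float)
            self.rates = np.asarray(self.rates, float)
            if np.any(self.rates < 0):
                raise ScenarioConfigurationError("infusion rates must be >= 0")

    @classmethod
    def bolus(cls, substance: str, rate: float, start: float,
              duration: float) -> "InfusionProfile":
        eps = 1e-3
        t = np.array([0.0, start - eps, start, start + duration,
                      start + duration + eps, start + duration + 48.0])
        r = np.array([0.0, 0.0, rate, rate, 0.0, 0.0])
        return cls(substance, t, r)

    @classmethod
    def gamma_appearance(cls, substance: str, total: float, start: float,
                         shape: float = 2.5, scale: float = 0.8,
                         horizon: float = 24.0) -> "InfusionProfile":
        """Appearance curve rate(t) ∝ gamma-density(t − start); ``total`` is
        the integrated amount (µmol/g).  Models the delay between oral
        intake and appearance in the plasma."""
        from scipy.stats import gamma as gamma_dist
        t = np.linspace(0.0, horizon, int(horizon * 8) + 1)
        r = np.where(t >= start,
                     gamma_dist.pdf(t - start, a=shape, scale=scale), 0.0)
        area = np.trapezoid(r, t)
        r = r * (total / area) if area > 0 else r
        return cls(substance, t, r)

    @classmethod
    def zero(cls, substance: str) -> "InfusionProfile":
        return cls(substance, np.array([0.0, 48.0]), np.zeros(2))

    def rate_at(self, t):
        return np.interp(t, self.times, self.rates, left=0.0, right=0.0)


# -------------------------------------------------------------- hypoxia scan

def hypoxia_scan(model: KineticModel, po2_grid_mmhg,
                 boundary_mean: dict | None = None,
                 compiled: CompiledModel | None = None) -> pd.DataFrame:
    """Steady states over a partial-O2-pressure grid.

    Per grid point: the O2 clamp, ATP/ADP ratio, the cytochrome-c reduction
    state, gross glucose production (glucose-6-phosphatase flux), urea
    production, oxygen uptake, and each production normalized to its
    normoxic reference.  Non-convergent points are flagged rather than
    fabricated.
    """
    po2_grid = np.asarray(po2_grid_mmhg, float)
    if np.any(po2_grid < 0):
        raise ScenarioConfigurationError("pO2 grid must be non-negative")
    if boundary_mean is None:
        from .demo import mean_boundary
        boundary_mean = mean_boundary()
    cm = compiled or compile_model(model)
    ref = find_steady_state(model, boundary_mean, compiled=cm)
    glc0 = ref.flux("G6PASE")
    urea0 = ref.flux("UREA_EXP")
    rows = []
    x_warm = ref.state
    for po2 in sorted(po2_grid, reverse=True):
        clamp = dict(boundary_mean)
        clamp["o2_ext"] = po2_mmhg_to_mm(po2)
        try:
            ss = find_steady_state(model, clamp, x0=x_warm, compiled=cm)
            x_warm = ss.state
            cred = ss.conc("cytc_red") / (ss.conc("cytc_red") + ss.conc("cytc_ox"))
            rows.append({
                "po2_mmhg": po2, "converged": True,
                "atp_mM": ss.conc("atp_c"),
                "atp_adp_ratio": ss.conc("atp_c") / ss.conc("adp_c"),
                "cytc_reduction": cred,
                "o2_uptake": ss.flux("O2_T"),
                "glucose_production": ss.flux("G6PASE"),
                "urea_production": ss.flux("UREA_EXP"),
                "rel_glucose_production": ss.flux("G6PASE") / glc0,
                "rel_urea_production": ss.flux("UREA_EXP") / urea0,
                "membrane_potential_mv": ss.potential,
            })
        except SteadyStateError as exc:
            rows.append({"po2_mmhg": po2, "converged": False,
                         "error": str(exc)})
    return pd.DataFrame(rows).sort_values("po2_mmhg").reset_index(drop=True)


# ---------------------------------------------------------- plasma-pool runs

def _with_plasma_pool(model: KineticModel, species_id: str,
                      infusion: InfusionProfile,
                      initial: float = 0.0) -> tuple:
    """Convert a clamped plasma species into an integrated one-pool state
    fed by an infusion forcing function.

    The pool lives in the extracellular compartment (its volume fraction is
    the distribution volume per gram of liver), cleared only by the
    hepatocyte's own exchange reactions; the infusion enters through a
    forcing species carrying the rate series (µmol/g/h).
    """
    m = model.copy()
    spc = m.species[species_id]
    if spc.role != "external":
        raise ScenarioConfigurationError(f"{species_id!r} is not external")
    m.species[species_id] = Species(species_id, spc.compartment, "internal",
                                    initial, spc.bounds, spc.name)
    forcing = f"{species_id}_infusion"
    m.species[forcing] = Species(forcing, "ext", "external", 0.0,
                                 name="infusion forcing (µmol/g/h)")
    from .model import Reaction
    m.reactions[f"INF_{species_id}"] = Reaction(
        f"INF_{species_id}", {species_id: 1},
        custom(forcing), pathway="scenario",
        name=f"{species_id} infusion")
    m.validate()
    return m, forcing


def _infusion_boundary(boundary: BoundaryProfile, forcing: str,
                       infusion: InfusionProfile,
                       horizon: float) -> BoundaryProfile:
    grid = np.arange(0.0, horizon + 0.1251, 0.125)
    out = boundary.overlay(forcing, grid, infusion.rate_at(grid), mode="replace")
    return out


@dataclass
class EthanolResult:
    trajectory: Trajectory
    reference: Trajectory
    panels: pd.DataFrame  # time, plasma ethanol, lactate/acetate exchange, acetaldehyde, TG


def ethanol_bolus(model: KineticModel, boundary: BoundaryProfile,
                  infusion: InfusionProfile, t_span=(0.0, 24.0),
                  x0=None) -> EthanolResult:
    """Acute alcohol challenge.

    Plasma ethanol obeys a one-pool mass balance: infusion input minus
    hepatic clearance through ADH/ALDH; the panels mirror the classic
    readouts (plasma ethanol, lactate and acetate exchange, the toxic
    intermediate acetaldehyde, triglyceride content).
    """
    if infusion.substance != "etoh_ext":
        raise ScenarioConfigurationError("infusion substance must be etoh_ext")
    pooled, forcing = _with_plasma_pool(model, "etoh_ext", infusion)
    cm = compile_model(pooled)
    bnd = _infusion_boundary(boundary, forcing, infusion, t_span[1])
    bnd_ref = _infusion_boundary(boundary, forcing,
                                 InfusionProfile.zero("etoh_ext"), t_span[1])
    t_eval = np.arange(t_span[0], t_span[1] + 0.05, 0.1)
    if x0 is None:
        x0 = cm.x0
    traj = simulate(pooled, bnd, t_span, t_eval=t_eval, x0=x0, compiled=cm)
    ref = simulate(pooled, bnd_ref, t_span, t_eval=t_eval, x0=x0, compiled=cm)
    panels = pd.DataFrame({
        "time_h": traj.times,
        "plasma_ethanol_mM": traj.conc("etoh_ext"),
        "lactate_exchange": traj.exchange_flux("lac_ext"),
        "acetate_exchange": traj.exchange_flux("ac_ext"),
        "acetaldehyde_mM": traj.conc("acald"),
        "tg_mM": traj.conc("tg"),
        "tg_reference_mM": ref.conc("tg"),
    })
    return EthanolResult(trajectory=traj, reference=ref, panels=panels)


# ------------------------------------------------------------ drug inhibition

@dataclass
class DrugTarget:
    enzyme: str
    mechanism: str  # competitive | vmax_scaling
    ki: float | None = None        # mM, for competitive
    factor: float | None = None    # dimensionless, for vmax_scaling
    km_param: str | None = None    # the substrate KM hit by the competitor

    def __post_init__(self):
        if self.mechanism not in ("competitive", "vmax_scaling"):
            raise ScenarioConfigurationError(
                f"unknown inhibition mechanism {self.mechanism!r}")
        if self.mechanism == "competitive":
            if self.ki is None or self.ki <= 0:
                raise ScenarioConfigurationError("competitive target needs Ki > 0")
            if self.km_param is None:
                raise ScenarioConfigurationError(
                    "competitive target must name the KM parameter it raises")
        if self.mechanism == "vmax_scaling" and (self.factor is None
                                                 or self.factor < 0):
            raise ScenarioConfigurationError("vmax_scaling target needs factor >= 0")


@dataclass
class DrugInhibition:
    drug: str                       # plasma species id, e.g. vpa_ext
    targets: list
    profile_times: np.ndarray | None = None
    profile_conc: np.ndarray | None = None  # mM

    def plasma_profile(self):
        return np.asarray(self.profile_times, float), \
            np.asarray(self.profile_conc, float)


def apply_drug(model: KineticModel, drug: DrugInhibition) -> KineticModel:
    """Return a model carrying the drug interactions.

    Competitive inhibition substitutes KM → KM·(1 + [drug]/Ki) inside the
    target's rate law, with [drug] the (time-varying) plasma concentration
    of the drug species; on washout ([drug] = 0) the rate evaluations
    revert exactly.  Vmax-scaling targets multiply the maximal activity by
    a constant factor.
    """
    m = model.copy()
    if drug.drug not in m.species:
        m.species[drug.drug] = Species(drug.drug, "ext", "external", 0.0,
                                       name=f"{drug.drug} plasma level")
    drug_sym = sp.Symbol(drug.drug, real=True)
    for tgt in drug.targets:
        if tgt.enzyme not in m.reactions:
            raise ScenarioConfigurationError(
                f"drug target enzyme {tgt.enzyme!r} not in model")
        rxn = m.reactions[tgt.enzyme]
        if tgt.mechanism == "vmax_scaling":
            m.scale_vmax(tgt.enzyme, tgt.factor)
            continue
        km_sym = sp.Symbol(tgt.km_param, real=True)
        expr = rxn.rate_law.expr
        if km_sym not in expr.free_symbols:
            raise ScenarioConfigurationError(
                f"KM parameter {tgt.km_param!r} not in rate law of {tgt.enzyme!r}")
        ki = sp.Float(tgt.ki)
        new_expr = expr.xreplace({km_sym: km_sym * (1 + drug_sym / ki)})
        law = RateLaw(kind=rxn.rate_law.kind, expression=str(new_expr),
                      modifiers=list(rxn.rate_law.modifiers)
                      + [(drug.drug, "competitive_inhibitor")],
                      vmax_params=list(rxn.rate_law.vmax_params))
        law._expr_cache = new_expr
        from .model import Reaction
        m.reactions[tgt.enzyme] = Reaction(
            rxn.id, rxn.stoichiometry, law, rxn.vmax_ref,
            rxn.charge_transfer, rxn.pathway, rxn.name)
    m.validate()
    return m


def default_vpa_inhibition(dose_peak_mm: float = 0.8, t_bolus: float = 2.0,
                           half_life_h: float = 3.0,
                           horizon: float = 24.0) -> DrugInhibition:
    """Bundled valproate fixture: a single oral bolus appearing at
    ``t_bolus`` and decaying exponentially (its microsomal clearance is
    exogenous to the model), inhibiting the mitochondrial fatty-acid
    carnitine shuttle competitively and throttling N-acetylglutamate
    synthesis."""
    t = np.linspace(0.0, horizon, int(horizon * 8) + 1)
    lam = np.log(2.0) / half_life_h
    rise = 0.5  # absorption time constant, h
    conc = np.where(t >= t_bolus,
                    dose_peak_mm * (1 - np.exp(-(t - t_bolus) / rise))
                    * np.exp(-lam * np.maximum(t - t_bolus - rise, 0.0)), 0.0)
    return DrugInhibition(
        drug="vpa_ext",
        targets=[DrugTarget("CPT_BOX", "competitive", ki=0.40,
                            km_param="km_cpt_ffa"),
                 DrugTarget("AGS", "competitive", ki=1.00,
                            km_param="km_ags_glu")],
        profile_times=t, profile_conc=conc)


@dataclass
class VPAResult:
    trajectory: Trajectory
    reference: Trajectory
    panels: pd.DataFrame
    urea_mean_drug: float
    urea_mean_reference: float
    urea_mean_window: tuple  # means over the exposure window (2-12 h)


def vpa_scenario(model: KineticModel, boundary: BoundaryProfile,
                 inhibition: DrugInhibition | None = None,
                 t_span=(0.0, 24.0), x0=None) -> VPAResult:
    """Single-dose valproate run against the drug-free reference."""
    inhibition = inhibition or default_vpa_inhibition()
    drugged = apply_drug(model, inhibition)
    cm = compile_model(drugged)
    tt, cc = inhibition.plasma_profile()
    bnd = boundary.overlay(inhibition.drug, tt, cc, mode="replace")
    bnd_ref = boundary.overlay(inhibition.drug, tt, np.zeros_like(cc),
                               mode="replace")
    t_eval = np.arange(t_span[0], t_span[1] + 0.05, 0.1)
    if x0 is None:
        x0 = cm.x0
    traj = simulate(drugged, bnd, t_span, t_eval=t_eval, x0=x0, compiled=cm)
    ref = simulate(drugged, bnd_ref, t_span, t_eval=t_eval, x0=x0, compiled=cm)
    urea_d = traj.flux("UREA_EXP")
    urea_r = ref.flux("UREA_EXP")
    win = (traj.times >= 2.0) & (traj.times <= 12.0)
    panels = pd.DataFrame({
        "time_h": traj.times,
        "plasma_vpa_mM": traj.ext_value(inhibition.drug),
        "urea_production": urea_d,
        "urea_production_reference": urea_r,
        "cholesterol_synthesis": traj.flux("CHOLSYN"),
        "cholesterol_synthesis_reference": ref.flux("CHOLSYN"),
        "tg_mM": traj.conc("tg"),
        "tg_reference_mM": ref.conc("tg"),
    })
    mean = lambda y, t: float(np.trapezoid(y, t) / (t[-1] - t[0]))
    return VPAResult(
        trajectory=traj, reference=ref, panels=panels,
        urea_mean_drug=mean(urea_d, traj.times),
        urea_mean_reference=mean(urea_r, ref.times),
        urea_mean_window=(mean(urea_d[win], traj.times[win]),
                          mean(urea_r[win], ref.times[win])))


# ------------------------------------------------------------- galactosemia

@dataclass
class EnzymeVariant:
    """A (possibly deficient) enzyme variant: Vmax scaling and/or kinetic
    constant overrides."""
    enzyme: str | None = None
    vmax_scale: float = 1.0
    param_overrides: dict = field(default_factory=dict)
    label: str = "normal"

    def apply(self, model: KineticModel) -> KineticModel:
        m = model.copy()
        if self.enzyme is not None:
            if self.enzyme not in m.reactions:
                raise ScenarioConfigurationError(
                    f"variant enzyme {self.enzyme!r} not in model")
            m.scale_vmax(self.enzyme, self.vmax_scale)
        for pid, value in self.param_overrides.items():
            m.set_parameter(pid, value)
        return m


LELOIR_VARIANTS = {
    "normal": EnzymeVariant(label="normal"),
    "GALK-null": EnzymeVariant("GALK", 0.0, label="GALK-null (type II)"),
    "GALT-null": EnzymeVariant("GALT", 0.0, label="GALT-null (type I)"),
    "GALE-null": EnzymeVariant("GALE", 0.0, label="GALE-null (type III)"),
}


@dataclass
class GalactosemiaResult:
    variant: str
    trajectory: Trajectory
    auc_gal1p: float
    auc_galactitol: float
    panels: pd.DataFrame


def galactosemia_run(model: KineticModel, boundary: BoundaryProfile,
                     variant: EnzymeVariant,
                     challenge: InfusionProfile | None = None,
                     t_span=(0.0, 24.0), x0=None) -> GalactosemiaResult:
    """Galactose challenge of an enzyme variant.

    Plasma galactose becomes a one-pool state fed by a delayed (gamma-
    shaped) appearance curve starting at t = 2 h; the areas under the
    cellular galactose-1-phosphate and galactitol curves are the risk
    markers for systemic complications and cataract respectively.
    """
    if challenge is None:
        challenge = InfusionProfile.gamma_appearance(
            "gal_ext", total=120.0, start=2.0)
    if challenge.substance != "gal_ext":
        raise ScenarioConfigurationError("challenge substance must be gal_ext")
    varied = variant.apply(model)
    pooled, forcing = _with_plasma_pool(varied, "gal_ext", challenge,
                                        initial=0.08)
    cm = compile_model(pooled)
    bnd = _infusion_boundary(boundary, forcing, challenge, t_span[1])
    t_eval = np.arange(t_span[0], t_span[1] + 0.05, 0.1)
    if x0 is None:
        x0 = cm.x0
    traj = simulate(pooled, bnd, t_span, t_eval=t_eval, x0=x0, compiled=cm)
    auc1 = float(np.trapezoid(traj.conc("gal1p"), traj.times))
    auc2 = float(np.trapezoid(traj.conc("galtol_c"), traj.times))
    panels = pd.DataFrame({
        "time_h": traj.times,
        "plasma_galactose_mM": traj.conc("gal_ext"),
        "glycogen_mM": traj.conc("glycogen"),
        "gal1p_mM": traj.conc("gal1p"),
        "galactitol_mM": traj.conc("galtol_c"),
        "galactitol_export": traj.flux("GALTOL_EXP"),
    })
    return GalactosemiaResult(variant=variant.label, trajectory=traj,
                              auc_gal1p=auc1, auc_galactitol=auc2,
                              panels=panels)


def compare_galactosemia(model: KineticModel, boundary: BoundaryProfile,
                         challenge: InfusionProfile | None = None,
                         variants: dict | None = None,
                         t_span=(0.0, 24.0), x0=None) -> pd.DataFrame:
    """Run the galactose challenge for the normal liver and the three
    classic Leloir deficiencies; returns the AUC risk-marker table."""
    variants = variants or LELOIR_VARIANTS
    rows = []
    for key, var in variants.items():
        res = galactosemia_run(model, boundary, var, challenge, t_span, x0)
        rows.append({"variant": key, "label": res.variant,
                     "auc_gal1p": res.auc_gal1p,
                     "auc_galactitol": res.auc_galactitol})
    return pd.DataFrame(rows)


# --------------------------------------------------------- proteome scaling

@dataclass
class ProteomeScaling:
    """Tumor/normal protein-abundance ratios used to rescale maximal
    activities, phenotyping the expression state of a (malignant) liver."""
    ratios: dict   # enzyme (reaction) id -> abundance ratio > 0
    label: str = ""

    def __post_init__(self):
        bad = {k: v for k, v in self.ratios.items() if not v > 0}
        if bad:
            raise ScenarioConfigurationError(
                f"abundance ratios must be positive: {bad}")


def apply_proteome_scaling(model: KineticModel,
                           scaling: ProteomeScaling) -> tuple:
    """Scale each mapped enzyme's maximal activity by its abundance ratio.

    Returns (new model, coverage report).  Unknown enzyme ids in the table
    are skipped with a warning entry; unmapped model enzymes keep their
    reference Vmax and are listed in the report.
    """
    m = model.copy()
    scaled, unknown = [], []
    for rid, ratio in scaling.ratios.items():
        if rid not in m.reactions or not m.reactions[rid].vmax_params:
            unknown.append(rid)
            continue
        m.scale_vmax(rid, float(ratio))
        scaled.append(rid)
    unmapped = [rid for rid, r in m.reactions.items()
                if r.vmax_params and rid not in scaling.ratios]
    report = {"label": scaling.label, "scaled": scaled,
              "unknown_entries": unknown, "unmapped_enzymes": unmapped,
              "coverage": len(scaled) / max(1, len(scaled) + len(unmapped))}
    return m, report


def read_proteome_table(path) -> ProteomeScaling:
    """Read a delimited enzyme_id → ratio table (TSV/CSV, header row)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ScenarioConfigurationError(
            "proteome table needs columns: enzyme_id, ratio")
    ratios = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))
    return ProteomeScaling(ratios=ratios, label=str(path))
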