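"""Penalty-augmented least-squares calibration of maximal activities.

Maximal activities are the only parameters treated as free (they carry the
variable part of enzyme expression); all other kinetic constants are fixed
enzyme properties.  The fit criterion combines, per experiment group α,

    (1/ȳ_α)² · Σ_i (y_i^exp − y_i^mod)²            (data term)
  + (1/M̄)²  · Σ_i Σ_j H(M_ij)                      (penalty term)

where H is a one-sided quadratic penalty for internal metabolite
concentrations leaving their physiological ranges, ȳ_α is the mean
observed value of group α, and M̄ is the mean metabolite concentration
scale (1.48 mM by default).  Both normalizations make the terms
dimensionless, so a constrained fit becomes a single unconstrained
minimization.  The penalty is evaluated at the observation times of each
experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .boundary import BoundaryProfile
from .functions import evaluate_variable
from .model import KineticModel
from .simulate import CompiledModel, compile_model, simulate

#: mean internal metabolite concentration (mM) normalizing the penalty term
DEFAULT_METABOLITE_SCALE_MM = 1.48

#: optimizer-safe objective value reported when a simulation fails
FAILURE_OBJECTIVE = 1e9


def penalty(m: float, m_min: float, m_max: float) -> float:
    """One-sided quadratic penalty H(M) for a concentration outside
    [M_min, M_max]; zero inside, continuous with continuous derivative at
    both boundaries."""
    if m_min > m_max:
        raise ValueError(f"inverted bounds: [{m_min}, {m_max}]")
    if m > m_max:
        return (m - m_max) ** 2
    if m < m_min:
        return (m_min - m) ** 2
    return 0.0


@dataclass
class Experiment:
    """One simulated experiment with observations.

    ``observations`` is a list of (variable spec, time_h, value); variable
    specs follow :func:`hepatodyn.functions.evaluate_variable`.
    ``function_class`` is the liver-function group label α the experiment
    belongs to in the outer sum of the objective.
    """
    id: str
    boundary: object  # dict of fixed concentrations or BoundaryProfile
    t_span: tuple
    observations: list
    function_class: str = "default"
    x0: np.ndarray | None = None

    def __post_init__(self):
        if len(self.observations) < 1:
            raise ValueError(f"experiment {self.id!r}: needs >= 1 observation")

    @property
    def obs_times(self):
        return sorted({t for _, t, _ in self.observations})

    def profile(self) -> BoundaryProfile:
        if isinstance(self.boundary, BoundaryProfile):
            return self.boundary
        return BoundaryProfile.constant(self.boundary, t_span=self.t_span)


@dataclass
class CalibrationProblem:
    model: KineticModel
    experiments: list
    vmax_ids: list
    bounds: dict = field(default_factory=dict)  # species -> (M_min, M_max) mM
    metabolite_scale: float = DEFAULT_METABOLITE_SCALE_MM
    vmax_bounds: dict = field(default_factory=dict)  # id -> (lo, hi)

    def __post_init__(self):
        if self.metabolite_scale <= 0:
            raise ValueError("metabolite scale must be positive")
        for sid in self.bounds:
            if sid not in self.model.species:
                raise ValueError(f"bounded metabolite {sid!r} not in model")
        for pid in self.vmax_ids:
            if pid not in self.model.parameters:
                raise ValueError(f"unknown Vmax parameter {pid!r}")


@dataclass
class ObjectiveReport:
    value: float
    data_terms: dict         # group -> data term
    penalty_terms: dict      # group -> penalty term
    residuals: dict          # experiment id -> list of (spec, t, exp, mod)
    violations: list         # (experiment, species, time, conc, lo, hi)
    failed: list             # (experiment id, error message)

    @property
    def ok(self) -> bool:
        return not self.failed


def _simulate_experiment(problem, exp, cm, params):
    t_eval = np.unique(np.concatenate(
        [np.linspace(exp.t_span[0], exp.t_span[1], 50),
         np.asarray(exp.obs_times, float)]))
    x0 = exp.x0 if exp.x0 is not None else None
    return simulate(problem.model, exp.profile(), exp.t_span, t_eval=t_eval,
                    x0=x0, compiled=cm, params=params)


def objective(problem: CalibrationProblem, vmax_vector,
              compiled: CompiledModel | None = None,
              full_report: bool = False):
    """Evaluate the calibration objective F at the given Vmax values.

    Simulation failure in any experiment yields a documented large finite
    value plus a failure flag; the experiment is never silently dropped.
    """
    vmax_vector = np.asarray(vmax_vector, float)
    if np.any(vmax_vector <= 0):
        raise ValueError("Vmax values must be positive")
    cm = compiled or compile_model(problem.model)
    params = cm.param_values(problem.model)
    for pid, val in zip(problem.vmax_ids, vmax_vector):
        params[cm.param_ids.index(pid)] = val

    groups = {}
    residuals, violations, failed = {}, [], []
    for exp in problem.experiments:
        g = groups.setdefault(exp.function_class,
                              {"sq": 0.0, "y": [], "pen": 0.0})
        try:
            traj = _simulate_experiment(problem, exp, cm, params)
        except Exception as exc:
            failed.append((exp.id, str(exc)))
            continue
        res = []
        for spec, t_obs, y_exp in exp.observations:
            series = evaluate_variable(traj, spec)
            y_mod = float(np.interp(t_obs, traj.times, series))
            g["sq"] += (y_exp - y_mod) ** 2
            g["y"].append(y_exp)
            res.append((spec, t_obs, y_exp, y_mod))
        residuals[exp.id] = res
        for t_obs in exp.obs_times:
            for sid, (lo, hi) in problem.bounds.items():
                conc = float(np.interp(t_obs, traj.times, traj.conc(sid)))
                h = penalty(conc, lo, hi)
                if h > 0:
                    violations.append((exp.id, sid, t_obs, conc, lo, hi))
                g["pen"] += h

    data_terms, pen_terms = {}, {}
    total = 0.0
    for name, g in groups.items():
        if not g["y"]:
            continue
        ybar = float(np.mean(g["y"]))
        data = g["sq"] / ybar ** 2 if ybar != 0 else g["sq"]
        pen = g["pen"] / problem.metabolite_scale ** 2
        data_terms[name] = data
        pen_terms[name] = pen
        total += data + pen
    if failed:
        total = FAILURE_OBJECTIVE + total
    report = ObjectiveReport(total, data_terms, pen_terms, residuals,
                             violations, failed)
    return report if full_report else total


@dataclass
class FitResult:
    vmax: dict
    objective: float
    objective_initial: float
    report: ObjectiveReport
    n_evaluations: int
    converged: bool
    message: str
    trace: list = field(default_factory=list)
    flat_directions: list = field(default_factory=list)

    def __repr__(self):
        state = "converged" if self.converged else "NOT converged"
        return (f"FitResult({state}, F = {self.objective:.4g}, "
                f"{self.n_evaluations} evaluations)")


def fit_vmax(problem: CalibrationProblem, optimizer_options: dict | None = None,
             seed: int = 0, n_starts: int = 10,
             compiled: CompiledModel | None = None) -> FitResult:
    """Estimate maximal activities by derivative-free minimization of the
    calibration objective in log-Vmax space.

    Multistart (``n_starts`` random log-uniform initial points inside the
    Vmax bounds, plus the model's current values) controlled by ``seed``;
    the best local optimum wins.  Diagnostics include per-experiment
    residuals, bound violations, the evaluation trace, and flat
    (practically unidentifiable) directions detected by a ±10 % profile
    scan around the optimum.
    """
    cm = compiled or compile_model(problem.model)
    opts = {"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000, "adaptive": True}
    opts.update(optimizer_options or {})
    explore_opts = dict(opts)
    explore_opts.update({"maxiter": int(opts["maxiter"] * 0.25),
                         "xatol": 1e-3, "fatol": 1e-6})
    rng = np.random.default_rng(seed)
    ids = list(problem.vmax_ids)
    p0 = np.array([problem.model.parameters[pid].value for pid in ids])
    lo = np.array([problem.vmax_bounds.get(pid, (p * 1e-3, p * 1e3))[0]
                   for pid, p in zip(ids, p0)])
    hi = np.array([problem.vmax_bounds.get(pid, (p * 1e-3, p * 1e3))[1]
                   for pid, p in zip(ids, p0)])
    if np.any(p0 < lo) or np.any(p0 > hi):
        raise ValueError("initial Vmax values must lie inside vmax_bounds")

    trace = []
    n_eval = [0]

    def fun(logv):
        v = np.exp(np.clip(logv, np.log(lo), np.log(hi)))
        f = objective(problem, v, compiled=cm)
        n_eval[0] += 1
        trace.append((n_eval[0], float(f)))
        return f

    f_init = objective(problem, p0, compiled=cm)
    starts = [np.log(p0)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.uniform(np.log(lo), np.log(hi)))

    # cheap exploration from every start, then one thorough local polish
    # from the best exploration result
    best = (np.log(p0), f_init, "initial point", False)
    for s in starts:
        res = minimize(fun, s, method="Nelder-Mead", options=explore_opts)
        if res.fun < best[1]:
            best = (res.x, float(res.fun), res.message, bool(res.success))
    res = minimize(fun, best[0], method="Nelder-Mead", options=opts)
    if res.fun < best[1]:
        best = (res.x, float(res.fun), res.message, bool(res.success))
    x_best, f_best, message, success = best
    v_best = np.exp(np.clip(x_best, np.log(lo), np.log(hi)))
    if f_best > f_init:  # never return worse than the starting point
        v_best, f_best = p0, f_init

    flat = _flat_directions(problem, ids, v_best, f_best, cm)

    report = objective(problem, v_best, compiled=cm, full_report=True)
    return FitResult(vmax=dict(zip(ids, v_best)), objective=f_best,
                     objective_initial=float(f_init), report=report,
                     n_evaluations=n_eval[0],
                     converged=success and report.ok, message=str(message),
                     trace=trace, flat_directions=flat)


def _flat_directions(problem, ids, v_best, f_best, cm,
                     step: float = 0.05, rel_tol: float = 1e-2) -> list:
    """Detect practically unidentifiable directions: eigenvectors of the
    numeric log-space Hessian of the objective whose curvature is tiny
    relative to the largest (a profile-likelihood-style local scan).
    Returns a list of (eigenvalue, {parameter: component}) tuples."""
    k = len(ids)
    u0 = np.log(v_best)

    def f_at(u):
        return objective(problem, np.exp(u), compiled=cm)

    H = np.zeros((k, k))
    base = f_best
    fp = np.zeros(k)
    fm = np.zeros(k)
    for i in range(k):
        e = np.zeros(k); e[i] = step
        fp[i] = f_at(u0 + e)
        fm[i] = f_at(u0 - e)
        H[i, i] = (fp[i] - 2 * base + fm[i]) / step ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k); ei[i] = step
            ej = np.zeros(k); ej[j] = step
            cross = (f_at(u0 + ei + ej) - f_at(u0 + ei - ej)
                     - f_at(u0 - ei + ej) + f_at(u0 - ei - ej))
            H[i, j] = H[j, i] = cross / (4.0 * step ** 2)
    w, vecs = np.linalg.eigh((H + H.T) / 2)
    wmax = max(np.max(np.abs(w)), 1e-30)
    flat = []
    for lam, vec in zip(w, vecs.T):
        if abs(lam) < rel_tol * wmax:
            flat.append((float(lam),
                         {pid: float(c) for pid, c in zip(ids, vec)
                          if abs(c) > 0.05}))
    return flat


# ----------------------------------------------------------------- file IO

def read_bounds_table(path) -> dict:
    """Read a delimited metabolite-range table (species, min, max; header
    row) into a bounds mapping."""
    import pandas as pd
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 3:
        raise ValueError("bounds table needs columns: species, min, max")
    out = {}
    for _, row in df.iterrows():
        lo, hi = float(row.iloc[1]), float(row.iloc[2])
        if lo > hi or lo < 0:
            raise ValueError(f"invalid range for {row.iloc[0]!r}: [{lo}, {hi}]")
        out[str(row.iloc[0])] = (lo, hi)
    return out


def read_experiment(path) -> Experiment:
    """Read one experiment description from structured text (JSON): id,
    fixed boundary concentrations (or a profile file path), protocol time
    span, group label, and observations as [variable, time, value]."""
    import json
    with open(path) as fh:
        doc = json.load(fh)
    boundary = doc["boundary"]
    if isinstance(boundary, str):
        from .io import read_boundary_profile
        boundary = read_boundary_profile(boundary)
    return Experiment(
        id=doc["id"], boundary=boundary,
        t_span=tuple(doc["t_span"]),
        observations=[(o[0], float(o[1]), float(o[2]))
                      for o in doc["observations"]],
        function_class=doc.get("function_class", "default"))


# ------------------------------------------------------------- toy problem

def make_toy_model(vmax=(8.0, 5.0, 3.0, 4.0, 1.5)) -> KineticModel:
    """Five-reaction linear pathway with a branch: uptake of S from the
    plasma, two conversions S → A → B, export of B, and a branch A → C
    with export folded in.  Used as the bundled calibration test bed."""
    from .model import Compartment, Parameter, Reaction, Species
    from . import ratelaws as rl
    m = KineticModel(id="calibration-toy")
    m.compartments["ext"] = Compartment("ext", 10.0)
    m.compartments["cyt"] = Compartment("cyt", 1.0)
    m.species["S_ext"] = Species("S_ext", "ext", "external", 5.0)
    m.species["B_ext"] = Species("B_ext", "ext", "external", 0.1)
    m.species["C_ext"] = Species("C_ext", "ext", "external", 0.1)
    for sid, c0 in [("S", 0.5), ("A", 0.5), ("B", 0.5)]:
        m.species[sid] = Species(sid, "cyt", "internal", c0)
    names = ["v_up", "v_sa", "v_ab", "v_bx", "v_ac"]
    kms = [("km_up", 2.0), ("km_sa", 0.4), ("km_ab", 0.6),
           ("km_bx", 0.8), ("km_ac", 0.3)]
    for (nid, v), (kid, k) in zip(zip(names, vmax), kms):
        m.parameters[nid] = Parameter(nid, float(v), "VMAX")
        m.parameters[kid] = Parameter(kid, k, "KM")
    m.parameters["keq_up"] = Parameter("keq_up", 1.0, "OTHER")
    m.parameters["km_up_c"] = Parameter("km_up_c", 2.0, "KM")
    m.reactions["UP"] = Reaction("UP", {"S_ext": -1, "S": 1},
                                 rl.reversible_mm("v_up", {"S_ext": "km_up"},
                                                  {"S": "km_up_c"}, "keq_up"))
    m.reactions["SA"] = Reaction("SA", {"S": -1, "A": 1},
                                 rl.reversible_mm("v_sa", {"S": "km_sa"}))
    m.reactions["AB"] = Reaction("AB", {"A": -1, "B": 1},
                                 rl.reversible_mm("v_ab", {"A": "km_ab"}))
    m.reactions["BX"] = Reaction("BX", {"B": -1, "B_ext": 1},
                                 rl.reversible_mm("v_bx", {"B": "km_bx"}))
    m.reactions["AC"] = Reaction("AC", {"A": -1, "C_ext": 1},
                                 rl.reversible_mm("v_ac", {"A": "km_ac"}))
    m.validate()
    return m


def make_toy_problem(noise: float = 0.0, seed: int = 0,
                     true_vmax=(8.0, 5.0, 3.0, 4.0, 1.5)) -> CalibrationProblem:
    """Calibration problem over the toy pathway with synthetic observations
    generated from the known ground truth (noiseless by default)."""
    truth = make_toy_model(true_vmax)
    boundary = {"S_ext": 5.0, "B_ext": 0.1, "C_ext": 0.1}
    t_span = (0.0, 12.0)
    obs_specs = [("conc:S", t) for t in (1.0, 3.0, 8.0)] + \
                [("conc:A", t) for t in (1.0, 3.0, 8.0)] + \
                [("conc:B", t) for t in (1.0, 3.0, 8.0)] + \
                [("flux:BX", t) for t in (4.0, 12.0)] + \
                [("flux:AC", t) for t in (4.0, 12.0)] + \
                [("flux:UP", t) for t in (4.0, 12.0)]
    prof = BoundaryProfile.constant(boundary, t_span=t_span)
    t_eval = np.unique([t for _, t in obs_specs])
    traj = simulate(truth, prof, t_span,
                    t_eval=np.union1d(np.linspace(*t_span, 49), t_eval))
    rng = np.random.default_rng(seed)
    observations = []
    for spec, t in obs_specs:
        y = float(np.interp(t, traj.times, evaluate_variable(traj, spec)))
        if noise > 0:
            y *= float(rng.lognormal(0.0, noise))
        observations.append((spec, t, y))
    exp = Experiment(id="toy-timecourse", boundary=boundary, t_span=t_span,
                     observations=observations, function_class="toy")
    # a mildly perturbed starting model: truth is not the initial guess
    start = make_toy_model(tuple(v * f for v, f in
                                 zip(true_vmax, (2.2, 0.5, 1.8, 0.6, 1.7))))
    bounds = {"S": (0.0, 10.0), "A": (0.0, 10.0), "B": (0.0, 10.0)}
    return CalibrationProblem(model=start, experiments=[exp],
                              vmax_ids=["v_up", "v_sa", "v_ab", "v_bx", "v_ac"],
                              bounds=bounds,
                              vmax_bounds={pid: (0.05, 100.0) for pid in
                                           ["v_up", "v_sa", "v_ab", "v_bx", "v_ac"]})
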