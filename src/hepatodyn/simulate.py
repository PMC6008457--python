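"""ODE assembly, integration, and steady-state solving.

The right-hand side is d(c)/dt = diag(1/f) · S · v(c, b(t), p) over the
internal species, with external species clamped to the boundary profile
b(t) and, when present, the lumped membrane potential integrated as
d(Δψ)/dt = (1/C) · Σ_r z_r v_r.  Rate laws are compiled once per model
structure with sympy.lambdify; maximal activities and all other parameters
stay run-time arguments, so Vmax perturbation studies (control analysis,
Monte-Carlo sampling, proteome scaling) re-use one compilation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .boundary import BoundaryProfile
from .model import KineticModel, conserved_moieties, moiety_totals
from .ratelaws import POTENTIAL_SYMBOL

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-9  # mM
DEFAULT_METHOD = "LSODA"


class IntegrationError(RuntimeError):
    def __init__(self, message, t_last=None):
        super().__init__(message)
        self.t_last = t_last


class SteadyStateError(RuntimeError):
    pass


# --------------------------------------------------------------------- compile

class CompiledModel:
    """Structure-level compilation of a model: symbol ordering, scaled
    stoichiometry, and one vectorized rate evaluator shared by every run
    that only changes parameter values."""

    def __init__(self, model: KineticModel):
        model.validate()
        self.model_id = model.id
        self.int_ids = model.internal_species
        self.ext_ids = model.external_species
        self.param_ids = list(model.parameters)
        self.reaction_ids = model.reaction_ids
        self.has_potential = model.membrane_potential is not None
        self.capacitance = (model.membrane_potential.capacitance
                           if self.has_potential else None)
        self.initial_potential = (model.membrane_potential.initial_mv
                                  if self.has_potential else None)

        S_int = model.stoichiometry_matrix(self.int_ids)
        vols = model.volume_fractions(self.int_ids)
        self.S_int = S_int
        self.A = S_int / vols[:, None]
        self.S_ext = model.stoichiometry_matrix(self.ext_ids)
        self.charge = np.array([r.charge_transfer for r in model.reactions.values()])
        self.x0 = np.array([model.species[s].initial_concentration
                            for s in self.int_ids])
        if self.has_potential:
            self.x0 = np.append(self.x0, self.initial_potential)
        self.n_int = len(self.int_ids)

        syms = ([sp.Symbol("t", real=True)]
                + [sp.Symbol(s, real=True) for s in self.int_ids]
                + ([sp.Symbol(POTENTIAL_SYMBOL, real=True)] if self.has_potential else [])
                + [sp.Symbol(s, real=True) for s in self.ext_ids]
                + [sp.Symbol(p, real=True) for p in self.param_ids])
        exprs = [r.rate_law.expr for r in model.reactions.values()]
        # two compiled evaluators: a fast scalar path (math module, common
        # subexpressions shared) driving the integrator, and a numpy path
        # for vectorized post-processing over whole time grids
        self._fn_scalar = sp.lambdify(syms, exprs, modules="math", cse=True)
        self._fn = sp.lambdify(syms, exprs, modules="numpy")
        self.referenced_externals = model.referenced_externals()

    def param_values(self, model: KineticModel) -> np.ndarray:
        return model.parameter_vector(self.param_ids)

    def state_from(self, mapping: dict, potential: float | None = None) -> np.ndarray:
        """Build a state vector from a species → concentration mapping;
        species not in the mapping keep their model initial values.  The
        membrane potential may come from ``mapping['dpsi']`` or the
        ``potential`` argument."""
        x = self.x0.copy()
        for i, sid in enumerate(self.int_ids):
            if sid in mapping:
                x[i] = float(mapping[sid])
        if self.has_potential:
            if potential is not None:
                x[self.n_int] = float(potential)
            elif "dpsi" in mapping:
                x[self.n_int] = float(mapping["dpsi"])
        return x

    def resolve_state(self, x0) -> np.ndarray:
        if x0 is None:
            return self.x0.copy()
        if isinstance(x0, dict):
            return self.state_from(x0)
        return np.asarray(x0, float)

    def rates(self, t, state, ext, p) -> np.ndarray:
        """Reaction rates; ``state``/``ext`` may be 1-D (one time point) or
        2-D stacks (n_points per row inner axis) for vectorized output."""
        state = np.asarray(state)
        if state.ndim > 1:
            args = [t, *state, *np.asarray(ext), *p]
            n = state.shape[-1]
            return np.vstack([np.broadcast_to(np.asarray(o, float), (n,))
                              for o in self._fn(*args)])
        return np.array(self._fn_scalar(t, *state, *ext, *p), float)

    def bind_boundary(self, boundary: BoundaryProfile):
        missing = [s for s in self.referenced_externals
                   if s not in boundary.species_ids]
        if missing:
            raise IntegrationError(
                f"boundary profile lacks external species {missing}")
        prof_ids = boundary.species_ids
        cols = np.array([prof_ids.index(s) if s in prof_ids else 0
                         for s in self.ext_ids], int)
        mask = np.array([1.0 if s in prof_ids else 0.0 for s in self.ext_ids])

        def ext_at(t):
            vals = boundary.values_at(t)
            return vals[..., cols] * mask
        return ext_at


def compile_model(model: KineticModel) -> CompiledModel:
    return CompiledModel(model)


def build_rhs(model: KineticModel, boundary: BoundaryProfile,
              compiled: CompiledModel | None = None,
              params: np.ndarray | None = None):
    """Return the derivative function f(t, state) -> d(state)/dt.

    ``state`` stacks the internal concentrations (model order) and, last,
    the membrane potential if the model has one.
    """
    cm = compiled or compile_model(model)
    p = cm.param_values(model) if params is None else np.asarray(params, float)
    ext_at = cm.bind_boundary(boundary)
    A, charge, n_int = cm.A, cm.charge, cm.n_int
    cap = cm.capacitance

    if cm.has_potential:
        def rhs(t, x):
            v = cm.rates(t, x, ext_at(t), p)
            dx = A @ v
            return np.append(dx, charge @ v / cap)
    else:
        def rhs(t, x):
            return A @ cm.rates(t, x, ext_at(t), p)
    rhs.compiled = cm
    rhs.params = p
    rhs.ext_at = ext_at
    return rhs


# ------------------------------------------------------------------ trajectory

@dataclass
class Trajectory:
    """Time-stamped record of an integration: internal concentrations (mM),
    reaction fluxes (µmol/g/h), clamped external values, and
    plasma-membrane exchange fluxes (uptake-positive: negative values mean
    net release to the plasma)."""
    times: np.ndarray
    species: list
    state: np.ndarray            # (n_t, n_internal)
    reaction_ids: list
    fluxes: np.ndarray           # (n_t, n_reactions)
    external: list
    ext_values: np.ndarray       # (n_t, n_external)
    exchange: np.ndarray         # (n_t, n_external), uptake-positive
    potential: np.ndarray | None = None  # mV
    metadata: dict = field(default_factory=dict)

    def conc(self, sid: str) -> np.ndarray:
        return self.state[:, self.species.index(sid)]

    def flux(self, rid: str) -> np.ndarray:
        return self.fluxes[:, self.reaction_ids.index(rid)]

    def exchange_flux(self, sid: str) -> np.ndarray:
        return self.exchange[:, self.external.index(sid)]

    def ext_value(self, sid: str) -> np.ndarray:
        return self.ext_values[:, self.external.index(sid)]

    def ratio(self, num: str, den: str) -> np.ndarray:
        return self.conc(num) / self.conc(den)

    def state_dict(self, i: int = -1) -> dict:
        """Species → concentration mapping at output index ``i`` (default
        final), including 'dpsi'; useful to warm-start a differently
        structured model."""
        out = {sid: float(self.state[i, j]) for j, sid in enumerate(self.species)}
        for j, sid in enumerate(self.external):
            out.setdefault(sid, float(self.ext_values[i, j]))
        if self.potential is not None:
            out["dpsi"] = float(self.potential[i])
        return out

    @property
    def final_state(self) -> np.ndarray:
        x = self.state[-1]
        if self.potential is not None:
            x = np.append(x, self.potential[-1])
        return x

    def to_frame(self):
        import pandas as pd
        data = {"time_h": self.times}
        for i, s in enumerate(self.species):
            data[s] = self.state[:, i]
        if self.potential is not None:
            data["dpsi_mv"] = self.potential
        for i, r in enumerate(self.reaction_ids):
            data[f"flux:{r}"] = self.fluxes[:, i]
        for i, s in enumerate(self.external):
            data[f"ext:{s}"] = self.ext_values[:, i]
            data[f"uptake:{s}"] = self.exchange[:, i]
        return pd.DataFrame(data)


def _assemble_trajectory(cm: CompiledModel, p, ext_at, t, X,
                         metadata) -> Trajectory:
    n_int = cm.n_int
    state = X[:, :n_int]
    potential = X[:, n_int] if cm.has_potential else None
    ext_vals = np.array([ext_at(ti) for ti in t])
    # vectorized flux evaluation over the whole grid
    V = cm.rates(t, X.T, ext_vals.T, p).T
    exchange = -(V @ cm.S_ext.T)
    return Trajectory(times=t, species=cm.int_ids, state=state,
                      reaction_ids=cm.reaction_ids, fluxes=V,
                      external=cm.ext_ids, ext_values=ext_vals,
                      exchange=exchange, potential=potential,
                      metadata=metadata)


def simulate(model: KineticModel, boundary: BoundaryProfile, t_span,
             t_eval=None, x0=None, rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL,
             method=DEFAULT_METHOD, max_step=np.inf,
             compiled: CompiledModel | None = None,
             params: np.ndarray | None = None) -> Trajectory:
    """Integrate the model under the boundary forcing over ``t_span`` (h)."""
    if not boundary.supports(t_span):
        raise IntegrationError(
            f"t_span {t_span} outside the boundary profile support and the "
            f"profile is not periodic")
    cm = compiled or compile_model(model)
    rhs = build_rhs(model, boundary, compiled=cm, params=params)
    x_init = cm.resolve_state(x0)
    if t_eval is None:
        t_eval = np.linspace(t_span[0], t_span[1],
                             int(round((t_span[1] - t_span[0]) / 0.1)) + 1)
    sol = solve_ivp(rhs, t_span, x_init, method=method, t_eval=t_eval,
                    rtol=rtol, atol=atol, max_step=max_step)
    if not sol.success:
        t_last = sol.t[-1] if len(sol.t) else t_span[0]
        dx = rhs(t_last, sol.y[:, -1]) if len(sol.t) else None
        stiff = ("" if dx is None else
                 f"; |dx/dt|_max at failure = {np.max(np.abs(dx)):.3g}/h "
                 f"(stiffness: consider method='BDF' or smaller max_step)")
        raise IntegrationError(
            f"integration failed at t = {t_last:.4g} h: {sol.message}{stiff}",
            t_last=t_last)
    metadata = {"rtol": rtol, "atol": atol, "method": method,
                "t_span": [float(t_span[0]), float(t_span[1])],
                "model_id": cm.model_id}
    return _assemble_trajectory(cm, rhs.params, rhs.ext_at, sol.t, sol.y.T, metadata)


# ---------------------------------------------------------------- steady state

@dataclass
class SteadyState:
    state: np.ndarray          # internal concentrations (+ potential last)
    species: list
    fluxes: np.ndarray
    reaction_ids: list
    residual_norm: float
    converged: bool
    hours_integrated: float

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.state, dtype=dtype)

    def conc(self, sid: str) -> float:
        return float(self.state[self.species.index(sid)])

    def flux(self, rid: str) -> float:
        return float(self.fluxes[self.reaction_ids.index(rid)])

    @property
    def potential(self):
        return float(self.state[len(self.species)]) \
            if len(self.state) > len(self.species) else None


def find_steady_state(model: KineticModel, fixed_boundary: dict,
                      x0=None, tol=1e-9, max_hours=40000.0,
                      compiled: CompiledModel | None = None,
                      params: np.ndarray | None = None,
                      polish: bool = True) -> SteadyState:
    """Steady state at clamped external concentrations.

    Long stiff integration to relax onto the attractor, then a damped
    least-squares polish that also pins the conserved-moiety totals of the
    starting state.  Raises :class:`SteadyStateError` when no fixed point
    is reached within the integration budget (e.g., an oscillatory
    attractor keeps the residual from shrinking).
    """
    cm = compiled or compile_model(model)
    missing = [s for s in cm.referenced_externals if s not in fixed_boundary]
    if missing:
        raise SteadyStateError(f"fixed boundary lacks external species {missing}")
    bnd = BoundaryProfile.constant(fixed_boundary, t_span=(0.0, 1.0))
    rhs = build_rhs(model, bnd, compiled=cm, params=params)
    x = cm.resolve_state(x0)

    def resnorm(xx):
        return float(np.max(np.abs(rhs(0.0, xx))))

    scale = max(1.0, float(np.max(np.abs(x))))
    target = tol * scale
    hours = 0.0
    chunk = 50.0
    prev = resnorm(x)
    while hours < max_hours and prev > 0.01 * max(target, 1e-12):
        sol = solve_ivp(rhs, (0.0, chunk), x, method=DEFAULT_METHOD,
                        rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL)
        if not sol.success:
            raise SteadyStateError(
                f"relaxation integration failed at t = {hours + sol.t[-1]:.4g} h: "
                f"{sol.message}")
        x = sol.y[:, -1]
        hours += chunk
        cur = resnorm(x)
        if cur > 0.5 * prev and cur > 1e3 * max(target, 1e-12) and hours > 2000.0:
            # residual no longer shrinking: give the Newton polish a chance
            # before declaring failure (slow quasi-linear drift of a large
            # storage pool looks like a stall to the integrator)
            if polish:
                cand = _polish(model, cm, rhs, x)
                if np.max(np.abs(rhs(0.0, cand))) <= tol * max(1.0, float(np.max(np.abs(cand)))):
                    x = cand
                    prev = resnorm(x)
                    break
            raise SteadyStateError(
                f"residual stalled at {cur:.3g} after {hours:.0f} h: no steady "
                f"state (possibly an oscillatory attractor)")
        prev = cur
        chunk = min(chunk * 2.0, 6400.0)

    if polish:
        x = _polish(model, cm, rhs, x)
    res = resnorm(x)
    scale = max(1.0, float(np.max(np.abs(x))))
    converged = res <= tol * scale
    if not converged and prev > 1e-4:
        raise SteadyStateError(
            f"no steady state within the iteration budget (residual {res:.3g})")
    ext = np.array([fixed_boundary.get(s, 0.0) for s in cm.ext_ids])
    p = cm.param_values(model) if params is None else np.asarray(params, float)
    fluxes = cm.rates(0.0, x, ext, p)
    return SteadyState(state=x, species=cm.int_ids, fluxes=fluxes,
                       reaction_ids=cm.reaction_ids, residual_norm=res,
                       converged=converged, hours_integrated=hours)


def _polish(model, cm, rhs, x):
    """Least-squares Newton polish of d(state)/dt = 0 in log-concentration
    coordinates, with conserved-moiety totals appended as constraints."""
    moieties = conserved_moieties(model)
    totals0 = moiety_totals(model, moieties, x[:cm.n_int]) if moieties else np.zeros(0)
    n_int = cm.n_int
    base = np.where(x[:n_int] > 1e-12, x[:n_int], 1e-12)

    def unpack(u):
        xx = x.copy()
        xx[:n_int] = base * np.exp(np.clip(u[:n_int], -30, 30))
        if cm.has_potential:
            xx[n_int] = u[n_int]
        return xx

    def fun(u):
        xx = unpack(u)
        r = rhs(0.0, xx)
        if moieties:
            m = moiety_totals(model, moieties, xx[:n_int]) - totals0
            r = np.concatenate([r, m])
        return r

    u0 = np.zeros_like(x)
    if cm.has_potential:
        u0[n_int] = x[n_int]
    try:
        sol = root(fun, u0, method="lm", options={"maxiter": 2000})
    except Exception:
        return x
    cand = unpack(sol.x)
    if np.max(np.abs(rhs(0.0, cand))) < np.max(np.abs(rhs(0.0, x))):
        return cand
    return x


def check_conservation(model: KineticModel, traj: Trajectory,
                       rel_tol: float = 1e-6) -> float:
    """Max relative drift of any conserved moiety along a trajectory."""
    moieties = conserved_moieties(model)
    if not moieties:
        return 0.0
    totals = moiety_totals(model, moieties, traj.state)
    worst = 0.0
    for row in totals:
        ref = row[0]
        if abs(ref) < 1e-12:
            continue
        worst = max(worst, float(np.max(np.abs(row - ref)) / abs(ref)))
    return worst
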