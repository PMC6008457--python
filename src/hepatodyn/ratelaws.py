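"""Composable enzyme and transporter rate laws.

Every constructor returns a :class:`RateLaw` holding a sympy expression over
species and parameter symbols.  The closed constructor set covers the
mechanisms a compartmental hepatocyte model needs: mass action, reversible
Michaelis-Menten with a Haldane-consistent numerator (rate is exactly zero
when the mass-action ratio equals the equilibrium constant), Hill kinetics,
Goldman-Hodgkin-Katz electrodiffusion, allosteric/competitive modifier
wrapping, and interpolation between a phosphorylated and a dephosphorylated
enzyme state driven by plasma glucose.  A ``custom`` escape hatch accepts an
arbitrary expression string.

Maximal-activity parameters always enter as multiplicative pre-factors, so
the scaled elasticity of any constructed rate with respect to its Vmax is 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import sympy as sp

from .units import FARADAY, GAS_CONSTANT, THERMAL_VOLTAGE_MV

#: Reserved symbol for the lumped inner-membrane potential (mV).
POTENTIAL_SYMBOL = "dpsi"

_RESERVED = {POTENTIAL_SYMBOL, "t", "exp", "log", "Abs", "Piecewise", "Min", "Max"}

MODIFIER_MODES = ("allosteric_activator", "allosteric_inhibitor",
                  "competitive_inhibitor")


class RateLawError(ValueError):
    pass


def _sym(name: str) -> sp.Symbol:
    return sp.Symbol(name, real=True)


@dataclass
class RateLaw:
    """A symbolic reaction rate.

    ``expression`` is the canonical string form (source of truth for
    serialization); ``modifiers`` records (species id, mode) pairs for
    bookkeeping; ``vmax_params`` lists the maximal-activity parameter ids
    entering as pre-factors (two for phospho-interpolated laws).
    """
    kind: str
    expression: str
    modifiers: list = field(default_factory=list)
    vmax_params: list = field(default_factory=list)

    _expr_cache: object = field(default=None, repr=False, compare=False)

    @property
    def expr(self) -> sp.Expr:
        if self._expr_cache is None:
            self._expr_cache = parse_expression(self.expression)
        return self._expr_cache

    def symbols(self) -> set:
        return {s.name for s in self.expr.free_symbols}


_FUNCTIONS = {"exp": sp.exp, "log": sp.log, "Abs": sp.Abs, "abs": sp.Abs,
              "sqrt": sp.sqrt, "Piecewise": sp.Piecewise, "Min": sp.Min,
              "Max": sp.Max, "sign": sp.sign, "tanh": sp.tanh}
_NAME_RE = __import__("re").compile(r"[A-Za-z_][A-Za-z0-9_]*")


def parse_expression(text: str) -> sp.Expr:
    """Parse a rate-law expression string into sympy, treating every bare
    name as a real symbol (sympy built-in names like S, E, I, pi never
    capture species or parameter ids)."""
    local = {}
    for name in set(_NAME_RE.findall(text)):
        if name in _FUNCTIONS or name == "True":
            continue
        local[name] = _sym(name)
    local.update(_FUNCTIONS)
    expr = sp.sympify(text, locals=local, evaluate=True)
    subs = {s: _sym(s.name) for s in expr.free_symbols}
    return expr.xreplace(subs)


def _from_expr(kind: str, expr: sp.Expr, modifiers=None, vmax_params=None) -> RateLaw:
    law = RateLaw(kind=kind, expression=str(expr),
                  modifiers=list(modifiers or []),
                  vmax_params=list(vmax_params or []))
    law._expr_cache = expr
    return law


def mass_action(k: str, substrates: dict, products: dict | None = None,
                keq: str | None = None) -> RateLaw:
    """v = k·(ΠS^n − ΠP^m / Keq); irreversible when ``products`` is None.

    ``substrates``/``products`` map species id → kinetic order.
    """
    fwd = sp.Integer(1)
    for sid, order in substrates.items():
        fwd *= _sym(sid) ** order
    expr = _sym(k) * fwd
    if products:
        if keq is None:
            raise RateLawError("reversible mass action requires an equilibrium constant")
        rev = sp.Integer(1)
        for sid, order in products.items():
            rev *= _sym(sid) ** order
        expr = _sym(k) * (fwd - rev / _sym(keq))
    return _from_expr("mass_action", expr, vmax_params=[k])


def reversible_mm(vmax: str, substrates: dict, products: dict | None = None,
                  keq: str | None = None) -> RateLaw:
    """Generalized (reversible) Michaelis-Menten.

    ``substrates``/``products`` map species id → its KM parameter id.
    Numerator (ΠS − ΠP/Keq)/ΠKmS vanishes exactly at equilibrium
    (Haldane-consistent); denominator Π(1+S/KmS) + Π(1+P/KmP) − 1.
    With ``products=None`` this is irreversible Michaelis-Menten.
    """
    prod_s = sp.Integer(1)
    den_s = sp.Integer(1)
    km_prod = sp.Integer(1)
    for sid, km in substrates.items():
        s, k = _sym(sid), _sym(km)
        prod_s *= s
        den_s *= 1 + s / k
        km_prod *= k
    if products:
        if keq is None:
            raise RateLawError("reversible MM requires an equilibrium constant")
        prod_p = sp.Integer(1)
        den_p = sp.Integer(1)
        for sid, km in products.items():
            p, k = _sym(sid), _sym(km)
            prod_p *= p
            den_p *= 1 + p / k
        num = (prod_s - prod_p / _sym(keq)) / km_prod
        den = den_s + den_p - 1
    else:
        num = prod_s / km_prod
        den = den_s
    expr = _sym(vmax) * num / den
    return _from_expr("reversible_mm", expr, vmax_params=[vmax])


def hill(vmax: str, substrate: str, k_half: str, n: str) -> RateLaw:
    """v = Vmax · S^n / (K^n + S^n)."""
    s, k, h = _sym(substrate), _sym(k_half), _sym(n)
    expr = _sym(vmax) * s ** h / (k ** h + s ** h)
    return _from_expr("hill", expr, vmax_params=[vmax])


def ghk_expression(perm: sp.Expr, charge: int, c_in: sp.Expr, c_out: sp.Expr,
                   potential: sp.Expr) -> sp.Expr:
    """Symbolic GHK constant-field flux, outward-positive, with a series
    branch near zero potential so the expression stays finite."""
    u = sp.Integer(charge) * potential / sp.Float(THERMAL_VOLTAGE_MV)
    main = perm * u * (c_in - c_out * sp.exp(-u)) / (1 - sp.exp(-u))
    series = perm * ((c_in - c_out) + u * (c_in + c_out) / 2
                     + u ** 2 * (c_in - c_out) / 12)
    return sp.Piecewise((series, sp.Abs(u) < sp.Float(1e-4)), (main, True))


def ghk_ion(perm: str, charge: int, c_in: str, c_out: str,
            orientation: int = 1) -> RateLaw:
    """Goldman-Hodgkin-Katz electrodiffusive flux of an ion of valence
    ``charge`` across the charged membrane, driven by the lumped membrane
    potential symbol ``dpsi`` (mV).  ``c_in``/``c_out`` are species or
    parameter ids (mM).  Flux is positive outward (in → out).
    ``orientation=-1`` flips the potential sign for membranes whose "in"
    side is the electrically negative side (e.g., the mitochondrial matrix
    when ``dpsi`` is stored as the positive proton-motive potential)."""
    if not isinstance(charge, int) or isinstance(charge, bool):
        raise RateLawError(f"ion charge must be an integer, got {charge!r}")
    if charge == 0:
        raise RateLawError("GHK flux requires a nonzero integer charge")
    if orientation not in (1, -1):
        raise RateLawError("orientation must be +1 or -1")
    expr = ghk_expression(_sym(perm), charge, _sym(c_in), _sym(c_out),
                          orientation * _sym(POTENTIAL_SYMBOL))
    return _from_expr("ghk_ion", expr, vmax_params=[perm])


def ghk_flux(permeability: float, charge: int, potential_mv: float,
             conc_in: float, conc_out: float,
             temperature: float = 310.15) -> float:
    """Numeric GHK constant-field flux (outward positive).

    Continuous at ``potential_mv → 0`` through a series branch; at the
    Nernst potential of the ion the flux is exactly zero.
    """
    if not isinstance(charge, int) or isinstance(charge, bool):
        raise RateLawError(f"ion charge must be an integer, got {charge!r}")
    if charge == 0:
        raise RateLawError("GHK flux requires a nonzero integer charge")
    if permeability < 0:
        raise RateLawError("permeability must be non-negative")
    phi = GAS_CONSTANT * temperature / FARADAY * 1000.0  # mV
    u = charge * potential_mv / phi
    if abs(u) < 1e-4:
        return permeability * ((conc_in - conc_out)
                               + u * (conc_in + conc_out) / 2.0
                               + u * u * (conc_in - conc_out) / 12.0)
    return permeability * u * (conc_in - conc_out * math.exp(-u)) / (1.0 - math.exp(-u))


def with_modifiers(core: RateLaw, activators=(), inhibitors=(),
                   competitive=()) -> RateLaw:
    """Wrap a core rate law with regulatory terms.

    ``activators``/``inhibitors``: iterables of (species id, affinity
    parameter id) or (species id, affinity id, hill exponent id); each
    multiplies the core rate by a saturating activation term
    E^h/(KA^h + E^h) or the complementary inhibition term KA^h/(KA^h + E^h).

    ``competitive``: iterable of (inhibitor species id, Ki parameter id,
    KM parameter id); substitutes KM → KM·(1 + I/Ki) in the core law, the
    textbook apparent-KM effect of a competitive inhibitor.
    """
    expr = core.expr
    modifiers = list(core.modifiers)
    for item in competitive:
        sid, ki, km = item
        km_s = _sym(km)
        if km_s not in expr.free_symbols:
            raise RateLawError(f"competitive target KM {km!r} not in rate law")
        expr = expr.xreplace({km_s: km_s * (1 + _sym(sid) / _sym(ki))})
        modifiers.append((sid, "competitive_inhibitor"))
    for item in activators:
        sid, ka = item[0], item[1]
        h = _sym(item[2]) if len(item) > 2 else sp.Integer(1)
        e, k = _sym(sid), _sym(ka)
        expr = expr * e ** h / (k ** h + e ** h)
        modifiers.append((sid, "allosteric_activator"))
    for item in inhibitors:
        sid, ka = item[0], item[1]
        h = _sym(item[2]) if len(item) > 2 else sp.Integer(1)
        e, k = _sym(sid), _sym(ka)
        expr = expr * k ** h / (k ** h + e ** h)
        modifiers.append((sid, "allosteric_inhibitor"))
    return _from_expr(core.kind, expr, modifiers=modifiers,
                      vmax_params=core.vmax_params)


def phospho_fraction_expr(glucose: sp.Expr, half_saturation: float,
                          steepness: float, direction: str) -> sp.Expr:
    """Phosphorylated-enzyme fraction γ(glc) ∈ [0,1] as a Hill sigmoid.

    ``direction='falling'``: γ decreases with glucose (the physiological
    case — insulin at high glucose activates phosphatases);
    ``direction='rising'``: γ increases with glucose.
    """
    if direction not in ("rising", "falling"):
        raise RateLawError("direction must be 'rising' or 'falling'")
    k = sp.Float(half_saturation)
    n = sp.Float(steepness)
    rising = glucose ** n / (k ** n + glucose ** n)
    return rising if direction == "rising" else 1 - rising


def phospho_interpolated(gamma: sp.Expr, law_phospho: RateLaw,
                         law_dephospho: RateLaw) -> RateLaw:
    """Interpolate between the phosphorylated-state rate law and the
    dephosphorylated-state rate law: v = γ·v_P + (1−γ)·v_D.

    The two states carry their own maximal activities and kinetic
    constants; γ is the phosphorylation-state expression (a function of
    plasma glucose, see :func:`phospho_fraction_expr`).
    """
    expr = gamma * law_phospho.expr + (1 - gamma) * law_dephospho.expr
    return _from_expr(
        "phospho_interpolated", expr,
        modifiers=list(law_phospho.modifiers) + list(law_dephospho.modifiers),
        vmax_params=list(law_phospho.vmax_params) + list(law_dephospho.vmax_params))


def custom(expression: str, vmax_params=()) -> RateLaw:
    """Escape hatch: an arbitrary expression string over species/parameter
    ids (plus ``dpsi`` and ``t`` where meaningful)."""
    expr = parse_expression(expression)
    return _from_expr("custom_expression", expr, vmax_params=list(vmax_params))
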