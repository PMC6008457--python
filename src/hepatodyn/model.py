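"""Domain types for the compartmental kinetic network.

A :class:`KineticModel` bundles compartments, species, a global parameter
table (with the four biochemical categories KM / KA / VMAX / N), reactions
with symbolic rate laws, glucose-driven phosphorylation functions, and an
optional lumped inner-membrane potential.  Internal species obey
d(c_i)/dt = (1/f_i) · Σ_r S_ir · v_r with f_i the volume fraction of the
species' compartment; external species are boundary conditions and are
never integrated.  There are no implicit sources or sinks: all carbon and
nitrogen enters or leaves through explicit exchange reactions with the
extracellular compartment.
"""

from __future__ import annotations

import copy as _copy
import hashlib
import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction

import numpy as np
import sympy as sp

from .ratelaws import RateLaw, POTENTIAL_SYMBOL

PARAMETER_CATEGORIES = ("KM", "KA", "VMAX", "N", "OTHER")


class ModelDefinitionError(ValueError):
    pass


@dataclass
class Compartment:
    id: str
    volume_fraction: float
    name: str = ""

    def __post_init__(self):
        if self.volume_fraction <= 0:
            raise ModelDefinitionError(
                f"compartment {self.id!r}: volume fraction must be positive")


@dataclass
class Species:
    id: str
    compartment: str
    role: str = "internal"  # internal | external
    initial_concentration: float = 0.0
    bounds: tuple | None = None  # (M_min, M_max) in mM
    name: str = ""

    def __post_init__(self):
        if self.role not in ("internal", "external"):
            raise ModelDefinitionError(f"species {self.id!r}: bad role {self.role!r}")
        if self.initial_concentration < 0:
            raise ModelDefinitionError(
                f"species {self.id!r}: negative initial concentration")
        if self.bounds is not None:
            lo, hi = self.bounds
            if lo < 0 or hi < 0 or lo > hi:
                raise ModelDefinitionError(
                    f"species {self.id!r}: invalid bounds {self.bounds}")


@dataclass
class Parameter:
    id: str
    value: float
    category: str = "OTHER"
    unit: str = ""
    reaction: str | None = None
    note: str = ""

    def __post_init__(self):
        if self.category not in PARAMETER_CATEGORIES:
            raise ModelDefinitionError(
                f"parameter {self.id!r}: unknown category {self.category!r}")
        if self.category in ("KM", "KA") and self.value <= 0:
            raise ModelDefinitionError(
                f"parameter {self.id!r}: {self.category} value must be positive")
        # VMAX may be exactly zero: knocked-out enzymes and disabled pathways
        if self.category == "VMAX" and self.value < 0:
            raise ModelDefinitionError(
                f"parameter {self.id!r}: VMAX value must be non-negative")
        if self.category == "N" and self.value < 1:
            raise ModelDefinitionError(
                f"parameter {self.id!r}: Hill-type exponent must be >= 1")


@dataclass
class PhosphoFunction:
    """Phenomenological link between plasma glucose and the fraction of an
    enzyme pool in the phosphorylated state."""
    id: str
    half_saturation: float  # mM glucose
    steepness: float
    direction: str = "falling"  # of the phosphorylated fraction with glucose
    glucose_species: str = "glc_ext"

    def __post_init__(self):
        if self.direction not in ("rising", "falling"):
            raise ModelDefinitionError(
                f"phospho function {self.id!r}: bad direction {self.direction!r}")
        if self.half_saturation <= 0 or self.steepness <= 0:
            raise ModelDefinitionError(
                f"phospho function {self.id!r}: parameters must be positive")


def phospho_fraction(fn: PhosphoFunction, glucose: float) -> float:
    """Evaluate γ(glc) ∈ [0,1]; monotone in glucose, 0.5 at half-saturation."""
    if glucose < 0:
        raise ValueError("glucose concentration must be non-negative")
    g = float(glucose) ** fn.steepness
    k = fn.half_saturation ** fn.steepness
    rising = g / (k + g) if g > 0 else 0.0
    return rising if fn.direction == "rising" else 1.0 - rising


@dataclass
class Reaction:
    id: str
    stoichiometry: dict  # species id -> signed coefficient
    rate_law: RateLaw
    vmax_ref: str | None = None
    charge_transfer: float = 0.0  # charges moved outward across the inner membrane per unit flux
    pathway: str = ""
    name: str = ""

    def __post_init__(self):
        if not any(c != 0 for c in self.stoichiometry.values()) \
                and self.charge_transfer == 0:
            raise ModelDefinitionError(
                f"reaction {self.id!r}: needs at least one nonzero "
                f"stoichiometric entry (or a charge transfer)")

    @property
    def vmax_params(self) -> list:
        if self.rate_law.vmax_params:
            return list(self.rate_law.vmax_params)
        return [self.vmax_ref] if self.vmax_ref else []


@dataclass
class MembranePotential:
    """Lumped proton-motive-force state (mV) with capacitance bookkeeping:
    d(dpsi)/dt = (1/C) · Σ_r charge_transfer_r · v_r."""
    capacitance: float  # µmol charge per g per mV
    initial_mv: float = 150.0

    def __post_init__(self):
        if self.capacitance <= 0:
            raise ModelDefinitionError("membrane capacitance must be positive")


@dataclass
class KineticModel:
    id: str
    compartments: dict = field(default_factory=dict)
    species: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    reactions: dict = field(default_factory=dict)
    phospho_functions: dict = field(default_factory=dict)
    membrane_potential: MembranePotential | None = None
    schema_version: str = "1"
    notes: str = ""

    # ------------------------------------------------------------------ views
    @property
    def internal_species(self) -> list:
        return [s.id for s in self.species.values() if s.role == "internal"]

    @property
    def external_species(self) -> list:
        return [s.id for s in self.species.values() if s.role == "external"]

    @property
    def reaction_ids(self) -> list:
        return list(self.reactions)

    def parameter_vector(self, ids=None) -> np.ndarray:
        ids = list(self.parameters) if ids is None else ids
        return np.array([self.parameters[p].value for p in ids], float)

    def referenced_externals(self) -> list:
        """External species appearing in at least one rate-law expression."""
        used = set()
        for r in self.reactions.values():
            used |= r.rate_law.symbols()
        return [s for s in self.external_species if s in used]

    # ------------------------------------------------------------ stoichiometry
    def stoichiometry_matrix(self, species_ids=None) -> np.ndarray:
        if species_ids is None:
            species_ids = self.internal_species
        idx = {s: i for i, s in enumerate(species_ids)}
        S = np.zeros((len(species_ids), len(self.reactions)))
        for j, r in enumerate(self.reactions.values()):
            for sid, coeff in r.stoichiometry.items():
                if sid in idx:
                    S[idx[sid], j] = coeff
        return S

    def volume_fractions(self, species_ids=None) -> np.ndarray:
        if species_ids is None:
            species_ids = self.internal_species
        return np.array([self.compartments[self.species[s].compartment].volume_fraction
                         for s in species_ids], float)

    # ------------------------------------------------------------------ editing
    def copy(self) -> "KineticModel":
        return _copy.deepcopy(self)

    def set_parameter(self, pid: str, value: float) -> None:
        if pid not in self.parameters:
            raise ModelDefinitionError(f"unknown parameter {pid!r}")
        p = self.parameters[pid]
        self.parameters[pid] = Parameter(p.id, value, p.category, p.unit,
                                         p.reaction, p.note)

    def scale_vmax(self, reaction_id: str, factor: float) -> None:
        """Multiply every maximal-activity parameter of a reaction."""
        r = self.reactions[reaction_id]
        if not r.vmax_params:
            raise ModelDefinitionError(
                f"reaction {reaction_id!r} has no maximal-activity parameter")
        for pid in r.vmax_params:
            self.set_parameter(pid, self.parameters[pid].value * factor)

    # ---------------------------------------------------------------- validation
    def validate(self) -> None:
        ids = list(self.species) + list(self.parameters)
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ModelDefinitionError(f"species/parameter id collision: {dupes}")
        for s in self.species.values():
            if s.compartment not in self.compartments:
                raise ModelDefinitionError(
                    f"species {s.id!r}: unknown compartment {s.compartment!r}")
        known = set(self.species) | set(self.parameters) | {POTENTIAL_SYMBOL, "t"}
        for r in self.reactions.values():
            for sid in r.stoichiometry:
                if sid not in self.species:
                    raise ModelDefinitionError(
                        f"reaction {r.id!r}: stoichiometry names unknown species {sid!r}")
            unresolved = r.rate_law.symbols() - known
            if unresolved:
                raise ModelDefinitionError(
                    f"reaction {r.id!r}: unresolved symbols {sorted(unresolved)}")
            if r.charge_transfer and self.membrane_potential is None:
                raise ModelDefinitionError(
                    f"reaction {r.id!r} moves charge but the model has no membrane potential")
        for pid in {p for r in self.reactions.values() for p in r.vmax_params}:
            if pid not in self.parameters:
                raise ModelDefinitionError(
                    f"maximal-activity parameter {pid!r} missing from parameter table")

    # -------------------------------------------------------------------- hashing
    def content_hash(self) -> str:
        from .io import model_to_dict  # local import to avoid a cycle
        text = json.dumps(model_to_dict(self), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def conserved_moieties(model: KineticModel) -> list:
    """Basis of the left null space of the internal stoichiometry matrix.

    Returns a list of dicts mapping species id → rational coefficient.  The
    volume-weighted dot product of each vector with the internal
    concentration vector is a conserved total along any trajectory.
    Computed exactly over the rationals.
    """
    internal = model.internal_species
    S = model.stoichiometry_matrix(internal)
    if S.size == 0:
        return []
    rows = [[sp.Rational(Fraction(x).limit_denominator(10**6)) for x in row]
            for row in S]
    basis = sp.Matrix(rows).T.nullspace()
    out = []
    for vec in basis:
        denom = sp.lcm([sp.fraction(v)[1] for v in vec])
        vec = vec * denom
        out.append({sid: vec[i] for i, sid in enumerate(internal) if vec[i] != 0})
    return out


def moiety_totals(model: KineticModel, moieties: list, state: np.ndarray) -> np.ndarray:
    """Volume-weighted conserved totals for a state (or trajectory matrix)
    over the internal species."""
    internal = model.internal_species
    vols = model.volume_fractions(internal)
    idx = {s: i for i, s in enumerate(internal)}
    totals = []
    for m in moieties:
        w = np.zeros(len(internal))
        for sid, coeff in m.items():
            w[idx[sid]] = float(coeff) * vols[idx[sid]]
        totals.append(np.asarray(state) @ w)
    return np.array(totals)
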