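"""The 24 metabolic liver functions scored by sensitivity and control
analysis.

Each function maps a trajectory (or steady state) to a scalar time series
(or scalar): exchange fluxes with the plasma, storage pools, biosynthetic
rates, the mitochondrial membrane potential, and the three redox/energy
ratios.  Indices 1-24 are stable across the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SteadyState, Trajectory


class VariableError(KeyError):
    pass


def evaluate_variable(obj, spec: str):
    """Evaluate a variable spec on a Trajectory or SteadyState.

    Specs: ``conc:<species>``, ``flux:<reaction>``, ``uptake:<external>``,
    ``release:<external>``, ``ratio:<a>/<b>``, ``potential``.
    """
    kind, _, arg = spec.partition(":")
    try:
        if kind == "conc":
            return obj.conc(arg)
        if kind == "flux":
            return obj.flux(arg)
        if kind == "ratio":
            a, b = arg.split("/")
            if isinstance(obj, SteadyState):
                return obj.conc(a) / obj.conc(b)
            return obj.conc(a) / obj.conc(b)
        if kind == "potential":
            return obj.potential
        if kind in ("uptake", "release"):
            sign = 1.0 if kind == "uptake" else -1.0
            if isinstance(obj, SteadyState):
                # net uptake = - sum of stoichiometric production of the
                # external species; reconstruct from reaction fluxes
                raise VariableError(
                    "uptake/release specs need a Trajectory; use flux: on the "
                    "transport reaction for steady states")
            return sign * obj.exchange_flux(arg)
    except (ValueError, KeyError) as exc:
        raise VariableError(f"cannot evaluate variable {spec!r}: {exc}") from exc
    raise VariableError(f"unknown variable spec {spec!r}")


@dataclass(frozen=True)
class MetabolicFunction:
    index: int
    name: str
    spec: str

    def __call__(self, traj):
        return evaluate_variable(traj, self.spec)


class MetabolicFunctionRegistry:
    """Ordered registry of the 24 metabolic functions."""

    def __init__(self, functions):
        self.functions = list(functions)
        seen = [f.index for f in self.functions]
        if seen != list(range(1, len(seen) + 1)):
            raise ValueError("function indices must be 1..N in order")

    def __len__(self):
        return len(self.functions)

    def __iter__(self):
        return iter(self.functions)

    def __getitem__(self, index: int) -> MetabolicFunction:
        return self.functions[index - 1]

    @property
    def names(self):
        return [f.name for f in self.functions]

    def evaluate(self, traj) -> dict:
        return {f.index: np.asarray(f(traj), float) for f in self.functions}


def demo_registry() -> MetabolicFunctionRegistry:
    """The canonical 24-function registry of the demo hepatocyte model:
    21 plasma exchange / storage / synthesis readouts plus membrane
    potential and the cytosolic redox and energy ratios."""
    entries = [
        (1, "glucose exchange rate", "uptake:glc_ext"),
        (2, "lactate exchange rate", "uptake:lac_ext"),
        (3, "pyruvate exchange rate", "uptake:pyr_ext"),
        (4, "glycerol exchange rate", "uptake:glyc_ext"),
        (5, "fatty acid uptake rate", "uptake:ffa_ext"),
        (6, "acetoacetate secretion rate", "release:acac_ext"),
        (7, "beta-hydroxybutyrate secretion rate", "release:bhb_ext"),
        (8, "oxygen uptake rate", "uptake:o2_ext"),
        (9, "ammonia uptake rate", "uptake:nh4_ext"),
        (10, "glutamine exchange rate", "uptake:gln_ext"),
        (11, "glutamate exchange rate", "uptake:glu_ext"),
        (12, "serine exchange rate", "uptake:ser_ext"),
        (13, "alanine exchange rate", "uptake:ala_ext"),
        (14, "urea secretion rate", "flux:UREA_EXP"),
        (15, "acetate exchange rate", "uptake:ac_ext"),
        (16, "VLDL secretion rate", "flux:VLDL_EXP"),
        (17, "glycogen storage", "conc:glycogen"),
        (18, "cellular triglyceride concentration", "conc:tg"),
        (19, "cholesterol synthesis rate", "flux:CHOLSYN"),
        (20, "fatty acid synthesis rate", "flux:FAS"),
        (21, "mitochondrial membrane potential", "potential"),
        (22, "ATP/ADP ratio", "ratio:atp_c/adp_c"),
        (23, "NAD/NADH ratio (cytosolic)", "ratio:nad_c/nadh_c"),
        (24, "NADP/NADPH ratio (cytosolic)", "ratio:nadp_c/nadph_c"),
    ]
    return MetabolicFunctionRegistry(
        MetabolicFunction(i, n, s) for i, n, s in entries)
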