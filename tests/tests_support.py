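"""Small analytic models shared across test modules."""

from hepatodyn import ratelaws as rl
from hepatodyn.model import (Compartment, KineticModel, Parameter, Reaction,
                             Species)


def linear_source_sink(k_in=2.0, k_out=4.0):
    """Constant source + first-order sink: S* = k_in/k_out exactly, so the
    response coefficients have closed forms."""
    m = KineticModel(id="lin")
    m.compartments["e"] = Compartment("e", 1.0)
    m.compartments["c"] = Compartment("c", 1.0)
    m.species["X_ext"] = Species("X_ext", "e", "external", 1.0)
    m.species["S"] = Species("S", "c", "internal", 0.5)
    m.parameters["k_in"] = Parameter("k_in", k_in)
    m.parameters["k_out"] = Parameter("k_out", k_out)
    m.reactions["IN"] = Reaction("IN", {"X_ext": -1, "S": 1},
                                 rl.mass_action("k_in", {"X_ext": 1}))
    m.reactions["OUT"] = Reaction("OUT", {"S": -1, "X_ext": 1},
                                  rl.mass_action("k_out", {"S": 1}))
    m.validate()
    return m
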