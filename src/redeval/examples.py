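"""Built-in example networks.

The four-compound linear pathway used throughout the documentation:
an inflow feeds compound 1, which is converted to compound 4 along a main
route (via compound 2) and a slow side route (via compound 3); compound 4
drains out of the system.  All complexes are single compounds, kinetics are
mass action, and the important set is M_I = {1, 4}, leaving the two
intermediates as reduction candidates.
"""

from __future__ import annotations

from importlib import resources

from .io import read_network
from .network import NetworkModel, ParameterSet

__all__ = ["build_simple_example", "simple_example_path"]


def simple_example_path():
    """Path to the bundled definition file of the four-compound example."""
    return resources.files("redeval.data") / "simple_example.toml"


def build_simple_example() -> tuple[NetworkModel, ParameterSet]:
    """The four-compound example network with its reference parameter set.

    Reference kinetic constants are (k1..k6) = (0.44, 0.03, 0.55, 0.44,
    0.42, 0.33) — k5 the inflow, k6 the first-order outflow — and initial
    values (0.4, 0.0, 0.5, 0.4).
    """
    with resources.as_file(simple_example_path()) as p:
        return read_network(p)
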