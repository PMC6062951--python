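"""Random linear mass-action test networks.

The generator emulates the structure shared by the analyses this package
targets: single-compound complexes, a constant inflow into a source
compound, a first-order outflow from a sink compound, and parallel
conversion routes between them.  A network consists of a main chain
``source -> ... -> sink`` plus ``n_branches`` extra compounds each bridging
the source and sink directly, and M_I = {source, sink}.  All consumption
rates are positive, so the induced linear ODE system is asymptotically
stable and a steady state always exists.
"""

from __future__ import annotations

import numpy as np

from .network import BoundaryFlux, NetworkModel, ParameterSet

__all__ = ["generate_fixture_network"]


def generate_fixture_network(n_compounds: int, n_branches: int = 1,
                             seed: int = 0) -> tuple[NetworkModel, ParameterSet]:
    """Random linear network with ``n_compounds`` total compounds, of which
    ``n_branches`` sit on direct source->branch->sink side routes and the
    rest form the main chain.  Rate constants are drawn uniformly from
    [0.1, 1.0), initial values from [0.1, 1.0); same seed, same network.
    """
    if n_compounds < 2:
        raise ValueError("need at least a source and a sink compound")
    n_chain = n_compounds - n_branches
    if n_chain < 2:
        raise ValueError("too many branches for the compound count")
    rng = np.random.default_rng(seed)
    names = tuple(f"x{i+1}" for i in range(n_compounds))
    source, sink = 0, n_chain - 1
    Z = np.eye(n_compounds, dtype=int)  # complexes are the compounds
    edges: list[tuple[int, int]] = []
    edges += [(i, i + 1) for i in range(n_chain - 1)]
    for b in range(n_branches):
        bi = n_chain + b
        edges += [(source, bi), (bi, sink)]
    B = np.zeros((n_compounds, len(edges)), dtype=int)
    for j, (s, p) in enumerate(edges):
        B[s, j] = -1
        B[p, j] = 1
    n_r = len(edges)
    model = NetworkModel(
        compound_names=names,
        complex_names=names,
        Z=Z,
        B=B,
        reaction_names=tuple(f"k{j+1}" for j in range(n_r)),
        modifiers=("mass_action",) * n_r,
        boundary=(
            BoundaryFlux(source, "inflow", f"k{n_r+1}"),
            BoundaryFlux(sink, "outflow", f"k{n_r+2}"),
        ),
        important=(source, sink),
        name=f"fixture-{n_compounds}c-{n_branches}b-{seed}",
    )
    params = ParameterSet(
        kinetic=rng.uniform(0.1, 1.0, n_r),
        boundary=rng.uniform(0.1, 1.0, 2),
        initial=rng.uniform(0.1, 1.0, n_compounds),
    )
    return model, params


def linear_system(model: NetworkModel, params: ParameterSet) -> tuple[np.ndarray, np.ndarray]:
    """(A, b) with dx/dt = A x + b for a network whose complexes are all
    single compounds with unit stoichiometry and mass-action kinetics.
    Used as the closed-form (matrix exponential) oracle for such models.
    """
    if not np.array_equal(np.sort(model.Z.sum(axis=0)), np.ones(model.n_complexes)) \
            or np.any(model.Z > 1):
        raise ValueError("model is not single-compound mass action")
    comp_of = np.argmax(model.Z, axis=0)  # compound behind each complex
    n = model.n_compounds
    A = np.zeros((n, n))
    b = np.zeros(n)
    sub = model.substrate_index
    prod = np.argmax(model.B, axis=0)
    for j in range(model.n_reactions):
        s, p = comp_of[sub[j]], comp_of[prod[j]]
        A[s, s] -= params.kinetic[j]
        A[p, s] += params.kinetic[j]
    for bf, val in zip(model.boundary, params.boundary):
        c = comp_of[bf.complex_index]
        if bf.kind == "inflow":
            b[c] += val
        else:
            A[c, c] -= val
    return A, b
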