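"""Core representation of biochemical reaction networks in the complex formalism.

A network is described by a complex-stoichiometry matrix ``Z`` (compounds x
complexes, non-negative integers), a linkage matrix ``B`` (complexes x
reactions, one -1 for the substrate complex and one +1 for the product
complex per column), per-reaction kinetics of the generalised mass-action
form

    v_j(x) = k_j * d_j(x) * prod_i x_i ** Z[i, substrate_j]

and boundary fluxes (constant inflows and first-order outflows attached to
complexes).  The resulting dynamics are

    dx/dt = Z B v(x) + Z v_b(x).

The power-product form of the flux is the exponential-of-log expression on
the positive orthant, extended continuously to the boundary: a substrate
compound at concentration zero yields a zero flux instead of log(0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "NetworkModel",
    "ParameterSet",
    "Trajectory",
    "BoundaryFlux",
    "NetworkStructureError",
    "DomainError",
    "SimulationError",
    "SteadyStateNotReached",
    "evaluate_fluxes",
    "rhs",
    "simulate",
    "steady_state",
    "resolve_horizon",
    "KINETIC_MODIFIERS",
]


class NetworkStructureError(ValueError):
    """The structural description of a network is inconsistent."""


class DomainError(ValueError):
    """A numeric input lies outside the model's domain (e.g. negative state)."""


class SimulationError(RuntimeError):
    """ODE integration failed (blow-up or step-size collapse)."""

    def __init__(self, message: str, label: object = None):
        super().__init__(message)
        self.label = label


class SteadyStateNotReached(RuntimeError):
    """The trajectory did not settle below tolerance within the horizon cap."""


#: Registry of kinetic modifier functions d_j(x).  Only constant-one
#: (pure mass action) is shipped; users may register additional state
#: dependencies under new identifiers.
KINETIC_MODIFIERS: dict[str, Callable[[np.ndarray], float]] = {
    "mass_action": lambda x: 1.0,
}


@dataclass(frozen=True)
class BoundaryFlux:
    """A boundary term attached to one complex.

    ``inflow`` contributes ``+b`` to the complex; ``outflow`` contributes
    ``-b * w_c(x)`` where ``w_c`` is the complex concentration (the same
    power product used by internal fluxes), i.e. a first-order drain for
    single-compound complexes.
    """

    complex_index: int
    kind: str  # "inflow" | "outflow"
    parameter: str

    def __post_init__(self):
        if self.kind not in ("inflow", "outflow"):
            raise NetworkStructureError(f"unknown boundary kind {self.kind!r}")


@dataclass(frozen=True)
class NetworkModel:
    compound_names: tuple[str, ...]
    complex_names: tuple[str, ...]
    Z: np.ndarray  # (n_compounds, n_complexes) non-negative integers
    B: np.ndarray  # (n_complexes, n_reactions) columns with one -1, one +1
    reaction_names: tuple[str, ...]  # doubles as kinetic-constant names
    modifiers: tuple[str, ...]  # per reaction, key into KINETIC_MODIFIERS
    boundary: tuple[BoundaryFlux, ...]
    important: tuple[int, ...]  # compound indices of M_I
    name: str = "network"

    def __post_init__(self):
        Z = np.asarray(self.Z)
        B = np.asarray(self.B)
        object.__setattr__(self, "Z", Z)
        object.__setattr__(self, "B", B)
        n_cpd, n_cplx = Z.shape
        if len(self.compound_names) != n_cpd or len(self.complex_names) != n_cplx:
            raise NetworkStructureError("label counts do not match Z")
        if np.any(Z < 0) or np.any(Z != np.round(Z)):
            raise NetworkStructureError("Z must contain non-negative integers")
        if np.any(~Z.any(axis=0)):
            raise NetworkStructureError("Z has an all-zero complex column")
        if B.shape[0] != n_cplx or B.shape[1] != len(self.reaction_names):
            raise NetworkStructureError("B shape does not match complexes/reactions")
        for j in range(B.shape[1]):
            col = B[:, j]
            if np.sum(col == -1) != 1 or np.sum(col == 1) != 1 or np.sum(col != 0) != 2:
                raise NetworkStructureError(
                    f"column {j} of B must have exactly one -1 and one +1"
                )
        if len(self.modifiers) != B.shape[1]:
            raise NetworkStructureError("one kinetic modifier required per reaction")
        for m in self.modifiers:
            if m not in KINETIC_MODIFIERS:
                raise NetworkStructureError(f"unknown kinetic modifier {m!r}")
        if not self.important:
            raise NetworkStructureError("important set M_I must be non-empty")
        if any(i < 0 or i >= n_cpd for i in self.important):
            raise NetworkStructureError("important set out of compound range")
        for bf in self.boundary:
            if bf.complex_index < 0 or bf.complex_index >= n_cplx:
                raise NetworkStructureError("boundary complex index out of range")

    # -- derived structure -------------------------------------------------

    @property
    def n_compounds(self) -> int:
        return self.Z.shape[0]

    @property
    def n_complexes(self) -> int:
        return self.Z.shape[1]

    @property
    def n_reactions(self) -> int:
        return self.B.shape[1]

    @property
    def substrate_index(self) -> np.ndarray:
        """Per reaction, the row of the -1 entry in its B column."""
        return np.argmin(self.B, axis=0)

    @property
    def substrate_matrix(self) -> np.ndarray:
        """Z_S: column j is the substrate complex stoichiometry of reaction j."""
        return self.Z[:, self.substrate_index]

    @property
    def boundary_parameter_names(self) -> tuple[str, ...]:
        return tuple(bf.parameter for bf in self.boundary)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        """Names of all sampled parameters: kinetic constants then boundary."""
        return self.reaction_names + self.boundary_parameter_names

    # -- evaluation --------------------------------------------------------

    def complex_concentrations(self, state: np.ndarray) -> np.ndarray:
        """w_c(x) = prod_i x_i^Z[i,c]; the power product handles zeros (0^0 = 1)."""
        return np.prod(state[:, None] ** self.Z, axis=0)

    def internal_fluxes(self, params: "ParameterSet", state: np.ndarray,
                        w: np.ndarray | None = None) -> np.ndarray:
        if w is None:
            w = self.complex_concentrations(state)
        if all(m == "mass_action" for m in self.modifiers):
            return params.kinetic * w[self.substrate_index]
        d = np.array([KINETIC_MODIFIERS[m](state) for m in self.modifiers])
        return params.kinetic * d * w[self.substrate_index]

    def boundary_fluxes(self, params: "ParameterSet", state: np.ndarray,
                        w: np.ndarray | None = None) -> np.ndarray:
        if w is None:
            w = self.complex_concentrations(state)
        vb = np.zeros(self.n_complexes)
        for b, bf in zip(params.boundary, self.boundary):
            if bf.kind == "inflow":
                vb[bf.complex_index] += b
            else:
                vb[bf.complex_index] -= b * w[bf.complex_index]
        return vb

    def rhs(self, params: "ParameterSet", state: np.ndarray) -> np.ndarray:
        state = _check_state(self, state)
        w = self.complex_concentrations(state)
        v = self.internal_fluxes(params, state, w)
        vb = self.boundary_fluxes(params, state, w)
        return self.Z @ (self.B @ v + vb)

    def initial_state(self, params: "ParameterSet") -> np.ndarray:
        return params.initial.copy()


@dataclass(frozen=True)
class ParameterSet:
    """One realization of all kinetic constants, boundary parameters and
    initial values for a given model."""

    kinetic: np.ndarray  # one non-negative constant per reaction
    boundary: np.ndarray  # one non-negative value per boundary flux
    initial: np.ndarray  # one non-negative concentration per compound

    def __post_init__(self):
        for name in ("kinetic", "boundary", "initial"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr < 0):
                raise DomainError(f"{name} values must be non-negative")
            object.__setattr__(self, name, arr)

    def validate_for(self, model: NetworkModel) -> None:
        if len(self.kinetic) != model.n_reactions:
            raise NetworkStructureError("kinetic constant count mismatch")
        if len(self.boundary) != len(model.boundary):
            raise NetworkStructureError("boundary parameter count mismatch")
        if len(self.initial) != model.n_compounds:
            raise NetworkStructureError("initial value count mismatch")

    @property
    def sampled(self) -> np.ndarray:
        """Concatenated (kinetic, boundary) vector: the parameters subject
        to uncertainty sampling.  Initial values are not sampled."""
        return np.concatenate([self.kinetic, self.boundary])

    def with_sampled(self, values: np.ndarray) -> "ParameterSet":
        nk = len(self.kinetic)
        return replace(self, kinetic=values[:nk], boundary=values[nk:])


@dataclass(frozen=True)
class Trajectory:
    """Concentrations of all compounds reported on a shared time grid."""

    t: np.ndarray  # strictly increasing, t[0] = 0, t[-1] = T
    x: np.ndarray  # (len(t), n_compounds)
    compound_names: tuple[str, ...] = ()

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if x.shape[0] != len(t):
            raise ValueError("state rows must match time grid")

    @property
    def horizon(self) -> float:
        return float(self.t[-1])

    def restrict(self, compounds: Sequence[int]) -> np.ndarray:
        return self.x[:, list(compounds)]


def _check_state(model: NetworkModel, state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (model.n_compounds,):
        raise NetworkStructureError(
            f"state has shape {state.shape}, expected ({model.n_compounds},)"
        )
    if np.any(state < 0):
        raise DomainError("negative concentration in state vector")
    return state


# -- module-level operation surface ---------------------------------------


def evaluate_fluxes(model: NetworkModel, params: ParameterSet,
                    state: np.ndarray) -> np.ndarray:
    """Internal flux vector v(x) of the generalised mass-action kinetics."""
    params.validate_for(model)
    state = _check_state(model, state)
    return model.internal_fluxes(params, state)


def rhs(model: NetworkModel, params: ParameterSet, state: np.ndarray) -> np.ndarray:
    """Time derivative Z B v(x) + Z v_b(x)."""
    params.validate_for(model)
    return model.rhs(params, state)


def simulate(model, params: ParameterSet, horizon: float, n_grid: int = 1000,
             rtol: float = 1e-8, atol: float = 1e-10,
             label: object = None) -> Trajectory:
    """Integrate the model from its initial values and report the solution
    on a uniform grid of ``n_grid`` points on [0, horizon].

    ``model`` may be a :class:`NetworkModel` or any object exposing
    ``rhs(params, state)`` and ``initial_state(params)`` (reduced models do).
    Uses an adaptive stiffness-switching solver (LSODA).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if n_grid < 2:
        raise ValueError("n_grid must be at least 2")
    x0 = model.initial_state(params)
    t_eval = np.linspace(0.0, horizon, n_grid)
    sol = solve_ivp(
        lambda t, x: model.rhs(params, np.maximum(x, 0.0)),
        (0.0, horizon), x0, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise SimulationError(f"integration failed: {sol.message}", label=label)
    x = sol.y.T.copy()
    x[0] = x0  # report the initial values exactly
    names = getattr(model, "compound_names", ())
    traj = Trajectory(t_eval, x, tuple(names))
    if hasattr(model, "postprocess"):  # algebraic states of reduced models
        traj = model.postprocess(params, traj)
    return traj


def steady_state(model, params: ParameterSet, tol_factor: float = 1e-8,
                 window: float = 10.0, cap: float = 1e6,
                 rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Integrate in doubling windows until the derivative max-norm falls
    below ``tol_factor * (1 + max state)``; the model is assumed
    asymptotically stable.  Raises :class:`SteadyStateNotReached` at the cap.
    """
    x = model.initial_state(params)
    elapsed = 0.0
    while True:
        tol = tol_factor * (1.0 + float(np.max(np.abs(x), initial=0.0)))
        if float(np.max(np.abs(model.rhs(params, x)))) < tol:
            return x
        if elapsed >= cap:
            raise SteadyStateNotReached(
                f"no steady state within t = {cap:g} (|rhs| still above {tol:g})"
            )
        sol = solve_ivp(
            lambda t, y: model.rhs(params, np.maximum(y, 0.0)),
            (0.0, window), x, method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise SimulationError(f"integration failed: {sol.message}")
        x = np.maximum(sol.y[:, -1], 0.0)
        elapsed += window
        window *= 2.0


def resolve_horizon(model, params: ParameterSet, rel: float = 0.01,
                    xss: np.ndarray | None = None, n_probe: int = 1024,
                    **ss_kwargs) -> float:
    """Shortest time at which the trajectory is within ``rel`` (relative,
    per compound) of the steady state.  Used as the default evaluation
    horizon T: the error integral should cover the whole transient, but a
    needlessly long T dilutes every time-averaged error toward the bare
    steady-state difference and washes out the dynamics being compared.
    """
    if xss is None:
        xss = steady_state(model, params, **ss_kwargs)
    scale = np.abs(xss) + 1e-12
    window = 10.0
    while window <= 1e7:
        traj = simulate(model, params, window, n_grid=n_probe)
        dev = np.max(np.abs(traj.x - xss) / scale, axis=1)
        hit = np.nonzero(dev <= rel)[0]
        # require the criterion to hold from the hit onwards (no re-excursion)
        for i in hit:
            if np.all(dev[i:] <= rel):
                return float(traj.t[i]) if traj.t[i] > 0 else float(traj.t[1])
        window *= 2.0
    raise SteadyStateNotReached("could not bracket the 1% settling time")
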