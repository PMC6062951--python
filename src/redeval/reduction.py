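"""Model reduction by steady-state elimination of complexes.

A complex that contains no important compound may be *reduced*: its
concentration is tied to the steady-state balance of the full model rather
than evolving dynamically.  Concretely, the compound behind a reduced
complex is placed in quasi-steady state — its net production is set to zero
and its concentration becomes the algebraic function of the remaining
states that solves that balance (for the linear mass-action networks of the
examples this is the Schur complement / Kron reduction of the complex
graph).  At the full model's steady state the eliminated concentrations
coincide with their full steady-state values, which is the sense in which
the reduction fixes them at the steady state of the full model.

Reductions commute, so the 2^c subsets of the c eligible complexes
enumerate all possible reduced models; a greedy one-complex-at-a-time
baseline is provided for comparison.

Supported reductions: each reduced complex must consist of a single
compound with unit stoichiometry that appears in no other complex (the
structure of the analyses this package targets).  Anything else would
require additional semantics that are not defined here and is rejected
explicitly.  Kinetic modifiers d_j(x) of reactions touching reduced
compounds must not depend on those compounds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .metrics import ErrorConfig, symmetric_error
from .network import (
    KINETIC_MODIFIERS,
    NetworkModel,
    ParameterSet,
    Trajectory,
    simulate,
    steady_state,
)

__all__ = [
    "ReductionSpec",
    "ReducedModel",
    "ReductionError",
    "UnsupportedReductionError",
    "eligible_complexes",
    "enumerate_reductions",
    "reduce_model",
    "greedy_reduce",
]

#: Enumeration refuses beyond this many eligible complexes (2^16 subsets);
#: larger problems should go through two-stage prefiltering.
ENUMERATION_CAP = 16


class ReductionError(ValueError):
    """A reduction specification is invalid for the given model."""


class UnsupportedReductionError(ReductionError):
    """The requested reduction falls outside the supported structure."""


@dataclass(frozen=True)
class ReductionSpec:
    """A subset of eligible complexes to eliminate; empty means the full model."""

    reduced_complexes: tuple[int, ...]
    eligible: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "reduced_complexes",
                           tuple(sorted(self.reduced_complexes)))
        if not set(self.reduced_complexes) <= set(self.eligible):
            raise ReductionError("reduced complexes must lie in the eligible set")

    @property
    def size(self) -> int:
        return len(self.reduced_complexes)

    @property
    def bitmask(self) -> str:
        """One character per eligible complex, '1' where reduced ('00..0'
        is the full model).  Used as the reduction key in all outputs."""
        red = set(self.reduced_complexes)
        return "".join("1" if c in red else "0" for c in self.eligible)

    @classmethod
    def from_bitmask(cls, mask: str, eligible: tuple[int, ...]) -> "ReductionSpec":
        if len(mask) != len(eligible):
            raise ReductionError("bitmask length must equal the eligible count")
        return cls(tuple(c for ch, c in zip(mask, eligible) if ch == "1"),
                   tuple(eligible))


def eligible_complexes(model: NetworkModel) -> list[int]:
    """Complexes with zero stoichiometry for every important compound,
    in ascending index order."""
    imp = list(model.important)
    return [c for c in range(model.n_complexes)
            if not np.any(model.Z[imp, c])]


def enumerate_reductions(eligible: list[int] | tuple[int, ...],
                         cap: int = ENUMERATION_CAP) -> list[ReductionSpec]:
    """All 2^c subsets of the eligible complexes, ordered by size then
    lexicographically; the first entry is the full (unreduced) model."""
    eligible = tuple(eligible)
    if len(eligible) > cap:
        raise ReductionError(
            f"{len(eligible)} eligible complexes exceed the enumeration cap "
            f"({cap}); use two-stage prefiltering to shrink the candidate set"
        )
    return [ReductionSpec(combo, eligible)
            for size in range(len(eligible) + 1)
            for combo in itertools.combinations(eligible, size)]


@dataclass(frozen=True)
class ReducedModel:
    """A steady-state-eliminated model: drop-in replacement for
    NetworkModel in :func:`~redeval.network.simulate`.

    ``clamp_values`` records the eliminated complex concentrations at the
    full model's steady state (the values the algebraic solution converges
    to); ``reduced_compounds`` are the compounds behind the eliminated
    complexes, whose trajectories follow the balance relation instead of an
    ODE.
    """

    base: NetworkModel
    spec: ReductionSpec
    clamp_values: np.ndarray
    reduced_compounds: tuple[int, ...]
    # precomputed structure for the linear-in-x_R balance solve
    _j_red: np.ndarray = field(repr=False, default=None)
    _C_red: np.ndarray = field(repr=False, default=None)  # ZB rows of reduced cpds
    _P: np.ndarray = field(repr=False, default=None)  # one-hot substrate positions
    _out_diag_idx: tuple = field(repr=False, default=())

    @property
    def compound_names(self) -> tuple[str, ...]:
        return self.base.compound_names

    # -- algebraic elimination --------------------------------------------

    def _balance_matrix(self, params: ParameterSet, state: np.ndarray) -> np.ndarray:
        """M with rhs_R(x) = M x_R + f0(x_F): Jacobian of the reduced
        compounds' net production w.r.t. their own concentrations."""
        kd = params.kinetic[self._j_red]
        for pos, j in enumerate(self._j_red):
            mod = self.base.modifiers[j]
            if mod != "mass_action":
                kd[pos] *= KINETIC_MODIFIERS[mod](state)
        M = (self._C_red[:, self._j_red] * kd) @ self._P
        for i, b_idx in self._out_diag_idx:
            M[i, i] -= params.boundary[b_idx]
        return M

    def solve_reduced(self, params: ParameterSet, state: np.ndarray) -> np.ndarray:
        """Concentrations of the reduced compounds balancing production and
        consumption, given the free entries of ``state``."""
        x = np.asarray(state, dtype=float).copy()
        Rc = list(self.reduced_compounds)
        if not Rc:
            return np.empty(0)
        x[Rc] = 0.0
        f0 = self.base.rhs(params, np.maximum(x, 0.0))[Rc]
        M = self._balance_matrix(params, x)
        try:
            return np.linalg.solve(M, -f0)
        except np.linalg.LinAlgError as exc:
            raise ReductionError(
                "singular balance system: a reduced compound has no "
                "consumption route"
            ) from exc

    def rhs(self, params: ParameterSet, state: np.ndarray) -> np.ndarray:
        Rc = list(self.reduced_compounds)
        x = np.asarray(state, dtype=float).copy()
        if Rc:
            x[Rc] = np.maximum(self.solve_reduced(params, x), 0.0)
        dx = self.base.rhs(params, x)
        dx[Rc] = 0.0
        return dx

    def initial_state(self, params: ParameterSet) -> np.ndarray:
        x0 = params.initial.copy()
        Rc = list(self.reduced_compounds)
        if Rc:
            x0[Rc] = np.maximum(self.solve_reduced(params, x0), 0.0)
        return x0

    def postprocess(self, params: ParameterSet, traj: Trajectory) -> Trajectory:
        """Replace the reduced compounds' stored states with the algebraic
        balance solution at every grid point."""
        if not self.reduced_compounds:
            return traj
        Rc = list(self.reduced_compounds)
        x = traj.x.copy()
        for row in x:
            row[Rc] = np.maximum(self.solve_reduced(params, row), 0.0)
        return Trajectory(traj.t, x, traj.compound_names)


def reduce_model(model: NetworkModel, params: ParameterSet, spec: ReductionSpec,
                 full_steady_state: np.ndarray) -> ReducedModel:
    """Build the reduced model for ``spec``.

    ``full_steady_state`` must be the converged steady state of the *full*
    model under the *same* parameter set; the eliminated concentrations
    coincide with it there, which is verified on construction.
    """
    elig = set(eligible_complexes(model))
    if not set(spec.reduced_complexes) <= elig:
        raise ReductionError("spec reduces a complex containing an important compound")
    xss = np.asarray(full_steady_state, dtype=float)
    reduced = list(spec.reduced_complexes)
    # supported structure: single-compound, unit-stoichiometry, exclusive
    reduced_compounds = []
    for c in reduced:
        members = np.nonzero(model.Z[:, c])[0]
        if len(members) != 1 or model.Z[members[0], c] != 1:
            raise UnsupportedReductionError(
                f"complex {model.complex_names[c]!r} is not a single compound "
                "with unit stoichiometry; its elimination is not defined here"
            )
        i = int(members[0])
        other = np.delete(np.arange(model.n_complexes), c)
        if np.any(model.Z[i, other]):
            raise UnsupportedReductionError(
                f"compound {model.compound_names[i]!r} appears in another "
                "complex; eliminating it is not defined here"
            )
        reduced_compounds.append(i)
    Rc = tuple(reduced_compounds)
    ZB = model.Z @ model.B
    sub = model.substrate_index
    pos_of_complex = {c: p for p, c in enumerate(reduced)}
    j_red = np.array([j for j in range(model.n_reactions) if sub[j] in pos_of_complex],
                     dtype=int)
    P = np.zeros((len(j_red), len(reduced)))
    for row, j in enumerate(j_red):
        P[row, pos_of_complex[sub[j]]] = 1.0
    out_diag = tuple(
        (pos_of_complex[bf.complex_index], b_idx)
        for b_idx, bf in enumerate(model.boundary)
        if bf.kind == "outflow" and bf.complex_index in pos_of_complex
    )
    rm = ReducedModel(
        base=model, spec=spec,
        clamp_values=model.complex_concentrations(xss)[reduced],
        reduced_compounds=Rc,
        _j_red=j_red, _C_red=ZB[list(Rc), :] if Rc else np.empty((0, model.n_reactions)),
        _P=P, _out_diag_idx=out_diag,
    )
    if Rc:
        # consistency: at the full steady state the balance solution must
        # reproduce the eliminated compounds' steady-state concentrations
        x_check = rm.solve_reduced(params, xss)
        scale = 1.0 + np.abs(xss[list(Rc)])
        if np.any(np.abs(x_check - xss[list(Rc)]) > 1e-6 * scale):
            raise ReductionError(
                "balance solution at the full steady state does not match "
                "the steady-state concentrations; was the steady state converged?"
            )
    return rm


def greedy_reduce(model: NetworkModel, params: ParameterSet,
                  error_threshold: float, horizon: float,
                  n_grid: int = 1000, xss: np.ndarray | None = None) -> list[int]:
    """One-complex-at-a-time baseline: repeatedly reduce the single
    eligible complex whose addition gives the smallest symmetric error to
    the full model, stopping before the first addition whose best error
    exceeds the threshold.  Ties go to the lowest complex index.  Returns
    the reduced complexes in reduction order.
    """
    if error_threshold < 0:
        raise ValueError("error threshold must be non-negative")
    elig = tuple(eligible_complexes(model))
    if xss is None:
        xss = steady_state(model, params)
    full_traj = simulate(model, params, horizon, n_grid)
    cfg = ErrorConfig(horizon=horizon)
    chosen: list[int] = []
    remaining = list(elig)
    while remaining:
        best_c, best_err = None, np.inf
        for c in remaining:  # ascending order gives the tie-break for free
            spec = ReductionSpec(tuple(chosen) + (c,), elig)
            red = reduce_model(model, params, spec, xss)
            traj = simulate(red, params, horizon, n_grid)
            err = symmetric_error(traj, full_traj, model.important, cfg)
            if err < best_err:
                best_c, best_err = c, err
        if best_err > error_threshold:
            break
        chosen.append(best_c)
        remaining.remove(best_c)
    return chosen
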