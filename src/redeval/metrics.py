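"""Trajectory error measures and the all-pairs dissimilarity matrix.

The one-sided error integral between two models is the time-averaged
relative deviation over the important compounds,

    I_T(x_r, x_f) = 1/(T n(M_I)) * sum_{i in M_I} int_0^T |1 - x_ir/x_if| dt,

and the clustering dissimilarity is its symmetrisation
E_T = (I_T(a,b) + I_T(b,a)) / 2.  Integrals are evaluated by composite
trapezoidal quadrature on the shared uniform trajectory grid; denominators
are floored at a small epsilon so that a zero reference concentration (which
can occur at t = 0) does not produce an infinite integrand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .network import Trajectory

__all__ = [
    "ErrorConfig",
    "DissimilarityMatrix",
    "GridMismatchError",
    "error_integral",
    "symmetric_error",
    "dissimilarity_matrix",
]

logger = logging.getLogger(__name__)


class GridMismatchError(ValueError):
    """Trajectories to be compared do not share a time grid."""


@dataclass(frozen=True)
class ErrorConfig:
    """Evaluation interval and quadrature settings for the error measures."""

    horizon: float | None = None  # T; None means take it from the trajectories
    epsilon: float = 1e-12  # floor for the denominator trajectory

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _common_grid(a: Trajectory, b: Trajectory) -> np.ndarray:
    if a.t.shape != b.t.shape or not np.allclose(a.t, b.t, rtol=0, atol=1e-12):
        raise GridMismatchError("trajectories are not on the same time grid")
    return a.t


def error_integral(reduced: Trajectory, reference: Trajectory,
                   important_set: Sequence[int],
                   config: ErrorConfig = ErrorConfig()) -> float:
    """One-sided error I_T of ``reduced`` relative to ``reference``."""
    t = _common_grid(reduced, reference)
    if config.horizon is not None and not np.isclose(t[-1], config.horizon):
        raise GridMismatchError("trajectory horizon does not match the config")
    imp = list(important_set)
    xr = reduced.restrict(imp)
    xf = reference.restrict(imp)
    integrand = np.abs(1.0 - xr / np.maximum(xf, config.epsilon))
    T = t[-1] - t[0]
    return float(np.trapezoid(integrand, t, axis=0).sum() / (T * len(imp)))


def symmetric_error(traj_a: Trajectory, traj_b: Trajectory,
                    important_set: Sequence[int],
                    config: ErrorConfig = ErrorConfig()) -> float:
    """Symmetrised error E_T; a metric-like dissimilarity between any two
    models sharing M_I (their parameter sets may differ)."""
    return 0.5 * (error_integral(traj_a, traj_b, important_set, config)
                  + error_integral(traj_b, traj_a, important_set, config))


@dataclass(frozen=True)
class DissimilarityMatrix:
    """All-pairs symmetric errors; rows labelled by (set id, bitmask)."""

    labels: tuple[tuple[int, str], ...]
    values: np.ndarray
    excluded: tuple[tuple[int, str], ...] = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match the label count")

    @property
    def n(self) -> int:
        return len(self.labels)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("label\t" + "\t".join(f"{s}:{m}" for s, m in self.labels) + "\n")
            for (s, m), row in zip(self.labels, self.values):
                fh.write(f"{s}:{m}\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "DissimilarityMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            labels = tuple((int(h.split(":")[0]), h.split(":")[1]) for h in header)
            rows = [[float(v) for v in line.rstrip("\n").split("\t")[1:]]
                    for line in fh]
        return cls(labels, np.array(rows))


def dissimilarity_matrix(trajectories: Sequence[tuple[tuple[int, str], Trajectory]],
                         important_set: Sequence[int],
                         config: ErrorConfig = ErrorConfig()) -> DissimilarityMatrix:
    """Symmetric error between every pair of labelled trajectories.

    Trajectories containing non-finite values are excluded (with a logged
    warning) and reported in the result's ``excluded`` list.  The result is
    independent of input order up to the corresponding row permutation.
    """
    kept, excluded = [], []
    for label, traj in trajectories:
        if np.all(np.isfinite(traj.x)):
            kept.append((label, traj))
        else:
            logger.warning("excluding non-finite trajectory %s", label)
            excluded.append(label)
    if not kept:
        raise ValueError("no finite trajectories to compare")
    t = kept[0][1].t
    imp = list(important_set)
    for _, traj in kept[1:]:
        _common_grid(kept[0][1], traj)
    X = np.stack([traj.restrict(imp) for _, traj in kept])  # (N, grid, m)
    denom = np.maximum(X, config.epsilon)
    T = t[-1] - t[0]
    N = len(kept)
    I = np.empty((N, N))
    for a in range(N):  # row blocks keep the broadcast buffer small
        integrand = np.abs(1.0 - X[a][None] / denom)  # (N, grid, m)
        I[a] = np.trapezoid(integrand, t, axis=1).sum(axis=1) / (T * len(imp))
    E = 0.5 * (I + I.T)
    np.fill_diagonal(E, 0.0)
    return DissimilarityMatrix(tuple(lbl for lbl, _ in kept), E, tuple(excluded))
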