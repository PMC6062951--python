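"""Log-normal parameter uncertainty sampling.

Two parameterizations are supported, matching the two ways uncertainty is
commonly specified:

``log_sd``
    each positive parameter is log-normal with log-mean ln(ref) and the
    given log standard deviation (the spread is on the log scale);

``natural_cv``
    each positive parameter is log-normal with natural-scale mean equal to
    the reference and natural-scale standard deviation ref/s for a scaling
    divisor s, via the moment-matching conversion
    sigma_log^2 = ln(1 + 1/s^2),  mu_log = ln(ref) - sigma_log^2 / 2.

Parameters whose reference value is exactly zero stay zero in every sample,
and initial values are copied unchanged from the reference set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import DomainError, ParameterSet

__all__ = ["SamplingConfig", "sample_parameters", "sampling_plan", "lognormal_moments"]

MODES = ("log_sd", "natural_cv")


@dataclass(frozen=True)
class SamplingConfig:
    mode: str  # "log_sd" | "natural_cv"
    spread: float  # log-sd, or the scaling divisor s
    n_sets: int
    seed: int

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        if self.n_sets < 1:
            raise ValueError("n_sets must be at least 1")


def lognormal_moments(ref: np.ndarray, s: float) -> tuple[np.ndarray, float]:
    """(mu_log, sigma_log) giving natural-scale mean ``ref`` and sd ``ref/s``.

    The conversion is exact: for X = exp(N(mu, sigma^2)),
    E[X] = exp(mu + sigma^2/2) and Var[X] = (E[X])^2 (exp(sigma^2) - 1).
    """
    sigma2 = np.log1p(1.0 / s**2)
    with np.errstate(divide="ignore"):
        mu = np.log(ref) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def sample_parameters(reference: ParameterSet,
                      config: SamplingConfig) -> list[ParameterSet]:
    """Draw ``n_sets`` independent parameter sets around the reference."""
    ref = reference.sampled
    if np.any(ref < 0):
        raise DomainError("reference parameters must be non-negative")
    rng = np.random.default_rng(config.seed)
    z = rng.standard_normal((config.n_sets, ref.size))
    positive = ref > 0
    samples = np.zeros_like(z)
    if config.mode == "log_sd":
        samples[:, positive] = np.exp(
            np.log(ref[positive]) + config.spread * z[:, positive]
        )
    else:
        mu, sigma = lognormal_moments(ref[positive], config.spread)
        samples[:, positive] = np.exp(mu + sigma * z[:, positive])
    return [reference.with_sampled(row) for row in samples]


def sampling_plan(spreads: list[float], mode: str, n_sets: int,
                  master_seed: int) -> list[SamplingConfig]:
    """One config per spread, with deterministic per-config seeds derived
    from the master seed (seed + position in the plan)."""
    return [SamplingConfig(mode, s, n_sets, master_seed + i)
            for i, s in enumerate(spreads)]
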