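"""End-to-end analysis: sample parameter sets, simulate every reduction of
every set on a shared grid, build the all-pairs symmetric-error matrix,
cluster, and score reductions against the full model.

The evaluation horizon T is resolved once from the reference parameter set
(the time at which the full model is within 1% of its steady state) and
shared by all models, so that errors are comparable across the analysis.
Trajectories are computed once per (parameter set, reduction) pair; the
all-pairs matrix is the computational bottleneck and both it and the
simulations scale as n_sets * 2^c, which is why a resource guard refuses
oversized runs unless two-stage prefiltering is enabled.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import io as redio
from .clustering import (
    DEFAULT_ALPHA,
    LinkageTree,
    leaf_positions,
    prefilter_reductions,
    score_all,
    single_linkage,
    write_linkage,
    write_score_table,
)
from .metrics import DissimilarityMatrix, ErrorConfig, dissimilarity_matrix
from .network import (
    NetworkModel,
    ParameterSet,
    SimulationError,
    resolve_horizon,
    simulate,
    steady_state,
)
from .reduction import ReductionSpec, eligible_complexes, enumerate_reductions, reduce_model
from .sampling import SamplingConfig, sample_parameters

__all__ = ["AnalysisConfig", "AnalysisResult", "run_analysis"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Fully-defaulted run configuration; only ``network`` is required."""

    network: str | Path | None = None  # network definition file
    mode: str = "log_sd"
    spread: float = 0.1
    n_sets: int = 100
    seed: int = 0
    horizon: float | None = None  # None: resolve from the reference model
    n_grid: int = 1000
    rtol: float = 1e-8
    atol: float = 1e-10
    alpha: float = DEFAULT_ALPHA
    prefilter: float | None = None  # KS threshold enabling two-stage mode
    pilot_sets: int = 100
    outdir: str | Path | None = None
    workers: int = 1
    model_cap: int = 10_000
    plot: bool = False

    def resolved(self, horizon: float) -> dict:
        d = dataclasses.asdict(self)
        d["network"] = str(d["network"]) if d["network"] else None
        d["outdir"] = str(d["outdir"]) if d["outdir"] else None
        d["horizon"] = horizon
        return d


@dataclass
class AnalysisResult:
    score_table: pd.DataFrame
    tree: LinkageTree
    matrix: DissimilarityMatrix
    horizon: float
    parameter_sets: list[ParameterSet]
    specs: list[ReductionSpec]

    @property
    def best(self) -> str | None:
        marked = self.score_table[self.score_table["best"]]
        return None if marked.empty else str(marked.iloc[0]["bitmask"])


def _simulate_set(model: NetworkModel, params: ParameterSet,
                  specs: list[ReductionSpec], set_id: int, horizon: float,
                  n_grid: int, rtol: float, atol: float):
    """All reduced-model trajectories for one parameter set (its own full
    steady state defines the clamp levels)."""
    try:
        xss = steady_state(model, params, rtol=rtol, atol=atol)
    except Exception as exc:
        raise SimulationError(
            f"steady state failed for set {set_id}: {exc}", label=(set_id, None)
        ) from exc
    out = []
    for spec in specs:
        reduced = reduce_model(model, params, spec, xss)
        traj = simulate(reduced, params, horizon, n_grid, rtol=rtol, atol=atol,
                        label=(set_id, spec.bitmask))
        out.append(((set_id, spec.bitmask), traj))
    return out


def _cluster_and_score(trajectories, model, alpha):
    D = dissimilarity_matrix(trajectories, model.important)
    tree = single_linkage(D)
    table = score_all(tree, D.labels, alpha)
    return D, tree, table


def run_analysis(config: AnalysisConfig,
                 model: NetworkModel | None = None,
                 reference: ParameterSet | None = None) -> AnalysisResult:
    """Execute the full pipeline and return the score table with artifacts.

    In two-stage mode (``config.prefilter`` set) a pilot run over all 2^c
    reductions with ``pilot_sets`` parameter sets first discards reductions
    scoring at or above the prefilter threshold; the main run then covers
    only the survivors with ``n_sets`` freshly sampled parameter sets.
    """
    if model is None:
        if config.network is None:
            raise ValueError("either a network file or a model object is required")
        model, reference = redio.read_network(config.network)
    if reference is None:
        raise ValueError("a reference parameter set is required")

    elig = tuple(eligible_complexes(model))
    specs = enumerate_reductions(elig)
    if config.prefilter is None and config.n_sets * len(specs) > config.model_cap:
        raise ValueError(
            f"{config.n_sets} sets x {len(specs)} reductions exceeds the "
            f"model cap ({config.model_cap}); enable two-stage prefiltering "
            "or raise model_cap"
        )

    horizon = config.horizon
    if horizon is None:
        horizon = resolve_horizon(model, reference, rtol=config.rtol, atol=config.atol)
    logger.info("evaluation horizon T = %g", horizon)

    if config.prefilter is not None:
        pilot_cfg = SamplingConfig(config.mode, config.spread, config.pilot_sets,
                                   config.seed)
        pilot_sets = sample_parameters(reference, pilot_cfg)
        pilot_traj = _simulate_all(model, pilot_sets, specs, horizon, config)
        _, _, pilot_table = _cluster_and_score(pilot_traj, model, config.alpha)
        keep = set(prefilter_reductions(pilot_table, config.prefilter))
        specs = [s for s in specs if s.bitmask in keep]
        logger.info("prefilter kept %d of 2^%d reductions", len(specs), len(elig))
        main_seed = config.seed + 1
    else:
        main_seed = config.seed

    sampling = SamplingConfig(config.mode, config.spread, config.n_sets, main_seed)
    param_sets = sample_parameters(reference, sampling)
    trajectories = _simulate_all(model, param_sets, specs, horizon, config)
    D, tree, table = _cluster_and_score(trajectories, model, config.alpha)

    result = AnalysisResult(table, tree, D, horizon, param_sets, list(specs))
    if config.outdir is not None:
        _write_artifacts(config, model, result)
    return result


def _simulate_all(model, param_sets, specs, horizon, config: AnalysisConfig):
    args = [(model, ps, list(specs), i, horizon, config.n_grid,
             config.rtol, config.atol) for i, ps in enumerate(param_sets)]
    if config.workers > 1:
        blocks = Parallel(n_jobs=config.workers)(
            delayed(_simulate_set)(*a) for a in args)
    else:
        blocks = [_simulate_set(*a) for a in args]
    return [item for block in blocks for item in block]


def _write_artifacts(config: AnalysisConfig, model: NetworkModel,
                     result: AnalysisResult) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    redio.write_parameter_table(outdir / "parameters.tsv", model,
                                result.parameter_sets)
    result.matrix.write(outdir / "dissimilarity.tsv")
    write_linkage(outdir / "linkage.tsv", result.tree)
    positions = leaf_positions(result.tree)
    with open(outdir / "positions.tsv", "w") as fh:
        fh.write("set_id\tbitmask\tposition\n")
        for (sid, mask), pos in zip(result.matrix.labels, positions):
            fh.write(f"{sid}\t{mask}\t{pos}\n")
    write_score_table(outdir / "scores.tsv", result.score_table)
    with open(outdir / "config.json", "w") as fh:
        json.dump(config.resolved(result.horizon), fh, indent=2)
        fh.write("\n")
    with open(outdir / "run.log", "w") as fh:
        fh.write(f"network = {model.name}\n")
        fh.write(f"seed = {config.seed}\n")
        fh.write(f"horizon = {result.horizon!r}\n")
        fh.write(f"models = {result.matrix.n}\n")
        fh.write(f"best = {result.best}\n")
    if config.plot:
        plot_dendrogram(result, outdir / "dendrogram.png")


def plot_dendrogram(result: AnalysisResult, path: str | Path) -> None:
    """Dendrogram with leaves colored by reduction (full model first color)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    masks = [m for _, m in result.matrix.labels]
    unique = sorted(set(masks), key=lambda m: (m.count("1"), m))
    cmap = plt.get_cmap("tab20", max(len(unique), 1))
    colors = {m: cmap(i) for i, m in enumerate(unique)}
    fig, ax = plt.subplots(figsize=(12, 4))
    dd = dendrogram(result.tree.merges, ax=ax, no_labels=True,
                    color_threshold=0.0, above_threshold_color="0.5")
    for leaf, x in zip(dd["leaves"], ax.get_xticks()):
        ax.plot(x, 0, "s", color=colors[masks[leaf]], markersize=3,
                clip_on=False, zorder=3)
    handles = [plt.Line2D([], [], marker="s", linestyle="", color=colors[m],
                          label=m) for m in unique]
    ax.legend(handles=handles, fontsize=6, ncol=4, title="reduction")
    ax.set_ylabel("symmetric error")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
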