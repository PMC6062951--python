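"""Reading and writing the package's text formats.

Network definitions are TOML files (read with :mod:`tomllib`); the writer
emits a canonical layout so that reading and re-writing a definition file
reproduces it byte for byte.  Tabular outputs (trajectories, parameter
tables, dissimilarity matrices, linkage tables) are tab-separated text with
``repr``-precision floats, so they round-trip exactly.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .network import BoundaryFlux, NetworkModel, NetworkStructureError, ParameterSet, Trajectory

__all__ = [
    "read_network",
    "write_network",
    "network_to_toml",
    "write_trajectory",
    "read_trajectory",
    "write_parameter_table",
    "read_parameter_table",
]


def read_network(path: str | Path) -> tuple[NetworkModel, ParameterSet]:
    """Load a network definition file: structure plus reference parameters."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    try:
        compounds = tuple(doc["compounds"])
        cpd_index = {c: i for i, c in enumerate(compounds)}
        complexes = doc["complexes"]
        complex_names = tuple(c["name"] for c in complexes)
        cplx_index = {c: i for i, c in enumerate(complex_names)}
        Z = np.zeros((len(compounds), len(complexes)), dtype=int)
        for ci, c in enumerate(complexes):
            for cpd, coef in c["stoichiometry"].items():
                Z[cpd_index[cpd], ci] = coef
        reactions = doc["reactions"]
        B = np.zeros((len(complexes), len(reactions)), dtype=int)
        for j, r in enumerate(reactions):
            B[cplx_index[r["substrate"]], j] = -1
            B[cplx_index[r["product"]], j] = 1
        boundary = tuple(
            BoundaryFlux(cplx_index[b["complex"]], b["kind"], b["name"])
            for b in doc.get("boundary", [])
        )
        model = NetworkModel(
            compound_names=compounds,
            complex_names=complex_names,
            Z=Z,
            B=B,
            reaction_names=tuple(r["name"] for r in reactions),
            modifiers=tuple(r.get("modifier", "mass_action") for r in reactions),
            boundary=boundary,
            important=tuple(cpd_index[c] for c in doc["important"]),
            name=doc.get("name", Path(path).stem),
        )
        kin = doc.get("kinetic_parameters", {})
        bnd = doc.get("boundary_parameters", {})
        ini = doc.get("initial_values", {})
        params = ParameterSet(
            kinetic=np.array([kin[n] for n in model.reaction_names], dtype=float),
            boundary=np.array([bnd[n] for n in model.boundary_parameter_names], dtype=float),
            initial=np.array([ini[c] for c in compounds], dtype=float),
        )
    except KeyError as exc:
        raise NetworkStructureError(f"network file {path}: missing key {exc}") from exc
    params.validate_for(model)
    return model, params


def _fmt(x: float) -> str:
    return repr(float(x))


def network_to_toml(model: NetworkModel, params: ParameterSet) -> str:
    """Serialize to the canonical TOML layout used by :func:`read_network`."""
    lines: list[str] = []
    lines.append(f'name = "{model.name}"')
    lines.append("compounds = [" + ", ".join(f'"{c}"' for c in model.compound_names) + "]")
    lines.append("important = ["
                 + ", ".join(f'"{model.compound_names[i]}"' for i in model.important) + "]")
    for ci, cname in enumerate(model.complex_names):
        lines.append("")
        lines.append("[[complexes]]")
        lines.append(f'name = "{cname}"')
        stoich = ", ".join(
            f"{model.compound_names[i]} = {int(model.Z[i, ci])}"
            for i in np.nonzero(model.Z[:, ci])[0]
        )
        lines.append("stoichiometry = { " + stoich + " }")
    sub = model.substrate_index
    prod = np.argmax(model.B, axis=0)
    for j, rname in enumerate(model.reaction_names):
        lines.append("")
        lines.append("[[reactions]]")
        lines.append(f'name = "{rname}"')
        lines.append(f'substrate = "{model.complex_names[sub[j]]}"')
        lines.append(f'product = "{model.complex_names[prod[j]]}"')
        lines.append(f'modifier = "{model.modifiers[j]}"')
    for bf in model.boundary:
        lines.append("")
        lines.append("[[boundary]]")
        lines.append(f'name = "{bf.parameter}"')
        lines.append(f'complex = "{model.complex_names[bf.complex_index]}"')
        lines.append(f'kind = "{bf.kind}"')
    lines.append("")
    lines.append("[kinetic_parameters]")
    for n, v in zip(model.reaction_names, params.kinetic):
        lines.append(f"{n} = {_fmt(v)}")
    lines.append("")
    lines.append("[boundary_parameters]")
    for n, v in zip(model.boundary_parameter_names, params.boundary):
        lines.append(f"{n} = {_fmt(v)}")
    lines.append("")
    lines.append("[initial_values]")
    for n, v in zip(model.compound_names, params.initial):
        lines.append(f"{n} = {_fmt(v)}")
    return "\n".join(lines) + "\n"


def write_network(path: str | Path, model: NetworkModel, params: ParameterSet) -> None:
    Path(path).write_text(network_to_toml(model, params))


# -- trajectories ----------------------------------------------------------


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    names = traj.compound_names or tuple(f"x{i+1}" for i in range(traj.x.shape[1]))
    with open(path, "w") as fh:
        fh.write("time\t" + "\t".join(names) + "\n")
        for ti, row in zip(traj.t, traj.x):
            fh.write(_fmt(ti) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return Trajectory(df["time"].to_numpy(), df.iloc[:, 1:].to_numpy(),
                      tuple(df.columns[1:]))


# -- parameter tables ------------------------------------------------------


def write_parameter_table(path: str | Path, model: NetworkModel,
                          sets: list[ParameterSet]) -> None:
    """One row per sampled parameter set (kinetic then boundary values)."""
    with open(path, "w") as fh:
        fh.write("set_id\t" + "\t".join(model.parameter_names) + "\n")
        for i, ps in enumerate(sets):
            fh.write(str(i) + "\t" + "\t".join(_fmt(v) for v in ps.sampled) + "\n")


def read_parameter_table(path: str | Path, reference: ParameterSet) -> list[ParameterSet]:
    """Rebuild parameter sets from a table; initial values come from the
    reference set (they are shared across samples)."""
    df = pd.read_csv(path, sep="\t", index_col="set_id", float_precision="round_trip")
    return [reference.with_sampled(row.to_numpy()) for _, row in df.iterrows()]
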