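"""Directed acyclic network over wetland traits and its copula calibration.

A non-parametric Bayesian network here is a DAG whose nodes are the trait
variables plus a single target (species richness), and whose arcs carry
(conditional) rank correlations realized through a normal copula with
empirical margins.  Calibration ("fit") estimates each node's empirical
margin and the z-space correlation structure:

* ``saturated`` mode keeps the full normal-scores correlation matrix of
  the data (PD-repaired if needed);
* ``bn_constrained`` mode (default) assigns to each arc (p_k -> v) the
  partial correlation of v and p_k given v's earlier-ordered parents
  p_1..p_{k-1}, and sets the partial correlation of v with every
  non-parent predecessor (given the parents) to zero.  The joint z-space
  matrix is then rebuilt from the arc partials alone by inverting the
  partial-correlation recursion along the topological ordering, so that
  re-extracting arc partials from the implied matrix reproduces them
  exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .copula import (
    EmpiricalMargin,
    GaussianCopulaModel,
    normal_rank_corr_matrix,
)
from .errors import ConstantColumnError, SchemaError, StructureError
from .traits import TARGET, WetlandTable

ROLES = ("spatial", "anthropic", "hydrological", "target")
SIGNS = ("+", "-", "unconstrained")

Arc = tuple[str, str]


@dataclass(frozen=True)
class NetworkNode:
    name: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise StructureError(f"unknown role {self.role!r} for node {self.name!r}")


@dataclass(frozen=True)
class NetworkArc:
    source: str
    dest: str
    expected_sign: str = "unconstrained"

    def __post_init__(self) -> None:
        if self.expected_sign not in SIGNS:
            raise StructureError(
                f"arc sign must be one of {SIGNS}, got {self.expected_sign!r}"
            )


@dataclass
class NetworkStructure:
    """Validated DAG of named, role-tagged nodes with signed arcs."""

    nodes: tuple[NetworkNode, ...]
    arcs: tuple[NetworkArc, ...]

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        self.arcs = tuple(self.arcs)
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise StructureError("duplicate node names")
        known = set(names)
        for arc in self.arcs:
            for end in (arc.source, arc.dest):
                if end not in known:
                    raise StructureError(f"arc references unknown node {end!r}")
        if len({(a.source, a.dest) for a in self.arcs}) != len(self.arcs):
            raise StructureError("duplicate arcs")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise StructureError(f"structure contains a cycle: {cycle}")
        targets = [n.name for n in self.nodes if n.role == "target"]
        if len(targets) != 1:
            raise StructureError(
                f"exactly one target node required, found {len(targets)}"
            )
        if g.out_degree(targets[0]) > 0:
            raise StructureError(f"target node {targets[0]!r} has outgoing arcs")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(n.name for n in self.nodes)
        g.add_edges_from((a.source, a.dest) for a in self.arcs)
        return g

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    @property
    def target(self) -> str:
        return next(n.name for n in self.nodes if n.role == "target")

    @property
    def ordering(self) -> list[str]:
        """Topological order; ties broken by node declaration order."""
        pos = {n.name: i for i, n in enumerate(self.nodes)}
        return list(nx.lexicographical_topological_sort(self.graph(), key=pos.get))

    def parents(self, name: str) -> list[str]:
        """Parents of ``name`` in topological (ordering) position."""
        order = {n: i for i, n in enumerate(self.ordering)}
        ps = [a.source for a in self.arcs if a.dest == name]
        return sorted(ps, key=order.get)

    def arc_sign(self, source: str, dest: str) -> str:
        for a in self.arcs:
            if (a.source, a.dest) == (source, dest):
                return a.expected_sign
        raise KeyError((source, dest))

    def to_dict(self) -> dict:
        return {
            "nodes": [{"name": n.name, "role": n.role} for n in self.nodes],
            "arcs": [
                {"from": a.source, "to": a.dest, "sign": a.expected_sign}
                for a in self.arcs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkStructure":
        try:
            nodes = tuple(NetworkNode(n["name"], n["role"]) for n in d["nodes"])
            arcs = tuple(
                NetworkArc(a["from"], a["to"], a.get("sign", "unconstrained"))
                for a in d.get("arcs", [])
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed structure specification: {exc}") from exc
        return cls(nodes, arcs)


def load_structure(path) -> NetworkStructure:
    """Load a network structure from a JSON or YAML file."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"structure file not found: {path}")
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        d = json.loads(text)
    else:
        d = yaml.safe_load(text)
    return NetworkStructure.from_dict(d)


def default_structure() -> NetworkStructure:
    """Shipped reconstruction of the conceptual wetland model.

    Three spatial traits (size, isolation, distance to the coastline),
    three anthropic pressures (tourism, anthropization, discharges) and
    three hydrological traits (diversions, salinity, water level) all
    point at species richness.  Signs follow the field expectation:
    pressures, salinity and high water depress richness; water diversions
    (which lower the water level) and wetland size favour it.  One
    inter-driver arc, diversions -> water level (negative), encodes the
    drainage mechanism; further inter-driver arcs can be supplied via a
    structure file.
    """
    nodes = (
        NetworkNode("wetland size", "spatial"),
        NetworkNode("isolation", "spatial"),
        NetworkNode("distance to coastline", "spatial"),
        NetworkNode("mean water level", "hydrological"),
        NetworkNode("water salinity", "hydrological"),
        NetworkNode("water diversions", "hydrological"),
        NetworkNode("water discharges", "anthropic"),
        NetworkNode("tourism pressure", "anthropic"),
        NetworkNode("anthropization", "anthropic"),
        NetworkNode(TARGET, "target"),
    )
    arcs = (
        NetworkArc("water diversions", "mean water level", "-"),
        NetworkArc("wetland size", TARGET, "+"),
        NetworkArc("isolation", TARGET, "-"),
        NetworkArc("distance to coastline", TARGET, "unconstrained"),
        NetworkArc("mean water level", TARGET, "-"),
        NetworkArc("water salinity", TARGET, "-"),
        NetworkArc("water diversions", TARGET, "+"),
        NetworkArc("water discharges", TARGET, "-"),
        NetworkArc("tourism pressure", TARGET, "-"),
        NetworkArc("anthropization", TARGET, "-"),
    )
    return NetworkStructure(nodes, arcs)


# ---------------------------------------------------------------------------
# partial correlations
# ---------------------------------------------------------------------------


def partial_correlation(R: pd.DataFrame, i: str, j: str, given=()) -> float:
    """Partial correlation of i and j given a conditioning set.

    Uses the precision-matrix formula on the submatrix over
    {i, j} | given; with an empty conditioning set this is the raw
    correlation R[i, j].
    """
    given = list(given)
    if i in given or j in given:
        raise ValueError("conditioning set must not contain i or j")
    if not given:
        return float(R.loc[i, j])
    idx = [i, j] + given
    sub = R.loc[idx, idx].to_numpy(dtype=float)
    try:
        P = np.linalg.inv(sub)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular submatrix for partial correlation ({i}, {j} | {given})"
        ) from exc
    denom = np.sqrt(P[0, 0] * P[1, 1])
    if not np.isfinite(denom) or denom <= 0:
        raise np.linalg.LinAlgError("ill-conditioned submatrix")
    return float(np.clip(-P[0, 1] / denom, -1.0, 1.0))


def extract_arc_partials(
    R: pd.DataFrame, structure: NetworkStructure
) -> dict[Arc, float]:
    """Arc partial correlations under the earlier-parents protocol.

    Arc (p_k -> v), with v's parents ordered topologically as p_1..p_m,
    carries rho(v, p_k | p_1..p_{k-1}).
    """
    partials: dict[Arc, float] = {}
    for v in structure.node_names:
        parents = structure.parents(v)
        for k, p in enumerate(parents):
            partials[(p, v)] = partial_correlation(R, v, p, parents[:k])
    return partials


def implied_correlation_matrix(
    structure: NetworkStructure, arc_partials: dict[Arc, float]
) -> pd.DataFrame:
    """Joint z-space correlation matrix implied by the arc partials.

    Nodes are processed in topological order.  For node v the correlations
    with its parents are recovered from the sequential arc partials by the
    C-vine inversion recursion; correlations with every other predecessor
    follow from the zero-partial constraint, i.e. the linear regression of
    v's score on its parents' scores.  The result is positive definite
    whenever every |arc partial| < 1.
    """
    order = structure.ordering
    k = len(order)
    R = pd.DataFrame(np.eye(k), index=order, columns=order)
    for pos in range(1, k):
        v = order[pos]
        preds = order[:pos]
        parents = structure.parents(v)
        r = [arc_partials[(p, v)] for p in parents]
        for r_k in r:
            if not abs(r_k) < 1:
                raise ValueError(f"arc partial magnitude must be < 1, got {r_k}")
        # parents -> raw correlations, peeling the conditioning set
        for kk, pk in enumerate(parents):
            x = r[kk]
            for jj in range(kk - 1, -1, -1):
                a = r[jj]  # rho(v, p_j | p_1..p_{j-1})
                b = partial_correlation(R, pk, parents[jj], parents[:jj])
                x = x * np.sqrt((1 - a * a) * (1 - b * b)) + a * b
            R.loc[v, pk] = R.loc[pk, v] = x
        # non-parent predecessors: zero partial given parents <=> regression
        others = [w for w in preds if w not in parents]
        if others:
            if parents:
                Rpp = R.loc[parents, parents].to_numpy(dtype=float)
                Rvp = R.loc[v, parents].to_numpy(dtype=float)
                beta = np.linalg.solve(Rpp, Rvp)
                Rpo = R.loc[parents, others].to_numpy(dtype=float)
                vals = beta @ Rpo
            else:
                vals = np.zeros(len(others))
            R.loc[v, others] = vals
            R.loc[others, v] = vals
    return R


# ---------------------------------------------------------------------------
# fitted model
# ---------------------------------------------------------------------------

FIT_MODES = ("bn_constrained", "saturated")


@dataclass
class FittedModel:
    """Calibrated copula network: margins + z-space matrix + arc partials."""

    structure: NetworkStructure
    margins: dict[str, EmpiricalMargin]
    copula: GaussianCopulaModel
    arc_partials: dict[Arc, float]
    fit_mode: str
    n_wetlands: int
    sample_matrix: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def target(self) -> str:
        return self.structure.target

    @property
    def node_names(self) -> list[str]:
        return list(self.copula.node_names)

    def arc_partial_table(self) -> pd.DataFrame:
        rows = [
            {
                "source": s,
                "dest": d,
                "partial_correlation": rho,
                "expected_sign": self.structure.arc_sign(s, d),
            }
            for (s, d), rho in sorted(self.arc_partials.items())
        ]
        return pd.DataFrame(rows)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "fit_mode": self.fit_mode,
            "n_wetlands": self.n_wetlands,
            "structure": self.structure.to_dict(),
            "margins": {
                name: list(map(float, m.sorted_values))
                for name, m in self.margins.items()
            },
            "correlation_matrix": {
                "nodes": list(self.copula.node_names),
                "values": self.copula.R.tolist(),
            },
            "arc_partials": [
                {"from": s, "to": d, "rho": float(rho)}
                for (s, d), rho in sorted(self.arc_partials.items())
            ],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        structure = NetworkStructure.from_dict(d["structure"])
        margins = {
            name: EmpiricalMargin.from_data(vals) for name, vals in d["margins"].items()
        }
        cop = GaussianCopulaModel(
            tuple(d["correlation_matrix"]["nodes"]),
            np.asarray(d["correlation_matrix"]["values"], dtype=float),
        )
        partials = {(a["from"], a["to"]): float(a["rho"]) for a in d["arc_partials"]}
        return cls(structure, margins, cop, partials, d["fit_mode"], d["n_wetlands"])

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def fit(
    table: WetlandTable,
    structure: NetworkStructure | None = None,
    mode: str = "bn_constrained",
) -> FittedModel:
    """Calibrate the network on a trait table.

    Estimates one empirical margin per node and the z-space correlation
    structure in the requested mode (see module docstring).  Requires
    n >= 5 rows, every structure node present as a column and no constant
    column.
    """
    if structure is None:
        structure = default_structure()
    if mode not in FIT_MODES:
        raise ValueError(f"mode must be one of {FIT_MODES}")
    missing = [n for n in structure.node_names if n not in table.columns]
    if missing:
        raise SchemaError(f"table lacks columns for nodes: {missing}")
    if table.n < 5:
        raise ValueError(f"need at least 5 wetlands to fit, got {table.n}")
    frame = table.data[structure.node_names]
    for name in structure.node_names:
        if np.ptp(frame[name].to_numpy(dtype=float)) == 0:
            raise ConstantColumnError(name)

    S = normal_rank_corr_matrix(frame, repair=True)
    arc_partials = extract_arc_partials(S, structure)
    if mode == "saturated":
        R = S
    else:
        R = implied_correlation_matrix(structure, arc_partials)
    order = structure.ordering
    copula = GaussianCopulaModel(
        tuple(order), R.loc[order, order].to_numpy(dtype=float)
    )
    margins = {
        name: EmpiricalMargin.from_data(frame[name].to_numpy(dtype=float))
        for name in structure.node_names
    }
    return FittedModel(
        structure=structure,
        margins=margins,
        copula=copula,
        arc_partials=arc_partials,
        fit_mode=mode,
        n_wetlands=table.n,
        sample_matrix=S,
    )
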