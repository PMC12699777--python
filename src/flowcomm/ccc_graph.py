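"""Receptor-centric spatially constrained flow graph.

Cells become nodes; for every ordered pair of cells (i, j) closer than a
distance cutoff, and every receptor R expressed in the target j that has at
least one ligand binder expressed in the source i, a directed edge
(i, j, R) is created. Each edge carries

* a cost  c_e = d_ij / d_cutoff + lambda * (1 - a_bar), where a_bar is the
  expression-weighted mean affinity of the expressed binders of R in i
  (short, high-affinity interactions are cheap);
* an upper bound  u_e = kappa * combine(E_R(j), S_L(i)), the scarcer (min,
  default) or the product of receptor abundance and aggregate expressed
  ligand supply;
* a lower bound  l_e = epsilon * u_e when some expressed binder carries
  prior confidence, else 0 — prior-supported signaling is forced to be
  nonzero yet bounded.

A gene counts as "expressed" when its value is strictly greater than the
threshold tau; the distance test is strict (d_ij < d_cutoff).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .lr_prior import LRDatabase

__all__ = [
    "ExpressionMatrix",
    "SpatialMap",
    "InferenceConfig",
    "ReceptorEdge",
    "FlowGraph",
    "pairwise_neighbors",
    "aggregate_affinity",
    "edge_cost",
    "edge_bounds",
    "build_flow_graph",
]


@dataclass
class ExpressionMatrix:
    """Dense cells x genes nonnegative expression matrix."""

    cells: list[str]
    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cells), len(self.genes)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression at cell {self.cells[i]!r}, gene {self.genes[j]!r}"
            )
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell identifiers")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        self._cell_index = {c: k for k, c in enumerate(self.cells)}
        self._gene_index = {g: k for k, g in enumerate(self.genes)}

    @property
    def cell_index(self) -> dict[str, int]:
        return self._cell_index

    @property
    def gene_index(self) -> dict[str, int]:
        return self._gene_index

    def value(self, cell: str, gene: str) -> float:
        return float(self.values[self._cell_index[cell], self._gene_index[gene]])


@dataclass
class SpatialMap:
    """Cell id -> (x, y) coordinates in consistent (but arbitrary) units."""

    coords: dict[str, tuple[float, float]]

    def distance(self, i: str, j: str) -> float:
        xi, yi = self.coords[i]
        xj, yj = self.coords[j]
        return float(np.hypot(xi - xj, yi - yj))


@dataclass
class InferenceConfig:
    """Tunable parameters of graph construction and the exact solver.

    d_cutoff        distance cutoff (coordinate units); edges need d < cutoff
    lambda_affinity weight of the (1 - a_bar) affinity penalty in the cost
    kappa_upper     proportionality constant of the upper bound
    epsilon_lower   lower bound as a fraction of the upper bound on
                    prior-supported edges (must be < 1)
    expr_threshold  tau; a gene is expressed when value > tau
    bound_combiner  'min' or 'product' of receptor abundance and ligand supply
    quantum         integer flow units per max upper bound for the exact solve
    """

    d_cutoff: float
    lambda_affinity: float = 1.0
    kappa_upper: float = 1.0
    epsilon_lower: float = 0.05
    expr_threshold: float = 0.0
    bound_combiner: str = "min"
    quantum: int = 1000

    def __post_init__(self) -> None:
        if self.d_cutoff <= 0:
            raise ValueError("d_cutoff must be > 0")
        if self.lambda_affinity < 0:
            raise ValueError("lambda_affinity must be >= 0")
        if self.kappa_upper <= 0:
            raise ValueError("kappa_upper must be > 0")
        if not (0.0 <= self.epsilon_lower < 1.0):
            raise ValueError("epsilon_lower must be in [0, 1)")
        if self.expr_threshold < 0:
            raise ValueError("expr_threshold must be >= 0")
        if self.bound_combiner not in ("min", "product"):
            raise ValueError("bound_combiner must be 'min' or 'product'")
        if int(self.quantum) < 1:
            raise ValueError("quantum must be a positive integer")
        self.quantum = int(self.quantum)


@dataclass(frozen=True)
class ReceptorEdge:
    """Directed edge i -> j indexed by the receptor R on the target."""

    source: str
    target: str
    receptor: str
    distance: float
    affinity_aggregate: float
    lower: float
    upper: float
    cost: float


@dataclass
class FlowGraph:
    """Cells with net supply b_v (default 0) plus receptor-centric edges."""

    nodes: list[str]
    edges: list[ReceptorEdge]
    balance: dict[str, float] = field(default_factory=dict)

    def balance_of(self, node: str) -> float:
        return self.balance.get(node, 0.0)

    def total_balance(self) -> float:
        return sum(self.balance.get(n, 0.0) for n in self.nodes)


def pairwise_neighbors(
    spatial: SpatialMap, d_cutoff: float
) -> list[tuple[str, str, float]]:
    """All ordered cell pairs with Euclidean distance strictly below cutoff.

    Both directions are listed; the result is sorted by (i, j).
    """
    if d_cutoff <= 0:
        raise ValueError("d_cutoff must be > 0")
    ids = sorted(spatial.coords)
    if len(ids) < 2:
        return []
    pts = np.array([spatial.coords[c] for c in ids], dtype=float)
    tree = cKDTree(pts)
    out: list[tuple[str, str, float]] = []
    for a, b in tree.query_pairs(r=d_cutoff):
        d = float(np.hypot(*(pts[a] - pts[b])))
        if d < d_cutoff:  # query_pairs is inclusive; the model is strict
            out.append((ids[a], ids[b], d))
            out.append((ids[b], ids[a], d))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def aggregate_affinity(
    source: str,
    receptor: str,
    expr: ExpressionMatrix,
    db: LRDatabase,
    tau: float = 0.0,
) -> float:
    """Expression-weighted mean affinity a_bar of the binders of `receptor`
    expressed (value > tau) in the source cell; 0 if none are expressed."""
    num = 0.0
    den = 0.0
    row = expr.cell_index[source]
    for ligand, affinity, _ in db.binders(receptor):
        col = expr.gene_index.get(ligand)
        if col is None:
            continue
        e = expr.values[row, col]
        if e > tau:
            num += affinity * e
            den += e
    return num / den if den > 0 else 0.0


def edge_cost(d_ij: float, affinity_aggregate: float, config: InferenceConfig) -> float:
    """c_e = d/d_cutoff + lambda * (1 - a_bar), in [0, 1 + lambda]."""
    if not (0.0 <= d_ij < config.d_cutoff):
        raise ValueError("distance must satisfy 0 <= d < d_cutoff")
    if not (0.0 <= affinity_aggregate <= 1.0):
        raise ValueError("affinity aggregate must be in [0, 1]")
    return d_ij / config.d_cutoff + config.lambda_affinity * (1.0 - affinity_aggregate)


def edge_bounds(
    source: str,
    target: str,
    receptor: str,
    expr: ExpressionMatrix,
    db: LRDatabase,
    config: InferenceConfig,
) -> tuple[float, float]:
    """(lower, upper) flow bounds of an admissible edge.

    upper = kappa * combine(E_R(target), sum of expressed binder expression
    in source); lower = epsilon * upper if any expressed binder is
    prior-confident, else 0.
    """
    tau = config.expr_threshold
    e_r = expr.value(target, receptor)
    row = expr.cell_index[source]
    s_l = 0.0
    any_confident = False
    for ligand, _, confident in db.binders(receptor):
        col = expr.gene_index.get(ligand)
        if col is None:
            continue
        e = expr.values[row, col]
        if e > tau:
            s_l += e
            any_confident = any_confident or confident
    if config.bound_combiner == "min":
        upper = config.kappa_upper * min(e_r, s_l)
    else:
        upper = config.kappa_upper * e_r * s_l
    if upper <= 0:
        raise RuntimeError(
            "internal error: admissible edge produced zero upper bound "
            f"({source}->{target} via {receptor})"
        )
    lower = config.epsilon_lower * upper if any_confident else 0.0
    return lower, upper


def build_flow_graph(
    expr: ExpressionMatrix,
    spatial: SpatialMap,
    db: LRDatabase,
    config: InferenceConfig,
) -> FlowGraph:
    """Construct the receptor-centric flow graph.

    One node per cell (b_v = 0); one edge per (source, target, receptor)
    passing the distance, receptor-expression and binder-expression gates.
    Edge order is lexicographic in (source, target, receptor), so identical
    inputs give identical graphs.
    """
    if set(expr.cells) != set(spatial.coords):
        missing = set(expr.cells) ^ set(spatial.coords)
        raise ValueError(
            f"expression and coordinates cover different cells (e.g. {sorted(missing)[:5]})"
        )
    tau = config.expr_threshold
    receptors = [r for r in db.receptors if r in expr.gene_index]
    edges: list[ReceptorEdge] = []
    for i, j, d in pairwise_neighbors(spatial, config.d_cutoff):
        row_j = expr.cell_index[j]
        for r in receptors:
            if expr.values[row_j, expr.gene_index[r]] <= tau:
                continue
            a_bar = aggregate_affinity(i, r, expr, db, tau)
            if a_bar == 0.0:
                # no binder of R expressed in the source -> no edge
                continue
            lower, upper = edge_bounds(i, j, r, expr, db, config)
            edges.append(
                ReceptorEdge(
                    source=i,
                    target=j,
                    receptor=r,
                    distance=d,
                    affinity_aggregate=a_bar,
                    lower=lower,
                    upper=upper,
                    cost=edge_cost(d, a_bar, config),
                )
            )
    if not edges:
        warnings.warn("flow graph has zero edges", stacklevel=2)
    nodes = sorted(expr.cells)
    return FlowGraph(nodes=nodes, edges=edges, balance={})
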