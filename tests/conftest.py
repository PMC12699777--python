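"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from flowcomm.ccc_graph import (
    ExpressionMatrix,
    FlowGraph,
    InferenceConfig,
    ReceptorEdge,
    SpatialMap,
)
from flowcomm.lr_prior import LRDatabase, LRPair


def random_circulation_instance(
    rng: np.random.Generator,
    max_nodes: int = 8,
    max_edges: int = 16,
    max_u: int = 5,
    max_c: int = 10,
) -> FlowGraph:
    """Random small bounded-circulation instance with integer data.

    At least one edge has positive capacity so quantization is defined.
    """
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"n{k}" for k in range(n)]
    m = int(rng.integers(1, max_edges + 1))
    edges = []
    for k in range(m):
        i, j = rng.choice(n, size=2, replace=False)
        u = int(rng.integers(0, max_u + 1))
        if k == 0 and u == 0:
            u = int(rng.integers(1, max_u + 1))
        lo = int(rng.integers(0, u + 1))
        c = int(rng.integers(0, max_c + 1))
        edges.append(
            ReceptorEdge(
                source=nodes[i], target=nodes[j], receptor=f"R{k}",
                distance=0.5, affinity_aggregate=1.0,
                lower=float(lo), upper=float(u), cost=float(c),
            )
        )
    return FlowGraph(nodes=nodes, edges=edges)


def enumeration_oracle(graph: FlowGraph) -> float | None:
    """Brute-force optimum over all integer flow vectors; None if infeasible.

    Only sensible for a handful of edges with small bounds; integrality of
    optimal network flows makes this exact for integer instances.
    """
    m = len(graph.edges)
    ranges = [np.arange(int(e.lower), int(e.upper) + 1) for e in graph.edges]
    node_idx = {n: k for k, n in enumerate(graph.nodes)}
    inc = np.zeros((len(graph.nodes), m))
    for k, e in enumerate(graph.edges):
        inc[node_idx[e.source], k] += 1.0
        inc[node_idx[e.target], k] -= 1.0
    b = np.array([graph.balance_of(n) for n in graph.nodes])
    costs = np.array([e.cost for e in graph.edges])
    combos = np.array(list(itertools.product(*ranges)), dtype=float)
    feasible = np.all(combos @ inc.T == b, axis=1)
    if not feasible.any():
        return None
    return float((combos[feasible] @ costs).min())


@pytest.fixture
def toy_db() -> LRDatabase:
    return LRDatabase(
        [
            LRPair("Psap", "Gpr37l1", 1.0, True),
            LRPair("Ptn", "Ptprz1", 0.8, True),
            LRPair("Ptn", "Ncl", 0.5, False),
            LRPair("Mdk", "Ptprz1", 0.6, False),
        ]
    )


@pytest.fixture
def toy_expr() -> ExpressionMatrix:
    # three cells, panel covering the toy database
    genes = ["Psap", "Ptn", "Mdk", "Gpr37l1", "Ptprz1", "Ncl"]
    values = np.array(
        [
            [2.0, 1.0, 0.0, 0.0, 3.0, 1.0],
            [0.0, 4.0, 2.0, 1.0, 0.0, 2.0],
            [1.0, 0.0, 3.0, 2.0, 1.0, 0.0],
        ]
    )
    return ExpressionMatrix(cells=["a", "b", "c"], genes=genes, values=values)


@pytest.fixture
def toy_spatial() -> SpatialMap:
    return SpatialMap(coords={"a": (0.0, 0.0), "b": (1.0, 0.0), "c": (0.0, 1.5)})


@pytest.fixture
def default_config() -> InferenceConfig:
    return InferenceConfig(d_cutoff=2.0)
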