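"""Post hoc redistribution of receptor-centric edge flows across ligands.

The optimizer resolves flow per (source, target, receptor). Each such flow
is then split among the ligands expressed in the source that can bind the
receptor, proportionally to w_L = a_LR**gamma * E_L(source): binding
affinity (through the weighting exponent gamma) combined with ligand
expression. The split conserves the edge flow exactly and never feeds back
into the optimization.
"""

from __future__ import annotations

import math

import pandas as pd

from .ccc_graph import ExpressionMatrix, FlowGraph, ReceptorEdge
from .flow_solver import FlowSolution
from .lr_prior import LRDatabase

__all__ = ["redistribution_weights", "split_edge_flow", "split_flows"]

FLOW_COLUMNS = ["source", "target", "ligand", "receptor", "flow"]


def redistribution_weights(
    source: str,
    receptor: str,
    expr: ExpressionMatrix,
    db: LRDatabase,
    gamma: float = 1.0,
    tau: float = 0.0,
) -> dict[str, float]:
    """Unnormalized split weights w_L = affinity**gamma * E_L(source) over
    the binders of `receptor` expressed (> tau) in the source cell."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    row = expr.cell_index[source]
    weights: dict[str, float] = {}
    for ligand, affinity, _ in db.binders(receptor):
        col = expr.gene_index.get(ligand)
        if col is None:
            continue
        e = expr.values[row, col]
        if e > tau:
            weights[ligand] = (affinity**gamma) * e
    if not weights:
        raise ValueError(
            f"no expressed binder of {receptor!r} in {source!r}; "
            "edges from the flow graph always have at least one"
        )
    return weights


def split_edge_flow(
    edge: ReceptorEdge,
    f_e: float,
    weights: dict[str, float],
) -> list[dict]:
    """Allocate the edge flow to ligands in proportion to their weights.

    Rows come out in lexicographic ligand order; the last row absorbs the
    floating-point residual so the rows sum to f_e bit-exactly. To make that
    exact under any summation order, the non-absorbing shares are snapped
    down onto the ulp(f_e) grid: every partial sum is then an exact multiple
    of a power of two below 2**53 ulps, so no addition rounds.
    """
    if f_e < 0:
        raise ValueError("edge flow must be >= 0")
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("split weights must have a positive sum")
    ligands = sorted(weights)
    grid = math.ulp(f_e) if f_e > 0 else 0.0
    rows = []
    allocated = 0.0
    for ligand in ligands[:-1]:
        share = f_e * (weights[ligand] / total)
        if grid > 0:
            share = math.floor(share / grid) * grid
        allocated += share
        rows.append(
            {
                "source": edge.source,
                "target": edge.target,
                "ligand": ligand,
                "receptor": edge.receptor,
                "flow": share,
            }
        )
    rows.append(
        {
            "source": edge.source,
            "target": edge.target,
            "ligand": ligands[-1],
            "receptor": edge.receptor,
            "flow": f_e - allocated,
        }
    )
    return rows


def split_flows(
    graph: FlowGraph,
    solution: FlowSolution,
    expr: ExpressionMatrix,
    db: LRDatabase,
    gamma: float = 1.0,
    tau: float = 0.0,
) -> pd.DataFrame:
    """Ligand-resolved flow table for a feasible solution.

    Columns: source, target, ligand, receptor, flow. For every edge the
    ligand rows sum exactly to the receptor-centric edge flow.
    """
    if not solution.feasible:
        raise ValueError("cannot split an infeasible solution")
    rows: list[dict] = []
    for edge in graph.edges:
        f_e = solution.flows[(edge.source, edge.target, edge.receptor)]
        weights = redistribution_weights(edge.source, edge.receptor, expr, db, gamma, tau)
        rows.extend(split_edge_flow(edge, f_e, weights))
    return pd.DataFrame(rows, columns=FLOW_COLUMNS)
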