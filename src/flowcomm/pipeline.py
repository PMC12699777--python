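"""End-to-end inference: graph build -> exact solve -> ligand split -> relays."""

from __future__ import annotations

import pandas as pd

from .ccc_graph import (
    ExpressionMatrix,
    FlowGraph,
    InferenceConfig,
    SpatialMap,
    build_flow_graph,
)
from .flow_solver import FlowSolution, lp_oracle, solve, solve_with_relaxation
from .ligand_split import split_flows
from .lr_prior import LRDatabase

__all__ = ["InfeasibleFlowError", "infer_ligand_flows", "edge_flow_frame"]


class InfeasibleFlowError(RuntimeError):
    """The bounded circulation admits no feasible flow."""

    def __init__(self, solution: FlowSolution):
        self.solution = solution
        lines = [
            f"  node {d['node']}: {d['side']} shortfall {d['shortfall']:.6g}"
            for d in solution.diagnostics[:10]
        ]
        super().__init__(
            "bounded circulation is infeasible; unsatisfied lower bounds:\n"
            + "\n".join(lines)
        )


def infer_ligand_flows(
    expr: ExpressionMatrix,
    spatial: SpatialMap,
    db: LRDatabase,
    config: InferenceConfig,
    gamma: float = 1.0,
    relax: bool = False,
    verify: bool = False,
    verify_rtol: float = 1e-3,
) -> tuple[pd.DataFrame, FlowSolution, float]:
    """Run the full inference and return (ligand-flow table, solution,
    lower-bound relaxation factor).

    With relax, infeasible lower bounds are halved (up to 10 times) until a
    circulation exists; without it infeasibility raises
    InfeasibleFlowError. With verify, the LP oracle cross-checks the
    objective on graphs small enough for the guard.
    """
    graph = build_flow_graph(expr, spatial, db, config)
    if relax:
        solution, factor = solve_with_relaxation(graph, config)
    else:
        solution, factor = solve(graph, config), 1.0
    if not solution.feasible:
        raise InfeasibleFlowError(solution)
    if verify and len(graph.edges) <= 500:
        ref = lp_oracle(_with_scaled_lower(graph, factor))
        if ref.feasible:
            denom = max(abs(ref.objective), 1.0)
            if abs(solution.objective - ref.objective) / denom > verify_rtol:
                raise RuntimeError(
                    f"LP verification failed: solver objective {solution.objective!r} "
                    f"vs LP {ref.objective!r}"
                )
    table = split_flows(
        graph, solution, expr, db, gamma=gamma, tau=config.expr_threshold
    )
    return table, solution, factor


def _with_scaled_lower(graph: FlowGraph, factor: float) -> FlowGraph:
    if factor == 1.0:
        return graph
    from .ccc_graph import ReceptorEdge

    return FlowGraph(
        nodes=list(graph.nodes),
        edges=[
            ReceptorEdge(
                source=e.source, target=e.target, receptor=e.receptor,
                distance=e.distance, affinity_aggregate=e.affinity_aggregate,
                lower=e.lower * factor, upper=e.upper, cost=e.cost,
            )
            for e in graph.edges
        ],
        balance=dict(graph.balance),
    )


def edge_flow_frame(solution: FlowSolution) -> pd.DataFrame:
    """Receptor-centric edge flows as a tidy table."""
    rows = [
        {"source": s, "target": t, "receptor": r, "flow": f}
        for (s, t, r), f in sorted(solution.flows.items())
    ]
    return pd.DataFrame(rows, columns=["source", "target", "receptor", "flow"])
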