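"""Exact solver for the bounded minimum-cost circulation.

The problem: find per-edge flows f_e with l_e <= f_e <= u_e, conservation
sum_out f - sum_in f = b_v at every node (b_v > 0 means net supply), and
minimal total cost sum f_e * c_e.

Solution path: (1) conservatively quantize bounds and costs to integers,
(2) eliminate lower bounds by substituting residual variables
f' = f - l — node imbalances become r_v = sum_in l - sum_out l + b_v, nodes
with r_v > 0 (excess forced inflow to push onward) attach to a super-source
and nodes with r_v < 0 to a super-sink via zero-cost auxiliary edges — and
(3) solve the residual min-cost flow exactly with the network simplex.
The original circulation is feasible iff all auxiliary edges saturate;
its optimum is the fixed lower-bound cost sum l_e c_e plus the residual
optimum, and flows are recovered as f = f' + l.

A direct LP formulation (`lp_oracle`) of the same problem serves as an
independent continuous cross-check on small instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from .ccc_graph import FlowGraph, InferenceConfig, ReceptorEdge

__all__ = [
    "QuantizedGraph",
    "ResidualProblem",
    "FlowSolution",
    "quantize",
    "transform_lower_bounds",
    "solve",
    "solve_with_relaxation",
    "lp_oracle",
]

COST_SCALE = 10**6  # fixed decimal cost quantum
_SUPER_SOURCE = ("__super__", "source")
_SUPER_SINK = ("__super__", "sink")
_ROUND_EPS = 1e-9  # absorbs float fuzz before ceil/floor


@dataclass
class QuantizedGraph:
    """Integer-bound copy of a FlowGraph plus the scale factors."""

    nodes: list[str]
    edges: list[ReceptorEdge]          # original (real-valued) edges
    lower: list[int]
    upper: list[int]
    cost: list[int]
    balance: dict[str, int]
    flow_scale: float                  # integer units per expression unit
    cost_scale: float


@dataclass
class ResidualProblem:
    """Lower-bound-free min-cost flow equivalent of a quantized graph."""

    edges: list[tuple[str, str, int, int, int]]  # (source, target, key, capacity, cost)
    imbalance: dict[str, int]                    # r_v = sum_in l - sum_out l + b_v
    super_source: object
    super_sink: object
    aux_edges: list[tuple[object, object, int]]  # zero-cost, (tail, head, capacity)
    fixed_cost: int                              # sum l_e * c_e, integer units


@dataclass
class FlowSolution:
    """Optimal flows in original units plus feasibility diagnostics."""

    flows: dict[tuple[str, str, str], float]
    objective: float
    feasible: bool
    diagnostics: list[dict] = field(default_factory=list)
    flows_int: dict[tuple[str, str, str], int] = field(default_factory=dict)
    fixed_cost_int: int = 0
    residual_cost_int: int = 0
    flow_scale: float = 1.0
    cost_scale: float = float(COST_SCALE)


def quantize(graph: FlowGraph, quantum: int) -> QuantizedGraph:
    """Scale bounds to integers, rounding conservatively (lower up, upper
    down) so the feasible set never widens.

    The flow scale is quantum / max_u, floored to an integer when >= 1 so
    that integer-valued inputs stay exactly representable. Costs use a
    fixed decimal scale of 1e6.
    """
    if quantum < 1:
        raise ValueError("quantum must be >= 1")
    if not graph.edges:
        raise ValueError("cannot quantize a graph with no edges")
    max_u = max(e.upper for e in graph.edges)
    if max_u <= 0:
        raise ValueError("empty capacity: all upper bounds are zero")
    s = float(quantum) / max_u
    if s >= 1.0:
        s = float(math.floor(s))
    lower: list[int] = []
    upper: list[int] = []
    cost: list[int] = []
    bad: list[tuple[str, str, str]] = []
    for e in graph.edges:
        li = math.ceil(e.lower * s - _ROUND_EPS)
        ui = math.floor(e.upper * s + _ROUND_EPS)
        if li > ui:
            bad.append((e.source, e.target, e.receptor))
        lower.append(li)
        upper.append(ui)
        cost.append(round(e.cost * COST_SCALE))
    if bad:
        raise ValueError(
            f"quantization voided {len(bad)} edge interval(s), e.g. {bad[:3]}; "
            "raise the quantum"
        )
    balance = {n: round(graph.balance_of(n) * s) for n in graph.nodes}
    return QuantizedGraph(
        nodes=list(graph.nodes),
        edges=list(graph.edges),
        lower=lower,
        upper=upper,
        cost=cost,
        balance=balance,
        flow_scale=s,
        cost_scale=float(COST_SCALE),
    )


def transform_lower_bounds(q: QuantizedGraph) -> ResidualProblem:
    """Eliminate lower bounds via f' = f - l.

    Residual edges keep cost and get capacity u - l. Node imbalances
    r_v = sum_in l - sum_out l + b_v must sum to zero; r_v > 0 nodes hang
    off the super-source (capacity r_v), r_v < 0 nodes feed the super-sink.
    """
    if sum(q.balance.values()) != 0:
        raise ValueError("node balances must sum to zero")
    imbalance = {n: q.balance.get(n, 0) for n in q.nodes}
    edges: list[tuple[str, str, int, int, int]] = []
    fixed = 0
    for k, e in enumerate(q.edges):
        li, ui, ci = q.lower[k], q.upper[k], q.cost[k]
        edges.append((e.source, e.target, k, ui - li, ci))
        imbalance[e.target] += li
        imbalance[e.source] -= li
        fixed += li * ci
    aux: list[tuple[object, object, int]] = []
    for n in q.nodes:
        r = imbalance[n]
        if r > 0:
            aux.append((_SUPER_SOURCE, n, r))
        elif r < 0:
            aux.append((n, _SUPER_SINK, -r))
    return ResidualProblem(
        edges=edges,
        imbalance=imbalance,
        super_source=_SUPER_SOURCE,
        super_sink=_SUPER_SINK,
        aux_edges=aux,
        fixed_cost=fixed,
    )


def _infeasibility_diagnostics(rp: ResidualProblem, flow_scale: float) -> list[dict]:
    """Per-node shortfalls of unsaturated auxiliary edges, via a plain
    max-flow on the (parallel-collapsed) residual network."""
    g = nx.DiGraph()
    for u, v, _k, cap, _c in rp.edges:
        if g.has_edge(u, v):
            g[u][v]["capacity"] += cap
        else:
            g.add_edge(u, v, capacity=cap)
    for u, v, cap in rp.aux_edges:
        if g.has_edge(u, v):
            g[u][v]["capacity"] += cap
        else:
            g.add_edge(u, v, capacity=cap)
    if rp.super_source not in g or rp.super_sink not in g:
        flow_dict: dict = {}
    else:
        _, flow_dict = nx.maximum_flow(g, rp.super_source, rp.super_sink)
    out = []
    for u, v, cap in rp.aux_edges:
        sent = flow_dict.get(u, {}).get(v, 0)
        if sent < cap:
            node = v if u == rp.super_source else u
            out.append(
                {
                    "node": node,
                    "side": "forced_inflow" if u == rp.super_source else "forced_outflow",
                    "shortfall": (cap - sent) / flow_scale,
                }
            )
    return out


def solve(graph: FlowGraph, config: InferenceConfig) -> FlowSolution:
    """Solve the bounded min-cost circulation exactly.

    Infeasibility is a normal outcome: the solution carries feasible=False
    and per-node shortfall diagnostics instead of flows.
    """
    if not graph.edges:
        return FlowSolution(flows={}, objective=0.0, feasible=True)
    q = quantize(graph, config.quantum)
    rp = transform_lower_bounds(q)

    g = nx.MultiDiGraph()
    total = sum(cap for u, _v, cap in rp.aux_edges if u == rp.super_source)
    for n in q.nodes:
        g.add_node(n, demand=0)
    g.add_node(rp.super_source, demand=-total)
    g.add_node(rp.super_sink, demand=total)
    for u, v, k, cap, c in rp.edges:
        g.add_edge(u, v, key=("e", k), capacity=cap, weight=c)
    for idx, (u, v, cap) in enumerate(rp.aux_edges):
        g.add_edge(u, v, key=("aux", idx), capacity=cap, weight=0)

    try:
        residual_cost, flow_dict = nx.network_simplex(g)
    except nx.NetworkXUnfeasible:
        return FlowSolution(
            flows={},
            objective=float("nan"),
            feasible=False,
            diagnostics=_infeasibility_diagnostics(rp, q.flow_scale),
            flow_scale=q.flow_scale,
        )

    flows_int: dict[tuple[str, str, str], int] = {}
    flows: dict[tuple[str, str, str], float] = {}
    objective = 0.0
    for k, e in enumerate(q.edges):
        f_int = flow_dict[e.source][e.target][("e", k)] + q.lower[k]
        key = (e.source, e.target, e.receptor)
        flows_int[key] = f_int
        f = f_int / q.flow_scale
        flows[key] = f
        objective += f * e.cost
    return FlowSolution(
        flows=flows,
        objective=objective,
        feasible=True,
        flows_int=flows_int,
        fixed_cost_int=rp.fixed_cost,
        residual_cost_int=int(residual_cost),
        flow_scale=q.flow_scale,
        cost_scale=q.cost_scale,
    )


def solve_with_relaxation(
    graph: FlowGraph,
    config: InferenceConfig,
    max_halvings: int = 10,
) -> tuple[FlowSolution, float]:
    """Solve; on infeasibility, halve all lower bounds (equivalently the
    prior fraction epsilon) up to `max_halvings` times until feasible.

    Returns (solution, factor) where factor is the final multiplier applied
    to the lower bounds (1.0 when no relaxation was needed).
    """
    factor = 1.0
    current = graph
    sol = solve(current, config)
    halvings = 0
    while not sol.feasible and halvings < max_halvings:
        factor /= 2.0
        halvings += 1
        current = FlowGraph(
            nodes=list(graph.nodes),
            edges=[
                ReceptorEdge(
                    source=e.source,
                    target=e.target,
                    receptor=e.receptor,
                    distance=e.distance,
                    affinity_aggregate=e.affinity_aggregate,
                    lower=e.lower * factor,
                    upper=e.upper,
                    cost=e.cost,
                )
                for e in graph.edges
            ],
            balance=dict(graph.balance),
        )
        sol = solve(current, config)
    return sol, factor


def lp_oracle(graph: FlowGraph, max_edges: int = 500) -> FlowSolution:
    """Continuous LP solve of the bounded circulation (HiGHS), for
    verification on small instances only."""
    m = len(graph.edges)
    if m > max_edges:
        raise ValueError(f"lp_oracle is guarded to <= {max_edges} edges (got {m})")
    if m == 0:
        return FlowSolution(flows={}, objective=0.0, feasible=True)
    node_idx = {n: k for k, n in enumerate(graph.nodes)}
    a_eq = np.zeros((len(graph.nodes), m))
    for k, e in enumerate(graph.edges):
        a_eq[node_idx[e.source], k] += 1.0
        a_eq[node_idx[e.target], k] -= 1.0
    b_eq = np.array([graph.balance_of(n) for n in graph.nodes])
    c = np.array([e.cost for e in graph.edges])
    bounds = [(e.lower, e.upper) for e in graph.edges]
    res = linprog(c, A_eq=a_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status == 2:
        return FlowSolution(flows={}, objective=float("nan"), feasible=False)
    if res.status != 0:
        raise RuntimeError(f"LP solver failed with status {res.status}: {res.message}")
    flows = {
        (e.source, e.target, e.receptor): float(res.x[k])
        for k, e in enumerate(graph.edges)
    }
    return FlowSolution(flows=flows, objective=float(res.fun), feasible=True)
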