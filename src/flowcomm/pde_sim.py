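"""Reaction-diffusion ground truth for intercellular signaling.

Cells sit on a square lattice. Each secreting cell produces ligand that
diffuses over the lattice (no-flux boundaries), degrades first-order, and
is consumed by binding to free receptors. For every (source cell, ligand)
with nonzero production we solve the steady state of

    du/dt = (D/h^2) * Lap(u) - k_deg*u - sum_R k_on*u*R_free(x) + p * delta_source

where the free receptor amount is shared by all ligand fields and obeys
the binding equilibrium

    R_free(x) = R_tot(x) / (1 + sum_L (k_on/k_off) * u_total_L(x)),

resolved by a damped fixed-point iteration (inner solves are sparse and
exact). Ground-truth communication from source i to target j via (L, R) is
the equilibrium bound complex (k_on/k_off) * u_iL(x_j) * R_free_R(x_j).

Three benchmark regimes vary the ligand/receptor cardinalities: type1 has
many ligands competing for few receptors, type2 the reverse, type3 a dense
random bipartite network (both sides >= 3, density >= 0.4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .ccc_graph import ExpressionMatrix, SpatialMap
from .lr_prior import LRDatabase, LRPair

__all__ = [
    "KineticParams",
    "Scenario",
    "GroundTruth",
    "make_scenario",
    "simulate_steady_state",
    "mass_balance_residual",
    "extract_ground_truth",
    "scenario_to_inputs",
]


@dataclass
class KineticParams:
    """Kinetic and numerical parameters of the simulator.

    D       ligand diffusion coefficient (length^2 / time)
    k_prod  production-rate scale (amount / time); per-cell rates are drawn
            log-uniform over [0.1, 1] * k_prod
    k_deg   first-order degradation rate (1 / time); > 0 so a steady state
            exists
    k_on    binding rate (1 / (amount * time))
    k_off   unbinding rate (1 / time)
    h       lattice spacing (length)
    tol     relative fixed-point tolerance on the free-receptor field
    max_outer  fixed-point iteration cap
    """

    D: float = 1.0
    k_prod: float = 1.0
    k_deg: float = 0.5
    k_on: float = 1.0
    k_off: float = 1.0
    h: float = 1.0
    tol: float = 1e-8
    max_outer: int = 500

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("D must be > 0")
        if self.k_deg <= 0:
            raise ValueError("k_deg must be > 0 (steady state requires degradation)")
        if min(self.k_prod, self.k_on, self.k_off) < 0:
            raise ValueError("rates must be >= 0")
        if self.h <= 0:
            raise ValueError("h must be > 0")


@dataclass
class Scenario:
    """A synthetic tissue: lattice cells, molecule panels, wiring, rates."""

    regime: str
    cells: list[str]
    positions: dict[str, tuple[float, float]]
    ligands: list[str]
    receptors: list[str]
    connectivity: frozenset  # of (ligand, receptor)
    production: np.ndarray  # cells x ligands, amount/time
    receptor_total: np.ndarray  # cells x receptors, amount
    seed: int

    @property
    def side(self) -> int:
        return int(round(math.sqrt(len(self.cells))))


@dataclass
class GroundTruth:
    """(source, target, ligand, receptor) -> steady-state bound complex."""

    amounts: dict[tuple[str, str, str, str], float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"source": i, "target": j, "ligand": lg, "receptor": rc, "amount": v}
            for (i, j, lg, rc), v in sorted(self.amounts.items())
        ]
        return pd.DataFrame(rows, columns=["source", "target", "ligand", "receptor", "amount"])


def _bernoulli_subset(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Boolean mask with at least one True (empty draws get one random hit)."""
    mask = rng.random(n) < p
    if not mask.any():
        mask[rng.integers(n)] = True
    return mask


def _draw_connectivity(
    rng: np.random.Generator, regime: str, ligands: list[str], receptors: list[str]
) -> frozenset:
    n_l, n_r = len(ligands), len(receptors)
    adj = rng.random((n_l, n_r)) < 0.5
    # every ligand binds >= 1 receptor and every receptor has >= 1 ligand
    for a in range(n_l):
        if not adj[a].any():
            adj[a, rng.integers(n_r)] = True
    for b in range(n_r):
        if not adj[:, b].any():
            adj[rng.integers(n_l), b] = True
    if regime == "type3":
        while adj.sum() / (n_l * n_r) < 0.4:
            zeros = np.argwhere(~adj)
            a, b = zeros[rng.integers(len(zeros))]
            adj[a, b] = True
    return frozenset(
        (ligands[a], receptors[b]) for a in range(n_l) for b in range(n_r) if adj[a, b]
    )


def make_scenario(
    regime: str,
    n_cells: int = 25,
    n_ligands: int = 4,
    n_receptors: int = 2,
    params: KineticParams | None = None,
    seed: int = 0,
    secretion_prob: float = 0.5,
    display_prob: float = 0.5,
    receptor_scale: float = 1.0,
) -> Scenario:
    """Draw a reproducible synthetic tissue for one benchmark regime.

    Cells occupy a sqrt(n) x sqrt(n) lattice with spacing h. Every cell
    secretes a random subset of ligands (rate log-uniform over
    [0.1, 1]*k_prod) and displays a random subset of receptors (amount
    log-uniform over [0.1, 1]*receptor_scale); empty subsets are topped up
    with one random symbol so each cell both sends and receives.
    """
    if regime not in ("type1", "type2", "type3"):
        raise ValueError(f"unknown regime {regime!r}")
    if regime == "type1" and not n_ligands > n_receptors:
        raise ValueError("type1 requires more ligands than receptors")
    if regime == "type2" and not n_receptors > n_ligands:
        raise ValueError("type2 requires more receptors than ligands")
    if regime == "type3" and (n_ligands < 3 or n_receptors < 3):
        raise ValueError("type3 requires at least 3 ligands and 3 receptors")
    side = int(round(math.sqrt(n_cells)))
    if side * side != n_cells:
        raise ValueError(f"n_cells must be a square number, got {n_cells}")
    params = params or KineticParams()
    rng = np.random.default_rng(seed)

    ligands = [f"LG{k + 1}" for k in range(n_ligands)]
    receptors = [f"RC{k + 1}" for k in range(n_receptors)]
    cells = [f"c{k:03d}" for k in range(n_cells)]
    positions = {
        cells[r * side + c]: (c * params.h, r * params.h)
        for r in range(side)
        for c in range(side)
    }

    connectivity = _draw_connectivity(rng, regime, ligands, receptors)

    production = np.zeros((n_cells, n_ligands))
    for k in range(n_cells):
        mask = _bernoulli_subset(rng, n_ligands, secretion_prob)
        rates = np.exp(rng.uniform(math.log(0.1), math.log(1.0), n_ligands)) * params.k_prod
        production[k, mask] = rates[mask]
    receptor_total = np.zeros((n_cells, n_receptors))
    for k in range(n_cells):
        mask = _bernoulli_subset(rng, n_receptors, display_prob)
        amounts = np.exp(rng.uniform(math.log(0.1), math.log(1.0), n_receptors)) * receptor_scale
        receptor_total[k, mask] = amounts[mask]

    return Scenario(
        regime=regime,
        cells=cells,
        positions=positions,
        ligands=ligands,
        receptors=receptors,
        connectivity=connectivity,
        production=production,
        receptor_total=receptor_total,
        seed=seed,
    )


def _lattice_laplacian(side: int) -> sp.csr_matrix:
    """Graph Laplacian of the side x side grid (no-flux boundaries):
    Lap(u) = sum_neighbors (u_n - u)."""
    n = side * side
    rows, cols, vals = [], [], []
    for r in range(side):
        for c in range(side):
            k = r * side + c
            deg = 0
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < side and 0 <= cc < side:
                    rows.append(k)
                    cols.append(rr * side + cc)
                    vals.append(1.0)
                    deg += 1
            rows.append(k)
            cols.append(k)
            vals.append(-float(deg))
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def simulate_steady_state(
    scenario: Scenario, params: KineticParams
) -> tuple[dict[tuple[str, str], np.ndarray], np.ndarray]:
    """Converged per-(source, ligand) ligand fields and shared free receptors.

    Returns (fields, R_free): fields maps (source cell id, ligand) with
    nonzero production to its steady field over all cells; R_free is a
    cells x receptors array. The R_free used in the final linear solves is
    returned, so mass balance holds to solver precision.
    """
    n = len(scenario.cells)
    side = scenario.side
    lap = _lattice_laplacian(side)
    diff = (params.D / params.h**2) * lap
    lig_idx = {lg: a for a, lg in enumerate(scenario.ligands)}
    rec_idx = {rc: b for b, rc in enumerate(scenario.receptors)}
    partners = {
        lg: [rec_idx[rc] for (l2, rc) in scenario.connectivity if l2 == lg]
        for lg in scenario.ligands
    }
    sources = {
        lg: np.flatnonzero(scenario.production[:, lig_idx[lg]] > 0)
        for lg in scenario.ligands
    }
    kon, koff = params.k_on, params.k_off
    k_eq = kon / koff if koff > 0 else 0.0

    r_free = scenario.receptor_total.copy()
    fields_by_ligand: dict[str, np.ndarray] = {}
    for _ in range(params.max_outer):
        # inner: exact solve of every source field given the current R_free
        for lg in scenario.ligands:
            src = sources[lg]
            if len(src) == 0:
                continue
            sink = np.full(n, params.k_deg)
            if kon > 0:
                for b in partners[lg]:
                    sink = sink + kon * r_free[:, b]
            a_mat = sp.diags(sink) - diff
            rhs = np.zeros((n, len(src)))
            for col, k in enumerate(src):
                rhs[k, col] = scenario.production[k, lig_idx[lg]]
            fields_by_ligand[lg] = splu(a_mat.tocsc()).solve(rhs)

        # equilibrium target for the shared free receptors
        target = scenario.receptor_total.copy()
        for b, rc in enumerate(scenario.receptors):
            occ = np.zeros(n)
            if k_eq > 0:
                for lg in scenario.ligands:
                    if (lg, rc) in scenario.connectivity and lg in fields_by_ligand:
                        occ += k_eq * fields_by_ligand[lg].sum(axis=1)
            target[:, b] = scenario.receptor_total[:, b] / (1.0 + occ)

        scale = max(scenario.receptor_total.max(), 1e-300)
        change = np.abs(target - r_free).max() / scale
        if change < params.tol:
            break
        r_free = 0.5 * r_free + 0.5 * target  # damped update
    else:
        raise RuntimeError(
            f"free-receptor fixed point did not converge in {params.max_outer} "
            f"iterations (last relative change {change:.3e})"
        )

    fields: dict[tuple[str, str], np.ndarray] = {}
    for lg, mat in fields_by_ligand.items():
        for col, k in enumerate(sources[lg]):
            fields[(scenario.cells[k], lg)] = mat[:, col].copy()
    return fields, r_free


def mass_balance_residual(
    fields: dict[tuple[str, str], np.ndarray],
    r_free: np.ndarray,
    scenario: Scenario,
    params: KineticParams,
) -> float:
    """Relative |production - (degradation + binding consumption)| at steady
    state, summed over all fields (diffusion redistributes, so it cancels)."""
    rec_idx = {rc: b for b, rc in enumerate(scenario.receptors)}
    lig_idx = {lg: a for a, lg in enumerate(scenario.ligands)}
    cell_idx = {c: k for k, c in enumerate(scenario.cells)}
    total_prod = 0.0
    total_sink = 0.0
    for (cell, lg), u in fields.items():
        total_prod += scenario.production[cell_idx[cell], lig_idx[lg]]
        sink = params.k_deg * u
        for (l2, rc) in scenario.connectivity:
            if l2 == lg:
                sink = sink + params.k_on * r_free[:, rec_idx[rc]] * u
        total_sink += float(sink.sum())
    if total_prod == 0:
        return abs(total_sink)
    return abs(total_prod - total_sink) / total_prod


def extract_ground_truth(
    fields: dict[tuple[str, str], np.ndarray],
    r_free: np.ndarray,
    scenario: Scenario,
    params: KineticParams,
) -> GroundTruth:
    """Equilibrium complexes G(i, j, L, R) = (k_on/k_off) * u_iL(x_j) *
    R_free_R(x_j), zero wherever production or connectivity is zero."""
    k_eq = params.k_on / params.k_off if params.k_off > 0 else 0.0
    rec_idx = {rc: b for b, rc in enumerate(scenario.receptors)}
    amounts: dict[tuple[str, str, str, str], float] = {}
    for (lg, rc) in sorted(scenario.connectivity):
        b = rec_idx[rc]
        for i in scenario.cells:
            u = fields.get((i, lg))
            for jdx, j in enumerate(scenario.cells):
                if u is None:
                    amounts[(i, j, lg, rc)] = 0.0
                else:
                    amounts[(i, j, lg, rc)] = float(k_eq * u[jdx] * r_free[jdx, b])
    return GroundTruth(amounts=amounts)


def scenario_to_inputs(
    scenario: Scenario,
) -> tuple[ExpressionMatrix, SpatialMap, LRDatabase]:
    """Expose a scenario to the inference pipeline: ligand 'expression' is
    the production rate, receptor 'expression' the total receptor amount,
    the database is the true connectivity (affinity 1, prior-confident)."""
    genes = list(scenario.ligands) + list(scenario.receptors)
    values = np.hstack([scenario.production, scenario.receptor_total])
    expr = ExpressionMatrix(cells=list(scenario.cells), genes=genes, values=values)
    spatial = SpatialMap(coords=dict(scenario.positions))
    db = LRDatabase(
        LRPair(ligand=lg, receptor=rc, affinity=1.0, prior_confident=True)
        for (lg, rc) in sorted(scenario.connectivity)
    )
    return expr, spatial, db
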