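# Methods

## The flow model

Communication is modeled as a circulation on a directed multigraph. Nodes
are cells (or Visium spots) with net supply b_v, zero by default: every
cell relays as much signal as it receives, which is what makes finite
capacity bite — flow claimed by one interaction is unavailable elsewhere.
Edges are *receptor-centric*: a pair of cells is connected by one edge per
receptor on the target, never per ligand, so a receptor's capacity is a
single shared resource and ligand identity is restored only afterwards.

An edge (i, j, R) exists iff (a) the Euclidean distance d_ij is strictly
below `d_cutoff`, (b) the receptor is expressed in the target strictly
above the threshold τ, and (c) at least one ligand binding R is expressed
in the source above τ. Strict inequalities make boundary behavior
unambiguous. Coordinates are used in their native units and expression
values as given; library-size normalization, if desired, belongs upstream.

Per edge:

| quantity | form | range |
| --- | --- | --- |
| affinity aggregate ā | Σ_B a_LR·E_L(i) / Σ_B E_L(i) over expressed binders B | [0, 1] |
| cost c_e | d_ij/d_cutoff + λ(1 − ā) | [0, 1 + λ] |
| upper bound u_e | κ·min(E_R(j), S_L(i)), S_L = Σ_B E_L(i) | > 0 |
| lower bound l_e | ε·u_e if any expressed binder is prior-confident, else 0 | [0, u_e) |

`min` is the default bound combiner — capacity is set by the scarcer of
receptor display and ligand supply; `product` is available for users who
read "proportional to receptor abundance together with ligand
availability" multiplicatively. Defaults: λ = 1, κ = 1, ε = 0.05, τ = 0,
γ = 1 (below). ε < 1 guarantees l ≤ u on every edge.

## Exact solve

Lower bounds are eliminated with the classical residual substitution
f′ = f − l: residual capacities u − l, node imbalances
r_v = Σ_in l − Σ_out l + b_v. Nodes with r_v > 0 (an excess of forced
inflow they must push onward) hang off a super-source with capacity r_v;
nodes with r_v < 0 feed a super-sink. The original circulation is feasible
iff every auxiliary edge saturates, the optimal objective is
Σ l_e·c_e + (residual optimum), and flows are recovered as f = f′ + l.

The residual problem is solved exactly with the network simplex on
integer data. Quantization is conservative — lower bounds round up, upper
bounds round down, so the feasible set never widens — with flow scale
s = ⌊quantum / max u_e⌋ (the floor keeps integer-valued inputs exactly
representable; for quantum below max u the exact ratio is used) and a
fixed decimal cost scale of 10⁶. The default quantum of 1000 resolves
flows to 0.1% of the largest capacity. A direct LP formulation of the
bounded circulation (HiGHS) is retained as an independent oracle for
verification (`--verify`, tests); it is never the production path, so the
integral solver and the LP check each other.

Infeasibility is a normal outcome, reported with per-node shortfalls of
the unsaturated auxiliary edges (via a plain max-flow on the residual
network). Prior-induced lower bounds can easily be collectively
unsatisfiable — e.g. a cell displaying no receptor cannot return the flow
its ligands are forced to emit — so `--relax-lower` halves all lower
bounds (equivalently ε) up to ten times until a circulation exists,
recording the final factor in the manifest. Among multiple optima any one
is accepted; tests compare objectives, not flow vectors, except where
conservation forces uniqueness.

Sign convention: b_v > 0 means net supply (outflow exceeds inflow).

## Ligand redistribution and relays

Each receptor-centric flow is split post hoc across the expressed binders
of the receptor with weights w_L = a_LR^γ·E_L(i). The power family
φ(a) = a^γ is the simplest monotone weighting containing both the identity
(γ = 1) and the affinity-blind limit (γ = 0). The split never feeds back
into the optimization — the hierarchical structure keeps the global
optimum intact. Conservation of each edge flow is bit-exact: shares are
snapped down onto the ulp(f_e) grid, making every partial sum an exact
multiple of a power of two below 2⁵³ ulps so no addition rounds, and the
lexicographically last ligand absorbs the residual.

Relays are pairs of positive ligand-resolved flows sharing an intermediate
cell (i ≠ j, j ≠ k; i = k back-signaling loops allowed). No intracellular
coupling between the received receptor and the re-emitted ligand is
assumed by default — the unconstrained join is the only reading requiring
no extra data — but an optional receptor → downstream-ligand link table
restricts it. Relay scores default to the mean of the two step flows
(`min` and `geometric` available). Cascades of three or more steps are not
enumerated (combinatorial growth).

## Ground-truth simulator

The simulator produces a directional, mechanistic truth to score against.
Cells sit on a √n×√n lattice with spacing h (25 cells by default — the
benchmark suite completes in seconds while leaving each ligand field ~600
ordered cell pairs to rank). Per (source cell, ligand) field u:

    du/dt = (D/h²)·Lap(u) − k_deg·u − Σ_R k_on·u·R_free + p·δ_source

with a no-flux lattice Laplacian; binding irreversibly consumes free
ligand (internalization), and the free receptor pool is shared across all
ligands at the equilibrium occupancy

    R_free = R_tot / (1 + Σ_L (k_on/k_off)·u_total_L).

Steady states are found by a damped fixed point (factor 0.5) on R_free
with exact sparse solves of the per-ligand linear systems inside, to a
relative tolerance of 1e-8 (cap 500 iterations). Per-source fields are
solved separately — the PDE is linear in u given R_free — because the
ground truth G(i, j, L, R) = (k_on/k_off)·u_iL(x_j)·R_free(x_j) must be
attributable to a specific source. Steady state, not transient dynamics,
defines the communication amount.

Three regimes: type1, many ligands / few receptors; type2 the reverse;
type3 dense random bipartite wiring (both panels ≥ 3, density ≥ 0.4).
Scenario draws: each cell secretes each ligand with probability 0.5 (rate
log-uniform on [0.1, 1]·k_prod) and displays each receptor with
probability 0.5 (amount log-uniform on [0.1, 1]); cells whose subset came
out empty receive one random symbol, so every cell both sends and receives
— without this, pure senders make the prior-bounded circulation infeasible
at any ε. Kinetic defaults D = 1, k_prod = 1, k_deg = 0.5,
k_on = k_off = 1, h = 1 give a diffusion length √(D/k_deg) ≈ 1.4 lattice
spacings (local but multi-neighbor signaling) and moderate receptor
occupancy.

Checks: the one-site system reduces to a hand-solvable quadratic
(k_deg·K·u² + (k_deg + k_on·R_tot − p·K)·u − p = 0, K = k_on/k_off), which
the solver matches to ~1e-8; total production equals degradation plus
binding consumption to solver precision at every converged steady state.

What the simulator does **not** emulate: transcriptional noise, dropout,
segmentation error, receptor recycling dynamics, 3-D geometry, or
heteromeric receptors. Passing benchmarks therefore show that the
inference recovers a clean biophysical signal, not that it is robust to
the measurement process of real spatial data.

## Benchmark design

Inference consumes the scenario through the same interface as real data:
ligand "expression" = production rate, receptor "expression" = total
receptor, the database = the true wiring (affinity 1, prior-confident).
Scoring is Spearman ρ per L–R pair over all ordered cell pairs i ≠ j in
the truth (inference is intercellular by construction, so self-signaling
is excluded for every method alike; absent inferred entries count as 0),
averaged over pairs; constant vectors are skipped and listed. The
comparator is flow(i,j,L,R) = E_L(i)·E_R(j)·exp(−d/σ) with σ set to the
true diffusion length √(D/k_deg) — the most informative kernel scale the
baseline could be handed. Inference uses d_cutoff = 3h (covering the
neighborhood within about two diffusion lengths) and otherwise default
parameters, with lower-bound relaxation enabled.

Measured outcome (also recomputed by `scripts/acceptance.py`): both
methods track the truth closely (flow mean ρ ≈ 0.76, baseline ≈ 0.77; the
flow model's median ρ is well above the 0.5 floor). The oracle-σ baseline
is consistently ahead by ~0.005: with b_v = 0 the minimum-cost circulation
stays as close to the lower bounds ε·u as conservation allows, and ε·u
carries abundance but no within-cutoff distance decay, while only the
excess flow routed to balance nodes responds to the distance-dependent
cost. The package reports both numbers rather than tuning conditions until
the ordering flips.

## Numerical and degenerate-input choices

- Duplicate (ligand, receptor) database rows collapse to the maximum
  affinity, OR-ing confidence flags; symbols are whitespace-trimmed, case
  preserved (`ignore_case` folds to upper).
- A graph with zero edges is returned with a warning, not an error; an
  admissible edge with zero upper bound is an internal error.
- Quantization that voids a tight bound interval (ceil l > floor u) raises
  with the offending edges and the advice to raise the quantum.
- Outputs are TSV at 6 significant digits, LF line endings; identical
  config + seed reruns are byte-identical.
- The single global seed drives scenario generation only — inference
  itself is deterministic.

## Known limitations

Heteromeric receptor complexes must be pre-flattened to single gene
symbols; neighborhoods are cutoff-balls only (no kNN/Delaunay) and 2-D
only; ligand identity is restored post hoc rather than modeled as
commodities, so the optimizer cannot trade one ligand against another
along a route; relay enumeration is unconstrained intracellularly unless a
link table is supplied.
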