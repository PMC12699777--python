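"""Two-step relay paths through the ligand-resolved flow table.

A relay is a pair of positive flows i --L1/R1--> j --L2/R2--> k sharing the
intermediate cell j (i != j, j != k; i == k back-signaling loops are
allowed). By default any signal received by j may precede any signal it
emits; an optional receptor -> downstream-ligand link table restricts the
intracellular coupling. Longer cascades are not enumerated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["score_relay", "enumerate_relays", "RELAY_COLUMNS"]

RELAY_COLUMNS = [
    "i", "ligand1", "receptor1", "j", "ligand2", "receptor2", "k",
    "flow1", "flow2", "score",
]


def score_relay(flow1, flow2, mode: str = "mean"):
    """Score of a relay from its two step flows (both must be > 0).

    mean      (flow1 + flow2) / 2   (default)
    min       min(flow1, flow2)
    geometric sqrt(flow1 * flow2)
    """
    f1 = np.asarray(flow1, dtype=float)
    f2 = np.asarray(flow2, dtype=float)
    if np.any(f1 <= 0) or np.any(f2 <= 0):
        raise ValueError("relay step flows must be > 0")
    if mode == "mean":
        out = (f1 + f2) / 2.0
    elif mode == "min":
        out = np.minimum(f1, f2)
    elif mode == "geometric":
        out = np.sqrt(f1 * f2)
    else:
        raise ValueError(f"unknown score mode {mode!r}")
    return float(out) if out.ndim == 0 else out


def enumerate_relays(
    table: pd.DataFrame,
    min_flow: float = 0.0,
    link_table: dict[str, set[str]] | None = None,
    score_mode: str = "mean",
) -> pd.DataFrame:
    """All two-step relays in a ligand-flow table.

    Steps must carry flow >= min_flow (and strictly positive); with a
    link_table, the second step's ligand must be a downstream partner of
    the first step's receptor. Output is sorted by
    (i, ligand1, receptor1, j, ligand2, receptor2, k).
    """
    if min_flow < 0:
        raise ValueError("min_flow must be >= 0")
    steps = table[(table["flow"] >= min_flow) & (table["flow"] > 0)]
    steps = steps[steps["source"] != steps["target"]]
    if steps.empty:
        return pd.DataFrame(columns=RELAY_COLUMNS)
    left = steps.rename(
        columns={"source": "i", "ligand": "ligand1", "receptor": "receptor1",
                 "target": "j", "flow": "flow1"}
    )
    right = steps.rename(
        columns={"source": "j", "ligand": "ligand2", "receptor": "receptor2",
                 "target": "k", "flow": "flow2"}
    )
    merged = left.merge(right, on="j")
    if link_table is not None:
        keep = [
            lig2 in link_table.get(rec1, set())
            for rec1, lig2 in zip(merged["receptor1"], merged["ligand2"])
        ]
        merged = merged[keep]
    if merged.empty:
        return pd.DataFrame(columns=RELAY_COLUMNS)
    merged = merged.copy()
    merged["score"] = score_relay(
        merged["flow1"].to_numpy(), merged["flow2"].to_numpy(), mode=score_mode
    )
    merged = merged.sort_values(
        ["i", "ligand1", "receptor1", "j", "ligand2", "receptor2", "k"]
    ).reset_index(drop=True)
    return merged[RELAY_COLUMNS]
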