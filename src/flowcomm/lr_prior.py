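"""Ligand-receptor prior-knowledge database.

Models curated ligand->receptor binding pairs (CellPhoneDB/CellChat-style
exports, pre-flattened to single gene symbols) with an optional per-pair
binding affinity in (0, 1] and a prior-confidence flag. Confident pairs
later induce nonzero lower bounds on the communication flow; affinities
enter both the edge cost and the ligand-level flow redistribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = ["LRPair", "LRDatabase", "load_lr_database"]

_TRUE = {"true", "1", "t", "yes"}
_FALSE = {"false", "0", "f", "no"}


@dataclass(frozen=True)
class LRPair:
    """A single ligand->receptor binding relationship.

    affinity is a dimensionless binding weight in (0, 1]; prior_confident
    marks pairs whose prior support is strong enough to force a lower bound
    on flow.
    """

    ligand: str
    receptor: str
    affinity: float = 1.0
    prior_confident: bool = True

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor:
            raise ValueError("ligand and receptor symbols must be non-empty")
        if not (0.0 < self.affinity <= 1.0):
            raise ValueError(
                f"affinity must be in (0, 1], got {self.affinity!r} "
                f"for pair ({self.ligand}, {self.receptor})"
            )


class LRDatabase:
    """Set of LRPair with a receptor-keyed binder index.

    The binder index maps each receptor to the lexicographically sorted
    list of (ligand, affinity, prior_confident) tuples that can bind it.
    """

    def __init__(self, pairs: Iterable[LRPair]):
        pairs = list(pairs)
        seen = set()
        for p in pairs:
            key = (p.ligand, p.receptor)
            if key in seen:
                raise ValueError(f"duplicate ligand-receptor pair {key}")
            seen.add(key)
        self._pairs = tuple(sorted(pairs, key=lambda p: (p.ligand, p.receptor)))
        index: dict[str, list[tuple[str, float, bool]]] = {}
        for p in self._pairs:
            index.setdefault(p.receptor, []).append(
                (p.ligand, p.affinity, p.prior_confident)
            )
        for r in index:
            index[r].sort(key=lambda t: t[0])
        self._binder_index = index

    @property
    def pairs(self) -> tuple[LRPair, ...]:
        return self._pairs

    @property
    def receptors(self) -> list[str]:
        return sorted(self._binder_index)

    @property
    def ligands(self) -> list[str]:
        return sorted({p.ligand for p in self._pairs})

    def binders(self, receptor: str) -> list[tuple[str, float, bool]]:
        """(ligand, affinity, prior_confident) binders of `receptor`, sorted
        by ligand; empty for unknown receptors."""
        return list(self._binder_index.get(receptor, []))

    def __len__(self) -> int:
        return len(self._pairs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LRDatabase) and self._pairs == other._pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ligand": [p.ligand for p in self._pairs],
                "receptor": [p.receptor for p in self._pairs],
                "affinity": [p.affinity for p in self._pairs],
                "prior_confident": [p.prior_confident for p in self._pairs],
            }
        )


def _parse_bool(value: object, row: int) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and not pd.isna(value):
        if value in (0, 1):
            return bool(value)
        raise ValueError(f"row {row}: prior_confident must be true/false/1/0, got {value!r}")
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"row {row}: prior_confident must be true/false/1/0, got {value!r}")


def database_from_frame(
    df: pd.DataFrame,
    default_affinity: float = 1.0,
    ignore_case: bool = False,
) -> LRDatabase:
    """Build an LRDatabase from a table with columns ligand, receptor
    [, affinity][, prior_confident].

    Missing affinity -> default_affinity; missing prior_confident -> True.
    Duplicate (ligand, receptor) rows collapse to the maximum affinity,
    OR-ing the confidence flags. Symbols are whitespace-trimmed; case is
    preserved unless ignore_case folds everything to upper case.
    """
    if not (0.0 < default_affinity <= 1.0):
        raise ValueError("default_affinity must be in (0, 1]")
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column '{col}'")
    if len(df) == 0:
        raise ValueError("ligand-receptor table contains no data rows")

    best: dict[tuple[str, str], tuple[float, bool]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        lig = str(rec["ligand"]).strip()
        r = str(rec["receptor"]).strip()
        if ignore_case:
            lig, r = lig.upper(), r.upper()
        if not lig or not r or lig.lower() == "nan" or r.lower() == "nan":
            raise ValueError(f"row {row_no}: empty ligand or receptor symbol")
        aff = rec.get("affinity")
        if aff is None or pd.isna(aff):
            aff = default_affinity
        else:
            aff = float(aff)
            if not (0.0 < aff <= 1.0):
                raise ValueError(f"row {row_no}: affinity {aff} outside (0, 1]")
        conf = rec.get("prior_confident")
        conf = True if conf is None or (not isinstance(conf, str) and pd.isna(conf)) \
            else _parse_bool(conf, row_no)
        key = (lig, r)
        if key in best:
            old_aff, old_conf = best[key]
            best[key] = (max(old_aff, aff), old_conf or conf)
        else:
            best[key] = (aff, conf)

    return LRDatabase(
        LRPair(ligand=k[0], receptor=k[1], affinity=v[0], prior_confident=v[1])
        for k, v in best.items()
    )


def load_lr_database(
    path: str | Path,
    default_affinity: float = 1.0,
    ignore_case: bool = False,
) -> LRDatabase:
    """Load a ligand-receptor database from a delimited text file.

    Comma or tab delimiter is auto-detected; a header row with at least
    `ligand` and `receptor` columns is required.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty ligand-receptor file") from None
    df.columns = [str(c).strip() for c in df.columns]
    return database_from_frame(df, default_affinity=default_affinity, ignore_case=ignore_case)
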