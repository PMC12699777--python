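"""Readers and writers for expression matrices, coordinates and flow tables.

Expression accepts either a dense delimited table (first column = cell ids,
header = gene symbols) or a Matrix Market triplet directory (one .mtx file
plus gene and barcode id lists). All outputs are TSV/CSV with LF line
endings and 6 significant digits, so reruns diff cleanly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .ccc_graph import ExpressionMatrix, InferenceConfig, SpatialMap

__all__ = [
    "RunConfig",
    "read_expression",
    "write_expression",
    "read_coords",
    "write_coords",
    "read_flow_table",
    "write_flow_table",
    "write_manifest",
]


@dataclass
class RunConfig:
    """Everything one inference run needs; the manifest reproduces it."""

    expression: str
    coords: str
    lrdb: str
    outdir: str
    d_cutoff: float
    lambda_affinity: float = 1.0
    kappa_upper: float = 1.0
    epsilon_lower: float = 0.05
    expr_threshold: float = 0.0
    bound_combiner: str = "min"
    quantum: int = 1000
    gamma: float = 1.0
    relay_min_flow: float = 0.0
    default_affinity: float = 1.0
    seed: int = 0
    relax_lower: bool = False
    verify: bool = False
    log_level: str = "INFO"

    def inference_config(self) -> InferenceConfig:
        return InferenceConfig(
            d_cutoff=self.d_cutoff,
            lambda_affinity=self.lambda_affinity,
            kappa_upper=self.kappa_upper,
            epsilon_lower=self.epsilon_lower,
            expr_threshold=self.expr_threshold,
            bound_combiner=self.bound_combiner,
            quantum=self.quantum,
        )


def _read_table(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", **kw)


def _read_ids(path: Path) -> list[str]:
    ids = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line:
            ids.append(line.split("\t")[0].split(",")[0])
    return ids


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a cells x genes matrix from a dense table or an MTX triplet
    directory; genes x cells MTX input is transposed automatically."""
    path = Path(path)
    if path.is_dir():
        mtx = sorted(path.glob("*.mtx"))
        if not mtx:
            raise ValueError(f"{path}: no .mtx file in triplet directory")
        mat = scipy.io.mmread(mtx[0])
        mat = mat.toarray() if sp.issparse(mat) else np.asarray(mat)
        genes_file = next((path / n for n in ("genes.txt", "features.txt", "genes.tsv", "features.tsv") if (path / n).exists()), None)
        barcodes_file = next((path / n for n in ("barcodes.txt", "barcodes.tsv") if (path / n).exists()), None)
        if genes_file is None or barcodes_file is None:
            raise ValueError(f"{path}: triplet directory needs gene and barcode id files")
        genes = _read_ids(genes_file)
        cells = _read_ids(barcodes_file)
        if mat.shape == (len(genes), len(cells)):
            mat = mat.T
        elif mat.shape != (len(cells), len(genes)):
            raise ValueError(
                f"{mtx[0].name}: shape {mat.shape} matches neither "
                f"cells x genes ({len(cells)}, {len(genes)}) nor its transpose"
            )
        return ExpressionMatrix(cells=cells, genes=genes, values=mat)
    df = _read_table(path, index_col=0)
    return ExpressionMatrix(
        cells=[str(c) for c in df.index],
        genes=[str(g) for g in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=expr.cells, columns=expr.genes)
    df.index.name = "cell"
    df.to_csv(path, lineterminator="\n")


def read_coords(path: str | Path) -> SpatialMap:
    df = _read_table(Path(path))
    for col in ("cell", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"coordinates file missing column '{col}'")
    coords: dict[str, tuple[float, float]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        cell = str(row.cell)
        if cell in coords:
            raise ValueError(f"row {row_no}: duplicate cell {cell!r}")
        try:
            coords[cell] = (float(row.x), float(row.y))
        except (TypeError, ValueError):
            raise ValueError(f"row {row_no}: non-numeric coordinate for {cell!r}") from None
    return SpatialMap(coords=coords)


def write_coords(spatial: SpatialMap, path: str | Path) -> None:
    df = pd.DataFrame(
        [{"cell": c, "x": x, "y": y} for c, (x, y) in sorted(spatial.coords.items())]
    )
    df.to_csv(path, index=False, lineterminator="\n")


def write_flow_table(df: pd.DataFrame, path: str | Path) -> None:
    """TSV with 6 significant digits on float columns."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def read_flow_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
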