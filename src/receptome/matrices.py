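"""Square/rectangular similarity containers and delimited-text round-trip I/O.

Matrices travel as TSV (row ids in the first column, column ids in the
header) with a JSON sidecar recording ids, kind and provenance so that a
write → read round trip is lossless to 1e-12.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimilarityMatrix", "read_matrix", "write_matrix"]

_KINDS = {"receptome", "FC", "SC", "MPC", "affinity", "cross", "generic"}


@dataclass
class SimilarityMatrix:
    """A labelled similarity/connectivity matrix.

    ``kind`` distinguishes the receptome (Spearman similarities, unit
    diagonal, [-1, 1]) from FC/SC/MPC matrices and from [0, 1] affinities.
    Rectangular cross-compartment matrices carry distinct row/col ids.
    """

    values: np.ndarray
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)
    kind: str = "generic"
    symmetric: bool | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, m = self.values.shape
        if not self.row_ids:
            self.row_ids = [f"r{i}" for i in range(n)]
        if not self.col_ids:
            self.col_ids = list(self.row_ids) if n == m else [f"c{j}" for j in range(m)]
        if len(self.row_ids) != n or len(self.col_ids) != m:
            raise ValueError("id lengths do not match matrix shape")
        if self.kind not in _KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.symmetric is None:
            self.symmetric = n == m and bool(np.allclose(self.values, self.values.T))
        if self.kind == "receptome":
            if not self.symmetric:
                raise ValueError("receptome must be symmetric")
            if np.nanmax(np.abs(self.values)) > 1 + 1e-9:
                raise ValueError("receptome entries must lie in [-1, 1]")
        if self.kind == "affinity":
            if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-9:
                raise ValueError("affinity entries must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


def write_matrix(mat: SimilarityMatrix, path: str | Path) -> Path:
    """Write a matrix as TSV plus a JSON sidecar (same stem, .json)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = mat.to_frame()
    df.to_csv(path, sep="\t", index_label="id", float_format="%.17g")
    sidecar = {
        "row_ids": list(mat.row_ids),
        "col_ids": list(mat.col_ids),
        "kind": mat.kind,
        "symmetric": bool(mat.symmetric),
        "meta": mat.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_matrix(path: str | Path) -> SimilarityMatrix:
    """Read a TSV matrix; warns and auto-generates ids if the sidecar is gone."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"parse error in {path}: {exc}") from exc
    side_path = path.with_suffix(path.suffix + ".json")
    if side_path.exists():
        side = json.loads(side_path.read_text())
        return SimilarityMatrix(
            values=values,
            row_ids=list(side["row_ids"]),
            col_ids=list(side["col_ids"]),
            kind=side.get("kind", "generic"),
            symmetric=side.get("symmetric"),
            meta=side.get("meta", {}),
        )
    warnings.warn(f"missing sidecar for {path}; ids auto-generated from the TSV header")
    return SimilarityMatrix(
        values=values,
        row_ids=[str(i) for i in df.index],
        col_ids=[str(c) for c in df.columns],
    )
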