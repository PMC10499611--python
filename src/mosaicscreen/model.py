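"""Shared data types of the screen readout and per-cell-type summaries.

Cell metadata lives in a plain pandas DataFrame with a fixed column
contract (``validate_cell_meta``); the expression matrix is a small
dataclass bundling the log-normalized cells x genes matrix with gene
names and per-cell total UMI counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file or table does not follow the expected column layout."""


class ValidationError(ValueError):
    """A table is well-formed but violates a content invariant."""


#: Cell-type vocabulary of the telencephalon organoid screen. Dorsal
#: progenitors and neurons, ventral progenitors and interneurons, plus
#: glial populations that carry no trajectory label.
DEFAULT_CELL_TYPES: tuple[str, ...] = (
    "RGC", "ccRGC", "oRGC", "IPC", "L5/6", "CThPN", "L4", "L2/3",
    "v-RGC", "ccv-RGC", "INP", "LGE-IN", "CGE-IN", "LGE PAX6+ IN",
    "astrocyte", "OPC",
)

#: Trajectory membership of the default cell types.
DEFAULT_TRAJECTORY_MAP: dict[str, str] = {
    "RGC": "dorsal", "ccRGC": "dorsal", "oRGC": "dorsal", "IPC": "dorsal",
    "L5/6": "dorsal", "CThPN": "dorsal", "L4": "dorsal", "L2/3": "dorsal",
    "v-RGC": "ventral", "ccv-RGC": "ventral", "INP": "ventral",
    "LGE-IN": "ventral", "CGE-IN": "ventral", "LGE PAX6+ IN": "ventral",
    "astrocyte": "none", "OPC": "none",
}

TRAJECTORIES = ("dorsal", "ventral", "none")

META_COLUMNS = (
    "cell_id", "library_id", "batch_id", "induced", "cell_type",
    "trajectory", "grna_label",
)

CONTROL_LABEL = "control"


def validate_cell_meta(
    meta: pd.DataFrame,
    cell_types: tuple[str, ...] | None = DEFAULT_CELL_TYPES,
    permissive: bool = False,
) -> pd.DataFrame:
    """Validate the per-cell metadata contract and return the table.

    Required columns: cell_id, library_id, batch_id, induced, cell_type,
    trajectory, grna_label (grna_label may be missing/NA). cell_id must be
    unique; trajectory must be dorsal/ventral/none; unknown cell types are
    rejected unless ``permissive`` is set or ``cell_types`` is None.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"cell metadata is missing columns: {missing}")
    dup = meta["cell_id"][meta["cell_id"].duplicated()]
    if len(dup):
        raise ValidationError(
            f"duplicate cell_id values: {sorted(set(dup))[:10]}"
        )
    bad_traj = set(meta["trajectory"].dropna()) - set(TRAJECTORIES)
    if bad_traj:
        raise ValidationError(f"unknown trajectory labels: {sorted(bad_traj)}")
    if cell_types is not None and not permissive:
        unknown = set(meta["cell_type"].dropna()) - set(cell_types)
        if unknown:
            raise ValidationError(f"unknown cell types: {sorted(unknown)}")
    with_grna = meta["grna_label"].notna()
    if meta.loc[with_grna, "library_id"].isna().any():
        raise ValidationError("cells with a grna_label must have a library_id")
    return meta


@dataclass
class ExpressionMatrix:
    """Log-normalized cells x genes expression with per-cell UMI totals."""

    X: np.ndarray  # (n_cells, n_genes) log-normalized, non-negative
    genes: list[str]
    cells: list[str]
    n_umi: np.ndarray | None = None  # (n_cells,) positive ints

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.genes = list(self.genes)
        self.cells = list(self.cells)
        if self.X.shape != (len(self.cells), len(self.genes)):
            raise ValidationError(
                f"matrix shape {self.X.shape} inconsistent with "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        if (self.X < 0).any():
            raise ValidationError("log-normalized expression must be >= 0")
        if self.n_umi is not None:
            self.n_umi = np.asarray(self.n_umi)
            if self.n_umi.shape != (len(self.cells),):
                raise ValidationError("n_umi length must match cell count")
            if (self.n_umi <= 0).any():
                raise ValidationError("n_umi must be positive for every cell")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_index(self, genes: list[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, mask_or_ids) -> "ExpressionMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = {c: i for i, c in enumerate(self.cells)}
            idx = np.array([pos[c] for c in mask_or_ids], dtype=int)
        return ExpressionMatrix(
            X=self.X[idx],
            genes=self.genes,
            cells=[self.cells[i] for i in idx],
            n_umi=None if self.n_umi is None else self.n_umi[idx],
        )

    def detection_fraction(self) -> np.ndarray:
        """Per-gene fraction of cells with nonzero expression."""
        return (self.X > 0).mean(axis=0)


def celltype_mean_expression(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Arithmetic mean of log-normalized expression per cell type.

    Returns a cell-type x gene DataFrame; entry (t, g) is the mean over all
    cells annotated as type t. Cells present in ``expr`` but absent from
    ``meta`` are an error, as is any requested gene not in the matrix.
    """
    genes = list(genes) if genes is not None else list(expr.genes)
    gidx = expr.gene_index(genes)
    types = meta.set_index("cell_id")["cell_type"]
    missing = [c for c in expr.cells if c not in types.index]
    if missing:
        raise ValidationError(f"cells without metadata: {missing[:10]}")
    labels = types.loc[expr.cells].to_numpy()
    sub = expr.X[:, gidx]
    frame = pd.DataFrame(sub, columns=genes)
    frame["__type"] = labels
    out = frame.groupby("__type", sort=True).mean()
    out.index.name = "cell_type"
    return out
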