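"""Readers and writers for the screen's plain-text interchange formats.

Everything is tab-separated UTF-8 with a header row and ``NA`` for
missing values. Expression matrices are accepted either as dense TSV
(cells x genes, ``cell_id`` index column, optional ``n_UMI`` column) or as
MatrixMarket triplets with gene/cell name sidecar files. FASTQ amplicon
reads are parsed with Biopython; the corrected cell barcode and UMI are
taken from ``CB:Z:``/``UB:Z:`` tags in the read description (upstream
barcode correction is out of scope here — it is done by the droplet
pipeline that produced the reads).
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .model import (
    ExpressionMatrix,
    FormatError,
    META_COLUMNS,
    validate_cell_meta,
)

_NA = "NA"


# ---------------------------------------------------------------------------
# cell metadata

def read_cell_meta(path, cell_types=None, permissive: bool = False,
                   **validate_kwargs) -> pd.DataFrame:
    """Read and validate a cell metadata TSV."""
    meta = pd.read_csv(
        path, sep="\t", dtype={c: "string" for c in META_COLUMNS if c != "induced"},
        na_values=[_NA], keep_default_na=False,
    )
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    meta["induced"] = meta["induced"].map(
        {"True": True, "False": False, "1": True, "0": False,
         True: True, False: False, 1: True, 0: False}
    )
    if meta["induced"].isna().any():
        raise FormatError(f"{path}: induced must be boolean (True/False/1/0)")
    meta["induced"] = meta["induced"].astype(bool)
    for col in META_COLUMNS:
        if col != "induced":
            meta[col] = meta[col].astype(object).where(meta[col].notna(), np.nan)
    if cell_types is not None:
        validate_kwargs["cell_types"] = tuple(cell_types)
    return validate_cell_meta(meta, permissive=permissive, **validate_kwargs)


def write_cell_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False, na_rep=_NA)


# ---------------------------------------------------------------------------
# expression matrices

def read_expression_tsv(path) -> ExpressionMatrix:
    """Dense TSV: cell_id index column, optional n_UMI column, gene columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    n_umi = None
    if "n_UMI" in df.columns:
        n_umi = df.pop("n_UMI").to_numpy()
    return ExpressionMatrix(
        X=df.to_numpy(dtype=float),
        genes=list(df.columns),
        cells=[str(c) for c in df.index],
        n_umi=n_umi,
    )


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.X, index=pd.Index(expr.cells, name="cell_id"),
                      columns=expr.genes)
    if expr.n_umi is not None:
        df.insert(0, "n_UMI", expr.n_umi)
    df.to_csv(path, sep="\t")


def read_expression_mtx(mtx_path, genes_path, cells_path,
                        n_umi_path=None) -> ExpressionMatrix:
    """MatrixMarket triplet (cells x genes) with name sidecar files."""
    mat = spio.mmread(mtx_path)
    genes = [line.strip() for line in open(genes_path) if line.strip()]
    cells = [line.strip() for line in open(cells_path) if line.strip()]
    n_umi = None
    if n_umi_path is not None:
        n_umi = np.loadtxt(n_umi_path, dtype=float)
    X = np.asarray(mat.todense()) if sparse.issparse(mat) else np.asarray(mat)
    return ExpressionMatrix(X=X, genes=genes, cells=cells, n_umi=n_umi)


def write_expression_mtx(expr: ExpressionMatrix, mtx_path, genes_path,
                         cells_path, n_umi_path=None) -> None:
    spio.mmwrite(str(mtx_path), sparse.csr_matrix(expr.X))
    Path(genes_path).write_text("".join(g + "\n" for g in expr.genes))
    Path(cells_path).write_text("".join(c + "\n" for c in expr.cells))
    if n_umi_path is not None and expr.n_umi is not None:
        np.savetxt(n_umi_path, expr.n_umi, fmt="%d")


# ---------------------------------------------------------------------------
# fate matrices

def read_fate_matrix(path) -> pd.DataFrame:
    """Cells x terminal-states TSV; header row gives state names."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_fate_matrix(fates: pd.DataFrame, path) -> None:
    fates.to_csv(path, sep="\t", index_label="cell_id")


# ---------------------------------------------------------------------------
# guide whitelist, gene sets and lists

def read_whitelist(path) -> pd.DataFrame:
    """Guide whitelist TSV with columns gene, spacer1, spacer2, is_control."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene", "spacer1", "spacer2", "is_control"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df["is_control"] = df["is_control"].astype(bool)
    return df


def write_whitelist(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_sets(path) -> dict[str, set[str]]:
    """Two-column TSV (set_name, gene) -> mapping of name to gene set."""
    df = pd.read_csv(path, sep="\t", header=0, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (set name, gene)")
    name_col, gene_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for name, group in df.groupby(name_col, sort=False):
        out[str(name)] = set(group[gene_col].astype(str))
    return out


def write_gene_sets(sets: dict[str, set[str]], path) -> None:
    rows = [(name, g) for name, genes in sets.items() for g in sorted(genes)]
    pd.DataFrame(rows, columns=["set", "gene"]).to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> set[str]:
    """One gene symbol per line."""
    return {line.strip() for line in open(path) if line.strip()}


# ---------------------------------------------------------------------------
# amplicon reads

def read_read_table(path) -> pd.DataFrame:
    """Aggregated read table: cbc, umi, seq, reads."""
    df = pd.read_csv(path, sep="\t",
                     dtype={"cbc": str, "umi": str, "seq": str})
    required = ["cbc", "umi", "seq", "reads"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def write_read_table(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", index=False)


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_reads(path) -> pd.DataFrame:
    """Parse a FASTQ of amplicon reads into the aggregated read table.

    Each record's description must carry ``CB:Z:<barcode>`` and
    ``UB:Z:<umi>`` tags. Identical (cbc, umi, seq) combinations are
    collapsed with their read counts summed.
    """
    from Bio import SeqIO

    rows = []
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            cbc = umi = None
            for token in rec.description.split():
                if token.startswith("CB:Z:"):
                    cbc = token[5:]
                elif token.startswith("UB:Z:"):
                    umi = token[5:]
            if cbc is None or umi is None:
                raise FormatError(
                    f"{path}: read {rec.id} lacks CB:Z:/UB:Z: tags"
                )
            rows.append((cbc, umi, str(rec.seq)))
    df = pd.DataFrame(rows, columns=["cbc", "umi", "seq"])
    return (
        df.groupby(["cbc", "umi", "seq"], sort=False)
        .size()
        .rename("reads")
        .reset_index()
    )


def write_fastq_reads(reads: pd.DataFrame, path) -> None:
    """Write the read table as FASTQ, one record per read copy."""
    with (gzip.open(str(path), "wt") if str(path).endswith(".gz")
          else open(path, "w")) as fh:
        i = 0
        for row in reads.itertuples(index=False):
            for _ in range(int(row.reads)):
                fh.write(f"@read{i} CB:Z:{row.cbc} UB:Z:{row.umi}\n")
                fh.write(f"{row.seq}\n+\n{'I' * len(row.seq)}\n")
                i += 1


# ---------------------------------------------------------------------------
# assignments

def read_assignments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cbc": str},
                     na_values=[_NA], keep_default_na=False)
    return df


def write_assignments(assignments: pd.DataFrame, path) -> None:
    assignments.to_csv(path, sep="\t", index=False, na_rep=_NA)
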