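"""Plain-text IO helpers: MatrixMarket count matrices, TSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix


def write_count_matrix_mtx(cm: pd.DataFrame, prefix: str | Path) -> None:
    """Write a gene x cell matrix as <prefix>.mtx plus gene/cell name files."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(cm.to_numpy()))
    prefix.with_name(prefix.name + "_genes.txt").write_text("\n".join(cm.index) + "\n")
    prefix.with_name(prefix.name + "_cells.txt").write_text("\n".join(cm.columns) + "\n")


def read_count_matrix_mtx(prefix: str | Path) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = mmread(str(prefix.with_suffix(".mtx"))).toarray()
    genes = prefix.with_name(prefix.name + "_genes.txt").read_text().splitlines()
    cells = prefix.with_name(prefix.name + "_cells.txt").read_text().splitlines()
    return pd.DataFrame(np.asarray(mat), index=genes, columns=cells)


def write_clustering(labels: pd.Series, path: str | Path) -> None:
    labels.rename("cluster").rename_axis("cell").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_clustering(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return pd.Series(df["cluster"].values, index=df["cell"].values, name="cluster")


def write_marker_table(mt: pd.DataFrame, path: str | Path) -> None:
    mt.to_csv(path, sep="\t", index=False)


def read_marker_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cluster": str, "gene": str})


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Import an externally produced DE table (gene, log2FC, padj[, de])."""
    df = pd.read_csv(path, sep="\t").set_index("gene")
    if "de" not in df:
        df["de"] = (df["log2FC"].abs() > 0.5) & (df["padj"] < 0.05)
    return df
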