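"""Readers and writers for the package's tabular interchange formats.

Spot tables travel as TSV, single-cell matrices as MatrixMarket (genes x
cells) plus features/barcodes/metadata TSVs, mIF cell tables as CSV, and
gene sets as GMT or two-column TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.io import mmread, mmwrite

from .scstats import GeneSet

SPOT_REQUIRED = ("spot_id", "x", "y", "sample_id", "condition")

ROI_REQUIRED = ("cell_id", "x", "y", "roi_id", "group")


def write_spot_table(spots: pd.DataFrame, path) -> None:
    spots.to_csv(path, sep="\t", index=False)


def read_spot_table(path) -> pd.DataFrame:
    spots = pd.read_csv(path, sep="\t")
    missing = [c for c in SPOT_REQUIRED if c not in spots.columns]
    if missing:
        raise ValueError(f"{path}: spot table missing columns {missing}")
    return spots


def write_cell_matrix(adata: AnnData, out_dir) -> None:
    """MTX (genes x cells) + features.tsv + barcodes.tsv + metadata.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    x = adata.X
    mat = sp.csr_matrix(x) if not sp.issparse(x) else x
    mmwrite(out / "matrix.mtx", mat.T.astype(np.int64))
    pd.Series(adata.var_names).to_csv(out / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    adata.obs.to_csv(out / "metadata.tsv", sep="\t")


def read_cell_matrix(in_dir) -> AnnData:
    src = Path(in_dir)
    mat = sp.csr_matrix(mmread(src / "matrix.mtx")).T
    features = pd.read_csv(src / "features.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(src / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    if mat.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"{src}: matrix shape {mat.shape[::-1]} (genes x cells) does not match "
            f"features ({len(features)}) x barcodes ({len(barcodes)})"
        )
    obs = pd.read_csv(src / "metadata.tsv", sep="\t", index_col=0)
    obs = obs.loc[barcodes]
    return AnnData(X=mat, obs=obs, var=pd.DataFrame(index=features.to_numpy()))


def write_roi_table(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def read_roi_table(path) -> pd.DataFrame:
    cells = pd.read_csv(path)
    missing = [c for c in ROI_REQUIRED if c not in cells.columns]
    if missing:
        raise ValueError(f"{path}: ROI cell table missing columns {missing}")
    return cells


def read_gene_sets(path) -> dict[str, GeneSet]:
    """GMT (name<TAB>description<TAB>gene...) or two-column TSV (set, gene)."""
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        sets = {}
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {line!r}")
            sets[parts[0]] = GeneSet(parts[0], parts[2:])
        return sets
    df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"])
    return {
        name: GeneSet(str(name), sub["gene"].astype(str).tolist())
        for name, sub in df.groupby("set", sort=True)
    }


def write_gene_sets(sets: dict[str, GeneSet], path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        lines = [
            "\t".join([name, "", *sorted(s.genes)]) for name, s in sorted(sets.items())
        ]
        path.write_text("\n".join(lines) + "\n")
    else:
        rows = [(name, g) for name, s in sorted(sets.items()) for g in sorted(s.genes)]
        pd.DataFrame(rows, columns=["set", "gene"]).to_csv(path, sep="\t", index=False, header=False)
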