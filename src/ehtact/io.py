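"""Readers and writers for the 10x-style triplet dialect and side tables.

Matrices travel as MatrixMarket triplets (genes x cells on disk, cells x
genes in memory) with ``features.tsv`` / ``barcodes.tsv`` side files, plain
or gzipped. Guide-capture matrices use the same dialect with guide ids as
features.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _find(dirpath: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = dirpath / name
            if p.exists():
                return p
    raise FileNotFoundError(f"none of {stems} found in {dirpath}")


def write_10x_mtx(adata: ad.AnnData, dirpath, layer: str | None = None) -> None:
    """Write cells x genes counts as a 10x triplet directory (uncompressed)."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    X = adata.layers[layer] if layer else adata.X
    X = sp.coo_matrix(X).T  # genes x cells on disk
    scipy.io.mmwrite(str(dirpath / "matrix.mtx"), X, field="integer")
    feats = pd.DataFrame({
        "id": adata.var_names, "name": adata.var_names,
        "type": "Gene Expression",
    })
    feats.to_csv(dirpath / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(dirpath / "barcodes.tsv", sep="\t",
                                      header=False, index=False)


def read_10x_mtx(dirpath) -> ad.AnnData:
    """Read a 10x triplet directory (plain or gzipped) into cells x genes."""
    dirpath = Path(dirpath)
    mtx = _find(dirpath, ("matrix.mtx",))
    feats = _find(dirpath, ("features.tsv", "genes.tsv"))
    barcodes = _find(dirpath, ("barcodes.tsv",))
    with _open_maybe_gz(mtx, "rb") as fh:
        X = scipy.io.mmread(fh).T.tocsr()  # cells x genes
    with _open_maybe_gz(feats) as fh:
        var_names = [line.rstrip("\n").split("\t")[0] for line in fh]
    with _open_maybe_gz(barcodes) as fh:
        obs_names = [line.rstrip("\n").split("\t")[0] for line in fh]
    if X.shape != (len(obs_names), len(var_names)):
        raise ValueError(
            f"matrix shape {X.shape} does not match barcodes x features "
            f"({len(obs_names)} x {len(var_names)})")
    X = sp.csr_matrix(X.astype(np.int64))
    return ad.AnnData(X=X, obs=pd.DataFrame(index=obs_names),
                      var=pd.DataFrame(index=var_names))


def write_guide_capture_mtx(capture: pd.DataFrame, dirpath) -> None:
    """Write a cells x guides capture count frame in the same dialect."""
    adata = ad.AnnData(X=sp.csr_matrix(capture.to_numpy()),
                       obs=pd.DataFrame(index=capture.index.astype(str)),
                       var=pd.DataFrame(index=capture.columns.astype(str)))
    write_10x_mtx(adata, dirpath)


def read_guide_capture_mtx(dirpath) -> pd.DataFrame:
    adata = read_10x_mtx(dirpath)
    return pd.DataFrame(adata.X.toarray(), index=adata.obs_names,
                        columns=adata.var_names)


def read_tf_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                out.append(sym)
    return out


def write_tf_list(symbols, path) -> None:
    Path(path).write_text("\n".join(symbols) + "\n")
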