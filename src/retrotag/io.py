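"""Readers and writers for the on-disk formats shared by all stages.

The count-matrix interchange layout mirrors the CellRanger convention:
``matrix.mtx`` (Matrix Market triplet, features x cells, 1-based indices),
``features.tsv`` (id, name, class; class in {endogenous, mito, transgene}),
``barcodes.tsv`` (one barcode per line). Ground-truth annotations, when
present, live in ``truth.tsv``. In memory everything is an AnnData with
cells as rows, features as columns, and the feature class in
``var["feature_class"]``.

Floats in TSV reports are formatted at 6 significant digits so that a rerun
with the same seed is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError

FEATURE_CLASSES = ("endogenous", "mito", "transgene")
FLOAT_FORMAT = "%.6g"


def _check_mtx_header(path: Path) -> None:
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("%%MatrixMarket matrix coordinate"):
        raise FormatError(
            f"{path}, line 1: malformed Matrix Market header {first!r}"
        )


def _locate_bad_triplet(path: Path, n_rows: int, n_cols: int) -> str:
    """Best-effort scan for the first out-of-bounds triplet line."""
    with open(path) as fh:
        lineno = 0
        seen_size = False
        for raw in fh:
            lineno += 1
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            if not seen_size:
                seen_size = True
                continue
            parts = line.split()
            try:
                i, j = int(parts[0]), int(parts[1])
            except (ValueError, IndexError):
                return f"line {lineno}: unparseable triplet {line!r}"
            if not (1 <= i <= n_rows and 1 <= j <= n_cols):
                return f"line {lineno}: index ({i}, {j}) out of bounds"
    return "unknown line"


def write_counts_dir(
    adata: ad.AnnData, path: str | Path, truth: pd.DataFrame | None = None
) -> Path:
    """Write an AnnData count matrix as a CellRanger-style directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = sp.csr_matrix(adata.X)
    X.eliminate_zeros()
    scipy.io.mmwrite(
        path / "matrix.mtx", sp.coo_matrix(X.T.astype(np.int64)), field="integer"
    )
    feats = pd.DataFrame(
        {
            "id": adata.var_names,
            "name": adata.var.get("name", adata.var_names),
            "class": adata.var["feature_class"],
        }
    )
    feats.to_csv(path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )
    if truth is not None:
        truth.to_csv(path / "truth.tsv", sep="\t", index_label="barcode")
    return path


def read_counts_dir(path: str | Path) -> tuple[ad.AnnData, pd.DataFrame | None]:
    """Read a counts directory back into (AnnData, truth-or-None)."""
    path = Path(path)
    mtx = path / "matrix.mtx"
    for required in (mtx, path / "features.tsv", path / "barcodes.tsv"):
        if not required.exists():
            raise FormatError(f"missing {required}")
    _check_mtx_header(mtx)
    try:
        mat = scipy.io.mmread(mtx)
    except ValueError as exc:
        # mmread reports no location; scan the file to find it
        with open(mtx) as fh:
            fh.readline()
            size_line = ""
            for line in fh:
                if not line.startswith("%"):
                    size_line = line
                    break
        try:
            n_rows, n_cols = (int(x) for x in size_line.split()[:2])
            where = _locate_bad_triplet(mtx, n_rows, n_cols)
        except Exception:
            where = "unknown line"
        raise FormatError(f"{mtx}, {where}: {exc}") from exc

    feats = pd.read_csv(
        path / "features.tsv", sep="\t", header=None, dtype=str
    )
    if feats.shape[1] < 3:
        raise FormatError(
            f"{path / 'features.tsv'}: expected 3 columns (id, name, class), "
            f"got {feats.shape[1]}"
        )
    feats.columns = ["id", "name", "class"][: feats.shape[1]]
    bad = set(feats["class"]) - set(FEATURE_CLASSES)
    if bad:
        raise FormatError(f"unknown feature classes {sorted(bad)}")
    barcodes = pd.read_csv(
        path / "barcodes.tsv", sep="\t", header=None, dtype=str
    )[0]

    X = sp.csr_matrix(mat.T)  # features x cells on disk -> cells x features
    if X.shape != (len(barcodes), len(feats)):
        raise FormatError(
            f"matrix shape {X.shape} does not match "
            f"{len(barcodes)} barcodes x {len(feats)} features"
        )
    var = pd.DataFrame(
        {"name": feats["name"].values, "feature_class": feats["class"].values},
        index=feats["id"].values,
    )
    adata = ad.AnnData(
        X=X.astype(np.int64), obs=pd.DataFrame(index=barcodes.values), var=var
    )

    truth = None
    truth_path = path / "truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t", index_col="barcode")
    return adata, truth


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """TSV writer with the package-wide stable float format."""
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_newick(text: str, path: str | Path) -> None:
    Path(path).write_text(text if text.endswith("\n") else text + "\n")
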