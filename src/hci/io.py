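"""Readers and writers for expression matrices, labels and run artifacts.

Dense input is TSV/CSV with the first column holding feature ids and the
header row holding sample ids.  Sparse input is a Matrix-Market
coordinate file with companion one-id-per-line feature and sample files
(the 10x-style triplet).  Labels are two-column TSV (sample_id, label).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from .datatypes import ExpressionMatrix, LabelVector

__all__ = [
    "load_expression",
    "load_labels",
    "write_expression",
    "write_labels",
]

_FEATURE_FILE_CANDIDATES = ("features.tsv", "genes.tsv", "features.txt")
_SAMPLE_FILE_CANDIDATES = ("barcodes.tsv", "samples.tsv", "barcodes.txt")


def _read_id_file(path: Path) -> list[str]:
    # 10x files may carry extra tab-separated columns; the first is the id
    with open(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    if not ids:
        raise ValueError(f"empty identifier file: {path}")
    return ids


def _find_companion(base: Path, candidates: tuple[str, ...], what: str) -> Path:
    for name in candidates:
        p = base / name
        if p.exists():
            return p
    raise FileNotFoundError(
        f"no {what} identifier file next to the matrix; looked for {candidates}"
    )


def load_expression(
    path,
    format: str | None = None,
    features_path=None,
    samples_path=None,
    view_name: str = "expression",
    impute_zero: bool = False,
) -> ExpressionMatrix:
    """Load a features-by-samples expression matrix.

    ``format`` is one of ``dense-tsv``, ``dense-csv``, ``mtx-triplet``;
    when omitted it is inferred from the file suffix (.tsv/.txt, .csv,
    .mtx).  For the sparse triplet, feature/sample id files default to
    the conventional names next to the matrix file.  Missing values are
    an error unless ``impute_zero=True`` maps them to 0 with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if format is None:
        format = {
            ".tsv": "dense-tsv",
            ".txt": "dense-tsv",
            ".csv": "dense-csv",
            ".mtx": "mtx-triplet",
        }.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")

    if format == "mtx-triplet":
        fpath = (
            Path(features_path)
            if features_path
            else _find_companion(path.parent, _FEATURE_FILE_CANDIDATES, "feature")
        )
        spath = (
            Path(samples_path)
            if samples_path
            else _find_companion(path.parent, _SAMPLE_FILE_CANDIDATES, "sample")
        )
        values = np.asarray(mmread(path).todense(), dtype=float)
        feature_ids = _read_id_file(fpath)
        sample_ids = _read_id_file(spath)
        return ExpressionMatrix(values, feature_ids, sample_ids, view_name)

    if format not in ("dense-tsv", "dense-csv"):
        raise ValueError(f"unknown format: {format!r}")
    sep = "\t" if format == "dense-tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed file {path}: {exc}") from exc
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        bad = df[non_numeric[0]]
        row = bad.index[~bad.map(lambda v: isinstance(v, (int, float)))][:1]
        raise ValueError(
            f"malformed file {path}: non-numeric value in column "
            f"{non_numeric[0]!r} (near row {row.tolist()})"
        )
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        if not impute_zero:
            raise ValueError(
                f"{path}: missing values present; pass impute_zero=True to zero-fill"
            )
        warnings.warn(f"{path}: imputing {int(np.isnan(values).sum())} missing values to 0")
        values = np.nan_to_num(values, nan=0.0)
    return ExpressionMatrix(
        values, list(map(str, df.index)), list(map(str, df.columns)), view_name
    )


def load_labels(path) -> LabelVector:
    """Two-column TSV (sample_id, label), with or without a header row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} must have two tab-separated columns")
    # tolerate a header row like "sample_id<TAB>label"
    if df.iloc[0, 0].lower() in ("sample_id", "sample", "cell", "barcode"):
        df = df.iloc[1:]
    return LabelVector(df.iloc[:, 1].to_numpy(), list(df.iloc[:, 0]))


def write_expression(X: ExpressionMatrix, path, sep: str = "\t") -> None:
    X.to_frame().to_csv(path, sep=sep, index_label="feature_id")


def write_labels(labels: LabelVector, path) -> None:
    pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.labels}).to_csv(
        path, sep="\t", index=False, header=False
    )
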