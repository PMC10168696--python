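"""Readers and writers for the pipeline's plain-text interchange formats.

Dense TSV/CSV (genes as rows, header = sample ids) is the primary format;
MTX triplets with gene/sample side files are accepted for single-cell-shaped
input. Every file written here carries a ``#`` header comment with the
package version, the seed and a config hash, and every reader tolerates
such comments.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from . import __version__
from .preprocess import ExpressionMatrix, SAMPLE_COLUMNS, validate_samples
from .synthetic import SyntheticTruth


def _header_lines(seed=None, config_hash=None, extra=None) -> str:
    parts = [f"# driftrescue v{__version__}"]
    if seed is not None:
        parts.append(f"# seed: {seed}")
    if config_hash is not None:
        parts.append(f"# config_hash: {config_hash}")
    if extra:
        parts.extend(f"# {line}" for line in extra)
    return "\n".join(parts) + "\n"


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, seed=None, cfg_hash=None, index=True) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, cfg_hash))
        df.to_csv(fh, sep="\t", index=index, float_format="%.17g")


def read_expression(path, fmt: str | None = None, scale: str = "linear") -> ExpressionMatrix:
    """Read a gene x sample matrix from TSV, CSV or an MTX triplet.

    For ``mtx``, ``<stem>.genes.tsv`` and ``<stem>.samples.tsv`` must sit
    next to the matrix file, one identifier per line.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower()
        )
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if fmt == "mtx":
        mat = scipy.io.mmread(path)
        genes = _read_id_file(path.parent / (path.stem + ".genes.tsv"))
        samples = _read_id_file(path.parent / (path.stem + ".samples.tsv"))
        arr = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        if arr.shape != (len(genes), len(samples)):
            raise ValueError(
                f"MTX shape {arr.shape} does not match id files "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        df = pd.DataFrame(arr, index=genes, columns=samples)
    else:
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#", float_precision="round_trip")
        df.index = df.index.astype(str)
    df.index.name = "gene_id"
    if df.isna().any().any():
        stacked = df.isna().stack()
        gene, sample = stacked.index[np.argmax(stacked.to_numpy())]
        raise ValueError(f"NA value at gene {gene!r}, sample {sample!r}")
    return ExpressionMatrix(df, scale=scale)


def _read_id_file(path: Path) -> pd.Index:
    if not path.exists():
        raise ValueError(f"missing id file {path}")
    with open(path) as fh:
        ids = [line.strip().split("\t")[0] for line in fh if line.strip() and not line.startswith("#")]
    return pd.Index(ids)


def write_expression(m: ExpressionMatrix, path, seed=None, cfg_hash=None) -> None:
    write_tsv(m.values, path, seed=seed, cfg_hash=cfg_hash)


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    return validate_samples(df)


def write_samples(samples: pd.DataFrame, path, seed=None, cfg_hash=None) -> None:
    write_tsv(samples[list(SAMPLE_COLUMNS)], path, seed=seed, cfg_hash=cfg_hash, index=False)


def write_truth(truth: SyntheticTruth, path) -> None:
    write_tsv(
        truth.table,
        path,
        seed=truth.seed,
        cfg_hash=config_hash(dataclass_dict(truth.params)),
    )


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id", comment="#",
                       float_precision="round_trip")


def read_id_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("gene_id", "protein_id"):
        if col not in df.columns:
            raise ValueError(f"id map is missing the {col!r} column")
    return df


def write_id_map(id_map: pd.DataFrame, path, seed=None) -> None:
    write_tsv(id_map, path, seed=seed, index=False)


def dataclass_dict(obj) -> dict:
    import dataclasses

    return dataclasses.asdict(obj)


def match_ids_case_insensitive(genes: pd.Index, symbols) -> pd.Series:
    """Map gene ids to symbols case-insensitively (layers match by symbol)."""
    lookup = {str(s).upper(): s for s in symbols}
    return pd.Series({g: lookup.get(str(g).upper()) for g in genes})


def pseudobulk(m: ExpressionMatrix, groups: dict | pd.Series) -> ExpressionMatrix:
    """Aggregate single-cell-shaped columns to per-replicate means.

    ``groups`` maps every column (cell) to a replicate label; every cell
    must be assigned and every replicate must be non-empty.
    """
    groups = pd.Series(groups)
    missing = m.sample_ids.difference(groups.index)
    if len(missing):
        raise ValueError(f"cells without a replicate assignment: {missing[:5].tolist()}")
    groups = groups.loc[m.sample_ids]
    if groups.isna().any():
        bad = m.sample_ids[groups.isna()].tolist()
        raise ValueError(f"cells without a replicate assignment: {bad[:5]}")
    out = m.values.T.groupby(groups).mean().T
    if (m.values.T.groupby(groups).size() == 0).any():
        raise ValueError("empty replicate group")
    return ExpressionMatrix(out, scale=m.scale)
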