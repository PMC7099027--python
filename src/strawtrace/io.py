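"""Readers and writers for the pipeline's plain-text formats.

All tables are UTF-8 TSV with '.' decimal separator.  Output tables carry a
comment header recording the seed and a config hash for provenance; readers
skip '#' comment lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .isotope import POOL_TABLE_COLUMNS, validate_pool_table


def provenance_header(seed, config_hash: str) -> str:
    return f"# strawtrace seed={seed} config={config_hash}"


def write_table(df: pd.DataFrame, outdir, name: str, header: str | None = None,
                float_format: str = "%.10g") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / name
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header:
            fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format,
                  lineterminator="\n")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_pool_table(path) -> pd.DataFrame:
    """Long-format pool measurements; validates schema and uniqueness."""
    df = validate_pool_table(read_table(path))
    return df[list(POOL_TABLE_COLUMNS)]


def read_taxa_table(path) -> pd.DataFrame:
    """Taxa × samples counts from TSV (taxa rows, first column = label)."""
    df = read_table(path)
    df = df.set_index(df.columns[0])
    df.index.name = "taxon"
    if (df.values < 0).any():
        raise ValueError("taxa table has negative counts")
    return df


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata sidecar: sample, treatment, replicate, day."""
    df = read_table(path)
    need = {"sample", "treatment", "replicate", "day"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return df


def read_biom(path) -> pd.DataFrame:
    """Minimal BIOM 1.0 (JSON) reader returning a taxa × samples DataFrame.

    Supports both dense and sparse matrix_type.  Only observation/sample ids
    and the count matrix are used; metadata blobs are ignored.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format_url") not in (None, "http://biom-format.org",
                                     "http://biom-format.org/documentation/format_versions/biom-1.0.html"):
        raise ValueError(f"not a BIOM 1.0 document: {doc.get('format_url')!r}")
    obs = [o["id"] for o in doc["rows"]]
    samples = [s["id"] for s in doc["columns"]]
    n_obs, n_samp = doc["shape"]
    if (n_obs, n_samp) != (len(obs), len(samples)):
        raise ValueError("BIOM shape disagrees with rows/columns")
    import numpy as np

    mat = np.zeros((n_obs, n_samp))
    if doc["matrix_type"] == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    elif doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        raise ValueError(f"unsupported matrix_type {doc['matrix_type']!r}")
    out = pd.DataFrame(mat, index=obs, columns=samples)
    out.index.name = "taxon"
    return out
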