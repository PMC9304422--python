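"""Tabular readers/writers for methylation matrices, phenotypes and annotation.

All on-disk formats are plain TSV (optionally gzipped, by file suffix):

* beta / M matrices -- first column ``cpg_id``, remaining columns one per
  sample; lines starting with ``#`` are header comments (e.g. recorded seeds).
* phenotype table  -- keyed by ``sample_id``.
* CpG annotation   -- BED-like: ``chrom start end cpg_id island_relation
  chromatin_state snp_maf genes`` (0-based half-open coordinates, genes
  semicolon-separated, missing MAF left empty).

In memory everything is a :class:`pandas.DataFrame`; matrices are CpG x
sample with the index named ``cpg_id``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = [
    "chrom", "start", "end", "cpg_id",
    "island_relation", "chromatin_state", "snp_maf", "genes",
]


def validate_beta(beta: pd.DataFrame, name: str = "beta") -> None:
    """Check the BetaMatrix contract: values in [0,1] (NaN allowed as an
    explicit missing mask), unique CpG and sample ids."""
    if beta.index.has_duplicates:
        dup = beta.index[beta.index.duplicated()][0]
        raise ValueError(f"{name}: duplicate CpG id {dup!r}")
    if beta.columns.has_duplicates:
        dup = beta.columns[beta.columns.duplicated()][0]
        raise ValueError(f"{name}: duplicate sample id {dup!r}")
    vals = beta.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    if np.any(np.isinf(vals)):
        raise ValueError(f"{name}: infinite entries are not allowed")
    if finite.any():
        v = vals[finite]
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError(f"{name}: beta values must lie in [0, 1]")


def _write_table(df: pd.DataFrame, path, header_comments=()) -> None:
    text = df.to_csv(sep="\t", lineterminator="\n")
    prefix = "".join(f"# {line}\n" for line in header_comments)
    data = (prefix + text).encode()
    if str(path).endswith(".gz"):
        import gzip
        # mtime pinned so identical content gives identical bytes
        with gzip.GzipFile(str(path), "wb", mtime=0) as fh:
            fh.write(data)
    else:
        with open(path, "wb") as fh:
            fh.write(data)


def write_beta(beta: pd.DataFrame, path, header_comments=()) -> None:
    validate_beta(beta)
    out = beta.copy()
    out.index.name = "cpg_id"
    _write_table(out, path, header_comments)


def read_beta(path, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="cpg_id")
    df = df.astype(float)
    if validate:
        validate_beta(df)
    return df


def write_matrix(m: pd.DataFrame, path, header_comments=()) -> None:
    """Write an M-value (or any real-valued) CpG x sample matrix."""
    out = m.copy()
    out.index.name = "cpg_id"
    _write_table(out, path, header_comments)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="cpg_id").astype(float)


def write_pheno(pheno: pd.DataFrame, path) -> None:
    out = pheno.copy()
    out.index.name = "sample_id"
    _write_table(out, path)


def read_pheno(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")


def write_annotation(ann: pd.DataFrame, path) -> None:
    out = ann.reset_index() if ann.index.name == "cpg_id" else ann.copy()
    missing = [c for c in ANNOTATION_COLUMNS if c not in out.columns]
    if missing:
        raise ValueError(f"annotation is missing columns: {missing}")
    _write_table(out[ANNOTATION_COLUMNS].set_index("chrom"), path)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    df = df.set_index("cpg_id")
    df["snp_maf"] = pd.to_numeric(df["snp_maf"], errors="coerce")
    df["genes"] = df["genes"].fillna("")
    return df


def write_cpg_list(cpgs, path) -> None:
    with open(path, "w") as fh:
        for c in cpgs:
            fh.write(f"{c}\n")


def read_cpg_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]
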