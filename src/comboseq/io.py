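"""Readers and writers for the pipeline's plain-text formats.

Counts are a TSV with the gene id in the first column and one column per
sample; the sample sheet is a TSV with columns sample, cell_line,
condition, replicate.  DE tables round-trip through TSV with a small
``# key=value`` metadata header carrying the contrast and cell line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .de import CountMatrix, CountMatrixError, DEResult


def read_counts(counts_path, samples_path) -> CountMatrix:
    """Read and validate a count matrix + sample sheet pair.

    Rejects non-integer or negative counts (naming the gene/sample
    coordinates), duplicate gene ids, and any mismatch between count
    columns and sample-sheet rows (naming the sample).
    """
    df = pd.read_csv(counts_path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise CountMatrixError(f"{counts_path}: expected gene id column plus samples")
    gene_col = df.columns[0]
    df = df.set_index(gene_col)
    df.index.name = "gene_id"
    vals = df.apply(pd.to_numeric, errors="coerce")
    bad = vals.isna() | (vals % 1 != 0)
    if bad.any().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise CountMatrixError(
            f"{counts_path}: non-integer count {df.iat[g, s]!r} at gene "
            f"{df.index[g]!r}, sample {df.columns[s]!r}"
        )
    counts = vals.astype(np.int64)

    meta = pd.read_csv(samples_path, sep="\t", dtype={"sample": str})
    if "sample" not in meta.columns:
        raise CountMatrixError(f"{samples_path}: missing 'sample' column")
    if meta["sample"].duplicated().any():
        raise CountMatrixError(f"{samples_path}: duplicate sample ids")
    meta = meta.set_index("sample")
    return CountMatrix(counts, meta)


def write_counts(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def write_sample_sheet(cm: CountMatrix, path) -> None:
    cm.sample_meta.to_csv(path, sep="\t", index_label="sample")


def write_de_table(de: DEResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# treatment={de.contrast[0]}\n")
        fh.write(f"# control={de.contrast[1]}\n")
        fh.write(f"# cell_line={de.cell_line or ''}\n")
        de.table.to_csv(fh, sep="\t", index_label="gene_id",
                        float_format="%.10g")


def read_de_table(path) -> DEResult:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("# "):
                break
            k, _, v = line[2:].strip().partition("=")
            meta[k] = v
    table = pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")
    table["separated"] = table["separated"].astype(bool)
    table["converged"] = table["converged"].astype(bool)
    if "treatment" not in meta or "control" not in meta:
        raise ValueError(f"{path}: missing contrast metadata header")
    return DEResult(
        contrast=(meta["treatment"], meta["control"]),
        table=table,
        cell_line=meta.get("cell_line") or None,
    )


def write_gene_set(genes, path) -> None:
    pd.Series(sorted(genes), name="gene_id").to_csv(path, sep="\t", index=False)


def read_flat_config(path) -> dict:
    """Parse a flat ``key = value`` configuration file ('#' comments)."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            k, _, v = line.partition("=")
            out[k.strip()] = v.strip()
    return out
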