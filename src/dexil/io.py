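"""TSV readers/writers for count matrices, sample tables and results.

All tabular files are tab-separated with a header row and "NA" for missing
values.  Validation errors carry file names and line numbers.
"""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd

from .simdata import CountMatrix

SAMPLE_COLUMNS = ("donor", "il17", "dex")


def read_counts(path: str) -> pd.DataFrame:
    """Read a gene x sample integer count table (first column gene_id)."""
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty counts file") from None
        if header[0] != "gene_id":
            raise ValueError(f"{path}:1: first column must be 'gene_id', got {header[0]!r}")
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError(f"{path}:1: duplicate sample ids in header")
        genes, rows = [], []
        seen = set()
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            gene = row[0]
            if gene in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            seen.add(gene)
            values = []
            for col, cell in zip(sample_ids, row[1:]):
                try:
                    v = int(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer count {cell!r} "
                        f"for gene {gene!r}, sample {col!r}"
                    ) from None
                if v < 0:
                    raise ValueError(
                        f"{path}:{lineno}: negative count for gene {gene!r}"
                    )
                values.append(v)
            genes.append(gene)
            rows.append(values)
    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64),
        index=pd.Index(genes, name="gene_id"),
        columns=pd.Index(sample_ids, name="sample_id"),
    )
    return counts


def read_samples(path: str) -> pd.DataFrame:
    """Read the sample annotation table (sample_id, donor, il17, dex[, permeability])."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor": str},
                     na_values=["NA"])
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sample_id'")
    for col in SAMPLE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    for col in ("il17", "dex"):
        vals = set(df[col].unique())
        if not vals <= {0, 1}:
            raise ValueError(f"{path}: column {col!r} must be 0/1, got {sorted(vals)}")
    if "permeability" not in df.columns:
        df["permeability"] = np.nan
    return df.set_index("sample_id")


def read_count_matrix(counts_path: str, samples_path: str) -> CountMatrix:
    """Read and cross-validate the two input tables into a CountMatrix."""
    counts = read_counts(counts_path)
    samples = read_samples(samples_path)
    only_counts = counts.columns.difference(samples.index).tolist()
    only_samples = samples.index.difference(counts.columns).tolist()
    if only_counts or only_samples:
        raise ValueError(
            f"samples present in counts but not annotations: {only_counts}; "
            f"annotated but missing from counts: {only_samples}"
        )
    samples = samples.loc[counts.columns]
    return CountMatrix(counts=counts, samples=samples)


def write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA")
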