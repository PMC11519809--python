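"""Readers and writers for the pipeline's plain-text formats.

Counts travel as TSV (first column ``gene_id``, one column per sample) or as
MatrixMarket with sidecar row/column id files; the sample sheet and truth
labels as CSV; regional and stage tables as long-format TSV; configs as YAML.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from mszscreen.simulate import REGIONS


# ---------------------------------------------------------------- counts

def write_counts_tsv(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col="gene_id")
    validate_counts(counts)
    return counts


def write_counts_mtx(counts: pd.DataFrame, prefix: str) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>_genes.txt`` / ``_samples.txt``."""
    scipy.io.mmwrite(f"{prefix}.mtx", scipy.sparse.coo_matrix(counts.to_numpy()))
    with open(f"{prefix}_genes.txt", "w") as fh:
        fh.write("\n".join(map(str, counts.index)) + "\n")
    with open(f"{prefix}_samples.txt", "w") as fh:
        fh.write("\n".join(map(str, counts.columns)) + "\n")


def read_counts_mtx(prefix: str) -> pd.DataFrame:
    m = scipy.io.mmread(f"{prefix}.mtx")
    genes = read_gene_list(f"{prefix}_genes.txt")
    samples = read_gene_list(f"{prefix}_samples.txt")
    counts = pd.DataFrame(
        np.asarray(m.todense() if scipy.sparse.issparse(m) else m, dtype=np.int64),
        index=pd.Index(genes, name="gene_id"),
        columns=samples,
    )
    validate_counts(counts)
    return counts


def validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in count matrix")
    if counts.columns.has_duplicates:
        dup = counts.columns[counts.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")


# ----------------------------------------------------------- sample sheet

def write_sample_sheet(samples: pd.DataFrame, path: str) -> None:
    samples.to_csv(path, index=False)


def read_sample_sheet(path: str) -> pd.DataFrame:
    samples = pd.read_csv(path)
    validate_sample_sheet(samples)
    return samples


def validate_sample_sheet(samples: pd.DataFrame) -> None:
    required = {"sample_id", "color", "method", "replicate"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet is missing columns: {sorted(missing)}")
    combos = samples.groupby(["method", "replicate", "color"]).size()
    bad = combos[combos != 1]
    if len(bad):
        raise ValueError(
            f"(method, replicate, color) combinations must occur exactly once; "
            f"violated at {bad.index[0]}"
        )


# -------------------------------------------------- regional / stage tables

def write_regional_tsv(regional: pd.DataFrame, path: str) -> None:
    long = regional.reset_index().melt(
        id_vars="gene_id", var_name="region", value_name="value"
    )
    long.to_csv(path, sep="\t", index=False)


def read_regional_tsv(path: str) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t")
    wide = long.pivot_table(index="gene_id", columns="region", values="value")
    missing = set(REGIONS) - set(wide.columns)
    if missing:
        raise ValueError(f"regional table is missing region(s): {sorted(missing)}")
    return wide[list(REGIONS)]


def write_stage_tsv(stages: pd.DataFrame, path: str) -> None:
    stages.to_csv(path, sep="\t", index=False)


def read_stage_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ------------------------------------------------------------ truth, lists

def write_truth_csv(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, index=False)


def read_truth_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def write_gene_list(genes: Sequence[str], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_list(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


# ------------------------------------------------------------------- yaml

def read_yaml(path: str) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path} must contain a mapping at the top level")
    return data
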