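"""Readers and writers for the on-disk dataset dialects.

All tables are plain text:

* ``beta.tsv`` / ``counts.tsv`` — tab-separated matrices; first column is the
  probe/gene identifier, header row holds sample ids.  Beta values are
  methylation fractions in [0, 1] (missing allowed, empty cell); counts are
  non-negative integers.
* ``manifest.csv`` — Illumina 450K manifest dialect: columns ``IlmnID``,
  ``CHR``, ``MAPINFO`` (1-based), ``UCSC_RefGene_Name`` (semicolon-joined),
  ``UCSC_RefGene_Group`` (semicolon-joined; values among TSS1500, TSS200,
  5'UTR, 1stExon, Body, 3'UTR).
* ``samples.csv`` — columns ``sample_id``, ``subject_id``, ``condition``
  (diagnosis|remission|healthy|parent|ref_cd34|ref_cd19), ``pair_id``
  (empty allowed), ``has_methylation``, ``has_expression``.
* ``truth.json`` — planted ground truth emitted by the simulator.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

REGION_CATEGORIES = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR")
CONDITIONS = ("diagnosis", "remission", "healthy", "parent", "ref_cd34", "ref_cd19")

MANIFEST_COLUMNS = ["IlmnID", "CHR", "MAPINFO", "UCSC_RefGene_Name", "UCSC_RefGene_Group"]
SAMPLE_COLUMNS = [
    "sample_id",
    "subject_id",
    "condition",
    "pair_id",
    "has_methylation",
    "has_expression",
]


class InputError(ValueError):
    """Raised when an input table or argument violates its contract."""


def _check_matrix(df: pd.DataFrame, name: str) -> pd.DataFrame:
    if df.index.has_duplicates:
        raise InputError(f"{name}: duplicate row identifiers")
    if df.columns.has_duplicates:
        raise InputError(f"{name}: duplicate sample identifiers")
    return df


def validate_beta(beta: pd.DataFrame) -> pd.DataFrame:
    """Check a probes x samples beta matrix: unique ids, values in [0, 1]."""
    _check_matrix(beta, "beta matrix")
    vals = beta.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise InputError("beta matrix: values outside [0, 1]")
    return beta


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    _check_matrix(counts, "count matrix")
    vals = counts.to_numpy()
    if vals.size and vals.min() < 0:
        raise InputError("count matrix: negative counts")
    return counts


def write_beta(beta: pd.DataFrame, path: str) -> None:
    beta.to_csv(path, sep="\t", index_label="probe_id")


def read_beta(path: str) -> pd.DataFrame:
    beta = pd.read_csv(path, sep="\t", index_col=0)
    beta.index = beta.index.astype(str)
    return validate_beta(beta)


def write_counts(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    return validate_counts(counts)


def write_manifest(manifest: pd.DataFrame, path: str) -> None:
    manifest.loc[:, MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path: str) -> pd.DataFrame:
    manifest = pd.read_csv(path, dtype={"IlmnID": str, "CHR": str}, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise InputError(f"manifest {path}: missing columns {missing}")
    if manifest["IlmnID"].duplicated().any():
        raise InputError(f"manifest {path}: duplicated IlmnID")
    manifest["MAPINFO"] = manifest["MAPINFO"].astype(int)
    return manifest


def write_samples(samples: pd.DataFrame, path: str) -> None:
    samples.loc[:, SAMPLE_COLUMNS].to_csv(path, index=False)


def read_samples(path: str) -> pd.DataFrame:
    samples = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise InputError(f"sample sheet {path}: missing columns {missing}")
    for col in ("has_methylation", "has_expression"):
        samples[col] = samples[col].map(
            {"True": True, "False": False, "1": True, "0": False}
        )
        if samples[col].isna().any():
            raise InputError(f"sample sheet {path}: non-boolean values in {col}")
    bad = set(samples["condition"]) - set(CONDITIONS)
    if bad:
        raise InputError(f"sample sheet {path}: unknown conditions {sorted(bad)}")
    if samples["sample_id"].duplicated().any():
        raise InputError(f"sample sheet {path}: duplicated sample_id")
    return samples


def ensure_dir(directory: str) -> str:
    os.makedirs(directory, exist_ok=True)
    return directory
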