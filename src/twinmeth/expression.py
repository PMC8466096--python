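"""Paired differential expression on gene-level counts.

Counts are normalized by median-of-ratios size factors and log2-transformed
with a pseudocount; differential expression between diagnosis and remission
is a two-sided paired t-test on the per-pair log2 differences, with
Benjamini-Hochberg FDR control at ``alpha`` (0.05 by default).  The stage is
pluggable: an externally produced table (gene, log2fc, p_fdr) can be loaded
with :func:`load_external_de` and used verbatim downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import InputError, validate_counts


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Per gene, the geometric mean across samples is computed (genes containing
    any zero are excluded); each sample's factor is the median over included
    genes of count / geometric mean.
    """
    validate_counts(counts)
    if counts.shape[1] < 2:
        raise InputError("size factors require at least two samples")
    vals = counts.to_numpy(dtype=float)
    allpos = (vals > 0).all(axis=1)
    if not allpos.any():
        raise InputError("no gene with all-positive counts; cannot compute size factors")
    pos = vals[allpos]
    log_geomean = np.mean(np.log(pos), axis=1)
    ratios = np.log(pos) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_log2(
    counts: pd.DataFrame, factors: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(count / size factor + pseudocount), per sample."""
    if set(factors.index) != set(counts.columns) or (factors <= 0).any():
        raise InputError("size factors must be positive and aligned to the samples")
    scaled = counts.to_numpy(dtype=float) / factors.reindex(counts.columns).to_numpy()
    return pd.DataFrame(
        np.log2(scaled + pseudocount), index=counts.index, columns=counts.columns
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    adj_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InputError("bh_adjust expects a 1-d array of p-values")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def paired_de(
    norm: pd.DataFrame,
    pairs: list[tuple[str, str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired t-test per gene on normalized log2 values (diagnosis - remission).

    Returns a table with ``mean_expression`` (mean normalized log2 value),
    ``log2fc`` (mean paired difference), ``p_value``, ``p_fdr`` and
    ``significant`` (p_fdr < alpha), indexed by gene.
    """
    if len(pairs) < 2:
        raise InputError("at least two diagnosis-remission pairs are required")
    flat = [s for pair in pairs for s in pair]
    if len(set(flat)) != len(flat):
        raise InputError("a sample id appears in more than one pair")
    for sid in flat:
        if sid not in norm.columns:
            raise InputError(f"unknown sample id: {sid!r}")
    n = len(pairs)
    diag = norm[[d for d, _ in pairs]].to_numpy(dtype=float)
    rem = norm[[r for _, r in pairs]].to_numpy(dtype=float)
    diffs = diag - rem
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    tiny = 1e-12
    degenerate = (sd <= tiny) & (np.abs(mean) > tiny)
    zero = (sd <= tiny) & (np.abs(mean) <= tiny)
    t[degenerate] = np.sign(mean[degenerate]) * np.inf
    t[zero] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[degenerate] = 0.0
    p[zero] = 1.0
    p_fdr = bh_adjust(p)
    table = pd.DataFrame(
        {
            "mean_expression": np.concatenate([diag, rem], axis=1).mean(axis=1),
            "log2fc": mean,
            "p_value": p,
            "p_fdr": p_fdr,
            "significant": p_fdr < alpha,
        },
        index=norm.index,
    )
    table.index.name = "gene"
    return table


def run_de(
    counts: pd.DataFrame,
    pairs: list[tuple[str, str]],
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Normalize and test: returns (DE table, normalized matrix, size factors).

    Genes with zero counts in every sample are dropped before testing.
    """
    expressed = counts.loc[counts.sum(axis=1) > 0]
    if expressed.empty:
        raise InputError("all genes have zero counts")
    factors = size_factors(expressed)
    norm = normalize_log2(expressed, factors, pseudocount=pseudocount)
    return paired_de(norm, pairs, alpha=alpha), norm, factors


def load_external_de(path: str, alpha: float = 0.05) -> pd.DataFrame:
    """Load an externally produced DE table (columns gene, log2fc, p_fdr).

    Used verbatim downstream in place of the built-in paired test, e.g. to
    plug in a count-model DE tool's output.
    """
    table = pd.read_csv(path, sep=None, engine="python")
    required = {"gene", "log2fc", "p_fdr"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"external DE table {path}: missing columns {sorted(missing)}")
    table = table.set_index("gene")
    if "p_value" not in table.columns:
        table["p_value"] = table["p_fdr"]
    if "mean_expression" not in table.columns:
        table["mean_expression"] = np.nan
    table["significant"] = table["p_fdr"] < alpha
    return table
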