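"""Structural QC: distance clustering, targeted PCA, parental comparability.

These stages check that the methylation structure, not the statistics alone,
supports the disease interpretation: unsupervised Euclidean-distance
clustering should first split leukemic from non-leukemic samples; a PCA
restricted to the replicated CpGs should separate the same groups with the
reference cell types (CD34+, CD19+) on the non-leukemic side; and the
parents' methylation at the signature CpGs should look like any healthy
reference, ruling out an inherited pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import InputError, validate_beta


def distance_matrix(beta: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Pairwise Euclidean distances over probes non-missing in both samples.

    Distances are rescaled by sqrt(P / P_shared) so samples with different
    missingness remain comparable; the diagonal is zero.
    """
    if len(samples) < 2:
        raise InputError("at least two samples are required")
    validate_beta(beta)
    for sid in samples:
        if sid not in beta.columns:
            raise InputError(f"unknown sample id: {sid!r}")
    x = beta[samples].to_numpy(dtype=float)
    n_probes = x.shape[0]
    k = len(samples)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            shared = np.isfinite(x[:, i]) & np.isfinite(x[:, j])
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise InputError(
                    f"samples {samples[i]!r} and {samples[j]!r} share no probes"
                )
            d = np.sqrt(np.sum((x[shared, i] - x[shared, j]) ** 2))
            out[i, j] = out[j, i] = d * np.sqrt(n_probes / n_shared)
    return pd.DataFrame(out, index=samples, columns=samples)


@dataclass
class ClusterResult:
    purity: float
    assignments: pd.Series  # sample -> cluster id (1 or 2)
    linkage: np.ndarray
    degenerate: bool


def cluster_and_purity(
    distances: pd.DataFrame,
    labels: dict[str, str] | pd.Series,
    method: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering cut at two clusters, scored against labels.

    Purity is the fraction of samples whose own label matches the majority
    label of their cluster.  With all-identical samples the cut is arbitrary;
    the result is flagged degenerate.
    """
    samples = list(distances.index)
    if len(samples) < 2:
        raise InputError("clustering requires at least two samples")
    labels = pd.Series(labels)
    missing = set(samples) - set(labels.index)
    if missing:
        raise InputError(f"missing labels for samples: {sorted(missing)}")
    condensed = squareform(distances.to_numpy(), checks=False)
    degenerate = bool(np.allclose(condensed, condensed[0]))
    link = hierarchy.linkage(condensed, method=method)
    assign = pd.Series(
        hierarchy.fcluster(link, t=2, criterion="maxclust"), index=samples
    )
    correct = 0
    for cl in np.unique(assign):
        members = labels[assign.index[assign == cl]]
        majority = members.value_counts().idxmax()
        correct += int((members == majority).sum())
    return ClusterResult(
        purity=correct / len(samples),
        assignments=assign,
        linkage=link,
        degenerate=degenerate,
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    explained_variance_fraction: np.ndarray
    loadings: pd.DataFrame  # probes x components
    n_dropped_probes: int
    degenerate: bool


def pca_top_sites(
    beta: pd.DataFrame,
    probes: list[str],
    samples: list[str],
    m_values: bool = False,
) -> PCAResult:
    """Centered, unscaled PCA of the selected probes over the samples.

    Probes missing in any selected sample are dropped (count reported).  A
    fixed sign convention — the largest-magnitude loading of each component is
    positive — makes the output fully deterministic.  ``m_values`` applies
    the logit transform log2(beta / (1 - beta)) with beta clipped to
    [0.001, 0.999] first.
    """
    if len(samples) < 2:
        raise InputError("PCA requires at least two samples")
    missing = set(probes) - set(beta.index)
    if missing:
        raise InputError(f"probes absent from the beta matrix: {sorted(missing)[:5]}")
    x = beta.loc[list(probes), samples].to_numpy(dtype=float)
    complete = np.isfinite(x).all(axis=1)
    n_dropped = int((~complete).sum())
    x = x[complete]
    kept_probes = [p for p, c in zip(probes, complete) if c]
    if x.shape[0] < 2:
        raise InputError("PCA requires at least two complete probes")
    if m_values:
        clipped = np.clip(x, 0.001, 0.999)
        x = np.log2(clipped / (1.0 - clipped))
    centered = (x - x.mean(axis=1, keepdims=True)).T  # samples x probes
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(len(samples) - 1, x.shape[0])
    u, s, vt = u[:, :k], s[:k], vt[:k]
    total = float((s**2).sum())
    degenerate = total == 0.0
    explained = s**2 / total if not degenerate else np.zeros(k)
    # Sign convention: largest-|loading| entry positive per component.
    for comp in range(k):
        pivot = np.argmax(np.abs(vt[comp]))
        if vt[comp, pivot] < 0:
            vt[comp] *= -1.0
            u[:, comp] *= -1.0
    scores = pd.DataFrame(
        u * s,
        index=samples,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    loadings = pd.DataFrame(
        vt.T, index=kept_probes, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return PCAResult(
        scores=scores,
        explained_variance_fraction=explained,
        loadings=loadings,
        n_dropped_probes=n_dropped,
        degenerate=degenerate,
    )


@dataclass
class ParentalCheck:
    flags: pd.Series  # probe -> comparable (bool)
    fraction_comparable: float


def parental_check(
    signature_probes: list[str],
    beta: pd.DataFrame,
    parents: list[str],
    healthy_refs: list[str],
    tolerance: float = 0.10,
) -> ParentalCheck:
    """Flag signature CpGs where every parent matches the healthy reference.

    A probe is comparable when, for every parent,
    |beta_parent - mean(beta over healthy references)| <= tolerance.
    """
    if not healthy_refs:
        raise InputError("healthy reference sample set is empty")
    if not signature_probes:
        raise InputError("signature probe set is empty")
    for sid in list(parents) + list(healthy_refs):
        if sid not in beta.columns:
            raise InputError(f"unknown sample id: {sid!r}")
    sub = beta.loc[list(signature_probes)]
    ref_mean = sub[list(healthy_refs)].mean(axis=1)
    ok = pd.Series(True, index=sub.index)
    for p in parents:
        ok &= (sub[p] - ref_mean).abs() <= tolerance
    return ParentalCheck(flags=ok, fraction_comparable=float(ok.mean()))
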