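"""CpG-gene correlation and signature-gene selection.

Each candidate (probe, gene) pair — a replicated CpG annotated to a
differentially expressed gene — is scored by the Pearson correlation between
the probe's beta values and the gene's normalized log2 expression over the
samples with both assays (the six samples of the three DNA+RNA
diagnosis-remission pairs by default).  Two-sided p-values use the t
transform t = rho * sqrt((n-2)/(1-rho^2)) with n-2 degrees of freedom and are
Benjamini-Hochberg adjusted across ALL tested candidates.  A gene enters the
signature when it is differentially expressed and carries at least
``min_cpgs`` CpGs with |rho| >= ``rho_min`` and adjusted p <= ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust
from .io import InputError


def correlate_cpg_gene(
    beta: pd.DataFrame,
    norm_expr: pd.DataFrame,
    candidates: pd.DataFrame,
    samples: list[str],
) -> pd.DataFrame:
    """Pearson rho per candidate (probe, gene) pair over the given samples.

    ``candidates`` needs columns ``probe_id`` and ``gene`` (an optional
    ``region`` column is carried through).  Pairs where either vector has
    zero variance are flagged ``degenerate`` and excluded from testing and
    from the BH family.
    """
    if len(samples) < 3:
        raise InputError("at least three samples with both assays are required")
    if candidates.empty:
        raise InputError("candidate (probe, gene) list is empty")
    for sid in samples:
        if sid not in beta.columns:
            raise InputError(f"sample {sid!r} lacks methylation data")
        if sid not in norm_expr.columns:
            raise InputError(f"sample {sid!r} lacks expression data")
    probes = candidates["probe_id"].to_numpy()
    genes = candidates["gene"].to_numpy()
    missing_p = set(probes) - set(beta.index)
    if missing_p:
        raise InputError(f"probes absent from the beta matrix: {sorted(missing_p)[:5]}")
    missing_g = set(genes) - set(norm_expr.index)
    if missing_g:
        raise InputError(f"genes absent from the expression matrix: {sorted(missing_g)[:5]}")

    x = beta.loc[probes, samples].to_numpy(dtype=float)
    y = norm_expr.loc[genes, samples].to_numpy(dtype=float)
    n = len(samples)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    degenerate = (sx == 0) | (sy == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (xc * yc).sum(axis=1) / (sx * sy)
    rho = np.clip(rho, -1.0, 1.0)
    rho[degenerate] = np.nan

    p = np.full(len(rho), np.nan)
    ok = ~degenerate
    r = rho[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
    p[ok] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[ok & np.isclose(np.abs(rho), 1.0)] = 0.0  # |rho| = 1: t is infinite

    p_corr = np.full(len(rho), np.nan)
    if ok.any():
        p_corr[ok] = bh_adjust(p[ok])

    out = pd.DataFrame(
        {
            "probe_id": probes,
            "gene": genes,
            "rho": rho,
            "p_value": p,
            "p_corr": p_corr,
            "n_samples": n,
            "degenerate": degenerate,
        }
    )
    if "region" in candidates.columns:
        out.insert(2, "region", candidates["region"].to_numpy())
    return out


@dataclass
class SignatureSelection:
    """Signature genes plus the per-candidate records with pass flags."""

    genes: pd.DataFrame  # gene, cpgs (list), n_cpgs, correlation_sign, log2fc, p_fdr
    records: pd.DataFrame  # correlation records with a `passes` column

    @property
    def signature_cpgs(self) -> list[str]:
        seen: dict[str, None] = {}
        for cpgs in self.genes["cpgs"]:
            for c in cpgs:
                seen[c] = None
        return list(seen)


def select_signature_genes(
    records: pd.DataFrame,
    de: pd.DataFrame,
    min_cpgs: int = 3,
    rho_min: float = 0.7,
    alpha: float = 0.05,
    require_rho: bool = True,
    require_pcorr: bool = True,
) -> SignatureSelection:
    """Select genes with >= ``min_cpgs`` passing CpGs among the DE genes.

    A record passes when |rho| >= ``rho_min`` (if ``require_rho``) and
    p_corr <= ``alpha`` (if ``require_pcorr``); both criteria are applied by
    default.  ``correlation_sign`` is '-' when every passing rho is negative,
    '+' when every one is positive, 'mixed' otherwise.  Output is sorted by
    the gene's DE p_fdr ascending.
    """
    records = records.copy()
    passes = ~records["degenerate"]
    if require_rho:
        passes &= records["rho"].abs() >= rho_min
    if require_pcorr:
        passes &= records["p_corr"] <= alpha
    records["passes"] = passes.fillna(False)

    sig_de = de[de["significant"]]
    rows = []
    for gene, grp in records[records["passes"]].groupby("gene", sort=True):
        if gene not in sig_de.index or len(grp) < min_cpgs:
            continue
        rhos = grp["rho"].to_numpy()
        if (rhos < 0).all():
            sign = "-"
        elif (rhos > 0).all():
            sign = "+"
        else:
            sign = "mixed"
        rows.append(
            {
                "gene": gene,
                "cpgs": list(grp["probe_id"]),
                "n_cpgs": len(grp),
                "correlation_sign": sign,
                "log2fc": float(sig_de.loc[gene, "log2fc"]),
                "p_fdr": float(sig_de.loc[gene, "p_fdr"]),
            }
        )
    genes = pd.DataFrame(
        rows, columns=["gene", "cpgs", "n_cpgs", "correlation_sign", "log2fc", "p_fdr"]
    )
    if not genes.empty:
        genes = genes.sort_values("p_fdr", kind="stable").reset_index(drop=True)
    return SignatureSelection(genes=genes, records=records)


def build_candidates(
    replicated_probes: list[str],
    manifest_long: pd.DataFrame,
    de: pd.DataFrame,
) -> pd.DataFrame:
    """Candidate (probe, gene) pairs: replicated CpGs annotated to DE genes.

    A probe annotated to several DE genes contributes one candidate per gene;
    duplicate (probe, gene) pairs arising from multiple region annotations
    keep the first region listed.
    """
    sig_genes = set(de.index[de["significant"]])
    long = manifest_long[
        manifest_long["probe_id"].isin(set(replicated_probes))
        & manifest_long["gene"].isin(sig_genes)
    ]
    return (
        long.drop_duplicates(subset=["probe_id", "gene"])
        .reset_index(drop=True)
        .loc[:, ["probe_id", "gene", "region"]]
    )
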