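"""Replication of twin-filtered CpGs in independent diagnosis-remission pairs.

A paired t statistic is computed per probe over the diagnosis-minus-remission
beta differences; replication then intersects the twin-retained set with
probes showing a mean paired difference strictly above ``effect_min`` in the
same direction.  No p-value cutoff is applied by default — the replication
criterion is the effect size and direction; an optional ``alpha`` restores a
significance requirement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import TwinFilterResult
from .io import InputError, validate_beta


@dataclass
class PairedTResult:
    """Per-probe paired t table: ``mean_paired_diff``, ``sd_paired_diff``,
    ``t_stat``, ``p_value``, ``n_pairs``, ``direction``, ``degenerate``.

    ``degenerate`` marks probes with zero difference variance but a nonzero
    mean, for which t is infinite and p is reported as 0 (the effect-size
    criterion, not p, is decisive downstream)."""

    table: pd.DataFrame
    n_excluded_incomplete: int


def paired_t_test(
    beta: pd.DataFrame, pairs: list[tuple[str, str]]
) -> PairedTResult:
    """Two-sided paired t-test per probe over diagnosis-remission pairs.

    Pairs with a missing value in either member are dropped per probe; probes
    with fewer than two complete pairs are excluded (their count is reported).
    """
    if len(pairs) < 2:
        raise InputError("at least two diagnosis-remission pairs are required")
    validate_beta(beta)
    flat = [s for pair in pairs for s in pair]
    if len(set(flat)) != len(flat):
        raise InputError("a sample id appears in more than one pair")
    for sid in flat:
        if sid not in beta.columns:
            raise InputError(f"unknown sample id: {sid!r}")

    diag = beta[[d for d, _ in pairs]].to_numpy(dtype=float)
    rem = beta[[r for _, r in pairs]].to_numpy(dtype=float)
    diffs = diag - rem
    complete = np.isfinite(diffs)
    n = complete.sum(axis=1)
    keep = n >= 2
    n_excluded = int((~keep).sum())

    diffs = np.where(complete, diffs, np.nan)[keep]
    n = n[keep]
    mean = np.nanmean(diffs, axis=1)
    sd = np.nanstd(diffs, axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    # identical differences up to float rounding: sd is effectively zero
    tiny = 1e-12
    degenerate = (sd <= tiny) & (np.abs(mean) > tiny)
    zero = (sd <= tiny) & (np.abs(mean) <= tiny)
    sd = np.where(sd <= tiny, 0.0, sd)
    t[degenerate] = np.sign(mean[degenerate]) * np.inf
    t[zero] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[degenerate] = 0.0
    p[zero] = 1.0

    table = pd.DataFrame(
        {
            "mean_paired_diff": mean,
            "sd_paired_diff": sd,
            "t_stat": t,
            "p_value": p,
            "n_pairs": n,
            "direction": np.where(mean > 0, "hyper", "hypo"),
            "degenerate": degenerate,
        },
        index=beta.index[keep],
    )
    table.index.name = "probe_id"
    return PairedTResult(table=table, n_excluded_incomplete=n_excluded)


@dataclass
class ReplicationIntersection:
    """Replicated probe set: twin-retained CpGs confirmed by the paired test."""

    table: pd.DataFrame
    n_hyper: int
    n_hypo: int

    @property
    def probes(self) -> list[str]:
        return list(self.table.index)


def replicate_intersect(
    twin_result: TwinFilterResult,
    rep_result: PairedTResult,
    effect_min: float = 0.30,
    alpha: float | None = None,
) -> ReplicationIntersection:
    """Intersect the twin-retained set with the paired-test results.

    A probe replicates when it is twin-retained, |mean paired difference| is
    strictly greater than ``effect_min``, and the paired direction matches the
    twin direction (twin hyper <-> positive mean difference).  Twin-discordant
    probes carry no direction and never replicate.  If ``alpha`` is given the
    paired p-value must also be <= ``alpha``.
    """
    if twin_result.table.empty or rep_result.table.empty:
        raise InputError("twin filter and paired-test results must be nonempty")
    twin = twin_result.table[twin_result.table["retained"]]
    rep = rep_result.table
    common = twin.index.intersection(rep.index)
    twin = twin.loc[common]
    rep = rep.loc[common]
    ok = (np.abs(rep["mean_paired_diff"]) > effect_min) & (
        twin["direction"] == rep["direction"]
    )
    if alpha is not None:
        ok &= rep["p_value"] <= alpha
    table = rep.loc[ok].copy()
    table["direction"] = twin.loc[ok, "direction"]
    return ReplicationIntersection(
        table=table,
        n_hyper=int((table["direction"] == "hyper").sum()),
        n_hypo=int((table["direction"] == "hypo").sum()),
    )
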