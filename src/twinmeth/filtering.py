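"""Twin-contrast delta-beta filter.

Defines disease-related methylation changes in a discordant-twin trio: a CpG
is retained when the proband at diagnosis differs from BOTH her healthy twin
and her own remission sample by at least ``delta_min`` (|delta-beta| >= 0.30
by default) while the two healthy samples agree within ``delta_max_healthy``
(<= 0.10 by default).  All deltas are proband minus healthy; a probe whose
two proband contrasts pass in magnitude but disagree in sign is retained but
labelled ``discordant`` and carries no hyper/hypo direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import InputError, validate_beta


@dataclass
class TwinFilterResult:
    """Per-probe twin-filter table plus bookkeeping.

    ``table`` columns: ``delta_proband_twin``, ``delta_proband_remission``,
    ``delta_healthy``, ``direction`` (hyper|hypo|discordant), ``retained``;
    indexed by probe id.  Probes with a missing value in any of the three
    samples are excluded and counted in ``n_excluded_missing``.
    """

    table: pd.DataFrame
    n_excluded_missing: int
    delta_min: float
    delta_max_healthy: float

    @property
    def retained_probes(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])

    def direction_counts(self) -> dict[str, int]:
        retained = self.table[self.table["retained"]]
        return {
            "hyper": int((retained["direction"] == "hyper").sum()),
            "hypo": int((retained["direction"] == "hypo").sum()),
            "discordant": int((retained["direction"] == "discordant").sum()),
        }


def twin_delta_filter(
    beta: pd.DataFrame,
    proband: str,
    twin: str,
    remission: str,
    delta_min: float = 0.30,
    delta_max_healthy: float = 0.10,
) -> TwinFilterResult:
    """Apply the twin-contrast filter to a probes x samples beta matrix.

    Thresholds are inclusive on both sides: |delta| >= ``delta_min`` for the
    two proband contrasts and |delta| <= ``delta_max_healthy`` between the
    healthy samples.
    """
    if beta.empty:
        raise InputError("beta matrix is empty")
    validate_beta(beta)
    ids = (proband, twin, remission)
    if len(set(ids)) != 3:
        raise InputError("proband, twin and remission sample ids must be distinct")
    for sid in ids:
        if sid not in beta.columns:
            raise InputError(f"unknown sample id: {sid!r}")

    sub = beta[[proband, twin, remission]].to_numpy(dtype=float)
    complete = np.isfinite(sub).all(axis=1)
    n_missing = int((~complete).sum())
    sub = sub[complete]
    index = beta.index[complete]

    d_twin = sub[:, 0] - sub[:, 1]
    d_rem = sub[:, 0] - sub[:, 2]
    d_healthy = sub[:, 1] - sub[:, 2]

    retained = (
        (np.abs(d_twin) >= delta_min)
        & (np.abs(d_rem) >= delta_min)
        & (np.abs(d_healthy) <= delta_max_healthy)
    )
    direction = np.where(
        (d_twin > 0) & (d_rem > 0),
        "hyper",
        np.where((d_twin < 0) & (d_rem < 0), "hypo", "discordant"),
    )
    table = pd.DataFrame(
        {
            "delta_proband_twin": d_twin,
            "delta_proband_remission": d_rem,
            "delta_healthy": d_healthy,
            "direction": direction,
            "retained": retained,
        },
        index=index,
    )
    table.index.name = "probe_id"
    return TwinFilterResult(
        table=table,
        n_excluded_missing=n_missing,
        delta_min=delta_min,
        delta_max_healthy=delta_max_healthy,
    )
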