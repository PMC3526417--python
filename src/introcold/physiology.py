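"""Electrolyte-leakage membrane-stability statistic.

Percent injury from conductivity measurements:

    injury = (L_t - L_c) / (100 - L_c) * 100

where L_t and L_c are percent conductivity of the treated and control
samples.  Injury is 0 when treated equals control, 100 when the treated
sample is fully leaked (L_t = 100), and is strictly increasing in L_t.
Negative values (treated below control) are reported as-is and flagged
rather than clipped.
"""

from __future__ import annotations

import pandas as pd

from .sam_test import ContractError


def percent_injury(L_t: float, L_c: float) -> float:
    """Percent injury from treated/control percent conductivities."""
    if not (0 <= L_c < 100):
        raise ContractError(f"control conductivity must be in [0, 100), got {L_c}")
    if not (0 <= L_t <= 100):
        raise ContractError(f"treated conductivity must be in [0, 100], got {L_t}")
    return (L_t - L_c) / (100.0 - L_c) * 100.0


def injury_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate injury plus group mean +/- sd.

    Expects columns ``group`` (any label, e.g. genotype), ``replicate``,
    ``L_t``, ``L_c``.  Returns ``(per_replicate, summary)``: the input with
    ``injury`` and ``negative_flagged`` columns added, and one mean +/- sd
    row per group.
    """
    required = {"group", "replicate", "L_t", "L_c"}
    missing = required - set(measurements.columns)
    if missing:
        raise ContractError(f"missing columns {sorted(missing)}")
    df = measurements.copy()
    df["injury"] = [
        percent_injury(row.L_t, row.L_c) for row in df.itertuples()
    ]
    df["negative_flagged"] = df["injury"] < 0
    summary = (
        df.groupby("group")["injury"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0)
        .reset_index()
    )
    return df, summary
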