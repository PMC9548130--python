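"""Behavioral indices shared by simulation predictions and assay data.

Two ratios summarize aversion behavior: the response index of the dry-drop
assay (fraction of stimulus presentations that elicit backward movement) and
the occupancy index of the lawn-avoidance assay (fraction of animals on the
bacterial lawn).  Both are exact rationals reported as floats so group
summaries carry no hidden rounding.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "response_index",
    "occupancy_index",
    "summarize_counts",
]


def response_index(n_responses: int, n_drops: int) -> float:
    """N_responses / N_drops, the dry-drop assay readout."""
    if n_drops <= 0:
        raise ValueError("n_drops must be > 0")
    if not 0 <= n_responses <= n_drops:
        raise ValueError("require 0 <= n_responses <= n_drops")
    return n_responses / n_drops


def occupancy_index(n_on_lawn: int, n_total: int) -> float:
    """N_on_lawn / N_total, the lawn-avoidance assay readout."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_on_lawn <= n_total:
        raise ValueError("require 0 <= n_on_lawn <= n_total")
    return n_on_lawn / n_total


def summarize_counts(
    counts_csv: str | Path, out_csv: str | Path | None = None
) -> pd.DataFrame:
    """Per-group means and standard deviations of the indices.

    Input: one row per animal or plate with columns ``group`` plus either
    ``n_responses,n_drops`` or ``n_on_lawn,n_total`` (or both).
    """
    df = pd.read_csv(counts_csv)
    if "group" not in df.columns:
        raise ValueError("counts CSV must have a 'group' column")
    if {"n_responses", "n_drops"}.issubset(df.columns):
        df["response_index"] = [
            response_index(int(a), int(b))
            for a, b in zip(df["n_responses"], df["n_drops"])
        ]
    if {"n_on_lawn", "n_total"}.issubset(df.columns):
        df["occupancy_index"] = [
            occupancy_index(int(a), int(b))
            for a, b in zip(df["n_on_lawn"], df["n_total"])
        ]
    value_cols = [
        c for c in ("response_index", "occupancy_index") if c in df.columns
    ]
    if not value_cols:
        raise ValueError(
            "counts CSV needs n_responses/n_drops or n_on_lawn/n_total columns"
        )
    out = df.groupby("group")[value_cols].agg(["mean", "std", "count"])
    out.columns = ["_".join(c) for c in out.columns]
    out = out.reset_index()
    if out_csv is not None:
        out.to_csv(out_csv, index=False)
    return out
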