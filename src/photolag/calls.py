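"""Shared regulation-calling logic for both omics layers.

A feature is *regulated* when at least one post-pulse condition passes both
the layer's significance criterion and an absolute fold-change cutoff
relative to the dark control.  The peak condition is the qualifying
condition with the largest |log2 fold-change| (ties broken by the earliest
time point), and regulated transcripts are classed *early* or *late* by
whether the peak falls at or before the early/late boundary.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

PROFILE_COLUMNS = ["feature_id", "condition", "minutes", "log2fc", "raw_p", "n_obs"]


def classify_timing(peak_minutes: float, boundary: float = 25.0) -> str:
    """'early' if the peak time is at or before ``boundary`` minutes, else 'late'."""
    if peak_minutes is None or (isinstance(peak_minutes, float) and math.isnan(peak_minutes)):
        raise ValueError("timing is undefined for unregulated features")
    return "early" if peak_minutes <= boundary else "late"


def call_regulated(
    profiles: pd.DataFrame,
    p_threshold: float,
    fc_threshold: float = 2.0,
    p_column: str = "raw_p",
    early_boundary: float = 25.0,
) -> pd.DataFrame:
    """Turn per-condition fold-change profiles into per-feature regulation calls.

    ``profiles`` is the tidy table produced by the layer pipelines (one row
    per feature x condition, control included with log2fc 0).  Returns one
    row per feature: regulated flag, direction (up/down), peak condition,
    peak minutes, peak log2fc and early/late timing ('none' if unregulated).
    """
    required = {"feature_id", "condition", "minutes", "log2fc", p_column}
    missing = required - set(profiles.columns)
    if missing:
        raise ValueError(f"profiles table lacks columns {sorted(missing)}")
    lfc_cut = math.log2(fc_threshold)

    candidates = profiles.loc[
        profiles["minutes"].notna()
        & (profiles[p_column] < p_threshold)
        & (profiles["log2fc"].abs() >= lfc_cut)
    ].copy()
    candidates["abs_lfc"] = candidates["log2fc"].abs()
    # peak = largest |log2fc| among qualifying conditions; tie -> earliest time
    candidates = candidates.sort_values(
        ["feature_id", "abs_lfc", "minutes"], ascending=[True, False, True],
        kind="mergesort",
    )
    peaks = candidates.drop_duplicates("feature_id", keep="first").set_index("feature_id")

    features = profiles["feature_id"].drop_duplicates()
    calls = pd.DataFrame(index=pd.Index(features, name="feature_id"))
    calls["regulated"] = calls.index.isin(peaks.index)
    calls["direction"] = pd.NA
    calls["peak_condition"] = pd.NA
    calls["peak_minutes"] = np.nan
    calls["peak_log2fc"] = np.nan
    calls["timing"] = "none"
    idx = peaks.index
    calls.loc[idx, "direction"] = np.where(peaks["log2fc"] > 0, "up", "down")
    calls.loc[idx, "peak_condition"] = peaks["condition"]
    calls.loc[idx, "peak_minutes"] = peaks["minutes"]
    calls.loc[idx, "peak_log2fc"] = peaks["log2fc"]
    calls.loc[idx, "timing"] = [
        classify_timing(m, early_boundary) for m in peaks["minutes"]
    ]
    return calls.reset_index()
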