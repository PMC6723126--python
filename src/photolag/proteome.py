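"""Protein reporter-intensity processing and regulation calling.

The pipeline stages, in fixed order:

1. ``vst_transform`` — per-sample affine calibration followed by arsinh
   (a generalized-log variance-stabilizing transform), making samples
   comparable in location and scale;
2. ``remove_batch`` — per-protein additive condition + batch least-squares
   model, subtracting the fitted batch effects (sum-to-zero across batches);
3. ``filter_presence`` — keep proteins quantified in at least ``min_runs``
   replicate runs (missingness marks whole-run absence);
4. ``knn_impute`` — fill remaining holes from the k nearest fully-observed
   proteins (inverse-distance-weighted mean over the observed columns);
5. ``test_protein`` — per-condition moderated one-sample test on
   replicate-paired differences vs the dark control, Benjamini-Hochberg
   FDR across proteins within each condition;
6. ``call_regulated_proteins`` — twofold cutoff at FDR < 0.05, any time point.

Fold-changes on the transformed scale are divided by ln 2, which for
intensities well above the calibration scale equals the log2 intensity
ratio (arsinh(x) -> ln(2x)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from statsmodels.stats.multitest import multipletests

from .calls import call_regulated
from .matrix import AbundanceMatrix

_LN2 = math.log(2.0)

PIPELINE_ORDER = ("vst", "batch", "presence", "impute", "test")


def vst_transform(
    matrix: AbundanceMatrix, scale_fraction: float = 0.02
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Variance-stabilizing transform: per-sample calibration + arsinh (glog).

    Each sample is calibrated by its own scale b_s = scale_fraction *
    median_s before the arsinh, y = arsinh(x / b_s), so samples differing by
    a loading or labelling factor become directly comparable (the transform
    is exactly equivariant under per-sample rescaling).  b_s plays the role
    of the additive-noise floor of a glog transform: intensities a few
    multiples of b_s and above transform on the log scale (arsinh(x) ->
    ln 2x), so their differences read as log fold-changes, while
    near-background intensities are compressed.  Strictly monotone per
    sample.  A zero-median sample falls back to scale 1 with a warning.
    """
    if matrix.layer != "protein":
        raise ValueError("vst_transform applies to the protein layer")
    if not scale_fraction > 0:
        raise ValueError("scale_fraction must be > 0")
    vals = matrix.values.to_numpy(dtype=float)
    out = np.empty_like(vals)
    rows = []
    for j, sample in enumerate(matrix.values.columns):
        col = vals[:, j]
        obs = col[~np.isnan(col)]
        if len(obs) == 0:
            raise ValueError(f"sample {sample!r} has no observed values")
        b = scale_fraction * float(np.median(obs))
        if b == 0:
            warnings.warn(f"sample {sample!r} has zero median; using scale 1")
            b = 1.0
        out[:, j] = np.arcsinh(col / b)
        rows.append({"sample": sample, "scale": b})
    transformed = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return (
        matrix.with_values(transformed, transformed=True),
        pd.DataFrame(rows).set_index("sample"),
    )


def remove_batch(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Subtract per-protein additive batch effects (least squares).

    Fits value = condition effect + batch effect per protein, with batch
    encoded by sum-to-zero contrasts so the removed effects sum to zero
    across batches and condition effects are untouched.  With a single
    batch the matrix is returned unchanged.  Warns on confounded designs.
    """
    samples = matrix.samples
    batches = sorted(samples["batch"].unique())
    if len(batches) == 1:
        return matrix.with_values(matrix.values.copy())
    conds = matrix.conditions
    per_batch = samples.groupby("condition")["batch"].nunique()
    if (per_batch < len(batches)).any():
        warnings.warn("some conditions are absent from some batches; "
                      "batch effects estimated from the available contrasts")

    cond_dummies = pd.get_dummies(samples["condition"], dtype=float)[conds]
    batch_codes = pd.Categorical(samples["batch"], categories=batches).codes
    n_b = len(batches)
    contrasts = np.zeros((len(samples), n_b - 1))
    for i, code in enumerate(batch_codes):
        if code < n_b - 1:
            contrasts[i, code] = 1.0
        else:
            contrasts[i, :] = -1.0
    X = np.hstack([cond_dummies.to_numpy(), contrasts])
    n_cond = len(conds)

    vals = matrix.values.to_numpy(dtype=float)
    out = vals.copy()
    complete = ~np.isnan(vals).any(axis=1)
    if complete.any():
        coef, *_ = np.linalg.lstsq(X, vals[complete].T, rcond=None)
        batch_fit = contrasts @ coef[n_cond:, :]
        out[complete] = vals[complete] - batch_fit.T
    for i in np.nonzero(~complete)[0]:
        obs = ~np.isnan(vals[i])
        if obs.sum() == 0:
            continue
        coef, *_ = np.linalg.lstsq(X[obs], vals[i, obs], rcond=None)
        out[i, obs] = vals[i, obs] - X[obs][:, n_cond:] @ coef[n_cond:]
    corrected = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(corrected)


def filter_presence(
    matrix: AbundanceMatrix, min_runs: int = 2
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Keep proteins detected in at least ``min_runs`` replicate runs.

    A protein counts as detected in a run when any of that run's samples
    holds an observed value.  Returns the filtered matrix and a presence
    table (protein_id, detected_in, n_detected) covering every input protein.
    """
    samples = matrix.samples
    runs = sorted(samples["batch"].unique())
    detected = pd.DataFrame(index=matrix.feature_ids, columns=runs, dtype=bool)
    for run in runs:
        cols = samples.index[samples["batch"] == run]
        detected[run] = matrix.values[cols].notna().any(axis=1)
    presence = pd.DataFrame(
        {
            "protein_id": matrix.feature_ids,
            "detected_in": [
                ";".join(r for r in runs if row[r]) for _, row in detected.iterrows()
            ],
            "n_detected": detected.sum(axis=1).to_numpy(),
        }
    )
    keep = presence.loc[presence["n_detected"] >= min_runs, "protein_id"]
    kept = matrix.with_values(matrix.values.loc[keep])
    return kept, presence


def replicate_overlap_counts(presence: pd.DataFrame) -> dict[str, int]:
    """Venn-style exclusive region counts from a presence table.

    Keys are sorted run combinations like ``"R1&R3"``; values are the number
    of proteins detected in exactly that set of runs.
    """
    counts: dict[str, int] = {}
    for det in presence["detected_in"]:
        runs = [r for r in det.split(";") if r]
        key = "&".join(sorted(runs)) if runs else "none"
        counts[key] = counts.get(key, 0) + 1
    return counts


def knn_impute(matrix: AbundanceMatrix, k: int = 10) -> AbundanceMatrix:
    """Impute missing cells from the k nearest fully-observed proteins.

    For each incomplete protein, candidate neighbors are the proteins with
    no missing values; distance is Euclidean over the columns where the
    target is observed; the imputed value is the 1/distance-weighted mean of
    the neighbors' values in the missing columns (a zero-distance neighbor
    set falls back to a simple mean).  Observed entries are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = matrix.values.to_numpy(dtype=float)
    out = vals.copy()
    nan_mask = np.isnan(vals)
    complete = ~nan_mask.any(axis=1)
    incomplete_idx = np.nonzero(~complete & ~nan_mask.all(axis=1))[0]
    if len(incomplete_idx) == 0:
        return matrix.with_values(matrix.values.copy())
    if not complete.any():
        raise ValueError("no fully-observed proteins available as neighbors")
    pool = vals[complete]
    if len(pool) < k:
        warnings.warn(
            f"only {len(pool)} complete proteins available; using all as neighbors"
        )
    k_eff = min(k, len(pool))

    # missingness is whole-run, so observation patterns repeat; group them
    patterns: dict[bytes, list[int]] = {}
    for i in incomplete_idx:
        patterns.setdefault(nan_mask[i].tobytes(), []).append(i)
    for key, members in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        obs_cols = np.nonzero(~mask)[0]
        mis_cols = np.nonzero(mask)[0]
        D = cdist(vals[np.ix_(members, obs_cols)], pool[:, obs_cols])
        order = np.argsort(D, axis=1, kind="stable")[:, :k_eff]
        for row_pos, i in enumerate(members):
            nb = order[row_pos]
            d = D[row_pos, nb]
            if (d == 0).any():
                nb = nb[d == 0]
                w = np.ones(len(nb))
            else:
                w = 1.0 / d
            out[np.ix_([i], mis_cols)] = (
                w @ pool[np.ix_(nb, mis_cols)] / w.sum()
            )
    imputed = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(imputed)


def test_protein(
    matrix: AbundanceMatrix, smoothing_weight: float = 0.5
) -> pd.DataFrame:
    """Moderated per-condition one-sample tests on run-paired differences.

    For each condition, the replicate-wise differences (condition minus
    control within the same run) are tested against zero with a moderated t
    statistic: the per-protein variance is shrunk toward a pooled estimate
    of the typical across-protein variance, s2_mod = (1 - w) * s2 + w * s0.
    The pool s0 is the median per-protein variance rescaled by the median
    of its chi-square sampling distribution — an estimator of the common
    variance that, unlike the plain mean, is not inflated by the heavy
    upper tail of a minority of high-variance proteins.  The shrinkage is
    the inverse-chi-square posterior mean with prior degrees of freedom
    d0 = d * w / (1 - w) for residual df d = n - 1, so the reference
    distribution is t with d + d0 degrees of freedom.
    ``smoothing_weight = 0`` recovers the plain one-sample t-test exactly.
    P-values are BH-adjusted across proteins within each condition.
    Requires a complete (imputed) matrix.
    """
    if not 0 <= smoothing_weight <= 1:
        raise ValueError("smoothing_weight must be in [0, 1]")
    vals = matrix.values
    if vals.isna().any().any():
        raise ValueError("test_protein requires a complete matrix (impute first)")
    samples = matrix.samples
    ctrl = matrix.control_label
    runs = sorted(samples["batch"].unique())
    if len(runs) < 2:
        raise ValueError("need >= 2 replicate runs")
    minutes = matrix.condition_minutes()

    def run_col(cond: str, run: str) -> str:
        sel = samples.index[(samples["condition"] == cond) & (samples["batch"] == run)]
        if len(sel) != 1:
            raise ValueError(f"expected one sample for {cond!r} in run {run!r}")
        return sel[0]

    ctrl_mat = np.column_stack([vals[run_col(ctrl, r)] for r in runs])
    n = len(runs)
    frames = []
    n_feat = len(vals)
    for cond in matrix.conditions:
        if cond == ctrl:
            frames.append(pd.DataFrame({
                "feature_id": vals.index, "condition": cond, "minutes": np.nan,
                "log2fc": 0.0, "raw_p": 1.0, "adj_p": 1.0, "n_obs": n,
            }))
            continue
        diff = np.column_stack([vals[run_col(cond, r)] for r in runs]) - ctrl_mat
        mean_d = diff.mean(axis=1)
        var_d = diff.var(axis=1, ddof=1)
        resid_df = n - 1
        # robust pooled variance: median corrected for chi-square skew
        s0 = np.median(var_d) * resid_df / stats.chi2.ppf(0.5, resid_df)
        s2_mod = (1 - smoothing_weight) * var_d + smoothing_weight * s0
        if smoothing_weight < 1:
            df = resid_df * (1 + smoothing_weight / (1 - smoothing_weight))
        else:
            df = np.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean_d / np.sqrt(s2_mod / n)
        p = 2 * stats.t.sf(np.abs(t), df=df)
        zero_var = s2_mod == 0
        p[zero_var & (mean_d == 0)] = 1.0
        p[zero_var & (mean_d != 0)] = 0.0
        adj = multipletests(p, method="fdr_bh")[1]
        frames.append(pd.DataFrame({
            "feature_id": vals.index, "condition": cond, "minutes": minutes[cond],
            "log2fc": mean_d / _LN2, "raw_p": p, "adj_p": adj, "n_obs": n,
        }))
    return pd.concat(frames, ignore_index=True)


def call_regulated_proteins(
    profiles: pd.DataFrame,
    fdr: float = 0.05,
    fc_threshold: float = 2.0,
    early_boundary: float = 25.0,
) -> pd.DataFrame:
    """Protein regulation rule: BH FDR and twofold at any time point.

    Adds ``peak_at_final``: whether the peak change sits at the last sampled
    time point (the hallmark of slowly accumulating protein responses).
    """
    calls = call_regulated(
        profiles,
        p_threshold=fdr,
        fc_threshold=fc_threshold,
        p_column="adj_p",
        early_boundary=early_boundary,
    )
    final_minute = profiles["minutes"].max()
    calls["peak_at_final"] = calls["regulated"] & (calls["peak_minutes"] == final_minute)
    return calls


@dataclass
class PeakTimeSummary:
    n_regulated: int
    n_peak_final: int
    percent_final: float


def peak_time_summary(calls: pd.DataFrame) -> PeakTimeSummary:
    """Fraction of regulated proteins whose change peaks at the final time point."""
    from .report import round_half_up

    reg = calls.loc[calls["regulated"]]
    n = len(reg)
    n_final = int(reg["peak_at_final"].sum()) if n else 0
    pct = round_half_up(100.0 * n_final / n, 1) if n else 0.0
    return PeakTimeSummary(n_regulated=n, n_peak_final=n_final, percent_final=pct)


def run_proteome_pipeline(
    matrix: AbundanceMatrix,
    min_runs: int = 2,
    knn_k: int = 10,
    smoothing_weight: float = 0.5,
    fdr: float = 0.05,
    fc_threshold: float = 2.0,
    scale_fraction: float = 0.02,
) -> dict:
    """Run the full fixed-order pipeline; returns all intermediate products."""
    transformed, calibration = vst_transform(matrix, scale_fraction=scale_fraction)
    corrected = remove_batch(transformed)
    kept, presence = filter_presence(corrected, min_runs=min_runs)
    imputed = knn_impute(kept, k=knn_k)
    profiles = test_protein(imputed, smoothing_weight=smoothing_weight)
    calls = call_regulated_proteins(profiles, fdr=fdr, fc_threshold=fc_threshold)
    return {
        "calibration": calibration,
        "presence": presence,
        "overlap_counts": replicate_overlap_counts(presence),
        "imputed": imputed,
        "profiles": profiles,
        "calls": calls,
        "order": PIPELINE_ORDER,
    }
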