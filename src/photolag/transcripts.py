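"""Transcript-layer differential expression against the dark control.

The layer starts from a gene-by-sample abundance matrix (counts or FPKM-like
values).  Samples are rescaled by median-of-ratios size factors, per-condition
log2 fold-changes are computed against the dark control on the
log2(x + pseudocount) scale, each condition is tested against the control
with Welch's two-sample t-test, and a gene is called light-regulated when at
least one time point satisfies both P < 0.01 and a twofold cutoff.  No
multiple-testing correction is applied on this layer; the significance
criterion is a raw P threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calls import call_regulated, classify_timing  # noqa: F401  (re-exported)
from .matrix import AbundanceMatrix


def normalize_library(matrix: AbundanceMatrix) -> tuple[AbundanceMatrix, pd.Series]:
    """Median-of-ratios library-size normalization.

    Each sample is divided by the median, over features with no zero value,
    of its ratio to the per-feature geometric mean.  Returns the rescaled
    matrix and the estimated size factors.
    """
    if matrix.layer != "transcript":
        raise ValueError("library normalization applies to the transcript layer")
    vals = matrix.values.to_numpy(dtype=float)
    if not (vals > 0).any():
        raise ValueError("cannot normalize an all-zero matrix")
    positive = (vals > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no zero-free features available for size-factor estimation")
    logs = np.log(vals[positive])
    log_geo = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo, axis=0))
    scaled = matrix.values / factors
    return matrix.with_values(scaled), pd.Series(
        factors, index=matrix.values.columns, name="size_factor"
    )


def _welch_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Welch p-values per row, with the degenerate-variance
    convention p=1 when both groups are constant with equal means (t=0/0)
    and p=0 when constant with different means."""
    import warnings

    with warnings.catch_warnings():
        # near-constant rows are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    ma = a.mean(axis=1)
    mb = b.mean(axis=1)
    # variances that are zero up to float cancellation noise
    tol = 1e-20 * (1.0 + ma**2 + mb**2)
    degenerate = (va <= tol) & (vb <= tol)
    if degenerate.any():
        equal = np.isclose(ma, mb)
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    p[np.isnan(p)] = 1.0
    return p


def fold_changes(
    matrix: AbundanceMatrix, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-feature, per-condition log2 fold-change vs control with Welch P.

    log2fc(condition) = mean over replicates of log2(x + pseudocount) at the
    condition minus the same at the control; the control row is exactly 0.
    Returns a tidy table (feature_id, condition, minutes, log2fc, raw_p, n_obs).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    ctrl = matrix.control_label
    log_vals = np.log2(matrix.values.to_numpy(dtype=float) + pseudocount)
    cols = list(matrix.values.columns)
    ctrl_idx = [cols.index(c) for c in matrix.condition_columns(ctrl)]
    ctrl_log = log_vals[:, ctrl_idx]
    ctrl_mean = ctrl_log.mean(axis=1)
    minutes = matrix.condition_minutes()

    frames = []
    n_feat = len(matrix.feature_ids)
    for cond in matrix.conditions:
        if cond == ctrl:
            lfc = np.zeros(n_feat)
            p = np.ones(n_feat)
            mins = np.nan
            n_obs = len(ctrl_idx)
        else:
            idx = [cols.index(c) for c in matrix.condition_columns(cond)]
            if len(idx) < 2 or len(ctrl_idx) < 2:
                raise ValueError("each group needs >= 2 replicates for testing")
            grp = log_vals[:, idx]
            lfc = grp.mean(axis=1) - ctrl_mean
            p = _welch_p(grp, ctrl_log)
            mins = minutes[cond]
            n_obs = len(idx)
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": matrix.feature_ids,
                    "condition": cond,
                    "minutes": mins,
                    "log2fc": lfc,
                    "raw_p": p,
                    "n_obs": n_obs,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def test_condition(
    matrix: AbundanceMatrix, condition: str, pseudocount: float = 1.0
) -> pd.Series:
    """Welch two-sample t-test of one condition vs the control (two-sided P)."""
    profiles = fold_changes(matrix, pseudocount=pseudocount)
    sub = profiles.loc[profiles["condition"] == condition]
    if sub.empty:
        raise KeyError(f"condition {condition!r} not present")
    return sub.set_index("feature_id")["raw_p"]


def call_regulated_transcripts(
    profiles: pd.DataFrame,
    p_threshold: float = 0.01,
    fc_threshold: float = 2.0,
    early_boundary: float = 25.0,
) -> pd.DataFrame:
    """Apply the transcript regulation rule (raw P and twofold, any time point)."""
    return call_regulated(
        profiles,
        p_threshold=p_threshold,
        fc_threshold=fc_threshold,
        p_column="raw_p",
        early_boundary=early_boundary,
    )


@dataclass
class PCASummary:
    coordinates: pd.DataFrame        # conditions x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame           # features x components


def pca_summary(profiles: pd.DataFrame, n_components: int | None = None) -> PCASummary:
    """PCA of the condition-by-feature log2 fold-change matrix.

    Conditions are the observations (so nearby points are time points with
    similar genome-wide responses).  Columns are centered; components are
    oriented so the first nonzero loading of each is positive.
    """
    wide = profiles.pivot(index="condition", columns="feature_id", values="log2fc")
    X = wide.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 conditions and >= 2 features")
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        raise ValueError("constant matrix has no principal components")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(Vt.shape[0]):
        nonzero = np.nonzero(np.abs(Vt[i]) > 1e-12)[0]
        if len(nonzero) and Vt[i, nonzero[0]] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    k = len(S) if n_components is None else min(n_components, len(S))
    var = S**2
    ratio = var / var.sum()
    comp_names = [f"PC{i+1}" for i in range(k)]
    coords = pd.DataFrame(U[:, :k] * S[:k], index=wide.index, columns=comp_names)
    loadings = pd.DataFrame(Vt[:k].T, index=wide.columns, columns=comp_names)
    return PCASummary(coordinates=coords, explained_variance_ratio=ratio[:k], loadings=loadings)
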