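"""Protein pipeline: VST, batch removal, presence filter, kNN, moderated test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from photolag import (
    NoiseModel,
    PulseDesign,
    call_regulated_proteins,
    filter_presence,
    generate_dataset,
    knn_impute,
    remove_batch,
    run_proteome_pipeline,
    vst_transform,
)
from photolag.proteome import peak_time_summary, replicate_overlap_counts
from photolag.proteome import test_protein as protein_test

from conftest import toy_matrix

DESIGN = PulseDesign()
RNG = np.random.default_rng(1)


# -- variance-stabilizing transform ----------------------------------------


def test_vst_removes_exact_sample_scale_factors():
    base = RNG.uniform(100, 10000, size=(200, 1))
    vals = np.tile(base, (1, 18))
    vals[:, 4] *= 3.7  # one sample loaded 3.7x heavier
    out, _ = vst_transform(toy_matrix(vals, "protein"))
    np.testing.assert_allclose(out.values.iloc[:, 4], out.values.iloc[:, 0], atol=1e-6)
    assert np.median(out.values.iloc[:, 4]) == pytest.approx(
        np.median(out.values.iloc[:, 0]), abs=1e-6
    )


def test_vst_is_strictly_monotone_per_sample():
    vals = RNG.uniform(1, 1e5, size=(500, 18))
    out, _ = vst_transform(toy_matrix(vals, "protein"))
    for j in range(18):
        order = np.argsort(vals[:, j])
        assert (np.diff(out.values.to_numpy()[order, j]) > 0).all()


def test_vst_differences_approach_log_scale_for_large_intensities():
    vals = np.tile(RNG.uniform(10, 100, size=(50, 1)), (1, 18))
    vals[0, :] = 1e6
    vals[1, :] = 2e6  # exact twofold, far above the calibration scale
    out, _ = vst_transform(toy_matrix(vals, "protein"))
    diff = out.values.iloc[1, 0] - out.values.iloc[0, 0]
    assert diff == pytest.approx(math.log(2.0), rel=1e-6)


def test_vst_zero_median_sample_warns_and_falls_back():
    vals = np.zeros((4, 18))
    vals[0, :] = 1.0
    with pytest.warns(UserWarning):
        out, calib = vst_transform(toy_matrix(vals, "protein"))
    assert (calib["scale"] == 1.0).all()


# -- batch removal ----------------------------------------------------------


def test_injected_batch_offsets_are_removed_exactly():
    vals = np.full((10, 18), 5.0)
    mat = toy_matrix(vals, "protein")
    offsets = {"R1": 1.0, "R2": -1.0, "R3": 0.0}
    shifted = mat.values + mat.samples["batch"].map(offsets).to_numpy()
    corrected = remove_batch(mat.with_values(shifted, transformed=True))
    np.testing.assert_allclose(corrected.values.to_numpy(), 5.0, atol=1e-9)


def test_batch_removal_is_idempotent():
    vals = RNG.normal(10, 2, size=(30, 18))
    mat = toy_matrix(vals, "protein").with_values(
        pd.DataFrame(vals, index=[f"f{i}" for i in range(30)],
                      columns=toy_matrix(vals, "protein").values.columns),
        transformed=True,
    )
    once = remove_batch(mat)
    twice = remove_batch(once)
    np.testing.assert_allclose(once.values.to_numpy(), twice.values.to_numpy(),
                               atol=1e-9)


def test_single_batch_matrix_unchanged():
    vals = RNG.normal(10, 2, size=(5, 18))
    mat = toy_matrix(vals, "protein")
    single = mat.samples.copy()
    single["batch"] = "R1"
    from photolag import AbundanceMatrix

    mat1 = AbundanceMatrix(values=mat.values, samples=single, layer="protein")
    out = remove_batch(mat1)
    pd.testing.assert_frame_equal(out.values, mat1.values)


def test_batch_offset_injection_changes_no_regulation_call():
    ds = generate_dataset(
        {"concordant": 20, "null": 80},
        design=DESIGN,
        noise=NoiseModel(missing_logistic=None),  # complete data
        seed=13,
    )
    base = run_proteome_pipeline(ds.proteins)["calls"]
    shifted_vals = ds.proteins.values * np.exp2(
        ds.proteins.samples["batch"].map({"R1": 0.9, "R2": -0.6, "R3": 0.2}).to_numpy()
    )
    shifted = ds.proteins.with_values(shifted_vals)
    out = run_proteome_pipeline(shifted)["calls"]
    pd.testing.assert_series_equal(base["regulated"], out["regulated"])


# -- presence filtering -----------------------------------------------------


def _with_missing_runs(missing: dict[str, list[str]]):
    """4-protein toy where the listed proteins are missing in the listed runs."""
    vals = RNG.uniform(100, 1000, size=(4, 18))
    mat = toy_matrix(vals, "protein", feature_ids=["p0", "p1", "p2", "p3"])
    values = mat.values.copy()
    for pid, runs in missing.items():
        for run in runs:
            cols = mat.samples.index[mat.samples["batch"] == run]
            values.loc[pid, cols] = np.nan
    return mat.with_values(values)


def test_presence_rule_drops_single_run_proteins():
    mat = _with_missing_runs({"p1": ["R1", "R2"], "p2": ["R3"]})
    kept, presence = filter_presence(mat, min_runs=2)
    assert list(kept.values.index) == ["p0", "p2", "p3"]
    rec = presence.set_index("protein_id")
    assert rec.loc["p1", "n_detected"] == 1
    assert rec.loc["p2", "detected_in"] == "R1;R2"
    assert rec.loc["p0", "n_detected"] == 3


def test_overlap_counts_match_hand_enumeration():
    mat = _with_missing_runs({"p1": ["R1"], "p2": ["R3"], "p3": ["R2", "R3"]})
    _, presence = filter_presence(mat)
    counts = replicate_overlap_counts(presence)
    assert counts == {"R1&R2&R3": 1, "R2&R3": 1, "R1&R2": 1, "R1": 1}


# -- kNN imputation ---------------------------------------------------------


def test_impute_identity_on_complete_matrix():
    vals = RNG.uniform(10, 100, size=(6, 18))
    mat = toy_matrix(vals, "protein")
    out = knn_impute(mat, k=3)
    pd.testing.assert_frame_equal(out.values, mat.values)


def test_impute_matches_hand_computed_weighted_mean():
    """4-protein toy, k=2: the imputed cell is the 1/d-weighted mean of the
    two nearest complete profiles, with distance on observed columns only."""
    design = PulseDesign(transcript_times=(0.0,), protein_times=(10.0,),
                         n_replicates=2)
    # 4 samples: DD_R1 DD_R2 | 5L 10D_R1 5L 10D_R2; target misses run 2
    vals = np.array([
        [1.0, 2.0, 1.0, 2.0],     # target
        [1.0, 2.0, 1.0, 2.0],     # neighbor at distance 0 ... not complete!
        [2.0, 3.0, 2.0, 10.0],    # complete, d = sqrt(1+1) = sqrt(2)
        [4.0, 5.0, 4.0, 20.0],    # complete, d = sqrt(9+9) = sqrt(18)
    ])
    vals[0, 1] = np.nan
    vals[0, 3] = np.nan  # run 2 absent for target
    vals[1, 1] = np.nan
    vals[1, 3] = np.nan  # also incomplete: must not serve as neighbor
    mat = toy_matrix(vals, "protein", design=design,
                     feature_ids=["t", "i", "a", "b"])
    out = knn_impute(mat, k=2)
    d_a, d_b = math.sqrt(2.0), math.sqrt(18.0)
    w_a, w_b = 1 / d_a, 1 / d_b
    expected_col1 = (w_a * 3.0 + w_b * 5.0) / (w_a + w_b)
    expected_col3 = (w_a * 10.0 + w_b * 20.0) / (w_a + w_b)
    assert out.values.loc["t"].iloc[1] == pytest.approx(expected_col1)
    assert out.values.loc["t"].iloc[3] == pytest.approx(expected_col3)
    # observed cells untouched
    assert out.values.loc["t"].iloc[0] == 1.0


def test_zero_distance_neighbors_use_simple_mean():
    design = PulseDesign(transcript_times=(0.0,), protein_times=(10.0,),
                         n_replicates=2)
    vals = np.array([
        [1.0, np.nan, 1.0, np.nan],
        [1.0, 7.0, 1.0, 9.0],   # distance 0 on observed columns
        [1.0, 3.0, 1.0, 5.0],   # distance 0 as well
        [9.0, 1.0, 9.0, 1.0],
    ])
    mat = toy_matrix(vals, "protein", design=design,
                     feature_ids=["t", "a", "b", "c"])
    out = knn_impute(mat, k=3)
    assert out.values.loc["t"].iloc[1] == pytest.approx((7.0 + 3.0) / 2)
    assert out.values.loc["t"].iloc[3] == pytest.approx((9.0 + 5.0) / 2)


def test_impute_errors_without_complete_neighbors():
    vals = RNG.uniform(1, 10, size=(3, 18))
    mat = toy_matrix(vals, "protein")
    values = mat.values.copy()
    values.iloc[:, 0] = np.nan
    with pytest.raises(ValueError):
        knn_impute(mat.with_values(values), k=2)


def test_impute_beats_column_mean_on_masked_synthetic_data():
    """Hide 5% of observed cells; kNN RMSE must beat column-mean RMSE."""
    rmse_knn, rmse_col = [], []
    for seed in range(1, 4):
        ds = generate_dataset(
            {"concordant": 30, "null": 170}, design=DESIGN,
            noise=NoiseModel(missing_logistic=None), seed=seed,
        )
        transformed, _ = vst_transform(ds.proteins)
        vals = transformed.values.to_numpy()
        rng = np.random.default_rng(seed)
        mask = rng.random(vals.shape) < 0.05
        mask[:40] = False  # keep a complete neighbor pool
        hidden = vals.copy()
        hidden[mask] = np.nan
        mat = transformed.with_values(
            pd.DataFrame(hidden, index=transformed.values.index,
                         columns=transformed.values.columns)
        )
        imputed = knn_impute(mat, k=10).values.to_numpy()
        col_mean = np.nanmean(hidden, axis=0, keepdims=True)
        rmse_knn.append(np.sqrt(np.mean((imputed[mask] - vals[mask]) ** 2)))
        rmse_col.append(
            np.sqrt(np.mean((np.broadcast_to(col_mean, vals.shape)[mask]
                             - vals[mask]) ** 2))
        )
    assert np.mean(rmse_knn) < np.mean(rmse_col)


# -- moderated testing and BH ----------------------------------------------


def test_all_zero_differences_give_p_one():
    vals = np.tile(RNG.uniform(5, 10, size=(8, 1)), (1, 18))
    mat = toy_matrix(vals, "protein").with_values(
        toy_matrix(vals, "protein").values, transformed=True
    )
    profiles = protein_test(mat)
    assert (profiles["raw_p"] == 1.0).all()
    assert (profiles["adj_p"] == 1.0).all()


def test_benjamini_hochberg_step_up_hand_case():
    """BH on p = {0.01, 0.02, 0.03, 0.04} with m = 4 gives 0.04 across."""
    from statsmodels.stats.multitest import multipletests

    adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
    np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
    # and through the pipeline's own tables: construct differences giving
    # those raw p-values is brittle; instead verify adj >= raw and
    # monotonicity on a real profile table
    ds = generate_dataset({"concordant": 10, "null": 40}, design=DESIGN,
                          noise=NoiseModel(missing_logistic=None), seed=21)
    transformed, _ = vst_transform(ds.proteins)
    profiles = protein_test(transformed)
    assert (profiles["adj_p"] >= profiles["raw_p"] - 1e-15).all()
    for _, grp in profiles.groupby("condition"):
        ordered = grp.sort_values("raw_p")
        assert (np.diff(ordered["adj_p"]) >= -1e-12).all()


def test_smoothing_weight_zero_equals_plain_one_sample_t():
    ds = generate_dataset({"concordant": 15, "null": 30}, design=DESIGN,
                          noise=NoiseModel(missing_logistic=None), seed=3)
    transformed, _ = vst_transform(ds.proteins)
    profiles = protein_test(transformed, smoothing_weight=0.0)
    vals = transformed.values
    samples = transformed.samples
    for cond in ["5L 10D", "5L 235D"]:
        diffs = []
        for run in ["R1", "R2", "R3"]:
            c = samples.index[(samples["condition"] == cond) & (samples["batch"] == run)][0]
            d = samples.index[(samples["condition"] == "DD") & (samples["batch"] == run)][0]
            diffs.append(vals[c] - vals[d])
        diffs = np.column_stack(diffs)
        expected = stats.ttest_1samp(diffs, 0.0, axis=1).pvalue
        got = profiles.loc[profiles["condition"] == cond].set_index("feature_id")
        np.testing.assert_allclose(got.loc[vals.index, "raw_p"], expected, atol=1e-12)


def test_protein_call_requires_both_fdr_and_fold():
    profiles = pd.DataFrame([
        {"feature_id": "p", "condition": "5L 235D", "minutes": 235.0,
         "log2fc": 1.3, "raw_p": 0.01, "adj_p": 0.2, "n_obs": 3},
    ])
    calls = call_regulated_proteins(profiles)
    assert not calls.loc[0, "regulated"]


def test_peak_time_summary_fraction():
    calls = pd.DataFrame({
        "feature_id": [f"p{i}" for i in range(60)],
        "regulated": [True] * 57 + [False] * 3,
        "peak_at_final": [True] * 51 + [False] * 6 + [False] * 3,
    })
    summary = peak_time_summary(calls)
    assert summary.n_regulated == 57
    assert summary.percent_final == 89.5


def test_recovery_of_protein_regulated_classes():
    """Concordant/protein-only recall and null specificity at FDR 5% + twofold."""
    recalls, null_rate = [], []
    for seed in range(1, 4):
        ds = generate_dataset(
            {"concordant": 40, "protein_only": 20, "null": 340},
            design=DESIGN, seed=seed,
        )
        result = run_proteome_pipeline(ds.proteins)
        merged = result["calls"].set_index("feature_id").join(
            ds.truth.set_index("gene_id")["reg_class"]
        )
        complete = result["presence"].set_index("protein_id")["n_detected"] == 3
        target = merged["reg_class"].isin(["concordant", "protein_only"])
        recalls.append(merged.loc[target & complete.loc[merged.index], "regulated"].mean())
        null_rate.append(merged.loc[merged["reg_class"] == "null", "regulated"].mean())
    assert np.mean(recalls) >= 0.85
    assert np.mean(null_rate) <= 0.01
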