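"""Microarray regulation calls and 2^-ddCt quantification."""

import numpy as np
import pytest

from cipkfam.expression import (
    CtObservation,
    StageMatrix,
    classify_regulation,
    cross_stage_summary,
    delta_delta_ct,
    fold_change_report,
    read_ct_table,
    write_ct_table,
)
from cipkfam.simulate import (
    ExpressionConfig,
    generate_expression,
    planted_stage_ratios,
)


# ---------------------------------------------------------------------------
# Microarray calls
# ---------------------------------------------------------------------------

def test_sign_rule_classification():
    calls = classify_regulation(
        StageMatrix("veg", {"g1": 1.2, "g2": -0.4, "g3": 0.0})
    )
    assert calls == {"g1": "up", "g2": "down", "g3": "unchanged"}


def test_dead_band_threshold():
    calls = classify_regulation(
        StageMatrix("veg", {"g1": 0.3, "g2": -0.3, "g3": 0.8}), threshold=0.5
    )
    assert calls == {"g1": "unchanged", "g2": "unchanged", "g3": "up"}


def test_planted_48_gene_stage_counts():
    genes = [f"g{i:02d}" for i in range(48)]
    ratios = planted_stage_ratios(genes, seed=4)
    calls1 = classify_regulation(StageMatrix("veg", ratios["vegetative"]))
    calls2 = classify_regulation(StageMatrix("rep", ratios["reproductive"]))
    count = lambda calls, what: sum(1 for c in calls.values() if c == what)
    assert (count(calls1, "up"), count(calls1, "down")) == (20, 28)
    assert (count(calls2, "up"), count(calls2, "down")) == (33, 15)


def test_cross_stage_summary_planted_overlap():
    genes = [f"g{i:02d}" for i in range(48)]
    ratios = planted_stage_ratios(genes, seed=4)
    summary = cross_stage_summary(
        StageMatrix("veg", ratios["vegetative"]),
        StageMatrix("rep", ratios["reproductive"]),
    )
    assert (summary["both_up"], summary["both_down"], summary["opposite"]) == (
        18, 13, 17,
    )
    assert summary["both_up"] + summary["both_down"] + summary["opposite"] == 48


def test_cross_stage_identical_matrices_have_no_opposites():
    m = StageMatrix("veg", {"a": 1.0, "b": -2.0, "c": 0.5})
    summary = cross_stage_summary(m, StageMatrix("rep", dict(m.ratios)))
    assert summary["opposite"] == 0
    assert summary["both_up"] == 2 and summary["both_down"] == 1


def test_cross_stage_disjoint_gene_sets_warn():
    with pytest.warns(UserWarning, match="no genes"):
        summary = cross_stage_summary(
            StageMatrix("veg", {"a": 1.0}), StageMatrix("rep", {"b": 1.0})
        )
    assert summary["n_common"] == 0


# ---------------------------------------------------------------------------
# 2^-ddCt
# ---------------------------------------------------------------------------

def _obs(gene, tissue, tp, cond, rep, ct):
    return CtObservation(gene, tissue, tp, cond, rep, ct)


def test_ddct_hand_computed_eightfold():
    # treated: Ct_target 25, Ct_ref 20; control: 28 vs 20 -> ddCt -3, fold 8
    obs = []
    for rep in (1, 2, 3):
        obs += [
            _obs("T", "leaf", 4, "drought", rep, 25.0),
            _obs("ref", "leaf", 4, "drought", rep, 20.0),
            _obs("T", "leaf", 4, "control", rep, 28.0),
            _obs("ref", "leaf", 4, "control", rep, 20.0),
        ]
    (res,) = delta_delta_ct(obs, "ref")
    assert res.fold == pytest.approx(8.0)
    assert res.se == 0.0


def test_ddct_identical_conditions_give_unity():
    obs = []
    for rep in (1, 2):
        for cond in ("drought", "control"):
            obs += [
                _obs("T", "leaf", 4, cond, rep, 26.0),
                _obs("ref", "leaf", 4, cond, rep, 21.0),
            ]
    (res,) = delta_delta_ct(obs, "ref")
    assert res.fold == 1.0
    assert res.p_value == 1.0 and not res.significant


def test_ddct_reciprocal_folds_multiply_to_one():
    obs = []
    for rep in (1, 2, 3):
        obs += [
            _obs("T", "leaf", 4, "drought", rep, 24.0),
            _obs("ref", "leaf", 4, "drought", rep, 20.0),
            _obs("T", "leaf", 4, "control", rep, 27.5),
            _obs("ref", "leaf", 4, "control", rep, 20.0),
        ]
    (fwd,) = delta_delta_ct(obs, "ref", control_condition="control")
    (rev,) = delta_delta_ct(obs, "ref", control_condition="drought")
    assert fwd.fold * rev.fold == pytest.approx(1.0)


def test_ddct_missing_reference_names_cell():
    obs = [
        _obs("T", "leaf", 4, "drought", 1, 25.0),
        _obs("T", "leaf", 4, "control", 1, 25.0),
        _obs("ref", "leaf", 4, "control", 1, 20.0),
    ]
    with pytest.raises(ValueError, match="condition=drought"):
        delta_delta_ct(obs, "ref")


def test_ddct_single_replicate_flagged_without_p_value():
    obs = [
        _obs("T", "leaf", 4, "drought", 1, 25.0),
        _obs("ref", "leaf", 4, "drought", 1, 20.0),
        _obs("T", "leaf", 4, "control", 1, 28.0),
        _obs("ref", "leaf", 4, "control", 1, 20.0),
    ]
    with pytest.warns(UserWarning, match="<2 replicates"):
        (res,) = delta_delta_ct(obs, "ref")
    assert res.p_value is None and not res.significant
    assert res.fold == pytest.approx(8.0)


def test_ddct_paired_mode_matches_mean_mode_on_constant_controls():
    obs = []
    for rep in (1, 2, 3):
        obs += [
            _obs("T", "leaf", 4, "drought", rep, 24.0 + 0.1 * rep),
            _obs("ref", "leaf", 4, "drought", rep, 20.0),
            _obs("T", "leaf", 4, "control", rep, 28.0),
            _obs("ref", "leaf", 4, "control", rep, 20.0),
        ]
    (mean_mode,) = delta_delta_ct(obs, "ref", pairing="mean_control")
    (paired,) = delta_delta_ct(obs, "ref", pairing="paired")
    assert mean_mode.fold == pytest.approx(paired.fold)


# ---------------------------------------------------------------------------
# Synthetic recovery
# ---------------------------------------------------------------------------

def test_noiseless_planted_fold_recovered_exactly():
    config = ExpressionConfig(
        planted_log2fc={"gA": {("leaf", 4): 3.0}},   # fold 8
        ct_noise_sd=0.0, seed=5,
        tissues=("leaf",), timepoints=(0, 4),
    )
    fixture = generate_expression(config, ["gA"])
    results = delta_delta_ct(fixture.observations, config.reference_gene)
    by_tp = {r.timepoint: r for r in results}
    assert by_tp[4].fold == pytest.approx(8.0)
    assert by_tp[4].se == 0.0
    assert by_tp[0].fold == pytest.approx(1.0)


def test_noiseless_null_table_has_no_significant_calls():
    config = ExpressionConfig(
        planted_log2fc={}, ct_noise_sd=0.0, seed=5,
        tissues=("leaf", "root"), timepoints=(0, 4, 8),
    )
    fixture = generate_expression(config, ["g1", "g2"])
    results = delta_delta_ct(fixture.observations, config.reference_gene)
    assert all(r.fold == pytest.approx(1.0) for r in results)
    assert not any(r.significant for r in results)


def test_monotone_planted_series_reported_monotone():
    config = ExpressionConfig(
        planted_log2fc={"g": {("leaf", 4): 1.0, ("leaf", 8): 2.0,
                              ("leaf", 12): 3.0}},
        ct_noise_sd=0.0, seed=0, tissues=("leaf",),
    )
    fixture = generate_expression(config, ["g"])
    report = fold_change_report(
        delta_delta_ct(fixture.observations, config.reference_gene)
    )
    folds = report.sort_values("timepoint")["fold"].tolist()
    assert folds == sorted(folds)
    assert folds[0] == pytest.approx(1.0)      # day 0 baseline


def test_report_shape_and_day_zero(tmp_path):
    config = ExpressionConfig(planted_log2fc={}, ct_noise_sd=0.2, seed=8)
    genes = ["g1", "g2"]
    fixture = generate_expression(config, genes)
    results = delta_delta_ct(fixture.observations, config.reference_gene)
    report = fold_change_report(results)
    assert len(report) == len(genes) * len(config.tissues) * len(
        config.timepoints
    )
    # Ct table survives a round trip through TSV
    path = tmp_path / "ct.tsv"
    write_ct_table(fixture.observations, path)
    again = read_ct_table(path)
    assert len(again) == len(fixture.observations)
    assert again[0].gene == fixture.observations[0].gene


def test_noisy_mean_fold_recovery_within_three_se():
    """Monte Carlo over 200 generator seeds: with Ct noise sd 0.3 and three
    biological replicates, the mean recovered fold of a planted 8-fold
    induction stays within 3 standard errors of 8."""
    estimates = []
    for seed in range(200):
        config = ExpressionConfig(
            planted_log2fc={"g": {("leaf", 4): 3.0}},
            ct_noise_sd=0.3, n_bio_reps=3, seed=seed,
            tissues=("leaf",), timepoints=(0, 4),
        )
        fixture = generate_expression(config, ["g"])
        results = delta_delta_ct(fixture.observations, config.reference_gene)
        (at4,) = [r for r in results if r.timepoint == 4]
        estimates.append(at4.fold)
    estimates = np.asarray(estimates)
    se = estimates.std(ddof=1) / np.sqrt(len(estimates))
    assert abs(estimates.mean() - 8.0) <= 3.0 * se
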