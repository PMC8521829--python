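"""D-value arithmetic, best-over-classifier tables, aggregation oracle,
and end-to-end determinism of a small study grid."""

import math

import numpy as np
import pandas as pd
import pytest

from ecgtb.report import (
    StudyConfig,
    aggregate,
    best_over_classifiers,
    d_value,
    directional_study,
    run_study,
)


def test_d_value_worked_examples():
    assert d_value(89.9, 80.8) == pytest.approx(9.1)
    assert d_value(91.9, 71.6) == pytest.approx(20.3)


def test_d_value_antisymmetry(rng):
    for _ in range(50):
        a, b = rng.uniform(0, 100, 2)
        assert d_value(a, b) == pytest.approx(-d_value(b, a), abs=1e-12)
    assert math.isnan(d_value(float("nan"), 50.0))
    assert math.isnan(d_value(50.0, float("nan")))


def _results_frame(rows):
    cols = ["trial", "balance", "variant", "feature", "transform", "classifier",
            "cv_f1", "test_f1"]
    return pd.DataFrame(rows, columns=cols)


def test_best_over_classifiers_and_tie_rule():
    base = ("Norm_vs_AF", "unbalanced", "filtered", "fS")
    rows = []
    for transform, scores in (
        ("identity", {"knn": 0.70, "neural_net": 0.80, "svm_quadratic": 0.80,
                      "tree": 0.60, "naive_bayes_kernel": 0.75}),
        ("reciprocal", {"knn": 0.90, "neural_net": 0.85, "svm_quadratic": 0.70,
                        "tree": 0.65, "naive_bayes_kernel": 0.72}),
    ):
        for clf, f1 in scores.items():
            rows.append([*base, transform, clf, f1, f1])
    out = best_over_classifiers(_results_frame(rows))
    ident = out[out["transform"] == "identity"].iloc[0]
    recip = out[out["transform"] == "reciprocal"].iloc[0]
    assert ident["best_f1"] == pytest.approx(80.0)
    # tie between neural_net and svm_quadratic -> first in canonical order
    assert ident["best_classifier"] == "neural_net"
    assert bool(ident["tie"])
    assert recip["best_f1"] == pytest.approx(90.0)
    assert recip["best_classifier"] == "knn"
    assert not bool(recip["tie"])
    assert recip["d_value"] == pytest.approx(10.0)
    assert ident["d_value"] == pytest.approx(0.0)
    assert out["complete"].all()


def test_best_over_classifiers_incomplete_flagged():
    rows = [["t", "unbalanced", "filtered", "fS", "identity", "knn", 0.5, 0.5]]
    out = best_over_classifiers(_results_frame(rows))
    assert not out["complete"].iloc[0]
    assert out["best_f1"].iloc[0] == pytest.approx(50.0)


def test_aggregate_matches_naive_two_loop_oracle(rng):
    """`aggregate` equals an explicit loop over (group, transform) means."""
    trials = ["Norm_vs_AF", "Norm_vs_PVC"]
    balances = ["unbalanced", "RUS"]
    variants = ["unfiltered", "filtered"]
    features = ["fS", "fK", "fE"]
    transforms = ["identity", "log", "reciprocal"]
    recs = []
    for t in trials:
        for b in balances:
            for v in variants:
                for f in features:
                    for k in transforms:
                        recs.append(dict(trial=t, balance=b, variant=v, feature=f,
                                         transform=k, best_f1=rng.uniform(0, 100)))
    table = pd.DataFrame(recs)
    fig2 = aggregate(table, "over_features")
    for t in trials:
        for b in balances:
            for v in variants:
                sub = table[(table.trial == t) & (table.balance == b) & (table.variant == v)]
                ident = sub[sub["transform"] == "identity"]["best_f1"].mean()
                for k in transforms:
                    want = sub[sub["transform"] == k]["best_f1"].mean()
                    got = fig2[(fig2.trial == t) & (fig2.balance == b)
                               & (fig2.variant == v) & (fig2["transform"] == k)]
                    assert got["mean_f1"].iloc[0] == pytest.approx(want)
                    assert got["n_cells"].iloc[0] == len(features)
                    assert got["d_value"].iloc[0] == pytest.approx(want - ident)
    fig4 = aggregate(fig2, "over_balance_regimes")
    for t in trials:
        for v in variants:
            sub = fig2[(fig2.trial == t) & (fig2.variant == v)]
            for k in transforms:
                want = sub[sub["transform"] == k]["mean_f1"].mean()
                got = fig4[(fig4.trial == t) & (fig4.variant == v) & (fig4["transform"] == k)]
                assert got["mean_f1"].iloc[0] == pytest.approx(want)
    with pytest.raises(ValueError):
        aggregate(table, "bogus")


TINY = dict(
    class_counts={"Norm": 16, "AF": 8, "PVC": 7, "APB": 4},
    trials=("AF",),
    balances=("unbalanced", "SMOTE"),
    features=("fS", "fZ"),
    transforms=("identity", "reciprocal"),
    classifiers=("knn", "tree"),
)


def test_run_study_row_count_and_schema():
    res = run_study(StudyConfig(seed=3, **TINY))
    # trials x balances x variants x features x transforms x classifiers
    assert len(res.results) == 1 * 2 * 2 * 2 * 2 * 2
    assert len(res.dvalues) == 1 * 2 * 2 * 2 * 2
    # identity rows have D-value exactly 0
    ident = res.dvalues[res.dvalues["transform"] == "identity"]
    assert np.allclose(ident["d_value"], 0.0)
    assert res.manifest["n_segments"] == 35
    assert (res.results["error"] == "").all()


def test_run_study_is_deterministic():
    a = run_study(StudyConfig(seed=3, **TINY))
    b = run_study(StudyConfig(seed=3, **TINY))
    pd.testing.assert_frame_equal(a.results, b.results)
    pd.testing.assert_frame_equal(a.dvalues, b.dvalues)
    pd.testing.assert_frame_equal(a.fig2, b.fig2)
    pd.testing.assert_frame_equal(a.fig4, b.fig4)


def test_run_study_writes_outputs(tmp_path):
    run_study(StudyConfig(seed=3, **TINY), out_dir=tmp_path)
    for name in ("results.csv", "dvalues.csv", "fig2_data.csv", "fig4_data.csv",
                 "dvalues_display.csv", "manifest.json"):
        assert (tmp_path / name).exists()
    disp = pd.read_csv(tmp_path / "dvalues_display.csv")
    # display table is rounded to one decimal, as in the study's tables
    assert np.allclose(disp["best_f1"], disp["best_f1"].round(1), equal_nan=True)


def test_directional_study_shape():
    out = directional_study(n_seeds=3)
    assert list(out.columns) == ["seed", "f1_original", "f1_reciprocal", "d_value"]
    assert len(out) == 3
    np.testing.assert_allclose(
        out["d_value"], out["f1_reciprocal"] - out["f1_original"], atol=1e-12
    )
    # deterministic
    pd.testing.assert_frame_equal(out, directional_study(n_seeds=3))


def test_unknown_source_rejected():
    with pytest.raises(ValueError, match="unknown source"):
        run_study(StudyConfig(source="bogus", **TINY))
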