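"""LOO cross-validation, null model and the validation metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import syntrobn as sb
from syntrobn import (CVOptions, bray_curtis_similarity,
                      community_reconstruction_report, loo_cv,
                      null_model_predict, r_squared, relative_rmse)
from syntrobn.table import default_metadata


def _table(columns: dict):
    frame = pd.DataFrame(columns)
    frame.index = [f"S{i}" for i in range(len(frame))]
    return sb.FeatureTable(frame, default_metadata(list(frame.columns)))


# -- leave-one-out cross-validation ------------------------------------------


def test_loo_produces_one_prediction_per_sample():
    table = _table({"a": [0.1, 0.5, 0.9], "b": [0.2, 0.4, 0.8]})
    cv = loo_cv(table, None, ["a", "b"])
    assert cv.predicted.shape == (3, 2)
    assert not cv.predicted.isna().any().any()
    assert cv.provenance["prediction_method"] == "parents"
    with pytest.raises(ValueError, match="at least 3"):
        loo_cv(_table({"a": [0.1, 0.2]}), None, ["a"])


def test_loo_fold_equals_manual_refit(rng):
    """Predictions for a fold are identical to retraining by hand on the
    explicit n-1 subset."""
    x = rng.normal(size=30)
    table = _table({"x": x, "y": 0.8 * x + rng.normal(0, 0.2, 30)})
    cv = loo_cv(table, None, ["y"])
    held_out = "S7"
    train = sb.FeatureTable(table.values.drop(index=held_out),
                            table.metadata)
    dag = sb.hill_climb(train, None, sb.SearchOptions())
    bn = sb.fit_mle(dag, train)
    expected = sb.predict_nodes(bn, dict(table.values.loc[held_out]),
                                ["y"], method="parents")
    assert cv.predicted.at[held_out, "y"] == pytest.approx(expected["y"],
                                                           rel=1e-12)


def test_loo_is_deterministic(rng):
    x = rng.normal(size=20)
    table = _table({"x": x, "y": x + rng.normal(0, 0.3, 20)})
    a = loo_cv(table, None, ["y"], CVOptions())
    b = loo_cv(table, None, ["y"], CVOptions())
    assert a.predicted.equals(b.predicted)


def test_loo_handles_fold_constant_column():
    # column 'c' is constant except in the held-out sample S0: that fold
    # drops it and still returns a prediction for it
    table = _table({"c": [0.9, 0.2, 0.2, 0.2],
                    "y": [0.1, 0.4, 0.6, 0.8]})
    cv = loo_cv(table, None, ["c", "y"])
    assert cv.predicted.at["S0", "c"] == pytest.approx(0.2)


def test_joint_prediction_method_is_supported(rng):
    x = rng.normal(size=25)
    table = _table({"x": x, "y": 0.9 * x + rng.normal(0, 0.2, 25)})
    cv = loo_cv(table, None, ["y"],
                CVOptions(prediction_method="joint"))
    assert cv.provenance["prediction_method"] == "joint"
    assert r_squared(cv.observed["y"], cv.predicted["y"]) > 0.5


# -- null model --------------------------------------------------------------


def test_null_model_is_the_leave_one_out_mean():
    table = _table({"v": [1.0, 2.0, 3.0]})
    null = null_model_predict(table, ["v"])
    assert null.predicted["v"].tolist() == pytest.approx([2.5, 2.0, 1.5])


def test_null_model_ignores_other_variables(rng):
    base = _table({"v": [1.0, 2.0, 3.0], "w": [9.0, 8.0, 7.0]})
    shuffled = _table({"v": [1.0, 2.0, 3.0], "w": [7.0, 9.0, 8.0]})
    a = null_model_predict(base, ["v"])
    b = null_model_predict(shuffled, ["v"])
    assert a.predicted.equals(b.predicted)
    const = null_model_predict(_table({"v": [4.0, 4.0, 4.0]}), ["v"])
    assert (const.predicted["v"] == 4.0).all()


# -- metrics -----------------------------------------------------------------


@pytest.mark.parametrize("u, v, expected", [
    ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 1.0),
    ([1.0, 0.0], [0.0, 1.0], 0.0),
    ([1.0, 1.0], [1.0, 3.0], 1.0 - 2.0 / 6.0),
])
def test_bray_curtis_examples(u, v, expected):
    assert bray_curtis_similarity(u, v) == pytest.approx(expected, abs=1e-12)


def test_bray_curtis_degenerate_cases():
    assert bray_curtis_similarity([0.0, 0.0], [0.0, 0.0]) == 1.0
    # negative masses are clipped before comparison
    assert bray_curtis_similarity([-1.0, 1.0], [0.0, 1.0]) == 1.0


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1e3), min_size=1,
                max_size=12),
       st.floats(min_value=0.01, max_value=100.0))
def test_bray_curtis_symmetric_and_scale_invariant(u, c):
    v = [x + 1.0 for x in u]  # strictly positive partner vector
    u = list(u)
    s_uv = bray_curtis_similarity(u, v)
    assert s_uv == pytest.approx(bray_curtis_similarity(v, u))
    assert s_uv == pytest.approx(
        bray_curtis_similarity([c * x for x in u], [c * x for x in v]),
        rel=1e-9)
    assert -1e-12 <= s_uv <= 1 + 1e-12


@pytest.mark.parametrize("y, t, expected", [
    ([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0], 0.0),
    ([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 0.0], 0.5),
])
def test_relative_rmse_examples(y, t, expected):
    assert relative_rmse(y, t) == pytest.approx(expected, abs=1e-12)


def test_relative_rmse_homogeneity_and_positivity(rng):
    y = rng.uniform(0.1, 5.0, 20)
    t = y + rng.normal(0, 0.5, 20)
    value = relative_rmse(y, t)
    assert value > 0
    assert relative_rmse(3.0 * y, 3.0 * t) == pytest.approx(value, rel=1e-12)
    assert relative_rmse(y, y) == 0.0
    with pytest.raises(ValueError, match="undefined"):
        relative_rmse([0.0, 0.0], [1.0, 1.0])


def test_r_squared_examples_and_affine_invariance():
    y = [1.0, 2.0, 3.0]
    assert r_squared(y, y) == pytest.approx(1.0)
    assert r_squared(y, [3 * v + 2 for v in y]) == pytest.approx(1.0)
    assert r_squared(y, [1.0, 3.0, 2.0]) == pytest.approx(0.25)
    with pytest.raises(ValueError, match="constant"):
        r_squared(y, [2.0, 2.0, 2.0])
    # the regression-based coefficient of determination is the alternative
    assert r_squared(y, [1.1, 2.1, 3.1],
                     kind="determination") == pytest.approx(1 - 0.03 / 2)


# -- report ------------------------------------------------------------------


def test_report_null_vs_null_and_perfect_predictor():
    table = _table({"a": [0.1, 0.4, 0.7, 0.9], "b": [0.3, 0.2, 0.8, 0.5]})
    null = null_model_predict(table, ["a", "b"])
    same = community_reconstruction_report(null, null)
    assert same.bray_curtis_mean == pytest.approx(
        same.null_bray_curtis_mean)
    perfect = sb.CVResult(observed=table.values[["a", "b"]],
                          predicted=table.values[["a", "b"]].copy(),
                          provenance={})
    report = community_reconstruction_report(perfect, null)
    assert report.bray_curtis_mean == pytest.approx(1.0)
    assert report.relative_rmse == pytest.approx(0.0)
    assert report.r_squared == pytest.approx(1.0)
    frame = report.to_frame()
    assert {"r_squared", "relative_rmse", "bray_curtis_mean",
            "null_bray_curtis_mean"} <= set(frame.columns)
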