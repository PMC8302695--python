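"""Leave-one-out validation of learned networks against a null model.

For every sample, structure and parameters are re-learned on the remaining
samples and the held-out sample's target variables are predicted; the
resulting prediction matrix is compared with the observations through
Bray–Curtis similarity (community reconstruction), squared Pearson
correlation (R²) and relative RMSE (root-mean-square error divided by the
maximum observed value). The null model predicts every target as the
training-fold mean, the discipline an informative network has to beat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import fit_mle, predict_nodes
from .network import EdgeConstraintSet, SearchOptions, hill_climb
from .preprocess import drop_zero_variance
from .table import FeatureTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVOptions:
    """Cross-validation options: search settings and prediction method."""

    search: SearchOptions = field(default_factory=SearchOptions)
    prediction_method: str = "parents"
    keep_models: bool = False

    def __post_init__(self) -> None:
        if self.prediction_method not in ("parents", "joint"):
            raise ValueError(
                f"unknown prediction method {self.prediction_method!r}")


@dataclass
class CVResult:
    """Observed and predicted target matrices from a LOO run."""

    observed: pd.DataFrame   # samples × targets
    predicted: pd.DataFrame  # samples × targets
    provenance: dict
    fold_models: list | None = None

    def __post_init__(self) -> None:
        if list(self.observed.index) != list(self.predicted.index) or \
                list(self.observed.columns) != list(self.predicted.columns):
            raise ValueError("observed/predicted shapes disagree")
        if self.predicted.isna().any().any():
            raise ValueError("predictions contain missing cells")


def loo_cv(data: FeatureTable, constraints: EdgeConstraintSet | None,
           targets: list[str], options: CVOptions | None = None) -> CVResult:
    """Leave-one-out cross-validation of the full learning pipeline.

    Per fold: drop the held-out sample, remove columns that became
    constant, hill-climb a structure under the constraints, fit ML
    parameters, and predict the targets for the held-out sample. A target
    that is constant within a training fold is predicted as that constant.
    """
    if data.n_samples < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    unknown = [t for t in targets if t not in data.variables]
    if unknown:
        raise ValueError(f"unknown target(s): {unknown}")
    options = options or CVOptions()
    constraints = constraints or EdgeConstraintSet()
    predicted = pd.DataFrame(np.nan, index=data.values.index,
                             columns=list(targets))
    models = [] if options.keep_models else None
    for sample in data.values.index:
        train = FeatureTable(data.values.drop(index=sample), data.metadata)
        train, dropped = drop_zero_variance(train)
        if dropped:
            logger.info("fold %s: dropped constant column(s) %s",
                        sample, dropped)
        fold_constraints = constraints.restrict(train.variables)
        dag = hill_climb(train, fold_constraints, options.search)
        bn = fit_mle(dag, train)
        if models is not None:
            models.append((sample, bn, dropped))
        row = data.values.loc[sample]
        predicted.loc[sample] = predict_fold(
            bn, row, targets, data, options.prediction_method, dropped)
    observed = data.values[list(targets)].copy()
    return CVResult(
        observed=observed,
        predicted=predicted.astype(float),
        provenance={
            "method": "loo_cv",
            "prediction_method": options.prediction_method,
            "search": options.search,
            "n_blacklist": len(constraints.blacklist),
            "n_whitelist": len(constraints.whitelist),
        },
        fold_models=models,
    )


def predict_fold(bn, row: pd.Series, targets: list[str], data: FeatureTable,
                 method: str, dropped: list[str],
                 zero_evidence: set[str] | None = None) -> pd.Series:
    """Predict targets for one held-out row from a fold model.

    Targets absent from the fold model (dropped as constant during
    training) are predicted as their training constant. ``zero_evidence``
    names variables whose observed values are replaced by 0 at prediction
    time (the evidence-only knockout mode).
    """
    evidence = dict(row)
    if zero_evidence:
        for v in zero_evidence:
            if v in evidence:
                evidence[v] = 0.0
    out = pd.Series(index=list(targets), dtype=float)
    in_model = [t for t in targets if t in bn.nodes]
    if method == "joint":
        for t in in_model:
            evidence.pop(t, None)
    if in_model:
        out[in_model] = predict_nodes(bn, evidence, in_model, method=method)
    for t in targets:
        if t not in bn.nodes:
            # constant in training: the fold's constant is the only forecast
            out[t] = float(data.values[t].drop(index=row.name).iloc[0])
    return out


def null_model_predict(data: FeatureTable, targets: list[str]) -> CVResult:
    """Leave-one-out mean predictor: each target is its training-fold mean."""
    if data.n_samples < 2:
        raise ValueError("need at least 2 samples")
    unknown = [t for t in targets if t not in data.variables]
    if unknown:
        raise ValueError(f"unknown target(s): {unknown}")
    values = data.values[list(targets)]
    n = data.n_samples
    # leave-one-out mean = (n·mean − x_i)/(n − 1), row-wise
    total = values.sum(axis=0)
    predicted = (total - values) / (n - 1)
    return CVResult(
        observed=values.copy(),
        predicted=predicted.astype(float),
        provenance={"method": "null_model", "prediction_method": "mean"},
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def bray_curtis_similarity(u, v) -> float:
    """1 − Σ|u−v| / Σ(u+v) on non-negative vectors (1 = identical).

    Negative entries are clipped to 0 first (abundances are masses); two
    all-zero vectors compare as identical (similarity 1) with a warning.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors differ in length")
    if (u < 0).any() or (v < 0).any():
        logger.warning("negative entries clipped to 0 before Bray-Curtis")
        u = np.clip(u, 0, None)
        v = np.clip(v, 0, None)
    denom = float(np.sum(u + v))
    if denom == 0:
        logger.warning("Bray-Curtis of two all-zero vectors defined as 1")
        return 1.0
    return 1.0 - float(np.sum(np.abs(u - v))) / denom


def relative_rmse(y, t) -> float:
    """Root-mean-square error divided by the maximum observed value."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.shape != t.shape or y.size == 0:
        raise ValueError("vectors must be non-empty and equal length")
    y_max = float(np.max(y))
    if y_max == 0:
        raise ValueError("relative RMSE undefined: max observed value is 0")
    return float(np.sqrt(np.mean((y - t) ** 2)) / y_max)


def r_squared(y, t, kind: str = "pearson") -> float:
    """Prediction R².

    ``kind='pearson'`` (default): squared Pearson correlation between
    observed and predicted — the convention used when "correlating the
    predicted and observed" values. ``kind='determination'``: the
    regression coefficient of determination ``1 − SS_res/SS_tot`` (can be
    negative for predictors worse than the mean).
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.shape != t.shape or y.size < 2:
        raise ValueError("vectors must be equal length with n >= 2")
    if kind == "determination":
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            raise ValueError("R² undefined for constant observations")
        return 1.0 - float(np.sum((y - t) ** 2)) / ss_tot
    if kind != "pearson":
        raise ValueError(f"unknown R² kind {kind!r}")
    if np.std(y) == 0 or np.std(t) == 0:
        raise ValueError("R² undefined for a constant vector")
    r = float(np.corrcoef(y, t)[0, 1])
    return r * r


@dataclass
class ValidationMetrics:
    """Summary of a model-vs-null community reconstruction comparison."""

    r_squared: float
    relative_rmse: float
    bray_curtis_mean: float
    null_bray_curtis_mean: float
    per_variable: pd.DataFrame = None  # type: ignore[assignment]
    aggregations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("bray_curtis_mean", "null_bray_curtis_mean"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError(f"{name} outside [0, 1]: {v}")

    def to_frame(self) -> pd.DataFrame:
        summary = pd.DataFrame({
            "variable": ["<mean over variables>"],
            "r_squared": [self.r_squared],
            "relative_rmse": [self.relative_rmse],
            "bray_curtis_mean": [self.bray_curtis_mean],
            "null_bray_curtis_mean": [self.null_bray_curtis_mean],
        })
        per_var = self.per_variable.copy()
        per_var["bray_curtis_mean"] = np.nan
        per_var["null_bray_curtis_mean"] = np.nan
        return pd.concat([per_var, summary], ignore_index=True)


def community_reconstruction_report(cv: CVResult,
                                    null: CVResult) -> ValidationMetrics:
    """Compare a network's LOO predictions with the mean null model.

    Per held-out sample, Bray–Curtis similarity between the predicted and
    observed target vector is averaged for both models (negative network
    predictions clipped to 0); per target variable, R² (squared Pearson)
    and relative RMSE of the network predictions are tabulated. The
    ``aggregations`` field reports R² averaged over variables and pooled
    over all cells, since either convention may be wanted.
    """
    if not cv.observed.index.equals(null.observed.index) or \
            not cv.observed.columns.equals(null.observed.columns):
        raise ValueError("network and null CV cover different samples/targets")
    predicted = cv.predicted
    if (predicted.to_numpy() < 0).any():
        logger.warning("negative predictions clipped to 0 for Bray-Curtis")
        predicted = predicted.clip(lower=0.0)
    bc = [bray_curtis_similarity(predicted.loc[s], cv.observed.loc[s])
          for s in cv.observed.index]
    bc_null = [bray_curtis_similarity(null.predicted.loc[s],
                                      null.observed.loc[s])
               for s in null.observed.index]
    rows = []
    for var in cv.observed.columns:
        y = cv.observed[var].to_numpy()
        t = cv.predicted[var].to_numpy()
        try:
            r2 = r_squared(y, t)
        except ValueError:
            r2 = np.nan
        rel = relative_rmse(y, t) if np.max(y) != 0 else np.nan
        rows.append((var, r2, rel))
    per_variable = pd.DataFrame(rows,
                                columns=["variable", "r_squared",
                                         "relative_rmse"])
    pooled_y = cv.observed.to_numpy().ravel()
    pooled_t = cv.predicted.to_numpy().ravel()
    aggregations = {
        "r_squared_mean_over_variables": float(
            np.nanmean(per_variable["r_squared"])),
        "r_squared_pooled": r_squared(pooled_y, pooled_t),
        "relative_rmse_mean_over_variables": float(
            np.nanmean(per_variable["relative_rmse"])),
    }
    return ValidationMetrics(
        r_squared=aggregations["r_squared_mean_over_variables"],
        relative_rmse=aggregations["relative_rmse_mean_over_variables"],
        bray_curtis_mean=float(np.mean(bc)),
        null_bray_curtis_mean=float(np.mean(bc_null)),
        per_variable=per_variable,
        aggregations=aggregations,
    )
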