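"""Evaluation statistics for drug-sensitivity prediction models.

Regression metrics
------------------
NRMSE  ``||y - yhat|| / ||y - ybar||`` — root-mean-square error normalized
       by the intercept-only model (1 means no better than the mean).
PCC    Pearson correlation between observations and predictions.
Bias   ``tan(theta)`` where theta summarizes the residual trend versus the
       observations: either the literal vector angle
       ``theta = arccos( y . (y - yhat) / (||y|| ||y - yhat||) )`` or the
       arctangent of the OLS slope of the residuals on the observations.
       The two definitions are not algebraically equivalent; both are
       provided and neither is silently reinterpreted.
NMAE   mean-absolute-error analogue of NRMSE.

Classification metrics (accuracy, precision, recall, F1, FPR, AUROC) follow
their textbook confusion-count definitions.

Model comparison
----------------
``gap_statistics`` pairs a model with a null model that predicts by sampling
the training-response distribution, bootstraps both over the test set, and
reports the two k-means (k=2) centroids of each pooled metric distribution —
the centroid gap is the performance difference.  ``robustness`` is the
fraction of bootstrap replicates in which one model strictly beats another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import nnls

from .data import ValidationError

__all__ = [
    "PredictionSet",
    "ConfusionCounts",
    "GapResult",
    "nrmse",
    "nmae",
    "pcc",
    "bias_angle",
    "classification_metrics",
    "auroc",
    "gap_statistics",
    "robustness",
    "jab_ci",
    "binomial_ci",
    "mcnemar",
    "bc1_correct",
    "stack_predictions",
]


@dataclass
class PredictionSet:
    """Paired observed and predicted responses."""

    y: np.ndarray
    y_hat: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.y_hat = np.asarray(self.y_hat, dtype=float)
        if self.y.shape != self.y_hat.shape or self.y.ndim != 1:
            raise ValidationError("y and y_hat must be 1-D vectors of equal length")
        if self.y.size < 2:
            raise ValidationError("need at least 2 observations")

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.y_hat


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if self.TP + self.TN + self.FP + self.FN == 0:
            raise ValidationError("empty confusion table")

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(bool)
        y_pred = np.asarray(y_pred).astype(bool)
        return cls(
            TP=int(np.sum(y_true & y_pred)),
            TN=int(np.sum(~y_true & ~y_pred)),
            FP=int(np.sum(~y_true & y_pred)),
            FN=int(np.sum(y_true & ~y_pred)),
        )


def nrmse(p: PredictionSet) -> float:
    """Root-mean-square error over the error of the mean-only predictor."""
    denom = np.linalg.norm(p.y - p.y.mean())
    if denom == 0:
        raise ValidationError("constant observations: NRMSE undefined")
    return float(np.linalg.norm(p.y - p.y_hat) / denom)


def nmae(p: PredictionSet) -> float:
    """Mean absolute error over the MAE of the mean-only predictor."""
    denom = np.sum(np.abs(p.y - p.y.mean()))
    if denom == 0:
        raise ValidationError("constant observations: NMAE undefined")
    return float(np.sum(np.abs(p.y - p.y_hat)) / denom)


def pcc(p: PredictionSet) -> float:
    """Pearson correlation between observations and predictions."""
    if np.std(p.y) == 0 or np.std(p.y_hat) == 0:
        raise ValidationError("constant input: PCC undefined")
    yc = p.y - p.y.mean()
    hc = p.y_hat - p.y_hat.mean()
    return float(yc @ hc / (np.linalg.norm(yc) * np.linalg.norm(hc)))


def bias_angle(p: PredictionSet, mode: str = "vector_angle"):
    """Residual-trend bias: returns (bias = tan(theta), theta in degrees).

    ``vector_angle`` computes the literal angle between the observation
    vector and the residual vector; ``ols_slope`` regresses the residuals on
    the observations and takes theta = arctan(slope).  A zero residual
    vector is a perfect prediction: bias 0 by convention.
    """
    eps = p.residuals
    if mode == "vector_angle":
        ny = np.linalg.norm(p.y)
        ne = np.linalg.norm(eps)
        if ny == 0:
            raise ValidationError("zero observation vector")
        if ne == 0:
            return 0.0, 0.0  # perfect prediction, flagged convention
        c = np.clip(p.y @ eps / (ny * ne), -1.0, 1.0)
        theta = float(np.degrees(np.arccos(c)))
        return float(np.tan(np.radians(theta))), theta
    if mode == "ols_slope":
        if np.std(p.y) == 0:
            raise ValidationError("constant observations: slope undefined")
        yc = p.y - p.y.mean()
        slope = float(yc @ (eps - eps.mean()) / (yc @ yc))
        theta = float(np.degrees(np.arctan(slope)))
        return slope, theta
    raise ValidationError(f"unknown bias mode {mode!r}")


def classification_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, precision, recall, F1 and FPR from confusion counts.

    A metric whose denominator is zero is reported as NaN (flagged, not
    fatal).
    """
    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    total = c.TP + c.TN + c.FP + c.FN
    return {
        "accuracy": ratio(c.TP + c.TN, total),
        "precision": ratio(c.TP, c.TP + c.FP),
        "recall": ratio(c.TP, c.TP + c.FN),
        "f1": ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN),
        "fpr": ratio(c.FP, c.FP + c.TN),
    }


def auroc(y_true, scores) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic."""
    y_true = np.asarray(y_true).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = int((~y_true).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")
    ranks = stats.rankdata(scores)  # ties averaged
    return float((ranks[y_true].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


_REGRESSION_METRICS = {
    "nrmse": (nrmse, "lower"),
    "nmae": (nmae, "lower"),
    "pcc": (pcc, "higher"),
    "bias": (lambda p: abs(bias_angle(p)[0]), "lower"),
}


@dataclass
class GapResult:
    """Bootstrap metric distributions for a model and its null, with k=2 centroids."""

    metrics: dict  # name -> dict(model=..., null=..., centroids=(lo, hi), gap=...)
    reps: int

    def gap(self, metric: str) -> float:
        return self.metrics[metric]["gap"]


def _canonical_pair_order(*vectors):
    """Lexicographic sort of aligned vectors so bootstrap results do not
    depend on the order the test samples arrive in."""
    arrs = [np.asarray(v, dtype=float) for v in vectors]
    order = np.lexsort(tuple(reversed(arrs)))
    return [a[order] for a in arrs]


def _kmeans2_1d(values: np.ndarray, max_iter: int = 100):
    """1-D two-means with centroids initialized at the two halves' means."""
    lo, hi = float(values.min()), float(values.max())
    c = np.array([lo, hi], dtype=float)
    if lo == hi:
        return c
    for _ in range(max_iter):
        assign = np.abs(values[:, None] - c[None, :]).argmin(axis=1)
        new = np.array(
            [values[assign == k].mean() if np.any(assign == k) else c[k] for k in (0, 1)]
        )
        if np.allclose(new, c):
            break
        c = new
    return np.sort(c)


def gap_statistics(
    y_test, y_pred, y_train, reps: int = 10000, seed: int = 0, metrics=("nrmse", "pcc", "bias")
) -> GapResult:
    """Bootstrap a model against a training-distribution null model.

    Per replicate, test indices are resampled with replacement; the model's
    predictions are scored on the resample while the null model predicts by
    drawing (with replacement) from the training responses.  Each pooled
    metric distribution pair is then summarized by its two k-means (k=2)
    centroids; the centroid difference is the gap.
    """
    y_test, y_pred = _canonical_pair_order(y_test, y_pred)
    y_train = np.sort(np.asarray(y_train, dtype=float))
    if reps < 2:
        raise ValidationError("reps must be >= 2")
    rng = np.random.default_rng(seed)
    n = y_test.size
    out = {name: {"model": np.empty(reps), "null": np.empty(reps)} for name in metrics}
    for r in range(reps):
        idx = rng.integers(0, n, size=n)
        yb = y_test[idx]
        pb = y_pred[idx]
        nb = rng.choice(y_train, size=n, replace=True)
        for name in metrics:
            fn = _REGRESSION_METRICS[name][0]
            try:
                out[name]["model"][r] = fn(PredictionSet(yb, pb))
            except ValidationError:
                out[name]["model"][r] = np.nan
            try:
                out[name]["null"][r] = fn(PredictionSet(yb, nb))
            except ValidationError:
                out[name]["null"][r] = np.nan
    result = {}
    for name in metrics:
        model = out[name]["model"]
        null = out[name]["null"]
        pooled = np.concatenate([model, null])
        pooled = pooled[np.isfinite(pooled)]
        centroids = _kmeans2_1d(pooled)
        result[name] = {
            "model": model,
            "null": null,
            "centroids": (float(centroids[0]), float(centroids[1])),
            "gap": float(centroids[1] - centroids[0]),
        }
    return GapResult(metrics=result, reps=reps)


def robustness(
    y_test, pred_a, pred_b, metric: str = "nrmse", reps: int = 10000, seed: int = 0
) -> float:
    """Fraction of bootstrap replicates where model A strictly beats model B."""
    if metric not in _REGRESSION_METRICS:
        raise ValidationError(f"unknown metric {metric!r}")
    fn, direction = _REGRESSION_METRICS[metric]
    y_test, pred_a, pred_b = _canonical_pair_order(y_test, pred_a, pred_b)
    rng = np.random.default_rng(seed)
    n = y_test.size
    wins = 0
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        try:
            ma = fn(PredictionSet(y_test[idx], pred_a[idx]))
            mb = fn(PredictionSet(y_test[idx], pred_b[idx]))
        except ValidationError:
            continue
        if direction == "lower":
            wins += ma < mb
        else:
            wins += ma > mb
    return wins / reps


def jab_ci(
    y_test, y_pred, metric: str = "nrmse", reps: int = 1000, alpha: float = 0.05, seed: int = 0
):
    """Percentile bootstrap confidence interval for one error metric."""
    if metric not in _REGRESSION_METRICS:
        raise ValidationError(f"unknown metric {metric!r}")
    fn = _REGRESSION_METRICS[metric][0]
    y_test, y_pred = _canonical_pair_order(y_test, y_pred)
    rng = np.random.default_rng(seed)
    n = y_test.size
    vals = []
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(fn(PredictionSet(y_test[idx], y_pred[idx])))
        except ValidationError:
            continue
    vals = np.asarray(vals)
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def binomial_ci(successes: int, n: int, alpha: float = 0.05, method: str = "normal"):
    """Binomial proportion confidence interval, clipped to [0, 1].

    Default is the normal approximation ``p +- z sqrt(p(1-p)/n)``; Wilson is
    available via ``method="wilson"`` (statsmodels).
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    if not 0 <= successes <= n:
        raise ValidationError("successes must lie in [0, n]")
    phat = successes / n
    if method == "normal":
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(phat * (1 - phat) / n)
        return float(max(0.0, phat - half)), float(min(1.0, phat + half))
    if method == "wilson":
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(successes, n, alpha=alpha, method="wilson")
        return float(lo), float(hi)
    raise ValidationError(f"unknown method {method!r}")


def mcnemar(correct_a, correct_b):
    """McNemar's paired test on two models' per-sample correctness vectors.

    Builds the 2x2 disagreement table; uses the exact binomial test when the
    discordant count is below 25, otherwise chi-square with continuity
    correction.  With no discordant pairs the models never disagree and p=1
    by convention.
    """
    correct_a = np.asarray(correct_a).astype(bool)
    correct_b = np.asarray(correct_b).astype(bool)
    if correct_a.shape != correct_b.shape:
        raise ValidationError("correctness vectors must have equal length")
    b = int(np.sum(correct_a & ~correct_b))
    c = int(np.sum(~correct_a & correct_b))
    if b + c == 0:
        return 0.0, 1.0
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

    n11 = int(np.sum(correct_a & correct_b))
    n00 = int(np.sum(~correct_a & ~correct_b))
    table = [[n11, b], [c, n00]]
    exact = (b + c) < 25
    res = sm_mcnemar(table, exact=exact, correction=True)
    return float(res.statistic), float(res.pvalue)


def bc1_correct(
    train_pred: PredictionSet, apply_to: PredictionSet, use_observed: bool = False
) -> PredictionSet:
    """Linear bias correction fitted on residuals (BC1-style).

    Fits ``eps = alpha + beta * y`` by OLS on the fitting set.  The
    correction added to new predictions is ``alpha + beta * g`` where ``g``
    is the observed response when available (``use_observed=True``) and
    otherwise the prediction itself, the proxy available at test time.
    """
    y = train_pred.y
    if np.std(y) == 0:
        raise ValidationError("constant fitting target")
    eps = train_pred.residuals
    beta, alpha = np.polyfit(y, eps, 1)
    g = apply_to.y if use_observed else apply_to.y_hat
    corrected = apply_to.y_hat + alpha + beta * g
    return PredictionSet(apply_to.y, corrected)


def stack_predictions(val_preds: list, test_preds: list):
    """Linear model stacking with nonnegative least-squares weights.

    Weights are fitted by NNLS of the validation responses on the validation
    prediction matrix; the stacked test prediction is the weighted sum using
    the raw NNLS coefficients (which guarantees the stack is at least as good
    as the best single model on the validation set).  Returns
    ``(stacked_test, raw_weights, normalized_weights)``.
    """
    if len(val_preds) == 0:
        raise ValidationError("need at least one model")
    if len(val_preds) != len(test_preds):
        raise ValidationError("validation and test model lists differ in length")
    y_val = val_preds[0].y
    for pset in val_preds[1:]:
        if not np.array_equal(pset.y, y_val):
            raise ValidationError("validation sets must share observed responses")
    a = np.column_stack([pset.y_hat for pset in val_preds])
    w, _ = nnls(a, y_val)
    total = w.sum()
    w_norm = w / total if total > 0 else np.full_like(w, 1.0 / len(w))
    test_matrix = np.column_stack([np.asarray(t, dtype=float) for t in test_preds])
    stacked = test_matrix @ w
    return stacked, w, w_norm


def regression_report(p: PredictionSet) -> dict:
    """All regression metrics in one record."""
    bias, theta = bias_angle(p)
    slope, theta_ols = bias_angle(p, mode="ols_slope")
    return {
        "nrmse": nrmse(p),
        "nmae": nmae(p),
        "pcc": pcc(p),
        "bias": bias,
        "theta_degrees": theta,
        "bias_ols_slope": slope,
        "theta_ols_degrees": theta_ols,
    }


def classification_report(y_true, y_pred, scores=None) -> dict:
    """All classification metrics (plus AUROC when scores are given)."""
    counts = ConfusionCounts.from_labels(y_true, y_pred)
    rec = classification_metrics(counts)
    if scores is not None:
        rec["auroc"] = auroc(y_true, scores)
    return rec
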