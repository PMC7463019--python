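"""Thin wrappers around standard comparator models (scikit-learn backed).

These are the reference regressors/classifiers the feature-image CNN is
benchmarked against; their algorithms are standard and configured through
keyword passthrough.
"""

from __future__ import annotations

import numpy as np

__all__ = ["make_baseline", "BASELINE_REGRESSORS", "BASELINE_CLASSIFIERS"]


def _rf(seed, **kw):
    from sklearn.ensemble import RandomForestRegressor

    return RandomForestRegressor(n_estimators=kw.pop("n_estimators", 300), random_state=seed, **kw)


def _svr(seed, **kw):
    from sklearn.svm import SVR

    return SVR(**kw)


def _en(seed, **kw):
    from sklearn.linear_model import ElasticNet

    return ElasticNet(alpha=kw.pop("alpha", 0.5), l1_ratio=kw.pop("l1_ratio", 1e-5),
                      random_state=seed, **kw)


def _ann(seed, **kw):
    from sklearn.neural_network import MLPRegressor

    return MLPRegressor(
        hidden_layer_sizes=kw.pop("hidden_layer_sizes", (512, 256, 64)),
        random_state=seed,
        max_iter=kw.pop("max_iter", 300),
        **kw,
    )


def _lr(seed, **kw):
    from sklearn.linear_model import LogisticRegression

    return LogisticRegression(random_state=seed, max_iter=kw.pop("max_iter", 1000), **kw)


def _svm(seed, **kw):
    from sklearn.svm import SVC

    return SVC(probability=True, random_state=seed, **kw)


def _rfc(seed, **kw):
    from sklearn.ensemble import RandomForestClassifier

    return RandomForestClassifier(n_estimators=kw.pop("n_estimators", 300), random_state=seed, **kw)


BASELINE_REGRESSORS = {"rf": _rf, "svr": _svr, "en": _en, "ann": _ann}
BASELINE_CLASSIFIERS = {"lr": _lr, "svm": _svm, "rf": _rfc}


def make_baseline(name: str, task: str = "regression", seed: int = 0, **kw):
    """Instantiate a named baseline model ('rf', 'svr', 'en', 'ann', 'lr', 'svm')."""
    table = BASELINE_REGRESSORS if task == "regression" else BASELINE_CLASSIFIERS
    if name not in table:
        raise ValueError(f"unknown baseline {name!r} for task {task!r}; options: {sorted(table)}")
    return table[name](seed, **kw)
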