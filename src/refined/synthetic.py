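"""Synthetic benchmark generator: GP-correlated features with spurious columns.

Features are drawn i.i.d. per sample from a zero-mean Gaussian process on the
lexicographic feature index with stationary covariance ``Sigma_ij =
gamma^|i-j|`` (an AR(1)-type decay), realized exactly as a multivariate
normal via the Cholesky factor of Sigma.  A stated fraction of features is
randomly selected as spurious and given exactly zero weight; the remaining
weights are nonzero standard-normal draws.  Targets are the linear
combination ``y = X w`` min-max normalized to [0, 1]; features are min-max
normalized to [0, 1] for downstream image rendering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import FeatureTable, ValidationError, normalize_features

__all__ = ["SyntheticDataset", "simulate_dataset", "train_val_test_split"]


@dataclass
class SyntheticDataset:
    """A simulated regression benchmark.

    ``table`` holds the [0, 1]-normalized features used downstream;
    ``raw_values`` keeps the unnormalized GP draws that generated ``y``.
    """

    table: FeatureTable
    y: np.ndarray
    weights: np.ndarray
    spurious_mask: np.ndarray
    gamma: float
    seed: int
    raw_values: np.ndarray = None

    def __post_init__(self):
        if np.any(self.weights[self.spurious_mask] != 0.0):
            raise ValidationError("spurious features must have exactly zero weight")
        if self.y.min() < -1e-12 or self.y.max() > 1 + 1e-12:
            raise ValidationError("targets must lie in [0, 1]")

    def write(self, directory, id_column: str = "id") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.table.write_csv(directory / "X.csv", id_column=id_column)
        pd.DataFrame({"id": self.table.sample_ids, "y": self.y}).to_csv(
            directory / "y.csv", index=False
        )
        manifest = {
            "N": self.table.n,
            "P": self.table.p,
            "gamma": self.gamma,
            "spurious_frac": float(self.spurious_mask.mean()),
            "seed": self.seed,
        }
        with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)


def simulate_dataset(
    N: int,
    P: int,
    gamma: float = 0.7,
    spurious_frac: float = 0.2,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> SyntheticDataset:
    """Simulate the GP-feature linear-target benchmark.

    Parameters
    ----------
    N, P : int
        Samples and features (both >= 2).
    gamma : float in (-1, 1)
        Lag-decay of the feature covariance ``gamma^|i-j|``.
    spurious_frac : float in [0, 1]
        Fraction of features given exactly zero weight (``round(frac * P)``).
    noise_sd : float
        Optional additive Gaussian noise on the raw targets (default off).
    """
    if N < 2 or P < 2:
        raise ValidationError("need N >= 2 and P >= 2")
    if not -1 < gamma < 1:
        raise ValidationError("gamma must lie in (-1, 1)")
    if not 0 <= spurious_frac <= 1:
        raise ValidationError("spurious_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    idx = np.arange(P)
    cov = gamma ** np.abs(idx[:, None] - idx[None, :])
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(P))
    x_raw = rng.standard_normal((N, P)) @ chol.T

    n_spurious = int(round(spurious_frac * P))
    spurious = np.zeros(P, dtype=bool)
    spurious[rng.choice(P, size=n_spurious, replace=False)] = True
    weights = np.zeros(P)
    n_live = P - n_spurious
    w = rng.standard_normal(n_live)
    while np.any(np.abs(w) < 1e-3):  # resample weights away from zero
        bad = np.abs(w) < 1e-3
        w[bad] = rng.standard_normal(bad.sum())
    weights[~spurious] = w

    y_raw = x_raw @ weights
    if noise_sd > 0:
        y_raw = y_raw + rng.normal(0.0, noise_sd, size=N)
    span = y_raw.max() - y_raw.min()
    if span <= 0:
        raise ValidationError("degenerate constant targets")
    y = (y_raw - y_raw.min()) / span

    names = [f"f{j:04d}" for j in range(P)]
    ids = [f"s{i:05d}" for i in range(N)]
    table = normalize_features(FeatureTable(ids, names, x_raw))
    return SyntheticDataset(
        table=table,
        y=y,
        weights=weights,
        spurious_mask=spurious,
        gamma=gamma,
        seed=seed,
        raw_values=x_raw,
    )


def train_val_test_split(ds_or_n, fractions=(0.8, 0.1, 0.1), seed: int = 0):
    """Disjoint, exhaustive, seeded index split (train, validation, test)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError("fractions must sum to 1")
    n = ds_or_n if isinstance(ds_or_n, (int, np.integer)) else ds_or_n.table.n
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test
    train = perm[:n_train]
    val = perm[n_train : n_train + n_val]
    test = perm[n_train + n_val :]
    return train, val, test
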