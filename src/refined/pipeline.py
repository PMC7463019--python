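"""End-to-end synthetic benchmark: feature maps -> images -> CNN vs baselines.

Runs the scaled-down study grid on the GP synthetic dataset: build a
distance-preserving feature map and a random map, render images under each,
train CNNs of identical architecture and budget on both, optionally train
standard flat-feature baselines, and score everything with NRMSE on a held
out test set.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .bmds import BmdsConfig
from .cnn_models import ArchitectureSpec, ConvLayerSpec, TrainConfig, predict, train_model
from .data import FeatureTable
from .gridmap import RefinedConfig, RefinedMapper, grid_side
from .imaging import images_to_array, pca_map, random_map, vectors_to_images
from .metrics import PredictionSet, nrmse
from .synthetic import simulate_dataset, train_val_test_split

__all__ = ["small_regressor_spec", "map_image_cnn_nrmse", "synthetic_benchmark"]


def small_regressor_spec(input_shape) -> ArchitectureSpec:
    """A compact CNN regressor for small grids (e.g. 10x10 for P=100).

    Follows the same pattern as the full regressor (strided valid conv with
    batch norm and ReLU, two dense layers, dropout retain 0.7, linear head)
    with kernels scaled down to fit small images.
    """
    conv = [
        ConvLayerSpec(32, (7, 7), stride=1),
        ConvLayerSpec(64, (3, 3), stride=1),
    ]
    return ArchitectureSpec(
        input_shapes=[tuple(input_shape)],
        conv_stacks=[conv],
        dense_sizes=[64, 16],
        dropout_keep=0.7,
        head="regression",
    )


def _cnn_scores(images, y, split, spec, train_cfg):
    tr, va, te = split
    model, history = train_model(spec, images, y, (tr, va), train_cfg)
    preds = predict(model, images)
    return {
        "nrmse_val": nrmse(PredictionSet(y[va], preds[va])),
        "nrmse_test": nrmse(PredictionSet(y[te], preds[te])),
        "history": history,
    }


def map_image_cnn_nrmse(
    ds,
    pixel_map,
    split,
    seed: int = 0,
    epochs: int = 200,
    lr: float = 3e-3,
    batch_size: int = 128,
):
    """Train the compact CNN on images rendered under one map; NRMSE scores."""
    images = images_to_array(vectors_to_images(ds.table, pixel_map))
    spec = small_regressor_spec(images.shape[1:])
    cfg = TrainConfig(lr=lr, epochs=epochs, batch_size=batch_size, seed=seed)
    return _cnn_scores(images, ds.y, split, spec, cfg)


def build_maps(ds, seed: int = 0, bmds_iter: int = 600, max_sweeps: int = 30):
    """REFINED and random maps (plus PCA) for one dataset."""
    burn = bmds_iter // 2
    cfg = RefinedConfig(
        bmds=BmdsConfig(n_iter=bmds_iter, burn_in=burn, seed=seed),
        max_sweeps=max_sweeps,
        seed=seed,
    )
    res = RefinedMapper(ds.table, cfg).fit()
    return {
        "refined": res.pixel_map,
        "random": random_map(ds.table.feature_names, seed=seed),
        "pca": pca_map(ds.table),
    }, res


def synthetic_benchmark(
    N: int = 1000,
    P: int = 100,
    gamma: float = 0.7,
    spurious_frac: float = 0.8,
    seed: int = 0,
    epochs: int = 60,
    bmds_iter: int = 600,
    n_training_seeds: int = 3,
    include_baselines: bool = True,
) -> pd.DataFrame:
    """The scaled-down benchmark grid; returns a tidy NRMSE table.

    One dataset and one REFINED/random/PCA map per call; CNNs are retrained
    with ``n_training_seeds`` seeds and the mean/per-seed NRMSEs reported,
    alongside flat-feature baselines trained on the identical split.
    """
    ds = simulate_dataset(N, P, gamma=gamma, spurious_frac=spurious_frac, seed=seed)
    split = train_val_test_split(ds, seed=seed)
    tr, va, te = split
    maps, _ = build_maps(ds, seed=seed, bmds_iter=bmds_iter)

    rows = []
    for name, pm in maps.items():
        for ts in range(n_training_seeds):
            scores = map_image_cnn_nrmse(ds, pm, split, seed=seed + 1000 * ts, epochs=epochs)
            rows.append(
                {
                    "model": f"{name}-cnn",
                    "training_seed": seed + 1000 * ts,
                    "nrmse_val": scores["nrmse_val"],
                    "nrmse_test": scores["nrmse_test"],
                }
            )

    if include_baselines:
        from .baselines import make_baseline

        x = ds.table.values
        fit_idx = np.concatenate([tr, va])
        for name in ("rf", "svr", "ann", "en"):
            model = make_baseline(name, "regression", seed=seed)
            model.fit(x[fit_idx], ds.y[fit_idx])
            preds = model.predict(x)
            rows.append(
                {
                    "model": name,
                    "training_seed": seed,
                    "nrmse_val": nrmse(PredictionSet(ds.y[va], preds[va])),
                    "nrmse_test": nrmse(PredictionSet(ds.y[te], preds[te])),
                }
            )
    frame = pd.DataFrame(rows)
    summary = (
        frame.groupby("model", as_index=False)
        .agg(nrmse_val=("nrmse_val", "mean"), nrmse_test=("nrmse_test", "mean"),
             n_runs=("nrmse_test", "size"))
        .sort_values("nrmse_test")
        .reset_index(drop=True)
    )
    return summary
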