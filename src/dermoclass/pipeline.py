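"""End-to-end pipeline: generate/load -> denoise -> segment -> featurize
-> train classifier by MRFO -> evaluate.

One ``RunConfig`` (YAML) drives the whole run.  A single global seed is
fanned out to per-stage seeds through a fixed counter scheme
(``stage_seed = (global_seed + 1000003 * stage_index) mod 2^31``), so
one integer reproduces every stage; every derived seed is recorded in
the run manifest.

Stage order follows the method's block diagram: bilateral filtering
denoises each image, fuzzy c-means segments the lesion, the compact CNN
is trained on the training split and produces feature vectors, and the
cascade-forward classifier's weights are found by minimizing the
training error rate with manta ray foraging optimization.  Metrics are
reported on a stratified held-out split.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cascade, evaluation, features, mrfo, preprocessing, segmentation, synth

__all__ = [
    "RunConfig",
    "RunManifest",
    "ConfigValidationError",
    "validate_config",
    "run_pipeline",
    "stage_seed",
]

_STAGES = ("generate", "split", "extractor", "mrfo", "noise")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    idx = _STAGES.index(stage)
    return (int(global_seed) + 1000003 * idx) % 2**31


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/latest"
    input_manifest: str | None = None  # if None, generate synthetic data
    train_fraction: float = 0.7
    # synthetic data
    n_per_class: int = 50
    image_size: tuple[int, int] = (64, 64)
    lesion_area_range: tuple[float, float] = (0.08, 0.25)
    asymmetry_scale: float = 1.0
    border_irregularity: float = 0.4
    color_variance_multiplier: float = 2.5
    gaussian_sigma: float = 0.02
    salt_pepper_fraction: float = 0.005
    # preprocessing
    sigma_spatial: float = 2.0
    sigma_range: float = 0.1
    radius: int | None = None
    # segmentation
    k: int = 2
    fuzzifier: float = 2.0
    tol: float = 1e-5
    max_iter: int = 100
    # features
    epochs: int = 100
    learning_rate: float = 0.005
    batch_size: int = 8
    momentum: float = 0.9
    feature_dim: int = 32
    # classifier / optimizer
    n_hidden: int = 10
    population: int = 30
    mrfo_iterations: int = 100
    weight_bound: float = 5.0
    margin_weight: float = 1.0


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict
    timings: dict
    artifacts: dict
    metrics_table: dict
    accuracy: float
    mean_dice: float
    n_train: int
    n_test: int


class ConfigValidationError(ValueError):
    """Carries the full list of violations, not just the first."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


_CONSTRAINTS = {
    "train_fraction": (lambda v: 0.0 < v < 1.0, "must be in (0, 1)"),
    "n_per_class": (lambda v: v >= 0, "must be >= 0"),
    "asymmetry_scale": (lambda v: v >= 0, "must be >= 0"),
    "border_irregularity": (lambda v: v >= 0, "must be >= 0"),
    "color_variance_multiplier": (lambda v: v >= 1, "must be >= 1"),
    "gaussian_sigma": (lambda v: v >= 0, "must be >= 0"),
    "salt_pepper_fraction": (lambda v: 0.0 <= v <= 1.0, "must be in [0, 1]"),
    "sigma_spatial": (lambda v: v > 0, "must be > 0"),
    "sigma_range": (lambda v: v > 0, "must be > 0"),
    "radius": (lambda v: v is None or v >= 1, "must be >= 1"),
    "k": (lambda v: v >= 2, "must be >= 2"),
    "fuzzifier": (lambda v: v > 1.0, "must be > 1"),
    "tol": (lambda v: v > 0, "must be > 0"),
    "max_iter": (lambda v: v >= 1, "must be >= 1"),
    "epochs": (lambda v: v >= 1, "must be >= 1"),
    "learning_rate": (lambda v: v >= 0, "must be >= 0"),
    "batch_size": (lambda v: v >= 1, "must be >= 1"),
    "momentum": (lambda v: 0.0 <= v < 1.0, "must be in [0, 1)"),
    "feature_dim": (lambda v: v >= 2, "must be >= 2"),
    "n_hidden": (lambda v: v >= 1, "must be >= 1"),
    "population": (lambda v: v >= 2, "must be >= 2"),
    "mrfo_iterations": (lambda v: v >= 1, "must be >= 1"),
    "weight_bound": (lambda v: v > 0, "must be > 0"),
    "margin_weight": (lambda v: v >= 0, "must be >= 0"),
}


def validate_config(raw_text: str) -> RunConfig:
    """Parse YAML config text into a typed, defaulted RunConfig.

    Collects every violation (unknown key, type error, constraint
    breach) and raises ``ConfigValidationError`` listing all of them.
    An empty document yields the defaults.
    """
    data = yaml.safe_load(raw_text) if raw_text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigValidationError(["top level: must be a mapping"])

    known = {f.name: f for f in dataclasses.fields(RunConfig)}
    violations: list[str] = []
    values: dict = {}
    for key, val in data.items():
        if key not in known:
            violations.append(f"{key}: unknown configuration key")
            continue
        values[key] = val
    for key in ("image_size", "lesion_area_range"):
        if key in values:
            try:
                values[key] = tuple(values[key])
            except TypeError:
                violations.append(f"{key}: must be a 2-element sequence")
                del values[key]
    if "lesion_area_range" in values:
        lo, hi = values["lesion_area_range"]
        if not (0.0 < lo < hi < 1.0):
            violations.append("lesion_area_range: must satisfy 0 < min < max < 1")
    if "image_size" in values:
        h, w = values["image_size"]
        if h < 16 or w < 16:
            violations.append("image_size: must be at least 16x16")
    for key, (check, msg) in _CONSTRAINTS.items():
        if key in values:
            try:
                ok = check(values[key])
            except TypeError:
                ok = False
            if not ok:
                violations.append(f"{key}: {msg}")
    if violations:
        raise ConfigValidationError(violations)
    return RunConfig(**values)


def _synth_config(config: RunConfig) -> synth.SynthConfig:
    return synth.SynthConfig(
        n_per_class=config.n_per_class,
        image_size=config.image_size,
        lesion_area_range=config.lesion_area_range,
        melanoma_effect=synth.MelanomaEffect(
            asymmetry_scale=config.asymmetry_scale,
            border_irregularity=config.border_irregularity,
            color_variance_multiplier=config.color_variance_multiplier,
        ),
        noise=synth.NoiseParams(
            gaussian_sigma=config.gaussian_sigma,
            salt_pepper_fraction=config.salt_pepper_fraction,
        ),
        seed=stage_seed(config.seed, "generate"),
    )


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage and write artifacts under ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(dataclasses.asdict(config), sort_keys=True)
    config_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
    seeds = {stage: stage_seed(config.seed, stage) for stage in _STAGES}
    timings: dict = {}
    artifacts: dict = {}

    def _stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return _Timer()

    # --- data -----------------------------------------------------------
    with _stage("generate"):
        if config.input_manifest is not None:
            dataset = synth.read_dataset(config.input_manifest)
        else:
            dataset = synth.generate_dataset(_synth_config(config))
        if not dataset:
            raise ValueError("empty dataset")
        labels = np.array([item.label for item in dataset])

    with _stage("split"):
        train_idx, test_idx = evaluation.stratified_split(
            labels, config.train_fraction, seed=seeds["split"]
        )

    # --- preprocessing + segmentation ----------------------------------
    with _stage("preprocess"):
        bparams = preprocessing.BilateralParams(
            sigma_spatial=config.sigma_spatial,
            sigma_range=config.sigma_range,
            radius=config.radius,
        )
        filtered = [preprocessing.bilateral_filter(it.image, bparams) for it in dataset]

    with _stage("segment"):
        fkm_cfg = segmentation.FkmConfig(
            k=config.k, fuzzifier=config.fuzzifier, tol=config.tol,
            max_iter=config.max_iter, seed=seeds["split"],
        )
        masks = [segmentation.segment_image(img, fkm_cfg) for img in filtered]
        dices = [
            segmentation.dice_coefficient(m, it.truth_mask)
            for m, it in zip(masks, dataset)
        ]
        mean_dice = float(np.mean(dices))

    # --- features -------------------------------------------------------
    with _stage("featurize"):
        ex_cfg = features.ExtractorConfig(
            conv_blocks=((8, 3, 1), (16, 3, 1), (config.feature_dim, 3, 1)),
            feature_dim=config.feature_dim,
            sgd=features.SgdConfig(
                learning_rate=config.learning_rate,
                epochs=config.epochs,
                batch_size=config.batch_size,
                momentum=config.momentum,
            ),
            seed=seeds["extractor"],
        )
        train_items = [dataset[i] for i in train_idx]
        train_masks = [masks[i] for i in train_idx]
        extractor = features.train_extractor(train_items, train_masks, ex_cfg)
        feats = np.stack(
            [
                features.extract_features(extractor, it.image, m, str(i)).values
                for i, (it, m) in enumerate(zip(dataset, masks))
            ]
        )
        # Standardize using training statistics only.
        mu = feats[train_idx].mean(axis=0)
        sd = feats[train_idx].std(axis=0)
        sd[sd == 0] = 1.0
        feats = (feats - mu) / sd

    # --- classifier training via MRFO -----------------------------------
    with _stage("train"):
        layout = cascade.ParamLayout(config.feature_dim, config.n_hidden)
        x_train, y_train = feats[train_idx], labels[train_idx]
        y01_train = (y_train == synth.MELANOMA).astype(float)
        opt_cfg = mrfo.MrfoConfig(
            population=config.population,
            max_iter=config.mrfo_iterations,
            bounds=(-config.weight_bound, config.weight_bound),
            dim=layout.size,
            seed=seeds["mrfo"],
        )
        n_train_pts = x_train.shape[0]

        def train_fitness(v: np.ndarray) -> float:
            # Error rate dominates; the mean score deviation from the
            # 0/1 targets is bounded by the error-rate granularity
            # (100/n), so it only orders weight vectors whose error
            # rates are equal — among zero-error solutions the one with
            # the largest decision margin wins.
            err = mrfo.error_rate_fitness(v, x_train, y_train, layout)
            scores = cascade.forward(cascade.unflatten(v, layout), x_train)
            margin_penalty = float(np.mean(np.abs(scores - y01_train)))
            return err + config.margin_weight * margin_penalty * (100.0 / n_train_pts)

        best_vec, best_fit, trace = mrfo.optimize(train_fitness, opt_cfg)
        params = cascade.unflatten(best_vec, layout)

    # --- evaluation ------------------------------------------------------
    with _stage("evaluate"):
        x_test, y_test = feats[test_idx], labels[test_idx]
        scores = cascade.forward(params, x_test)
        pred = cascade.predict(params, x_test)
        cm = evaluation.confusion(y_test, pred)
        report = evaluation.metrics(cm)
        report.roc = evaluation.roc_points(y_test, scores)
        report.pr = evaluation.pr_points(y_test, scores)

    # --- artifacts -------------------------------------------------------
    model_path = out_dir / "model.json"
    cascade.save_params(params, model_path)
    artifacts["model"] = str(model_path)

    metrics_path = out_dir / "metrics.json"
    metrics_payload = {
        "confusion": dataclasses.asdict(cm),
        "table": report.as_table(),
        "train_error_trace": [round(v, 6) for v in trace],
        "mean_dice": round(mean_dice, 6),
        "n_train": int(train_idx.size),
        "n_test": int(test_idx.size),
    }
    with open(metrics_path, "w") as fh:
        json.dump(metrics_payload, fh, indent=1, sort_keys=True)
    artifacts["metrics"] = str(metrics_path)

    features_path = out_dir / "features.csv"
    import pandas as pd

    pd.DataFrame(
        feats, columns=[f"f_{i}" for i in range(feats.shape[1])]
    ).assign(label=labels).to_csv(features_path, index=False)
    artifacts["features"] = str(features_path)

    manifest = RunManifest(
        config_hash=config_hash,
        seeds=seeds,
        timings=timings,
        artifacts=artifacts,
        metrics_table=report.as_table(),
        accuracy=report.accuracy,
        mean_dice=mean_dice,
        n_train=int(train_idx.size),
        n_test=int(test_idx.size),
    )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=1, sort_keys=True)
    return manifest
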