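"""Experimental protocols: accuracy, branch sweeps, cross-dataset
generalization, noise immunity, and the CNLE efficiency score.

The three headline protocols mirror the study design:

* branch sweep -- train models with different dendrite counts on a mixed
  eight-group dataset (75/25 split) and compare held-out accuracy;
* cross-validation -- train on a single background/object group only, then
  test both on that group and on a balanced mixture of all eight groups
  (cross-accuracy), probing generalization across color regimes;
* noise immunity -- evaluate a clean-trained model on test pairs corrupted
  by salt-and-pepper or Gaussian noise applied to both frames.

CNLE (compute-normalized learning efficiency) is
L = batch_size * delta_E * alpha / (R * P) with alpha = 100, R the training
wall time in seconds and P the processor utilization percentage; it is
hardware-dependent and reported for information only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import FramePair, NoiseSpec
from .dendritic_net import ModelParams, predict_batch
from .training import (TrainConfig, precompute_features, train)

__all__ = [
    "EvalReport", "accuracy", "cnle", "apply_noise",
    "run_branch_sweep", "run_cross_validation", "run_noise_immunity",
    "save_reports", "load_reports",
]

CNLE_ALPHA = 100.0


@dataclass
class EvalReport:
    """One experimental condition with mean +/- std accuracies (percent)."""

    condition: str
    train_accuracy: float = float("nan")
    train_accuracy_std: float = 0.0
    test_accuracy: float = float("nan")
    test_accuracy_std: float = 0.0
    cross_accuracy: float = float("nan")
    cross_accuracy_std: float = 0.0
    cnle: float = float("nan")
    n_repeats: int = 1
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def accuracy(params: ModelParams, pairs: Sequence[FramePair] | tuple) -> float:
    """Classification accuracy in percent over labeled frame pairs."""
    if isinstance(pairs, tuple):
        X, y = pairs
    else:
        if len(pairs) == 0:
            raise ValueError("empty evaluation set")
        X, y = precompute_features(pairs, params.theta_h)
    if len(y) == 0:
        raise ValueError("empty evaluation set")
    return float(np.mean(predict_batch(X, params) == y) * 100.0)


def cnle(batch_size: int, delta_E: float, R: float, P: float,
         alpha: float = CNLE_ALPHA) -> float:
    """L = batch_size * delta_E * alpha / (R * P)."""
    if R <= 0 or P <= 0:
        raise ValueError("wall time R and utilization P must be positive")
    return batch_size * delta_E * alpha / (R * P)


def apply_noise(pairs: Sequence[FramePair], spec: NoiseSpec,
                rng: np.random.Generator | int | None) -> list[FramePair]:
    """Apply one noise spec independently to both frames of every pair."""
    rng = np.random.default_rng(rng)
    return [p.with_noise(spec, rng) for p in pairs]


def _mean_std(vals: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(vals, dtype=np.float64)
    return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0


def run_branch_sweep(
    branches: Sequence[int],
    train_data,
    test_data,
    config: TrainConfig,
    n_repeats: int = 10,
    theta_h: int = 3,
) -> list[EvalReport]:
    """Train/test accuracy versus dendrite count on a fixed mixed split."""
    import time

    Xtr, ytr = (train_data if isinstance(train_data, tuple)
                else precompute_features(train_data, theta_h))
    Xte, yte = (test_data if isinstance(test_data, tuple)
                else precompute_features(test_data, theta_h))
    reports = []
    for j in branches:
        tr_accs, te_accs, cnles = [], [], []
        for r in range(n_repeats):
            seed = config.seed + 1000 * r + j
            model = ModelParams.init_random(j, rng=seed, theta_h=theta_h)
            t0 = time.perf_counter()
            model, recs = train(model, (Xtr, ytr), replace(config, seed=seed))
            wall = time.perf_counter() - t0
            tr_accs.append(recs[-1].train_accuracy)
            te_accs.append(accuracy(model, (Xte, yte)))
            cnles.append(cnle(config.batch_size, recs[-1].delta_E, wall, 100.0))
        tr_m, tr_s = _mean_std(tr_accs)
        te_m, te_s = _mean_std(te_accs)
        reports.append(EvalReport(
            condition=f"J={j}", train_accuracy=tr_m, train_accuracy_std=tr_s,
            test_accuracy=te_m, test_accuracy_std=te_s,
            cnle=float(np.mean(cnles)), n_repeats=n_repeats))
    return reports


def run_cross_validation(
    groups: Sequence[str],
    dataset_factory,
    mixed_test,
    config: TrainConfig,
    n_branches: int = 5,
    n_repeats: int = 10,
    theta_h: int = 3,
) -> list[EvalReport]:
    """Single-group training, mixed-set cross-testing.

    ``dataset_factory(group, seed)`` must return (train_pairs, test_pairs)
    for that group; ``mixed_test`` is a balanced sample over all groups.
    """
    Xmix, ymix = (mixed_test if isinstance(mixed_test, tuple)
                  else precompute_features(mixed_test, theta_h))
    reports = []
    for g in groups:
        tr_accs, te_accs, cx_accs = [], [], []
        for r in range(n_repeats):
            seed = config.seed + 1000 * r
            tr_pairs, te_pairs = dataset_factory(g, seed)
            Xtr, ytr = (tr_pairs if isinstance(tr_pairs, tuple)
                        else precompute_features(tr_pairs, theta_h))
            model = ModelParams.init_random(n_branches, rng=seed, theta_h=theta_h)
            model, recs = train(model, (Xtr, ytr), replace(config, seed=seed))
            tr_accs.append(recs[-1].train_accuracy)
            te_accs.append(accuracy(model, te_pairs))
            cx_accs.append(accuracy(model, (Xmix, ymix)))
        tr_m, tr_s = _mean_std(tr_accs)
        te_m, te_s = _mean_std(te_accs)
        cx_m, cx_s = _mean_std(cx_accs)
        reports.append(EvalReport(
            condition=g, train_accuracy=tr_m, train_accuracy_std=tr_s,
            test_accuracy=te_m, test_accuracy_std=te_s,
            cross_accuracy=cx_m, cross_accuracy_std=cx_s,
            n_repeats=n_repeats))
    return reports


DEFAULT_NOISE_SUITES: tuple[NoiseSpec, ...] = (
    NoiseSpec("salt_pepper", rate=0.01),
    NoiseSpec("salt_pepper", rate=0.02),
    NoiseSpec("salt_pepper", rate=0.05),
    NoiseSpec("salt_pepper", rate=0.10),
    NoiseSpec("gaussian", std=1.0),
    NoiseSpec("gaussian", std=5.0),
    NoiseSpec("gaussian", std=10.0),
    NoiseSpec("gaussian", std=20.0),
)


def run_noise_immunity(
    model: ModelParams,
    test_pairs: Sequence[FramePair],
    suites: Sequence[NoiseSpec] = DEFAULT_NOISE_SUITES,
    n_repeats: int = 10,
    seed: int = 0,
) -> list[EvalReport]:
    """Accuracy of a clean-trained model under test-time corruption.

    Each suite is applied ``n_repeats`` times with distinct noise seeds; the
    accuracy mean and sample std over repeats are reported.
    """
    reports = []
    for spec in suites:
        accs = []
        for r in range(n_repeats):
            kind_code = {"none": 0, "salt_pepper": 1, "gaussian": 2}[spec.kind]
            rng = np.random.default_rng(np.random.SeedSequence(
                [seed, kind_code, int(spec.param * 1000), r]))
            if spec.kind == "none":
                noisy = list(test_pairs)
            else:
                noisy = apply_noise(test_pairs, spec, rng)
            accs.append(accuracy(model, noisy))
        m, s = _mean_std(accs)
        label = ("clean" if spec.kind == "none"
                 else f"{spec.kind}={spec.param:g}")
        reports.append(EvalReport(condition=label, test_accuracy=m,
                                  test_accuracy_std=s, n_repeats=n_repeats))
    return reports


def save_reports(reports: Sequence[EvalReport], path: str | Path) -> None:
    """Write reports as JSON (and a CSV sibling for spreadsheet use)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [r.to_dict() for r in reports]
    path.write_text(json.dumps(payload, indent=2))
    pd.DataFrame(payload).to_csv(path.with_suffix(".csv"), index=False)


def load_reports(path: str | Path) -> list[EvalReport]:
    payload = json.loads(Path(path).read_text())
    return [EvalReport(**d) for d in payload]
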