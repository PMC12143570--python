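"""Experiment harness: training/evaluation grids over task distributions.

Reproduces the three evaluation designs used throughout the study:

* **in-distribution** accuracy as a function of the burst length ``k``
  (train and test on the same law);
* **generalisation** matrices — train on one fixed ``k``, test on another —
  together with the relative-accuracy (shortfall) curves
  ``A(k, k - dk) - max_k' A(k', k - dk)``;
* the **mixed-distribution suite** — a full train x test grid over the ten
  laws {fixed k = 1..8, uniform, levy}, with min-max envelopes across the
  fixed-k-trained models.

Task distributions are named by short spec strings: ``"k3"`` for a fixed
burst length of 3, ``"uniform"`` and ``"levy"`` for the mixed laws.  All
randomness is derived from one base seed: each (purpose, spec) pair maps to
its own integer sub-seed, so every cell of a grid is reproducible in
isolation and all trained models of one grid share each test set.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fusion import fit_classifier
from .rnn import RNNConfig, train_rnn
from .task import TaskConfig, batch_arrays, make_task_config, sample_batch

__all__ = [
    "FIXED_SPECS",
    "ALL_SPECS",
    "task_from_spec",
    "subseed",
    "generate_arrays",
    "train_model",
    "evaluate_accuracy",
    "EvaluationGrid",
    "run_generalisation_grid",
    "run_mixed_distribution_suite",
    "relative_accuracy_curve",
    "max_ood_shortfall",
    "fixed_k_envelope",
    "two_proportion_test",
    "grid_to_frame",
    "write_grid",
]

FIXED_SPECS = tuple(f"k{k}" for k in range(1, 9))
ALL_SPECS = FIXED_SPECS + ("uniform", "levy")

# model_kind -> (fusion kind, window) ; "rnn" handled separately
_FUSION_KINDS = {"lf": ("lf", 1), "nlf": ("nlf", 1), "nlf2": ("nlf_w", 2), "nlf3": ("nlf_w", 3)}
MODEL_WINDOW = {"lf": 1, "nlf": 1, "nlf2": 2, "nlf3": 3, "rnn": 1}


def task_from_spec(spec: str, **overrides) -> TaskConfig:
    """Task configuration for a spec string (``"k1".."k8"``, ``"uniform"``, ``"levy"``)."""
    if spec.startswith("k"):
        return make_task_config(kind="fixed", k=int(spec[1:]), **overrides)
    if spec in ("uniform", "levy"):
        return make_task_config(kind=spec, **overrides)
    raise ValueError(f"unknown task spec {spec!r}")


def subseed(base_seed: int, *tags) -> int:
    """Deterministic 31-bit sub-seed for a tagged purpose."""
    entropy = [int(base_seed)] + [zlib.crc32(str(t).encode()) for t in tags]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def generate_arrays(
    config: TaskConfig, n_trials: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a batch and return ``(labels, observations)`` arrays."""
    trials = sample_batch(config, n_trials, seed=seed)
    m, x, _ = batch_arrays(trials)
    return m, x


def train_model(
    model_kind: str,
    train_spec: str,
    n_trials: int,
    seed: int,
    task_overrides: Mapping | None = None,
    rnn_config: RNNConfig | None = None,
    rnn_learning_rate: float = 2e-4,
    **fusion_hyper,
):
    """Train one model on freshly simulated trials; returns the fitted model.

    Fusion models are deterministic given the data; the RNN additionally
    depends on its weight-initialisation seed (derived from ``seed`` unless
    an explicit :class:`RNNConfig` is supplied).
    """
    config = task_from_spec(train_spec, **(task_overrides or {}))
    labels, x = generate_arrays(config, n_trials, seed)
    if model_kind == "rnn":
        if rnn_config is None:
            rnn_config = RNNConfig(n_channels=config.n_channels, seed=seed)
        model, _ = train_rnn(x, labels, rnn_config, learning_rate=rnn_learning_rate)
        return model
    kind, w = _FUSION_KINDS[model_kind]
    return fit_classifier(x, labels, model_kind=kind, w=w, **fusion_hyper)


def evaluate_accuracy(
    model,
    test_spec: str | TaskConfig,
    n_trials: int,
    seed: int,
    task_overrides: Mapping | None = None,
    test_data: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Held-out accuracy with an exact binomial confidence interval."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if test_data is None:
        config = (
            test_spec
            if isinstance(test_spec, TaskConfig)
            else task_from_spec(test_spec, **(task_overrides or {}))
        )
        labels, x = generate_arrays(config, n_trials, seed)
    else:
        labels, x = test_data
    pred = model.predict(x)
    n_correct = int((pred == labels).sum())
    ci = stats.binomtest(n_correct, labels.size).proportion_ci(0.95)
    return {
        "accuracy": n_correct / labels.size,
        "n_correct": n_correct,
        "n_trials": int(labels.size),
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
    }


@dataclass
class EvaluationGrid:
    """Accuracy matrix over train x test task distributions."""

    model_kind: str
    accuracy: pd.DataFrame  # index = train spec, columns = test spec
    n_test_trials: int
    n_train_trials: int
    seed: int
    replicate_sd: pd.DataFrame | None = None

    def shortfall(self) -> pd.DataFrame:
        """Per cell: accuracy minus the best accuracy on that test column (<= 0)."""
        return self.accuracy - self.accuracy.max(axis=0)


def _run_grid(
    model_kind: str,
    train_specs: Sequence[str],
    test_specs: Sequence[str],
    n_train: int,
    n_test: int,
    seed: int,
    task_overrides: Mapping | None = None,
    replicates: int = 1,
    **train_kwargs,
) -> EvaluationGrid:
    # shared test sets: one per test spec, independent of the training spec
    test_sets = {}
    for spec in test_specs:
        config = task_from_spec(spec, **(task_overrides or {}))
        test_sets[spec] = generate_arrays(config, n_test, subseed(seed, "test", spec))

    acc = pd.DataFrame(index=list(train_specs), columns=list(test_specs), dtype=float)
    sd = pd.DataFrame(index=list(train_specs), columns=list(test_specs), dtype=float)
    for train in train_specs:
        per_rep = []
        for rep in range(replicates):
            model = train_model(
                model_kind,
                train,
                n_train,
                subseed(seed, "train", train, rep),
                task_overrides=task_overrides,
                **train_kwargs,
            )
            per_rep.append(
                [
                    evaluate_accuracy(model, test, n_test, 0, test_data=test_sets[test])[
                        "accuracy"
                    ]
                    for test in test_specs
                ]
            )
        per_rep = np.asarray(per_rep)
        acc.loc[train] = per_rep.mean(axis=0)
        sd.loc[train] = per_rep.std(axis=0, ddof=1) if replicates > 1 else 0.0
    return EvaluationGrid(
        model_kind=model_kind,
        accuracy=acc,
        n_test_trials=n_test,
        n_train_trials=n_train,
        seed=seed,
        replicate_sd=sd if replicates > 1 else None,
    )


def run_generalisation_grid(
    model_kind: str,
    train_ks: Iterable[int] = range(1, 9),
    test_ks: Iterable[int] = range(1, 9),
    n_train: int = 50_000,
    n_test: int = 20_000,
    seed: int = 0,
    task_overrides: Mapping | None = None,
    **train_kwargs,
) -> EvaluationGrid:
    """Train one model per fixed ``k`` and test it on every other ``k``."""
    return _run_grid(
        model_kind,
        [f"k{k}" for k in train_ks],
        [f"k{k}" for k in test_ks],
        n_train,
        n_test,
        seed,
        task_overrides=task_overrides,
        **train_kwargs,
    )


def run_mixed_distribution_suite(
    model_kinds: Sequence[str] = ("nlf2", "nlf3"),
    specs: Sequence[str] = ALL_SPECS,
    n_train: int = 50_000,
    n_test: int = 20_000,
    seed: int = 0,
    task_overrides: Mapping | None = None,
    **train_kwargs,
) -> dict[str, EvaluationGrid]:
    """Full train x test grid over {k=1..8, uniform, levy} per model kind."""
    return {
        kind: _run_grid(
            kind, specs, specs, n_train, n_test, seed,
            task_overrides=task_overrides, **train_kwargs,
        )
        for kind in model_kinds
    }


def relative_accuracy_curve(grid: EvaluationGrid) -> pd.DataFrame:
    """Shortfall vs burst-length offset: ``A(k, k - dk) - max_k' A(k', k - dk)``.

    Only defined for grids whose specs are all fixed-``k``; one row per
    (train k, delta_k) pair, values <= 0.
    """
    short = grid.shortfall()
    rows = []
    for train in short.index:
        k = int(str(train)[1:])
        for test in short.columns:
            k_test = int(str(test)[1:])
            rows.append(
                {"k_train": k, "delta_k": k - k_test, "value": float(short.loc[train, test])}
            )
    return pd.DataFrame(rows)


def max_ood_shortfall(
    grids: Iterable[EvaluationGrid] | EvaluationGrid,
    min_train_k: Mapping[str, int] | None = None,
) -> float:
    """Largest shortfall magnitude, in percentage points, across grids.

    ``min_train_k`` optionally restricts each grid to models trained on
    burst lengths at least that long (e.g. past the model's window length,
    where the window-fusion models have temporal structure to learn from).
    """
    if isinstance(grids, EvaluationGrid):
        grids = [grids]
    worst = 0.0
    for grid in grids:
        short = grid.shortfall()
        if min_train_k:
            lo = min_train_k.get(grid.model_kind, 1)
            keep = [s for s in short.index if int(str(s)[1:]) >= lo]
            short = short.loc[keep]
        worst = max(worst, float(-short.min().min()) * 100.0)
    return worst


def fixed_k_envelope(grid: EvaluationGrid) -> pd.DataFrame:
    """Min-max accuracy span, per test spec, across fixed-k-trained models."""
    fixed_rows = [s for s in grid.accuracy.index if str(s).startswith("k")]
    sub = grid.accuracy.loc[fixed_rows]
    return pd.DataFrame({"min": sub.min(axis=0), "max": sub.max(axis=0)})


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-sided two-proportion z-test; returns (z, p-value)."""
    p_pool = (k1 + k2) / (n1 + n2)
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    if se == 0.0:
        return 0.0, 1.0
    z = (k1 / n1 - k2 / n2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def grid_to_frame(grid: EvaluationGrid) -> pd.DataFrame:
    """Tidy one-row-per-cell representation of a grid."""
    rows = []
    for train in grid.accuracy.index:
        for test in grid.accuracy.columns:
            rows.append(
                {
                    "model": grid.model_kind,
                    "train": train,
                    "test": test,
                    "accuracy": float(grid.accuracy.loc[train, test]),
                    "replicate_sd": (
                        float(grid.replicate_sd.loc[train, test])
                        if grid.replicate_sd is not None
                        else 0.0
                    ),
                    "n_test_trials": grid.n_test_trials,
                }
            )
    return pd.DataFrame(rows)


def write_grid(grid: EvaluationGrid, out_dir: str | Path) -> None:
    """Write a grid as tidy CSV plus a JSON manifest of its configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid_to_frame(grid).to_csv(out / f"grid_{grid.model_kind}.csv", index=False)
    manifest = {
        "model_kind": grid.model_kind,
        "train_specs": list(grid.accuracy.index),
        "test_specs": list(grid.accuracy.columns),
        "n_train_trials": grid.n_train_trials,
        "n_test_trials": grid.n_test_trials,
        "seed": grid.seed,
    }
    with open(out / f"grid_{grid.model_kind}.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
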