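"""Burst-structured multisensory detection task.

A hidden target moves in direction ``M`` in {-1, +1} and intermittently emits
signal bursts.  At each of ``n`` time steps every sensory channel ``i``
reports a trinary observation ``X_it`` in {-1, 0, +1}:

* while the target is silent (``E_t = 0``) the channel sees unbiased noise:
  0 with probability ``p_n``, otherwise -1 or +1 with equal probability;
* while the target emits (``E_t = 1``) the channel sees the true direction
  ``M`` with probability ``p_c``, the wrong direction with probability
  ``p_i`` and 0 otherwise.

Emission episodes start independently at each step with probability ``p_g``
and last ``L`` steps, where ``L`` follows a burst-length law: a fixed length
``k``, uniform on ``1..L_max``, or a truncated power law ("Levy",
``P(L = l) \\propto 1 / l^2``).  A burst starting at ``s`` with length ``l``
covers steps ``s .. s+l-1``; starts are sampled on ``1-L_max+1 .. n`` so
bursts that began before the trial can still cover its first steps.  Trials
in which the target never emits are resampled, so every trial is solvable.

``p_g`` is normally derived from a target expected emission fraction ``p_e``
via :mod:`burstfusion.normalization`, which keeps the average amount of
signal constant across burst-length laws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import normalization

__all__ = [
    "BurstLengthModel",
    "TaskConfig",
    "Trial",
    "burst_length_pmf",
    "make_task_config",
    "emission_from_bursts",
    "sample_trial",
    "sample_batch",
    "batch_arrays",
    "sample_emission_sequences",
    "trials_to_frame",
    "write_trials_csv",
]

BURST_KINDS = ("fixed", "uniform", "levy")


@dataclass(frozen=True)
class BurstLengthModel:
    """Distribution of burst lengths on the support ``1 .. l_max``."""

    kind: str
    l_max: int
    pmf: np.ndarray
    k: int | None = None

    def __post_init__(self) -> None:
        pmf = np.asarray(self.pmf, dtype=float)
        object.__setattr__(self, "pmf", pmf)
        if self.kind not in BURST_KINDS:
            raise ValueError(f"unknown burst kind {self.kind!r}")
        if pmf.size != self.l_max:
            raise ValueError("pmf length must equal l_max")
        if abs(pmf.sum() - 1.0) > 1e-12 or np.any(pmf < 0):
            raise ValueError("pmf must be a probability vector summing to 1")
        if self.kind == "fixed":
            if self.k is None or self.pmf[self.k - 1] != 1.0:
                raise ValueError("fixed kind requires a point-mass pmf at k")

    @property
    def mean_length(self) -> float:
        return float(np.arange(1, self.l_max + 1) @ self.pmf)


def burst_length_pmf(kind: str, k: int | None = None, l_max: int | None = None) -> BurstLengthModel:
    """Build a burst-length model.

    ``fixed`` places all mass on ``k`` (``l_max`` defaults to ``k``);
    ``uniform`` is flat on ``1..l_max``; ``levy`` has mass proportional to
    ``1/l^2`` on ``1..l_max``.
    """
    if kind not in BURST_KINDS:
        raise ValueError(f"unknown burst kind {kind!r}; expected one of {BURST_KINDS}")
    if kind == "fixed":
        if k is None or k < 1:
            raise ValueError("fixed kind requires a positive integer k")
        if l_max is None:
            l_max = k
        if l_max < k:
            raise ValueError("l_max must be >= k for a fixed burst length")
        pmf = np.zeros(l_max)
        pmf[k - 1] = 1.0
        return BurstLengthModel(kind="fixed", l_max=l_max, pmf=pmf, k=k)
    if l_max is None or l_max < 1:
        raise ValueError(f"{kind} kind requires a positive integer l_max")
    lengths = np.arange(1, l_max + 1, dtype=float)
    if kind == "uniform":
        pmf = np.full(l_max, 1.0 / l_max)
    else:  # levy: truncated 1/l^2 law
        pmf = lengths**-2.0
        pmf /= pmf.sum()
    return BurstLengthModel(kind=kind, l_max=l_max, pmf=pmf)


@dataclass(frozen=True)
class TaskConfig:
    """All generative parameters of one task variant.

    ``p_g`` is the per-step burst-start probability, normally solved from the
    target emission fraction ``p_e`` (see :func:`make_task_config`).
    """

    n: int
    n_channels: int
    p_c: float
    p_i: float
    p_n: float
    p_e: float
    p_g: float
    burst_model: BurstLengthModel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.n_channels < 1:
            raise ValueError("n and n_channels must be positive")
        if not 0.0 <= self.p_i <= self.p_c:
            raise ValueError("require 0 <= p_i <= p_c")
        if self.p_c + self.p_i > 1.0:
            raise ValueError("require p_c + p_i <= 1")
        if not 0.0 <= self.p_n <= 1.0:
            raise ValueError("require 0 <= p_n <= 1")
        if not 0.0 < self.p_e < 1.0:
            raise ValueError("require 0 < p_e < 1")
        if not 0.0 < self.p_g < 1.0:
            raise ValueError("require 0 < p_g < 1")
        p_e_min = normalization.min_pe_general(self.burst_model, self.n)
        if self.p_e <= p_e_min:
            raise normalization.InfeasibleSparsityError(
                f"p_e={self.p_e} is not achievable: infimum for this burst "
                f"model at n={self.n} is {p_e_min:.6g}"
            )

    @property
    def l_max(self) -> int:
        return self.burst_model.l_max

    def with_seed(self, seed: int) -> "TaskConfig":
        return replace(self, seed=seed)


def make_task_config(
    kind: str = "fixed",
    k: int | None = None,
    l_max: int | None = None,
    n: int = 200,
    n_channels: int = 2,
    p_c: float = 0.45,
    p_i: float = 0.01,
    p_n: float = 0.33,
    p_e: float = 0.04,
    p_g: float | None = None,
    seed: int = 0,
) -> TaskConfig:
    """Build a :class:`TaskConfig`, solving ``p_g`` from ``p_e`` if not given.

    Defaults are the standard study conditions: two channels, 200-step
    trials, ``p_c = 0.45``, ``p_i = 0.01``, ``p_n = 0.33``, ``p_e = 0.04``;
    uniform and Levy laws default to ``l_max = 8``.
    """
    if kind in ("uniform", "levy") and l_max is None:
        l_max = 8
    model = burst_length_pmf(kind, k=k, l_max=l_max)
    if p_g is None:
        p_g = normalization.solve_pg(p_e, model, n).p_g
    return TaskConfig(
        n=n,
        n_channels=n_channels,
        p_c=p_c,
        p_i=p_i,
        p_n=p_n,
        p_e=p_e,
        p_g=p_g,
        burst_model=model,
        seed=seed,
    )


@dataclass(frozen=True)
class Trial:
    """One sampled trial.

    ``g`` and ``l`` run over the extended start axis ``1-L_max+1 .. n``
    (length ``n + L_max - 1``); ``l`` is 0 where no burst starts.  ``e`` is
    the in-trial emission indicator, ``x`` the ``n_channels x n`` observation
    grid with values in {-1, 0, +1}.
    """

    m: int
    g: np.ndarray
    l: np.ndarray
    e: np.ndarray
    x: np.ndarray


def emission_from_bursts(g: np.ndarray, l: np.ndarray, n: int) -> np.ndarray:
    """Emission indicator from burst starts and lengths.

    ``e_t = 1`` iff some start at ``s <= t`` with length ``>= t - s + 1``
    covers ``t``.  ``g``/``l`` have length ``n + L_max - 1``; index 0 maps to
    time ``1 - L_max + 1``.
    """
    g = np.asarray(g)
    l = np.asarray(l)
    if g.shape != l.shape or g.ndim != 1:
        raise ValueError("g and l must be 1-d arrays of equal length")
    if g.size < n:
        raise ValueError("start axis must be at least as long as the trial")
    offset = g.size - n  # == L_max - 1
    diff = np.zeros(n + 1, dtype=np.int64)
    starts = np.flatnonzero(g)
    if starts.size:
        lo = np.clip(starts - offset, 0, n)
        hi = np.clip(starts - offset + l[starts], 0, n)
        np.add.at(diff, lo, 1)
        np.add.at(diff, hi, -1)
    return (np.cumsum(diff[:-1]) > 0).astype(np.int8)


def _draw_lengths(model: BurstLengthModel, count: int, rng: np.random.Generator) -> np.ndarray:
    if model.kind == "fixed":
        return np.full(count, model.k, dtype=np.int64)
    cdf = np.cumsum(model.pmf)
    return np.searchsorted(cdf, rng.random(count), side="right") + 1


def _draw_observations(
    e: np.ndarray, m: int, config: TaskConfig, rng: np.random.Generator
) -> np.ndarray:
    u = rng.random((config.n_channels, config.n))
    # silent steps: 0 w.p. p_n, else +-1 symmetric
    noise = np.where(u < config.p_n, 0, np.where(u < config.p_n + (1 - config.p_n) / 2, 1, -1))
    # emitting steps: m w.p. p_c, -m w.p. p_i, 0 otherwise
    signal = np.where(u < config.p_c, m, np.where(u < config.p_c + config.p_i, -m, 0))
    return np.where(e.astype(bool)[None, :], signal, noise).astype(np.int8)


def sample_trial(config: TaskConfig, rng: np.random.Generator) -> Trial:
    """Sample one trial; all-silent outcomes are fully redrawn."""
    m = -1 if rng.random() < 0.5 else 1
    n_sites = config.n + config.l_max - 1
    while True:
        g = (rng.random(n_sites) < config.p_g).astype(np.int8)
        l = np.zeros(n_sites, dtype=np.int64)
        starts = np.flatnonzero(g)
        l[starts] = _draw_lengths(config.burst_model, starts.size, rng)
        e = emission_from_bursts(g, l, config.n)
        if e.any():
            break
    x = _draw_observations(e, m, config, rng)
    return Trial(m=m, g=g, l=l, e=e, x=x)


def sample_batch(
    config: TaskConfig, n_trials: int, seed: int | None = None
) -> list[Trial]:
    """Sample independent trials, one child RNG stream per trial.

    Streams are spawned deterministically from the root seed, so enlarging a
    batch never perturbs earlier trials.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    return [
        sample_trial(config, np.random.Generator(np.random.PCG64(child)))
        for child in root.spawn(n_trials)
    ]


def batch_arrays(trials: Sequence[Trial]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a batch into ``(m, x, e)`` arrays of shapes (T,), (T, Nc, n), (T, n)."""
    m = np.array([t.m for t in trials], dtype=np.int64)
    x = np.stack([t.x for t in trials])
    e = np.stack([t.e for t in trials])
    return m, x, e


def sample_emission_sequences(
    burst_model: BurstLengthModel,
    p_g: float,
    n: int,
    n_seq: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised sampler of rejection-filtered emission indicators.

    Returns an ``(n_seq, n)`` binary array; used for Monte-Carlo checks of
    the closed-form emission fraction where only ``E`` is needed.
    """
    n_sites = n + burst_model.l_max - 1
    out = np.empty((n_seq, n), dtype=np.int8)
    pending = np.arange(n_seq)
    while pending.size:
        g = rng.random((pending.size, n_sites)) < p_g
        l = np.zeros((pending.size, n_sites), dtype=np.int64)
        rows, cols = np.nonzero(g)
        l[rows, cols] = _draw_lengths(burst_model, rows.size, rng)
        offset = n_sites - n
        diff = np.zeros((pending.size, n + 1), dtype=np.int64)
        lo = np.clip(cols - offset, 0, n)
        hi = np.clip(cols - offset + l[rows, cols], 0, n)
        np.add.at(diff, (rows, lo), 1)
        np.add.at(diff, (rows, hi), -1)
        e = (np.cumsum(diff[:, :-1], axis=1) > 0).astype(np.int8)
        out[pending] = e
        pending = pending[~e.any(axis=1)]
    return out


def trials_to_frame(trials: Iterable[Trial]) -> pd.DataFrame:
    """Flatten a batch to one row per trial-timestep."""
    records = []
    for trial_id, trial in enumerate(trials):
        n_channels, n = trial.x.shape
        for t in range(n):
            row = {"trial_id": trial_id, "t": t + 1, "m": trial.m, "e": int(trial.e[t])}
            for i in range(n_channels):
                row[f"x_{i + 1}"] = int(trial.x[i, t])
            records.append(row)
    return pd.DataFrame.from_records(records)


def write_trials_csv(trials: Sequence[Trial], path: str) -> None:
    trials_to_frame(trials).to_csv(path, index=False)
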