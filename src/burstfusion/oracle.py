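"""Brute-force Bayes posterior for tiny trials.

The optimal decision maximises ``P(M = m | X)``, which requires summing the
trial likelihood over every hidden configuration of burst starts and
lengths.  The number of configurations grows exponentially with trial
length, which is exactly why the task is interesting — no plausible circuit
can run this computation.  For tiny ``n`` it is feasible, and this module
enumerates the sum exactly so it can serve as a correctness oracle for both
the simulator and the approximate classifiers.

Each of the ``n + L_max - 1`` start sites independently either hosts no
burst (probability ``1 - p_g``) or a burst of length ``l`` (probability
``p_g * q_l``).  Configurations whose emission indicator is identically zero
are excluded from the sum, matching the generator's rejection filtering.
The surviving configurations are grouped by their emission pattern, whose
prior weights are cached per task configuration, so repeated posterior
queries under one task cost only ``O(2^n * n)``.

Likelihood products are accumulated in log space with ``logsumexp``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .task import TaskConfig

__all__ = ["IntractabilityError", "PosteriorResult", "exact_posterior"]

DEFAULT_CONFIG_CAP = 10**7


class IntractabilityError(ValueError):
    """Hidden-configuration count exceeds the enumeration cap."""


@dataclass(frozen=True)
class PosteriorResult:
    """Exact posterior over the direction for one trial."""

    p_right: float
    map_label: int
    n_configs: int


# cache of (emission patterns, log prior weights, n_configs) per task
_marginal_cache: dict[tuple, tuple[np.ndarray, np.ndarray, int]] = {}


def _config_key(config: TaskConfig) -> tuple:
    return (
        config.n,
        config.l_max,
        round(config.p_g, 15),
        tuple(np.round(config.burst_model.pmf, 15)),
    )


def _emission_marginal(
    config: TaskConfig, cap: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Enumerate hidden configurations; return unique emission patterns with
    their aggregated log prior weights (all-silent pattern excluded)."""
    key = _config_key(config)
    if key in _marginal_cache:
        return _marginal_cache[key]

    n, l_max, p_g = config.n, config.l_max, config.p_g
    pmf = config.burst_model.pmf
    lengths = [int(l) for l in np.flatnonzero(pmf) + 1]
    # per-site options: no start, or a start with one of the feasible lengths
    option_lengths = np.array([0] + lengths, dtype=np.int64)
    option_logp = np.log(
        np.concatenate([[1.0 - p_g], p_g * pmf[np.array(lengths) - 1]])
    )
    n_sites = n + l_max - 1
    n_opts = option_lengths.size
    n_configs = n_opts**n_sites
    if n_configs > cap:
        raise IntractabilityError(
            f"{n_opts}**{n_sites} = {n_configs} hidden configurations exceed "
            f"the cap {cap}; exact marginalisation is only feasible for tiny n"
        )

    pattern_weights: dict[int, list] = {}
    offset = l_max - 1
    chunk = 1_000_000
    for start in range(0, n_configs, chunk):
        idx = np.arange(start, min(start + chunk, n_configs))
        opts = np.stack(
            np.unravel_index(idx, (n_opts,) * n_sites), axis=1
        )  # (C, n_sites)
        log_prior = option_logp[opts].sum(axis=1)
        burst_len = option_lengths[opts]
        # coverage via per-config difference arrays
        diff = np.zeros((idx.size, n + 1), dtype=np.int64)
        rows, cols = np.nonzero(burst_len)
        lo = np.clip(cols - offset, 0, n)
        hi = np.clip(cols - offset + burst_len[rows, cols], 0, n)
        np.add.at(diff, (rows, lo), 1)
        np.add.at(diff, (rows, hi), -1)
        e = np.cumsum(diff[:, :-1], axis=1) > 0
        codes = e @ (1 << np.arange(n, dtype=np.int64))
        keep = codes != 0  # condition on the non-silent event
        for code, lp in zip(codes[keep], log_prior[keep]):
            pattern_weights.setdefault(int(code), []).append(lp)

    codes = np.array(sorted(pattern_weights), dtype=np.int64)
    log_w = np.array([logsumexp(pattern_weights[c]) for c in codes])
    # normalise to the conditional prior P(config | not F)
    log_w -= logsumexp(log_w)
    e_patterns = ((codes[:, None] >> np.arange(n)) & 1).astype(np.int8)
    result = (e_patterns, log_w, n_configs)
    _marginal_cache[key] = result
    return result


def _obs_log_table(config: TaskConfig) -> np.ndarray:
    """log P(x | e, m) indexed as [e, m_idx, x + 1] (m_idx 0 -> -1, 1 -> +1)."""
    half = (1.0 - config.p_n) / 2.0
    table = np.empty((2, 2, 3))
    with np.errstate(divide="ignore"):
        table[0, :, :] = np.log([half, config.p_n, half])  # silent, m-independent
        neutral = 1.0 - config.p_c - config.p_i
        table[1, 0, :] = np.log([config.p_c, neutral, config.p_i])  # m = -1
        table[1, 1, :] = np.log([config.p_i, neutral, config.p_c])  # m = +1
    return table


def exact_posterior(
    x: np.ndarray, config: TaskConfig, cap: int = DEFAULT_CONFIG_CAP
) -> PosteriorResult:
    """Exact posterior ``P(M = +1 | X)`` by exhaustive marginalisation.

    Sums ``prod_t P(x_t | m, g, l)`` over every hidden start/length
    configuration, excluding the all-silent ones (the generator resamples
    those), and normalises over the two directions.  A posterior of exactly
    0.5 maps to +1, consistent with the fusion classifiers.
    """
    x = np.asarray(x)
    if x.ndim != 2 or x.shape[0] != config.n_channels or x.shape[1] != config.n:
        raise ValueError("x must be an (n_channels, n) observation grid")
    e_patterns, log_w, n_configs = _emission_marginal(config, cap)
    table = _obs_log_table(config)
    x_idx = x + 1  # (Nc, n) in {0,1,2}
    # step_ll[e, m_idx, t] = sum over channels of log P(x_it | e, m)
    step_ll = table[:, :, x_idx].sum(axis=2)  # (2, 2, n)
    # per-pattern log-likelihoods: sum step_ll[e_pattern[t], m, t] over t
    ll_patterns = np.where(
        e_patterns[:, None, :].astype(bool), step_ll[1][None, :, :], step_ll[0][None, :, :]
    ).sum(axis=2)  # (U, 2)
    with np.errstate(invalid="ignore"):
        ll_m = logsumexp(log_w[:, None] + ll_patterns, axis=0)  # (2,)
    if np.all(np.isneginf(ll_m)):
        raise ValueError(
            "observations have zero probability under both directions; "
            "not a trial of this task"
        )
    # p_right = 1 / (1 + L(-1)/L(+1)); exact 0.5 when the likelihoods tie
    with np.errstate(over="ignore"):
        p_right = float(1.0 / (1.0 + np.exp(ll_m[0] - ll_m[1])))
    return PosteriorResult(
        p_right=p_right,
        map_label=1 if p_right >= 0.5 else -1,
        n_configs=n_configs,
    )
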