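"""Signal-sparsity normalisation.

The generative task controls how often the target emits signal through the
per-step burst-start probability ``p_g``.  Comparing task variants (different
burst-length laws) is only fair if the expected fraction of emitting time
steps, ``p_e = P(E_t = 1 | not F)`` where ``F`` is the rejected all-silent
outcome, is held constant.  This module evaluates that emission fraction in
closed form for fixed-length and general (uniform / Levy) burst-length
distributions, and numerically inverts it to obtain ``p_g`` from a target
``p_e``.

Closed forms
------------
Fixed burst length ``k`` over a trial of ``n`` steps (burst starts are
sampled on the ``n + k - 1`` sites ``1-k+1 .. n``)::

    p_e = [1 - (1 - p_g)^k] / [1 - (1 - p_g)^(n+k-1)]

General burst-length pmf ``q_l`` on ``1..L_max`` with cdf ``Q_l = P(L < l)``::

    p_e = P(E_t = 1) / P(not F)
    P(E_t = 1) = 1 - prod_{l=1..L_max} (1 - p_g + p_g Q_l)
    P(F)       = (1 - p_g)^n * prod_{l=2..L_max} (1 - p_g + p_g Q_l)

The numerator is the standard per-step union over the ``L_max`` sites whose
burst could cover step ``t``.  The rejection probability ``P(F)`` factorises
over start *sites*, not over burst lengths: an in-trial site silences the
trial only if it hosts no start at all, while the pre-trial site ``1 - l + 1``
does so unless it hosts a start of length ``>= l + 1`` (one factor per
``l = 1 .. L_max - 1``).  A per-length factorisation
``prod_l (1 - p_g q_l)^(n+l-1)`` is sometimes quoted instead, but the
per-length events at a single site are mutually exclusive rather than
independent, and exhaustive enumeration over all hidden configurations at
tiny ``n`` confirms the site-wise form used here (the two coincide exactly
for a point-mass pmf).

Both maps are strictly increasing in ``p_g`` on (0, 1) for ``n >= 2``, so a
bracketing root finder inverts them reliably (at ``n = 1`` every surviving
trial emits everywhere and ``p_e`` is identically 1).  As ``p_g -> 0`` the
fixed-``k`` fraction tends to ``k / (n + k - 1)``; the general analogue is
``E[L] / (n + E[L] - 1)``.  Targets at or below this infimum are rejected as
infeasible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "InfeasibleSparsityError",
    "NormalizationResult",
    "pe_from_pg_fixed",
    "pe_from_pg_general",
    "min_pe_fixed",
    "min_pe_general",
    "solve_pg",
]


class InfeasibleSparsityError(ValueError):
    """Target emission fraction is at or below the infimum achievable."""


@dataclass(frozen=True)
class NormalizationResult:
    """Outcome of inverting the emission-fraction map."""

    p_g: float
    p_e_target: float
    p_e_achieved: float
    p_e_min: float
    iterations: int


def _check_pg(p_g: float) -> None:
    if not 0.0 <= p_g < 1.0:
        raise ValueError(f"p_g must lie in [0, 1); got {p_g}")


def pe_from_pg_fixed(p_g: float, k: int, n: int) -> float:
    """Emission fraction P(E_t=1 | not F) for fixed burst length ``k``.

    Evaluated as a ratio of ``-expm1(j * log1p(-p_g))`` terms so that small
    ``p_g`` and large ``n`` do not underflow.  ``p_g = 0`` returns the limit
    ``k / (n + k - 1)``.
    """
    if k < 1 or n < 1:
        raise ValueError("k and n must be positive integers")
    _check_pg(p_g)
    if p_g == 0.0:
        return k / (n + k - 1)
    log1m = np.log1p(-p_g)
    num = -np.expm1(k * log1m)
    den = -np.expm1((n + k - 1) * log1m)
    return float(num / den)


def _validate_pmf(pmf: np.ndarray) -> np.ndarray:
    pmf = np.asarray(pmf, dtype=float)
    if pmf.ndim != 1 or pmf.size < 1:
        raise ValueError("pmf must be a non-empty 1-d probability vector")
    if np.any(pmf < 0):
        raise ValueError("pmf has negative mass")
    if abs(pmf.sum() - 1.0) > 1e-12:
        raise ValueError(f"pmf sums to {pmf.sum()}, not 1")
    return pmf


def pe_from_pg_general(p_g: float, burst_model, n: int) -> float:
    """Emission fraction for an arbitrary burst-length pmf on ``1..L_max``.

    ``burst_model`` is anything with a ``pmf`` attribute (or a bare pmf
    array).  Reduces exactly to :func:`pe_from_pg_fixed` when the pmf is a
    point mass.
    """
    pmf = _validate_pmf(getattr(burst_model, "pmf", burst_model))
    if n < 1:
        raise ValueError("n must be positive")
    _check_pg(p_g)
    l_max = pmf.size
    ells = np.arange(1, l_max + 1)
    if p_g == 0.0:
        mean_l = float(ells @ pmf)
        return mean_l / (n + mean_l - 1)
    # Q_l = P(L < l), exclusive cdf
    q_excl = np.concatenate([[0.0], np.cumsum(pmf)[:-1]])
    # numerator: P(E_t = 1) = 1 - prod_l (1 - p_g (1 - Q_l))
    site_logs = np.log1p(-p_g * (1.0 - q_excl))  # one factor per offset l
    num = -np.expm1(np.sum(site_logs))
    # P(F): n in-trial sites host no start; pre-trial site 1-l+1 hosts no
    # start of length > l, i.e. the same factor at offset l+1
    log_pf = n * np.log1p(-p_g) + np.sum(site_logs[1:])
    den = -np.expm1(log_pf)
    return float(num / den)


def min_pe_fixed(k: int, n: int) -> float:
    """Infimum of the achievable emission fraction: ``k / (n + k - 1)``."""
    if k < 1 or n < 1:
        raise ValueError("k and n must be positive integers")
    return k / (n + k - 1)


def min_pe_general(burst_model, n: int) -> float:
    """Infimum emission fraction for a general burst-length pmf."""
    pmf = _validate_pmf(getattr(burst_model, "pmf", burst_model))
    mean_l = float(np.arange(1, pmf.size + 1) @ pmf)
    return mean_l / (n + mean_l - 1)


def solve_pg(
    p_e_target: float,
    burst_model,
    n: int,
    tol: float = 1e-10,
) -> NormalizationResult:
    """Invert the emission-fraction map: find ``p_g`` giving ``p_e_target``.

    Parameters
    ----------
    p_e_target
        Desired emission fraction, strictly between the model's infimum and 1.
    burst_model
        Burst-length model (anything with a ``pmf`` attribute, or a pmf).
    n
        Trial length in time steps.
    tol
        Absolute tolerance on the achieved ``p_e``.

    Raises
    ------
    InfeasibleSparsityError
        If ``p_e_target`` is at or below the infimum achievable fraction.
    """
    pmf = _validate_pmf(getattr(burst_model, "pmf", burst_model))
    p_e_min = min_pe_general(pmf, n)
    if not p_e_min < p_e_target < 1.0:
        raise InfeasibleSparsityError(
            f"p_e target {p_e_target} is infeasible: the smallest achievable "
            f"emission fraction for this burst model at n={n} is {p_e_min:.6g} "
            f"(fixed-k form: k/(n+k-1))"
        )

    def objective(p_g: float) -> float:
        return pe_from_pg_general(p_g, pmf, n) - p_e_target

    eps = 1e-15
    # forward map is strictly increasing, so (eps, 1-eps) brackets the root
    root, info = brentq(
        objective, eps, 1.0 - eps, xtol=1e-16, rtol=8.9e-16, full_output=True
    )
    achieved = pe_from_pg_general(root, pmf, n)
    if abs(achieved - p_e_target) > tol:
        raise RuntimeError(
            f"root find converged to p_g={root} but |p_e - target| = "
            f"{abs(achieved - p_e_target):.3g} exceeds tol={tol}"
        )
    return NormalizationResult(
        p_g=float(root),
        p_e_target=float(p_e_target),
        p_e_achieved=float(achieved),
        p_e_min=float(p_e_min),
        iterations=int(info.iterations),
    )
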