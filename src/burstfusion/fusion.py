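"""Count-feature fusion classifiers: LF, NLF and sliding-window NLF_w.

All three reduce a trial's ``n_channels x n`` trinary observation grid to a
vector of occurrence counts and classify the target direction with logistic
regression on those counts:

* **LF** (linear fusion) counts, per channel, how often each observation
  value {-1, 0, +1} occurs — marginal statistics, blind to both cross-channel
  and temporal structure.  ``3 * N_c`` features.
* **NLF** (nonlinear fusion) counts joint per-timestep patterns across
  channels — ``3 ** N_c`` features, still order-free in time.
* **NLF_w** counts joint patterns over sliding windows of ``w`` consecutive
  steps — ``3 ** (w * N_c)`` features; the only member of the family that
  sees temporal order.  NLF is exactly NLF_1.

Because the logistic decision is linear in the counts, the fitted
coefficients can be read as per-pattern log-likelihood contributions, and
summing them over windows is the model's evidence-accumulation step.

Pattern order (frozen for serialisation): a window is the ``(N_c, w)``
sub-grid flattened row-major — channel 1's ``w`` values, then channel 2's,
and so on — and patterns are enumerated lexicographically in that flattened
tuple from all-(-1) to all-(+1).  For ``N_c = 2, w = 2`` the 81 patterns run
(-1,-1,-1,-1), (-1,-1,-1,0), ..., (1,1,1,1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse as sp
from sklearn.linear_model import LogisticRegression

__all__ = [
    "PatternTable",
    "enumerate_patterns",
    "count_window_features",
    "count_features_batch",
    "lf_features",
    "lf_features_batch",
    "FusionClassifier",
    "fit_classifier",
]

DEFAULT_PATTERN_CAP = 3**10


@dataclass(frozen=True)
class PatternTable:
    """Enumeration of all ``w``-step, ``n_channels``-channel observation patterns."""

    n_channels: int
    w: int

    @property
    def n_digits(self) -> int:
        return self.n_channels * self.w

    @property
    def size(self) -> int:
        return 3**self.n_digits

    @property
    def patterns(self) -> np.ndarray:
        """``(size, n_digits)`` array of pattern tuples, values in {-1, 0, +1}."""
        d = self.n_digits
        idx = np.arange(self.size)
        digits = (idx[:, None] // 3 ** np.arange(d - 1, -1, -1)[None, :]) % 3
        return (digits - 1).astype(np.int8)

    def index_of(self, pattern: Sequence[int]) -> int:
        """Index of a flattened pattern tuple (channel-1 window, channel-2 window, ...)."""
        pattern = np.asarray(pattern, dtype=np.int64)
        if pattern.shape != (self.n_digits,):
            raise ValueError(f"pattern must have {self.n_digits} entries")
        if np.any(np.abs(pattern) > 1):
            raise ValueError("pattern values must lie in {-1, 0, +1}")
        weights = 3 ** np.arange(self.n_digits - 1, -1, -1)
        return int((pattern + 1) @ weights)


def enumerate_patterns(
    n_channels: int, w: int, cap: int = DEFAULT_PATTERN_CAP
) -> PatternTable:
    """Enumerate all ``3**(w * n_channels)`` window patterns.

    Raises if the table would exceed ``cap`` entries (default ``3**10``):
    the family's cost grows exponentially in ``w * n_channels``.
    """
    if n_channels < 1 or w < 1:
        raise ValueError("n_channels and w must be positive integers")
    size = 3 ** (n_channels * w)
    if size > cap:
        raise ValueError(
            f"pattern table with 3**{n_channels * w} = {size} entries exceeds cap {cap}"
        )
    return PatternTable(n_channels=n_channels, w=w)


def _window_codes(x_batch: np.ndarray, table: PatternTable) -> np.ndarray:
    """Base-3 pattern index of every sliding window; shape (T, n - w + 1)."""
    t_batch, n_channels, n = x_batch.shape
    w = table.w
    if n_channels != table.n_channels:
        raise ValueError("channel count does not match the pattern table")
    if n < w:
        raise ValueError(f"trial length {n} is shorter than the window {w}")
    n_win = n - w + 1
    d = table.n_digits
    codes = np.zeros((t_batch, n_win), dtype=np.int64)
    for i in range(n_channels):
        for tau in range(w):
            weight = 3 ** (d - 1 - (i * w + tau))
            codes += weight * (x_batch[:, i, tau : tau + n_win].astype(np.int64) + 1)
    return codes


def count_window_features(x: np.ndarray, table: PatternTable) -> np.ndarray:
    """Sliding-window pattern counts for one trial.

    Every window ``[t .. t+w-1]`` for ``t = 1 .. n-w+1`` contributes one
    count, so the counts sum to ``n - w + 1``.
    """
    x = np.asarray(x)
    if x.ndim != 2:
        raise ValueError("x must be an (n_channels, n) observation grid")
    codes = _window_codes(x[None, :, :], table)[0]
    return np.bincount(codes, minlength=table.size).astype(np.int64)


def count_features_batch(
    x_batch: np.ndarray, table: PatternTable, sparse: bool = False
):
    """Pattern-count feature matrix ``(T, table.size)`` for a trial batch."""
    x_batch = np.asarray(x_batch)
    codes = _window_codes(x_batch, table)
    t_batch = x_batch.shape[0]
    if sparse:
        data = np.ones(codes.size, dtype=np.float64)
        rows = np.repeat(np.arange(t_batch), codes.shape[1])
        mat = sp.csr_matrix(
            (data, (rows, codes.ravel())), shape=(t_batch, table.size)
        )
        mat.sum_duplicates()
        return mat
    flat = np.arange(t_batch)[:, None] * table.size + codes
    counts = np.bincount(flat.ravel(), minlength=t_batch * table.size)
    return counts.reshape(t_batch, table.size).astype(np.int64)


def lf_features(x: np.ndarray) -> np.ndarray:
    """Per-channel value counts, channel-major: (c1: -1,0,+1, c2: -1,0,+1, ...)."""
    x = np.asarray(x)
    if x.ndim != 2:
        raise ValueError("x must be an (n_channels, n) observation grid")
    return lf_features_batch(x[None, :, :])[0]


def lf_features_batch(x_batch: np.ndarray) -> np.ndarray:
    x_batch = np.asarray(x_batch)
    t_batch, n_channels, _ = x_batch.shape
    feats = np.empty((t_batch, 3 * n_channels), dtype=np.int64)
    for i in range(n_channels):
        for j, value in enumerate((-1, 0, 1)):
            feats[:, 3 * i + j] = (x_batch[:, i, :] == value).sum(axis=1)
    return feats


class FusionClassifier:
    """Logistic classifier over count features with a uniform predict contract.

    Parameters
    ----------
    model_kind : {"lf", "nlf", "nlf_w"}
        Feature family.  ``nlf`` is ``nlf_w`` with ``w = 1``.
    w : int
        Window length (``nlf_w`` only).
    C : float
        Inverse L2 regularisation strength.  Kept large (weak penalty) so
        that large-sample coefficient differences track pattern
        log-likelihood ratios.
    """

    def __init__(
        self,
        model_kind: str = "nlf",
        n_channels: int = 2,
        w: int = 1,
        C: float = 100.0,
        max_iter: int = 2000,
        pattern_cap: int = DEFAULT_PATTERN_CAP,
    ) -> None:
        if model_kind not in ("lf", "nlf", "nlf_w"):
            raise ValueError(f"unknown model_kind {model_kind!r}")
        if model_kind == "nlf":
            w = 1
        if w < 1:
            raise ValueError("w must be >= 1")
        self.model_kind = model_kind
        self.n_channels = n_channels
        self.w = w
        self.C = C
        self.max_iter = max_iter
        self.table = (
            None
            if model_kind == "lf"
            else enumerate_patterns(n_channels, w, cap=pattern_cap)
        )
        self._lr: LogisticRegression | None = None
        self.training_config: dict | None = None

    # -- features -----------------------------------------------------------
    def features(self, x_batch: np.ndarray, sparse: bool | None = None) -> np.ndarray:
        x_batch = np.asarray(x_batch)
        if x_batch.ndim == 2:
            x_batch = x_batch[None, :, :]
        if x_batch.shape[1] != self.n_channels:
            raise ValueError(
                f"expected {self.n_channels} channels, got {x_batch.shape[1]}"
            )
        if self.model_kind == "lf":
            return lf_features_batch(x_batch)
        if sparse is None:
            sparse = self.table.size > 3**7
        return count_features_batch(x_batch, self.table, sparse=sparse)

    # -- fitting ------------------------------------------------------------
    def fit(self, x_batch: np.ndarray, labels: np.ndarray) -> "FusionClassifier":
        labels = np.asarray(labels)
        classes = np.unique(labels)
        if not np.array_equal(classes, [-1, 1]):
            if classes.size < 2:
                raise ValueError("training batch contains a single class")
            raise ValueError("labels must take values in {-1, +1}")
        feats = self.features(x_batch)
        self._lr = LogisticRegression(
            C=self.C, solver="lbfgs", max_iter=self.max_iter
        )
        self._lr.fit(feats, labels)
        self.training_config = {
            "model_kind": self.model_kind,
            "w": self.w,
            "n_trials": int(labels.size),
            "C": self.C,
        }
        return self

    @property
    def n_parameters(self) -> int:
        """Learnable coefficients, excluding the intercept."""
        self._require_fitted()
        return int(self._lr.coef_.size)

    @property
    def coefficients(self) -> np.ndarray:
        self._require_fitted()
        return self._lr.coef_.ravel()

    @property
    def intercept(self) -> float:
        self._require_fitted()
        return float(self._lr.intercept_[0])

    def _require_fitted(self) -> None:
        if self._lr is None:
            raise RuntimeError("classifier has not been fitted")

    # -- prediction ---------------------------------------------------------
    def predict_proba(self, x_batch: np.ndarray) -> np.ndarray:
        """Estimated P(M = +1 | X) for each trial."""
        self._require_fitted()
        feats = self.features(x_batch)
        col = int(np.flatnonzero(self._lr.classes_ == 1)[0])
        return self._lr.predict_proba(feats)[:, col]

    def predict(self, x_batch: np.ndarray) -> np.ndarray:
        """Direction labels in {-1, +1}; a score of exactly 0.5 maps to +1."""
        proba = self.predict_proba(x_batch)
        return np.where(proba >= 0.5, 1, -1).astype(np.int64)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        self._require_fitted()
        return {
            "model_kind": self.model_kind,
            "n_channels": self.n_channels,
            "w": self.w,
            "C": self.C,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "classes": self._lr.classes_.tolist(),
            "training_config": self.training_config,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FusionClassifier":
        clf = cls(
            model_kind=payload["model_kind"],
            n_channels=payload["n_channels"],
            w=payload["w"],
            C=payload["C"],
        )
        lr = LogisticRegression(C=payload["C"], solver="lbfgs")
        lr.classes_ = np.asarray(payload["classes"])
        lr.coef_ = np.asarray(payload["coefficients"], dtype=float)[None, :]
        lr.intercept_ = np.asarray([payload["intercept"]])
        clf._lr = lr
        clf.training_config = payload.get("training_config")
        return clf


def fit_classifier(
    x_batch: np.ndarray,
    labels: np.ndarray,
    model_kind: str,
    w: int = 1,
    **hyper,
) -> FusionClassifier:
    """Convenience wrapper: build and fit a :class:`FusionClassifier`."""
    x_batch = np.asarray(x_batch)
    clf = FusionClassifier(
        model_kind=model_kind, n_channels=x_batch.shape[1], w=w, **hyper
    )
    return clf.fit(x_batch, labels)
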