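"""Pearson correlation, discretisation and mutual information.

Two expression profiles X and Y over the same N samples are compared in two
ways.  The Pearson coefficient r measures linear correlation.  Mutual
information I(X, Y) = H(X) + H(Y) - H(X, Y), in bits, measures dependency of
any shape: the value range of each profile is partitioned into M intervals,
per-interval relative frequencies k_i/N stand in for probabilities, and the
plug-in entropies are combined.  Equivalently, over the joint occupancy
counts k_ij,

    I = log2 N + (1/N) * sum_ij k_ij * log2(k_ij / (k_i * k_j)),

which is the form implemented here (base-2 logs throughout; 0*log2(0) = 0).

Two partition modes are provided.  Fixed-interval binning cuts the range
into M equal-width intervals (half-open, the last closed on the right).
Adaptive binning is equal-frequency: boundaries sit at empirical quantiles
so each interval holds approximately N/M points, which tempers the
overestimation the fixed plug-in estimator suffers on finite samples.  The
package default is M = 11 adaptive intervals, capping I at log2(11) ~ 3.459
bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy import stats

from .errors import (
    DegenerateInputError,
    InsufficientSamplesError,
    InvalidBinningError,
    InvalidValueError,
    LengthMismatchError,
    OutOfRangeError,
    ZeroVarianceError,
)

__all__ = [
    "BinningScheme",
    "BinningConfig",
    "JointCountTable",
    "pearson_r",
    "fixed_interval_bins",
    "adaptive_bins",
    "entropy",
    "joint_counts",
    "mutual_information",
    "mi_adaptive",
    "DEFAULT_ADAPTIVE_BINS",
]

#: Default number of adaptive (equal-frequency) intervals per profile.
DEFAULT_ADAPTIVE_BINS = 11

# MI within -_MI_ZERO_TOL of zero is reported as exactly 0.
_MI_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class BinningScheme:
    """A partition of one profile's value range plus per-sample labels.

    ``boundaries`` are M+1 increasing reals covering the observed range;
    interval i is ``[boundaries[i], boundaries[i+1])``, the last interval
    closed on the right.  ``labels[s]`` is the interval index of sample s.
    """

    boundaries: np.ndarray
    labels: np.ndarray
    mode: str  # "fixed" | "adaptive"

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) - 1

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def counts(self) -> np.ndarray:
        """Per-bin occupancy k_i (sums to N)."""
        return np.bincount(self.labels, minlength=self.n_bins)


@dataclass(frozen=True)
class JointCountTable:
    """M_X x M_Y joint occupancy counts k_ij over N shared samples."""

    counts: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def _as_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise InvalidValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(v)):
        raise InvalidValueError(f"{name} contains non-finite values")
    return v


def pearson_r(x, y) -> float:
    """Pearson correlation coefficient of two equal-length profiles.

    Raises :class:`ZeroVarianceError` for a constant input — the
    coefficient is undefined there, and silently returning 0 would conflate
    "no linear trend" with "no information".
    """
    xv, yv = _as_vector(x, "x"), _as_vector(y, "y")
    if xv.size != yv.size:
        raise LengthMismatchError(f"length mismatch: {xv.size} vs {yv.size}")
    if xv.size < 2:
        raise InvalidValueError("need at least 2 samples for a correlation")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ZeroVarianceError("correlation undefined for a constant profile")
    return float(stats.pearsonr(xv, yv).statistic)


def fixed_interval_bins(values, n_bins: int, range_low: float | None = None,
                        range_high: float | None = None) -> BinningScheme:
    """Partition into ``n_bins`` equal-width intervals over a fixed range.

    The range defaults to the observed [min, max].  Intervals are half-open
    ``[low, high)`` except the last, which includes the right edge.  Values
    outside the range are an error, not a clamp.
    """
    v = _as_vector(values, "values")
    if n_bins < 2:
        raise InvalidBinningError(f"need at least 2 bins, got {n_bins}")
    lo = float(v.min()) if range_low is None else float(range_low)
    hi = float(v.max()) if range_high is None else float(range_high)
    if not lo < hi:
        raise InvalidBinningError(f"empty range [{lo}, {hi}]")
    if np.any(v < lo) or np.any(v > hi):
        raise OutOfRangeError(f"values outside the declared range [{lo}, {hi}]")
    boundaries = np.linspace(lo, hi, n_bins + 1)
    labels = np.minimum(
        np.searchsorted(boundaries, v, side="right") - 1, n_bins - 1
    ).astype(np.intp)
    return BinningScheme(boundaries=boundaries, labels=labels, mode="fixed")


def adaptive_bins(values, n_bins: int = DEFAULT_ADAPTIVE_BINS) -> BinningScheme:
    """Equal-frequency partition: each interval holds ~N/M points.

    Boundaries sit at the empirical quantile positions ceil(i*N/M); if a
    boundary would split a run of tied values, the lower interval absorbs
    the whole run, so every interval remains a genuine sub-interval of the
    value range.  Profiles with fewer than ``n_bins`` distinct values (or
    ties so heavy that intervals would collapse) are rejected with
    :class:`DegenerateInputError` — silently merging bins would change the
    value range of every downstream rank statistic.
    """
    v = _as_vector(values, "values")
    n = v.size
    if n_bins < 2:
        raise InvalidBinningError(f"need at least 2 bins, got {n_bins}")
    if n < n_bins:
        raise InsufficientSamplesError(f"{n} samples cannot fill {n_bins} bins")
    s = np.sort(v)
    if len(np.unique(s)) < n_bins:
        raise DegenerateInputError(
            f"only {len(np.unique(s))} distinct values for {n_bins} bins"
        )
    cuts = []
    for i in range(1, n_bins):
        c = ceil(i * n / n_bins)
        while c < n and s[c - 1] == s[c]:  # absorb tie run into the lower bin
            c += 1
        cuts.append(c)
    if len(set(cuts)) != n_bins - 1 or cuts[-1] >= n:
        raise DegenerateInputError("ties collapse adjacent bins; lower n_bins")
    interior = np.array([(s[c - 1] + s[c]) / 2.0 for c in cuts])
    boundaries = np.concatenate(([s[0]], interior, [s[-1]]))
    labels = np.searchsorted(interior, v, side="right").astype(np.intp)
    return BinningScheme(boundaries=boundaries, labels=labels, mode="adaptive")


def entropy(scheme: BinningScheme) -> float:
    """Plug-in entropy H = -sum_i (k_i/N) log2(k_i/N), in bits.

    Empty bins contribute nothing (the 0*log2(0) = 0 convention); H is 0
    when one bin holds every point and log2(M) when all bins are equally
    occupied.
    """
    k = scheme.counts
    p = k[k > 0] / scheme.n_samples
    h = float(-(p * np.log2(p)).sum())
    return 0.0 if abs(h) < _MI_ZERO_TOL else h


def joint_counts(scheme_x: BinningScheme, scheme_y: BinningScheme) -> JointCountTable:
    """Joint occupancy table k_ij from two schemes over the same samples."""
    if scheme_x.n_samples != scheme_y.n_samples:
        raise LengthMismatchError(
            f"schemes cover {scheme_x.n_samples} vs {scheme_y.n_samples} samples"
        )
    mx, my = scheme_x.n_bins, scheme_y.n_bins
    flat = scheme_x.labels * my + scheme_y.labels
    counts = np.bincount(flat, minlength=mx * my).reshape(mx, my)
    return JointCountTable(counts=counts)


def mutual_information(table: JointCountTable) -> float:
    """Mutual information in bits from a joint count table.

    I = log2 N + (1/N) sum_ij k_ij log2(k_ij/(k_i k_j)); identical to
    H(X) + H(Y) - H(X, Y) on the same counts.  Nonnegative; tiny negative
    rounding residue is clamped to exactly 0.
    """
    k = table.counts
    n = table.n
    if n < 1:
        raise InvalidValueError("joint table is empty")
    ki = table.row_marginals
    kj = table.col_marginals
    nz = k > 0
    prod = np.outer(ki, kj)[nz].astype(float)
    i = float(np.log2(n) + (k[nz] * np.log2(k[nz] / prod)).sum() / n)
    if i < 0:
        if i < -_MI_ZERO_TOL * max(1.0, abs(np.log2(n))):
            # genuinely negative would mean a corrupt table
            raise InvalidValueError(f"negative mutual information {i}")
        i = 0.0
    return i


def mi_adaptive(x, y, n_bins: int = DEFAULT_ADAPTIVE_BINS) -> float:
    """Mutual information of two profiles under equal-frequency binning.

    The production estimator: ``n_bins`` adaptive intervals per axis
    (default 11), joint counts, plug-in MI.  Bounded by log2(n_bins).
    """
    sx = adaptive_bins(x, n_bins)
    sy = adaptive_bins(y, n_bins)
    return mutual_information(joint_counts(sx, sy))


@dataclass(frozen=True)
class BinningConfig:
    """Discretisation choice for MI: ``adaptive:M`` or ``fixed:M[:lo:hi]``."""

    mode: str = "adaptive"
    n_bins: int = DEFAULT_ADAPTIVE_BINS
    range_low: float | None = None
    range_high: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("adaptive", "fixed"):
            raise InvalidBinningError(f"unknown binning mode {self.mode!r}")
        if self.n_bins < 2:
            raise InvalidBinningError(f"need at least 2 bins, got {self.n_bins}")

    def bins(self, values) -> BinningScheme:
        if self.mode == "adaptive":
            return adaptive_bins(values, self.n_bins)
        return fixed_interval_bins(values, self.n_bins, self.range_low, self.range_high)

    def mi(self, x, y) -> float:
        return mutual_information(joint_counts(self.bins(x), self.bins(y)))

    @property
    def mi_cap(self) -> float:
        """Theoretical upper bound log2(M) on MI under this configuration."""
        return float(np.log2(self.n_bins))

    @classmethod
    def from_string(cls, text: str) -> "BinningConfig":
        """Parse ``adaptive:M`` or ``fixed:M:lo:hi`` (lo/hi optional)."""
        parts = text.split(":")
        try:
            if parts[0] == "adaptive" and len(parts) == 2:
                return cls(mode="adaptive", n_bins=int(parts[1]))
            if parts[0] == "fixed" and len(parts) in (2, 4):
                lo, hi = (float(parts[2]), float(parts[3])) if len(parts) == 4 else (None, None)
                return cls(mode="fixed", n_bins=int(parts[1]), range_low=lo, range_high=hi)
        except ValueError as e:
            raise InvalidBinningError(f"cannot parse binning string {text!r}: {e}") from e
        raise InvalidBinningError(
            f"cannot parse binning string {text!r}; expected adaptive:M or fixed:M[:lo:hi]"
        )

    def __str__(self) -> str:
        if self.mode == "adaptive":
            return f"adaptive:{self.n_bins}"
        if self.range_low is None:
            return f"fixed:{self.n_bins}"
        return f"fixed:{self.n_bins}:{self.range_low:g}:{self.range_high:g}"
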