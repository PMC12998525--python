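"""Knee-point detection on ranked contact-count distributions.

Enhancer-promoter contact counts, sorted in descending order, follow an
approximately exponential rank profile. The "highly interactive"
threshold is the knee of that curve, found by the distance-to-chord
method: fit ``value = a * exp(-b * rank)`` on log-values, normalize both
axes to their maxima, draw the chord between the first and last fitted
points, and take the rank whose fitted point lies farthest from the
chord. The observed count at that rank is the threshold; pairs with
counts >= the threshold are the highly interactive set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RankedDistribution", "KneeResult", "ExponentialFit", "fit_exponential", "knee_point"]


class NonDecayingError(ValueError):
    """Raised when a ranked distribution does not decay (fitted b <= 0)."""


@dataclass(frozen=True)
class RankedDistribution:
    """Positive values sorted in descending order with ranks 1..n."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) < 3:
            raise ValueError("need a 1-D distribution with at least 3 values")
        if (v <= 0).any():
            raise ValueError("all values must be positive (counts on a log-fit scale)")
        v = np.sort(v)[::-1]
        object.__setattr__(self, "values", v)

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, len(self.values) + 1)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ExponentialFit:
    """Least-squares fit of ``value ~ a * exp(-b * rank)`` on log-values."""

    a: float
    b: float

    @property
    def decaying(self) -> bool:
        return self.b > 0

    def __iter__(self):
        return iter((self.a, self.b))

    def predict(self, ranks: np.ndarray) -> np.ndarray:
        return self.a * np.exp(-self.b * np.asarray(ranks, dtype=float))


@dataclass(frozen=True)
class KneeResult:
    knee_rank: int
    knee_value: float
    fit_params: ExponentialFit
    max_chord_distance: float


def fit_exponential(dist: RankedDistribution) -> ExponentialFit:
    """Fit ``log(value) = log(a) - b * rank`` by ordinary least squares.

    A non-decaying fit (slope >= 0) is returned with ``b = 0`` and
    ``decaying=False``; :func:`knee_point` rejects such inputs.
    """
    log_v = np.log(dist.values)
    slope, intercept = np.polyfit(dist.ranks, log_v, deg=1)
    b = -slope
    if b <= 1e-10:  # non-decaying up to float noise on constant inputs
        return ExponentialFit(a=float(np.exp(intercept)), b=0.0)
    return ExponentialFit(a=float(np.exp(intercept)), b=float(b))


def knee_point(dist: RankedDistribution, distance: str = "perpendicular") -> KneeResult:
    """Locate the knee of a ranked distribution by distance-to-chord.

    Parameters
    ----------
    dist
        The descending contact-count distribution.
    distance
        ``"perpendicular"`` (default) measures perpendicular point-to-chord
        distance of the fitted curve; ``"vertical"`` measures the vertical
        gap between chord and fitted curve.

    Returns
    -------
    KneeResult
        ``knee_rank`` (1-based), ``knee_value`` = observed count at that
        rank (the threshold on the original count scale), the fit, and the
        maximal distance. Ties are broken toward the smallest rank, which
        retains more pairs above the threshold.
    """
    if distance not in ("perpendicular", "vertical"):
        raise ValueError(f"unknown distance mode {distance!r}")
    fit = fit_exponential(dist)
    if not fit.decaying:
        raise NonDecayingError(
            "ranked distribution does not decay (fitted rate b <= 0); "
            "no knee point exists"
        )
    n = len(dist)
    ranks = dist.ranks
    fitted = fit.predict(ranks)
    # normalized axes: ranks min-max scaled to [0, 1], values scaled to the
    # fitted maximum, so the chord always runs from (0, 1) to (1, y_min)
    x = (ranks - 1) / (n - 1)
    y = fitted / fitted.max()
    x0, y0 = x[0], y[0]
    x1, y1 = x[-1], y[-1]
    if distance == "perpendicular":
        chord_len = float(np.hypot(x1 - x0, y1 - y0))
        d = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0) / chord_len
    else:
        chord_y = y0 + (y1 - y0) * (x - x0) / (x1 - x0)
        d = chord_y - y
    idx = int(np.argmax(d))  # argmax returns the first (smallest-rank) maximum
    return KneeResult(
        knee_rank=idx + 1,
        knee_value=float(dist.values[idx]),
        fit_params=fit,
        max_chord_distance=float(d[idx]),
    )
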