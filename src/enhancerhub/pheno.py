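"""Phenotype scoring: Bliss-independence synergy and marker positivity.

Drug-combination synergy is read off confluency time courses: the
effect of a treatment is E = 1 - treated/control confluency (0 = no
effect, 1 = complete growth suppression), and the Bliss score of a
combination is

    E_combo - [E_a + E_b - E_a * E_b],

positive for synergy, zero for independence, negative for antagonism.

Marker positivity for multiplex-immunofluorescence tables is called on
log-transformed per-cell mean intensities via a two-component Gaussian
mixture: the threshold is the equal-posterior crossing between the two
component means, and cells at or above it are positive. Class-wise
co-positivity fractions (e.g. KLF5+ & Bcl-xL+ within classical
pan-CK+/HNF4A+/KRT5/6- cells) summarize coexpression per subtype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "ConfluencyCurve",
    "EffectValue",
    "GmmThreshold",
    "effect",
    "bliss_score",
    "gmm_threshold",
    "positivity_calls",
    "copositivity_fractions",
]


@dataclass(frozen=True)
class ConfluencyCurve:
    """A live-cell-imaging confluency time series for one condition."""

    condition: str
    timepoints: np.ndarray  # hours, strictly increasing
    confluency: np.ndarray  # percent, in [0, 100]

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        c = np.asarray(self.confluency, dtype=float)
        if len(t) != len(c):
            raise ValueError("timepoints and confluency lengths differ")
        if len(t) and (np.diff(t) <= 0).any():
            raise ValueError("timepoints must be strictly increasing")
        if len(c) and ((c < 0) | (c > 100)).any():
            raise ValueError("confluency must lie in [0, 100] percent")
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "confluency", c)

    def at(self, timepoint: float) -> float:
        idx = np.nonzero(np.isclose(self.timepoints, timepoint))[0]
        if not len(idx):
            raise ValueError(f"condition {self.condition!r} has no timepoint {timepoint}")
        return float(self.confluency[idx[0]])

    def auc(self, upto: float | None = None) -> float:
        """Trapezoidal area under the confluency curve."""
        t, c = self.timepoints, self.confluency
        if upto is not None:
            keep = t <= upto + 1e-9
            t, c = t[keep], c[keep]
        return float(np.trapezoid(c, t))


@dataclass(frozen=True)
class EffectValue:
    condition: str
    E: float

    def __post_init__(self) -> None:
        if self.E > 1:
            raise ValueError("effect cannot exceed 1 (treated confluency >= 0)")


def effect(
    treated: ConfluencyCurve,
    control: ConfluencyCurve,
    at: float | None = None,
    mode: str = "endpoint",
) -> EffectValue:
    """Treatment effect E = 1 - treated/control.

    By default compares confluency at `at` (last shared timepoint when
    omitted); ``mode="auc"`` compares trapezoidal AUCs up to that
    timepoint instead. Fails if the control value is zero.
    """
    if mode not in ("endpoint", "auc"):
        raise ValueError(f"unknown effect mode {mode!r}")
    if at is None:
        shared = np.intersect1d(treated.timepoints, control.timepoints)
        if not len(shared):
            raise ValueError("curves share no timepoint")
        at = float(shared.max())
    if mode == "endpoint":
        tr, co = treated.at(at), control.at(at)
    else:
        tr, co = treated.auc(upto=at), control.auc(upto=at)
    if co == 0:
        raise ValueError("control confluency is zero; effect undefined")
    return EffectValue(treated.condition, 1.0 - tr / co)


def _e(x) -> float:
    return x.E if isinstance(x, EffectValue) else float(x)


def bliss_score(E_combo, E_a, E_b) -> float:
    """Bliss synergy: E_combo - [E_a + E_b - E_a*E_b].

    Accepts floats or :class:`EffectValue`. Positive means synergy, zero
    independence, negative antagonism.
    """
    ea, eb, ec = _e(E_a), _e(E_b), _e(E_combo)
    return ec - (ea + eb - ea * eb)


# ---------------------------------------------------------------------------
# GMM marker positivity


@dataclass(frozen=True)
class GmmThreshold:
    """Equal-posterior threshold between the two mixture components (log scale)."""

    threshold: float
    means: tuple[float, float]  # low, high (log scale)
    sds: tuple[float, float]
    weights: tuple[float, float]
    unimodal: bool


def gmm_threshold(intensities: Iterable[float], seed: int = 0) -> GmmThreshold:
    """Positivity threshold from a 2-component GMM on log intensities.

    The mixture is fit with seeded EM initialized at the 25th/75th
    intensity quantiles; the threshold is the point between the component
    means where the posterior responsibilities are equal. Fits whose
    means are closer than the pooled component SD are flagged unimodal
    (the threshold is still returned but should be treated with caution).
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(list(intensities), dtype=float)
    if len(x) < 20:
        raise ValueError("need at least 20 intensities to fit a mixture")
    if (x <= 0).any():
        raise ValueError("intensities must be positive (log-transformable)")
    if len(np.unique(x)) < 2:
        raise ValueError("degenerate input: all intensities identical")
    log_x = np.log(x).reshape(-1, 1)
    means_init = np.quantile(log_x, [0.25, 0.75]).reshape(-1, 1)
    gmm = GaussianMixture(
        n_components=2, random_state=seed, means_init=means_init, n_init=1
    ).fit(log_x)
    order = np.argsort(gmm.means_.ravel())
    m = gmm.means_.ravel()[order]
    s = np.sqrt(gmm.covariances_.ravel()[order])
    w = gmm.weights_[order]

    def log_density_diff(t: float) -> float:
        z0 = np.log(w[0]) - np.log(s[0]) - 0.5 * ((t - m[0]) / s[0]) ** 2
        z1 = np.log(w[1]) - np.log(s[1]) - 0.5 * ((t - m[1]) / s[1]) ** 2
        return z0 - z1

    lo, hi = float(m[0]), float(m[1])
    if hi - lo < 1e-12:
        threshold = lo
    elif log_density_diff(lo) * log_density_diff(hi) < 0:
        threshold = float(brentq(log_density_diff, lo, hi, xtol=1e-12))
    else:  # no crossing strictly between the means (extreme weights)
        grid = np.linspace(lo, hi, 1001)
        threshold = float(grid[np.argmin(np.abs([log_density_diff(t) for t in grid]))])

    # Ashman's D: component separation in pooled-SD units; D < 2 means the
    # two fitted components do not describe a genuinely bimodal density
    ashman_d = (hi - lo) / np.sqrt((s[0] ** 2 + s[1] ** 2) / 2.0)
    unimodal = bool(ashman_d < 2.0)
    return GmmThreshold(
        threshold=threshold,
        means=(float(m[0]), float(m[1])),
        sds=(float(s[0]), float(s[1])),
        weights=(float(w[0]), float(w[1])),
        unimodal=unimodal,
    )


def positivity_calls(
    intensities: pd.DataFrame,
    thresholds: Mapping[str, float],
    loss_markers: Sequence[str] = (),
) -> pd.DataFrame:
    """Boolean positivity per cell and marker.

    `intensities` is cells x markers (positive mean intensities);
    positivity is log(intensity) >= threshold. Markers in `loss_markers`
    use <= semantics on the raw (already-normalized) value instead — the
    convention for calling marker *loss* against a fixed cutoff.
    """
    out = {}
    for marker, thr in thresholds.items():
        if marker not in intensities.columns:
            raise KeyError(f"marker {marker!r} absent from the intensity table")
        vals = intensities[marker].to_numpy(dtype=float)
        if marker in loss_markers:
            out[marker] = vals <= thr
        else:
            if (vals <= 0).any():
                raise ValueError(f"non-positive intensities for marker {marker!r}")
            out[marker] = np.log(vals) >= thr
    return pd.DataFrame(out, index=intensities.index)


def copositivity_fractions(
    calls: pd.DataFrame,
    classes: Mapping[str, Mapping[str, bool]],
    query_markers: Sequence[str],
) -> pd.DataFrame:
    """Fraction of cells positive for all query markers, per cell class.

    `calls` is cells x markers boolean; `classes` maps a class name to
    its defining marker requirements, e.g.
    ``{"classical": {"panCK": True, "HNF4A": True, "KRT5/6": False}}``.
    Empty classes get a missing fraction with n_cells = 0.
    """
    for marker in query_markers:
        if marker not in calls.columns:
            raise KeyError(f"query marker {marker!r} absent from the calls table")
    rows = []
    for cls_name, spec in classes.items():
        mask = np.ones(len(calls), dtype=bool)
        for marker, wanted in spec.items():
            if marker not in calls.columns:
                raise KeyError(f"class marker {marker!r} absent from the calls table")
            mask &= calls[marker].to_numpy(dtype=bool) == wanted
        n = int(mask.sum())
        if n == 0:
            frac = np.nan
        else:
            pos = np.ones(n, dtype=bool)
            for marker in query_markers:
                pos &= calls.loc[mask, marker].to_numpy(dtype=bool)
            frac = float(pos.mean())
        rows.append((cls_name, n, frac))
    return pd.DataFrame(rows, columns=["cls", "n_cells", "fraction"])
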