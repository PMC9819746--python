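"""Distribution statistics of orientation series.

Turns per-frame (Z, alpha, beta) series into the reported quantities:
probability histograms (1D and alpha/beta 2D), and uni-/bi-/trimodal Gaussian
mode fits summarised as median +- SD per mode (median = mean for a normal
component).  The number of modes k in {1, 2, 3} is chosen by minimal BIC;
modes with weight below 0.25 are flagged as low-population.

Rotation angles live on the circle: before mixture fitting they are shifted
so the +-180 cut falls in the middle of the longest empty arc of the angular
histogram, which makes a Gaussian description valid for clusters straddling
the cut.

Default bin widths (0.05 nm for Z, 2 deg for alpha, 4 deg for beta) resolve
the narrowest single-mode spreads seen in anchored three-finger proteins
(about 0.13 nm and 4-9 deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .orientation import wrap_angle

__all__ = [
    "Histogram1D", "Histogram2D", "GaussianMode", "ModeFitSet",
    "histogram", "histogram2d", "recenter_circular", "fit_modes", "pearson",
    "DEFAULT_BIN_WIDTHS", "LOW_POPULATION_WEIGHT",
]

DEFAULT_BIN_WIDTHS = {"Z": 0.05, "alpha": 2.0, "beta": 4.0}
LOW_POPULATION_WEIGHT = 0.25


@dataclass
class Histogram1D:
    """Probability histogram (probabilities sum to 1)."""

    edges: np.ndarray
    probabilities: np.ndarray
    label: str = ""
    circular: bool = False

    def __post_init__(self) -> None:
        if np.any(self.probabilities < 0):
            raise ValueError("negative probabilities")
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class Histogram2D:
    """Joint tilt/rotation probability histogram."""

    alpha_edges: np.ndarray
    beta_edges: np.ndarray
    probabilities: np.ndarray     # shape (n_alpha_bins, n_beta_bins)

    def argmax_cell(self) -> tuple[int, int]:
        """Indices of the most populated cell (the preferential orientation)."""
        return tuple(np.unravel_index(int(np.argmax(self.probabilities)),
                                      self.probabilities.shape))

    def argmax_center(self) -> tuple[float, float]:
        i, j = self.argmax_cell()
        return (float(0.5 * (self.alpha_edges[i] + self.alpha_edges[i + 1])),
                float(0.5 * (self.beta_edges[j] + self.beta_edges[j + 1])))


@dataclass
class GaussianMode:
    median: float      # mean of the Gaussian component (= its median)
    sd: float
    weight: float
    low_population: bool


@dataclass
class ModeFitSet:
    """Mixture fit of one observable; modes ordered by descending weight."""

    label: str
    modes: list[GaussianMode]
    k: int
    bic: dict[int, float]
    circular: bool = False
    recenter_offset: float = 0.0   # deg; 0 for linear observables

    def to_dict(self) -> dict:
        return {
            "label": self.label, "k": self.k,
            "bic": {str(k): v for k, v in self.bic.items()},
            "circular": self.circular, "recenter_offset_deg": self.recenter_offset,
            "modes": [
                {"median": m.median, "sd": m.sd, "weight": m.weight,
                 "low_population": m.low_population}
                for m in self.modes
            ],
        }


def histogram(series, bin_width: float, circular: bool = False,
              label: str = "", range_: tuple[float, float] | None = None
              ) -> Histogram1D:
    """Probability histogram with fixed bin width.

    Circular observables are wrapped and binned over (-180, 180].
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if circular:
        x = wrap_angle(x)
        lo, hi = -180.0, 180.0
    elif range_ is not None:
        lo, hi = range_
    else:
        lo, hi = float(x.min()), float(x.max())
        if lo == hi:
            lo, hi = lo - bin_width / 2, hi + bin_width / 2
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, edges = np.histogram(x, bins=edges)
    return Histogram1D(edges=edges, probabilities=counts / x.size,
                       label=label, circular=circular)


def histogram2d(alpha, beta, bins: tuple[int, int] = (90, 90)) -> Histogram2D:
    """Joint probability histogram of (alpha, beta), normalised to 1."""
    a = np.asarray(alpha, dtype=float)
    b = wrap_angle(np.asarray(beta, dtype=float))
    if a.shape != b.shape:
        raise ValueError("alpha and beta must have equal length")
    h, ae, be = np.histogram2d(a, b, bins=bins,
                               range=[[-90.0, 90.0], [-180.0, 180.0]])
    return Histogram2D(alpha_edges=ae, beta_edges=be, probabilities=h / a.size)


def recenter_circular(series, arc_bins: int = 360) -> tuple[np.ndarray, float]:
    """Move the angular cut into the longest empty arc of the data.

    The offset is the centre of the longest empty arc of the angular
    histogram; the returned values are re-expressed on the interval
    ``(offset - 360, offset]`` (``shifted = x - 360*(x > offset)``), so the
    data mass never straddles the cut and a plain Gaussian description
    becomes valid.  ``wrap_angle(shifted)`` restores the input exactly.
    Uniform data (no empty arc) are returned unchanged with offset 0.
    """
    x = wrap_angle(np.asarray(series, dtype=float))
    counts, _edges = np.histogram(x, bins=arc_bins, range=(-180.0, 180.0))
    if np.all(counts > 0):
        return x.copy(), 0.0
    # longest run of empty bins on the circle
    empty = counts == 0
    doubled = np.concatenate([empty, empty])
    best_len, best_start, run, start = 0, 0, 0, 0
    for i, e in enumerate(doubled):
        if e:
            if run == 0:
                start = i
            run += 1
            if run > best_len and start < arc_bins:
                best_len, best_start = run, start
        else:
            run = 0
    best_len = min(best_len, arc_bins)
    width = 360.0 / arc_bins
    offset = float(wrap_angle(-180.0 + (best_start + best_len / 2.0) * width))
    shifted = np.where(x > offset, x - 360.0, x)
    return shifted, offset


def fit_modes(series, max_modes: int = 3, seed: int = 0,
              circular: bool = False, label: str = "",
              n_init: int = 5) -> ModeFitSet:
    """Fit Gaussian mixtures with k = 1..max_modes and select k by BIC.

    Circular observables are recentered first; fitted means are wrapped back
    onto (-180, 180].  Modes are reported in descending weight order, with
    weight < 0.25 flagged low-population.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 30:
        raise ValueError(f"need at least 30 values to fit modes, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in series")
    if np.std(x) == 0:
        raise ValueError("zero-variance series: mode fit is degenerate")
    offset = 0.0
    if circular:
        x, offset = recenter_circular(x)
    X = x.reshape(-1, 1)
    bics: dict[int, float] = {}
    fits = {}
    for k in range(1, max_modes + 1):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=n_init, random_state=seed,
                             reg_covar=1e-8)
        gm.fit(X)
        bics[k] = float(gm.bic(X))
        fits[k] = gm
    k_best = min(bics, key=bics.get)
    gm = fits[k_best]
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.reshape(k_best))
    weights = gm.weights_
    order = np.argsort(-weights)
    modes = []
    for i in order:
        mean = float(means[i])
        if circular:
            mean = float(wrap_angle(mean))
        modes.append(GaussianMode(
            median=mean, sd=float(sds[i]), weight=float(weights[i]),
            low_population=bool(weights[i] < LOW_POPULATION_WEIGHT)))
    return ModeFitSet(label=label, modes=modes, k=k_best, bic=bics,
                      circular=circular, recenter_offset=offset)


def pearson(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate variance")
    return float(stats.pearsonr(x, y).statistic)
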