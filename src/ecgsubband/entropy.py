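"""Six entropy measures on real-valued sequences.

Shannon (wavelet-energy form), sample, permutation, dispersion, bubble and
slope entropy. Each measure is computed per wavelet sub-band in the
feature pipeline; here they are plain functions of a 1-D sequence plus an
``EntropyParams`` record.

Conventions (all deterministic, all recorded in output metadata):

* Shannon entropy uses the normalized squared coefficients as the
  probability distribution — the energy distribution over the sequence —
  optionally divided by ln N so the value lies in [0, 1]. A histogram
  estimator is available behind ``estimator="histogram"`` but is not the
  default.
* Sample entropy uses Chebyshev distance, tolerance r = r_factor * SD(x)
  (population SD), lag tau, self-matches excluded; both the m- and the
  (m+1)-point counts run over the first N - m*tau templates, so a strictly
  periodic sequence scores exactly 0.
* Ordinal patterns break ties by order of appearance (stable argsort).
* Dispersion entropy maps samples through the normal CDF fitted to the
  sequence mean/SD, then rounds c*u + 0.5 into 1..c classes.
* Bubble entropy is the normalized difference of Renyi-2 entropies of the
  bubble-sort swap-count distributions at embedding sizes m+1 and m.
* Slope entropy symbolizes consecutive differences into 5 classes with
  thresholds gamma (steep) and delta (flat) and takes the Shannon entropy
  of length-(m-1) symbol patterns.

Undefined cases (all-zero sequence for Shannon, no template matches for
sample entropy) raise typed errors so records can be dropped with a
logged reason instead of being silently imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import norm

from .errors import SignalTooShortError, UndefinedDistributionError, UndefinedEntropyError

logger = logging.getLogger("ecgsubband")

ENTROPY_NAMES = ("shannon", "sample", "permutation", "dispersion", "bubble", "slope")


@dataclass(frozen=True)
class EntropyParams:
    """Hyperparameters of the six entropy measures.

    Defaults follow each measure's originating literature: m=2, r=0.2*SD
    for sample entropy; ordinal order m=3 for permutation; m=2 with a=6
    classes for dispersion; m=8 for bubble; m=3 with gamma=1.0 (steep
    threshold, normalized-amplitude units per sample) and delta=1e-3
    (flatness threshold) for slope entropy.
    """

    m_sampen: int = 2
    r_factor: float = 0.2
    tau: int = 1
    m_perm: int = 3
    m_disp: int = 2
    n_classes: int = 6
    m_bubble: int = 8
    m_slope: int = 3
    slope_gamma: float = 1.0
    slope_delta: float = 1e-3
    normalize_shannon: bool = True
    normalize_perm: bool = True
    normalize_disp: bool = True
    normalize_slope: bool = True

    def __post_init__(self) -> None:
        for name in ("m_sampen", "m_perm", "m_disp", "m_bubble", "m_slope"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not self.r_factor > 0:
            raise ValueError("r_factor must be positive")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if not 0 <= self.slope_delta < self.slope_gamma:
            raise ValueError("need 0 <= slope_delta < slope_gamma")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class EntropyFeatures:
    shannon: float
    sample: float
    permutation: float
    dispersion: float
    bubble: float
    slope: float


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Delay-embedding matrix: rows (x[i], x[i+tau], ..., x[i+(m-1)tau])."""
    n = x.size - (m - 1) * tau
    if n < 1:
        raise SignalTooShortError(
            f"sequence of {x.size} too short for embedding m={m}, tau={tau}"
        )
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def _pattern_entropy(patterns: np.ndarray) -> float:
    """Shannon entropy (nats) of the empirical distribution of rows."""
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


# ---------------------------------------------------------------------------
# Shannon entropy (energy form)
# ---------------------------------------------------------------------------

def shannon_entropy(
    x: np.ndarray, normalize: bool = True, estimator: str = "energy", bins: int = 16
) -> float:
    """Shannon entropy of the energy distribution over the coefficients.

    p_i = x_i^2 / sum_j x_j^2; H = -sum p_i ln p_i, with zero-probability
    terms contributing 0; divided by ln(len(x)) when ``normalize``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise SignalTooShortError("Shannon entropy needs at least 2 samples")
    if estimator == "energy":
        e = x**2
        total = e.sum()
        if total == 0:
            raise UndefinedDistributionError("all-zero sequence: energy distribution undefined")
        p = e / total
    elif estimator == "histogram":
        counts, _ = np.histogram(x, bins=bins)
        p = counts / counts.sum()
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    p = p[p > 0]
    h = float(-np.sum(p * np.log(p)))
    if normalize:
        h /= math.log(x.size)
    return h


# ---------------------------------------------------------------------------
# Sample entropy
# ---------------------------------------------------------------------------

def sample_entropy(x: np.ndarray, p: EntropyParams = EntropyParams()) -> float:
    """SampEn = -ln(A/B), A and B the (m+1)- and m-point template match counts."""
    x = np.asarray(x, dtype=float)
    m, tau = p.m_sampen, p.tau
    if x.size < m * tau + 2:
        raise SignalTooShortError(
            f"sample entropy m={m}, tau={tau} needs at least {m * tau + 2} samples"
        )
    sd = float(np.std(x))
    if sd == 0:
        raise UndefinedEntropyError("constant sequence: tolerance r = 0 is degenerate")
    r = p.r_factor * sd
    emb = _embed(x, m + 1, tau)  # first N - m*tau templates, both sizes
    b = int(np.count_nonzero(pdist(emb[:, :m], metric="chebyshev") <= r))
    a = int(np.count_nonzero(pdist(emb, metric="chebyshev") <= r))
    if b == 0 or a == 0:
        raise UndefinedEntropyError(
            f"no template matches at r={r:.3g} (A={a}, B={b}); sample entropy undefined"
        )
    return float(-math.log(a / b))


# ---------------------------------------------------------------------------
# Permutation entropy
# ---------------------------------------------------------------------------

def permutation_entropy(
    x: np.ndarray, p: EntropyParams = EntropyParams(), normalize: bool | None = None
) -> float:
    """Shannon entropy of the ordinal-pattern distribution of embedded windows."""
    x = np.asarray(x, dtype=float)
    m, tau = p.m_perm, p.tau
    if x.size < m * tau + 1:
        raise SignalTooShortError(
            f"permutation entropy m={m}, tau={tau} needs at least {m * tau + 1} samples"
        )
    if normalize is None:
        normalize = p.normalize_perm
    patterns = np.argsort(_embed(x, m, tau), axis=1, kind="stable")
    h = _pattern_entropy(patterns)
    if normalize:
        h /= math.log(math.factorial(m))
    return h


# ---------------------------------------------------------------------------
# Dispersion entropy
# ---------------------------------------------------------------------------

def dispersion_classes(x: np.ndarray, n_classes: int) -> np.ndarray:
    """Map samples through the normal CDF (fitted mean/SD) into 1..n_classes."""
    mu, sd = float(np.mean(x)), float(np.std(x))
    y = norm.cdf(x, loc=mu, scale=sd)
    z = np.round(n_classes * y + 0.5)
    return np.clip(z, 1, n_classes).astype(int)


def dispersion_entropy(
    x: np.ndarray, p: EntropyParams = EntropyParams(), normalize: bool | None = None
) -> float:
    """Shannon entropy of normal-CDF dispersion patterns.

    A zero-variance input collapses to a single class; it returns 0 with a
    logged warning (all patterns identical) rather than raising, since the
    value is well defined in the limit.
    """
    x = np.asarray(x, dtype=float)
    m, tau, a = p.m_disp, p.tau, p.n_classes
    if x.size < m * tau + 1:
        raise SignalTooShortError(
            f"dispersion entropy m={m}, tau={tau} needs at least {m * tau + 1} samples"
        )
    if normalize is None:
        normalize = p.normalize_disp
    if np.std(x) == 0:
        logger.warning("dispersion entropy: zero-variance input, single class -> 0")
        return 0.0
    patterns = _embed(dispersion_classes(x, a).astype(float), m, tau)
    h = _pattern_entropy(patterns)
    if normalize:
        h /= m * math.log(a)
    return h


# ---------------------------------------------------------------------------
# Bubble entropy
# ---------------------------------------------------------------------------

def bubble_swap_counts(emb: np.ndarray) -> np.ndarray:
    """Bubble-sort swaps (= inversions, strict) to sort each row ascending."""
    m = emb.shape[1]
    counts = np.zeros(emb.shape[0], dtype=int)
    for i in range(m - 1):
        for j in range(i + 1, m):
            counts += emb[:, i] > emb[:, j]
    return counts


def _renyi2_swaps(x: np.ndarray, m: int, tau: int) -> float:
    swaps = bubble_swap_counts(_embed(x, m, tau))
    _, counts = np.unique(swaps, return_counts=True)
    p = counts / counts.sum()
    return float(-math.log(np.sum(p**2)))


def bubble_entropy(x: np.ndarray, p: EntropyParams = EntropyParams()) -> float:
    """Normalized Renyi-2 entropy growth of swap-count distributions, m -> m+1.

    bEn = (H_swaps(m+1) - H_swaps(m)) / log((m+1)/(m-1)); both monotone
    sequences give 0 (point swap-count distributions at both sizes).
    """
    x = np.asarray(x, dtype=float)
    m, tau = p.m_bubble, p.tau
    if x.size < (m + 1) * tau + 1:
        raise SignalTooShortError(
            f"bubble entropy m={m}, tau={tau} needs at least {(m + 1) * tau + 1} samples"
        )
    h_m = _renyi2_swaps(x, m, tau)
    h_m1 = _renyi2_swaps(x, m + 1, tau)
    return (h_m1 - h_m) / math.log((m + 1) / (m - 1))


# ---------------------------------------------------------------------------
# Slope entropy
# ---------------------------------------------------------------------------

def slope_symbols(x: np.ndarray, gamma: float, delta: float) -> np.ndarray:
    """Symbolize consecutive differences into {-2, -1, 0, +1, +2}.

    +2 for d > gamma, +1 for delta < d <= gamma, 0 for |d| <= delta,
    mirrored for negative slopes.
    """
    d = np.diff(np.asarray(x, dtype=float))
    return np.select(
        [d > gamma, d > delta, d >= -delta, d >= -gamma],
        [2, 1, 0, -1],
        default=-2,
    )


def slope_entropy(
    x: np.ndarray, p: EntropyParams = EntropyParams(), normalize: bool | None = None
) -> float:
    """Shannon entropy of length-(m-1) slope-symbol patterns.

    Normalization divides by ln(min(#windows, 5**(m-1))) — the largest
    entropy achievable given how many patterns the sequence can exhibit.
    """
    x = np.asarray(x, dtype=float)
    m = p.m_slope
    if x.size < m + 1:
        raise SignalTooShortError(f"slope entropy m={m} needs at least {m + 1} samples")
    if normalize is None:
        normalize = p.normalize_slope
    sym = slope_symbols(x, p.slope_gamma, p.slope_delta)
    patterns = _embed(sym.astype(float), m - 1, 1)
    h = _pattern_entropy(patterns)
    if normalize:
        denom = math.log(min(patterns.shape[0], 5 ** (m - 1)))
        h = h / denom if denom > 0 else 0.0
    return h


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

def entropy_features(x: np.ndarray, p: EntropyParams = EntropyParams()) -> EntropyFeatures:
    """All six measures of one sequence (raises on any undefined measure)."""
    return EntropyFeatures(
        shannon=shannon_entropy(x, normalize=p.normalize_shannon),
        sample=sample_entropy(x, p),
        permutation=permutation_entropy(x, p),
        dispersion=dispersion_entropy(x, p),
        bubble=bubble_entropy(x, p),
        slope=slope_entropy(x, p),
    )
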