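"""The probability image space Y = f_X(X).

Mapping observations through the model density produces a *univariate*
sample of density values y in [0, y_max]; the df over this space is a
distribution over level sets of f_X.  For a multivariate Gaussian the image
df is known in closed form: with C_n the Gaussian partition constant, the
Mahalanobis radius squared is chi-square with n degrees of freedom, and

    G(y) = P(f(X) <= y) = P(chi2_n >= t),   t = -2 log(y C_n),

which expands into the finite series implemented by :class:`GaussianImageDF`
(polynomial in t for even n, plus an erfc term for odd n).  The coefficient
table uses the unit-sphere surface area Omega_n = 2 pi^(n/2) / Gamma(n/2);
this is the constant that normalises G(1/C_n) = 1 (certified in the test
suite against the chi-square survival oracle and Monte Carlo).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc, gammaln

from .errors import DomainError, InsufficientDataError
from .models import DensityModel, log_density, modal_density, model_fingerprint

__all__ = [
    "ImageSample",
    "EmpiricalImageDF",
    "GaussianImageDF",
    "to_image",
    "empirical_df",
    "evaluate",
    "image_quantile",
    "gaussian_image_df",
]


@dataclass(frozen=True)
class ImageSample:
    """Density values y_i = f_X(x_i) together with the model's y_max."""

    values: np.ndarray
    y_max: float
    fingerprint: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size == 0:
            raise InsufficientDataError("image sample is empty")
        if np.any(v < 0) or np.any(v > self.y_max + 1e-12):
            raise DomainError("image values must lie in [0, y_max]")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EmpiricalImageDF:
    """Right-continuous empirical df over image values.

    Tail counting is *strict*: G_hat(u) = #{y_i < u} / N, matching the
    indicator I_{y_i < u} used to define the tail fraction N_u / N.
    """

    sorted_values: np.ndarray
    n: int

    def __post_init__(self) -> None:
        v = np.asarray(self.sorted_values, dtype=float).ravel()
        if v.size == 0:
            raise InsufficientDataError("empirical df needs at least one value")
        if np.any(np.diff(v) < 0):
            raise ValueError("sorted_values must be ascending")
        object.__setattr__(self, "sorted_values", v)
        object.__setattr__(self, "n", int(self.n))


def to_image(model: DensityModel, points: np.ndarray) -> ImageSample:
    """Map observations into image space; underflow clamps cleanly to 0."""
    with np.errstate(under="ignore"):
        values = np.exp(log_density(model, points))
    ymax = modal_density(model)
    values = np.minimum(values, ymax)  # guard fp noise at the mode
    return ImageSample(values, ymax, fingerprint=model_fingerprint(model))


def empirical_df(sample: ImageSample | np.ndarray) -> EmpiricalImageDF:
    values = sample.values if isinstance(sample, ImageSample) else np.asarray(sample, float)
    if values.size == 0:
        raise InsufficientDataError("cannot build an empirical df from no values")
    return EmpiricalImageDF(np.sort(values), values.size)


def evaluate(df: EmpiricalImageDF, u: float) -> float:
    """N_u / N with N_u = #{y_i < u} (strict)."""
    return float(np.searchsorted(df.sorted_values, u, side="left")) / df.n


def image_quantile(df: EmpiricalImageDF, q: float) -> float:
    """Smallest stored value whose empirical df reaches q (max value if none)."""
    if not 0.0 <= q <= 1.0:
        raise DomainError(f"quantile level must be in [0,1], got {q}")
    v = df.sorted_values
    # G_hat at each stored value, under strict counting (ties share a value)
    g = np.searchsorted(v, v, side="left") / df.n
    idx = int(np.searchsorted(g, q, side="left"))
    if idx >= v.size:
        return float(v[-1])
    return float(v[idx])


def _double_factorial(k: int) -> float:
    return float(math.prod(range(k, 0, -2))) if k > 0 else 1.0


@dataclass(frozen=True)
class GaussianImageDF:
    """Closed-form image-space df of an n-dimensional Gaussian.

    ``coefficients[k]`` is A_n^k multiplying t^(p-k-1) (even n = 2p) or
    t^(p-k-1/2) (odd n = 2p+1), with t = -2 log(y C_n).
    """

    dimension: int
    det_cov: float
    log_C: float = field(init=False)
    C_n: float = field(init=False)
    Omega_n: float = field(init=False)
    coefficients: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = int(self.dimension)
        if n < 1:
            raise DomainError("dimension must be >= 1")
        if self.det_cov <= 0:
            raise DomainError("det_cov must be positive")
        log_C = 0.5 * n * math.log(2 * math.pi) + 0.5 * math.log(self.det_cov)
        omega = 2.0 * math.pi ** (n / 2.0) / math.gamma(n / 2.0)
        p = n // 2
        sqrt_det = math.sqrt(self.det_cov)
        coeffs = np.empty(p)
        if n % 2 == 0:
            # A_{2p}^k = Omega_{2p} |S|^{1/2} 2^k (p-1)! / (p-1-k)!
            for k in range(p):
                coeffs[k] = (
                    omega * sqrt_det * 2.0**k * math.factorial(p - 1) / math.factorial(p - 1 - k)
                )
        else:
            # A_{2p+1}^k = C_{2p+1} sqrt(2/pi) / (2p-2k-1)!!
            # (equivalently Omega_{2p+1}-based; empty for p = 0, i.e. n = 1)
            for k in range(p):
                coeffs[k] = (
                    math.exp(log_C) * math.sqrt(2.0 / math.pi) / _double_factorial(2 * p - 2 * k - 1)
                )
        object.__setattr__(self, "dimension", n)
        object.__setattr__(self, "log_C", log_C)
        object.__setattr__(self, "C_n", math.exp(log_C))
        object.__setattr__(self, "Omega_n", omega)
        object.__setattr__(self, "coefficients", coeffs)

    def __call__(self, y) -> np.ndarray | float:
        scalar = np.isscalar(y)
        y = np.atleast_1d(np.asarray(y, dtype=float))
        ymax = 1.0 / self.C_n
        if np.any(y < -1e-12) or np.any(y > ymax * (1 + 1e-8)):
            raise DomainError("y outside [0, 1/C_n]")
        y = np.clip(y, 0.0, ymax)
        out = np.zeros_like(y)
        pos = y > 0.0
        if np.any(pos):
            log_yC = np.log(y[pos]) + self.log_C  # <= 0
            t = np.maximum(-2.0 * log_yC, 0.0)
            n, p = self.dimension, self.dimension // 2
            # series evaluated in the log domain: log term_k = log(y C_n / C_n
            # * A_k) + e_k log t, summed with logaddexp for tiny y
            acc = np.full(t.shape, -np.inf)
            with np.errstate(divide="ignore"):
                log_t = np.where(t > 0, np.log(t), -np.inf)
                for k in range(p):
                    expo = (p - k - 1) if n % 2 == 0 else (p - k - 0.5)
                    term = log_yC - self.log_C + math.log(self.coefficients[k])
                    term = term + (expo * log_t if expo != 0 else 0.0)
                    acc = np.logaddexp(acc, term)
            with np.errstate(under="ignore"):
                series = np.exp(acc)
            if n % 2 == 0:
                out[pos] = series
            else:
                out[pos] = series + erfc(np.sqrt(t / 2.0))
        return np.clip(out, 0.0, 1.0) if not scalar else float(np.clip(out[0], 0.0, 1.0))


_GDF_CACHE: dict[tuple[int, float], GaussianImageDF] = {}


def gaussian_image_df(n: int, det_cov: float, y) -> np.ndarray | float:
    """Closed-form G_Y(y) for an n-dimensional Gaussian with |Sigma|=det_cov."""
    key = (int(n), float(det_cov))
    gdf = _GDF_CACHE.get(key)
    if gdf is None:
        gdf = _GDF_CACHE.setdefault(key, GaussianImageDF(n, det_cov))
    return gdf(y)
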