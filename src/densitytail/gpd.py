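"""Generalised Pareto tail modelling in the probability image space.

Internal convention (``"internal-v1"``): the GPD df on a shortfall position
s >= 0 is

    G(s) = 1 - (1 + xi * s / beta)^(-1/xi)        (xi != 0)
         = 1 - exp(-s / beta)                      (xi  = 0)

with scale beta > 0, location fixed at 0, and compact support [0, -beta/xi]
when xi < 0.  Tail data are the image values y_i strictly below a low
threshold u; they enter the likelihood as shortfall depths s_i = u - y_i
(peaks-over-threshold for minima: the shortfall of the density value beneath
the threshold), so the support [0, u] corresponds to image values in [0, u]
with the boundary y = 0 at depth u.  This is the orientation under which the
GPD family is threshold-stable — refitting at a deeper threshold u' < u
leaves the shape invariant and moves the scale linearly, and an
exponentially-decaying image tail gives shape 0 at every threshold.
*Constrained* fits tie the support endpoint to the threshold, beta = -xi*u
(one free parameter, xi < 0, pinning the image-space boundary y = 0); *free*
fits estimate (xi, beta) jointly.  The scaled tail estimator anchors at the
empirical tail fraction: G_hat_Y(y) = (N_u / N) * (1 + xi (u-y)/beta)^(-1/xi),
so that G_hat_Y(u) = N_u / N exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .errors import (
    DimensionMismatchError,
    DomainError,
    FitConvergenceError,
    GridCoverageError,
    InsufficientDataError,
)
from .image import ImageSample, to_image
from .models import DensityModel, GaussianDensity, log_density, model_fingerprint

__all__ = [
    "GPDParams",
    "TailModel",
    "GridSpec",
    "ExtendedGPDField",
    "gpd_df",
    "gpd_pdf",
    "gpd_sf",
    "gpd_quantile",
    "fit_tail",
    "tail_df_estimate",
    "extended_gpd_gaussian",
    "extended_gpd_numeric",
    "save_tail_model",
    "load_tail_model",
]

_XI_ZERO = 1e-9  # |xi| below this uses the exponential branch
MIN_TAIL_SIZE = 30


@dataclass(frozen=True)
class GPDParams:
    """Shape xi, scale beta, location nu (fixed at 0 for novelty work)."""

    shape: float
    scale: float
    location: float = 0.0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise DomainError(f"GPD scale must be positive, got {self.scale}")

    @property
    def endpoint(self) -> float:
        """Upper support endpoint: -beta/xi for xi < 0, else +inf."""
        if self.shape < -_XI_ZERO:
            return -self.scale / self.shape
        return np.inf


def _as_s(s) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if np.any(s < -1e-12):
        raise DomainError("GPD is defined on shortfall positions s >= 0")
    return np.maximum(s, 0.0)


def gpd_sf(params: GPDParams, s) -> np.ndarray | float:
    """Survival 1 - G(s); saturates at 0 beyond a finite endpoint."""
    scalar = np.isscalar(s)
    s = _as_s(s)
    xi, beta = params.shape, params.scale
    if abs(xi) < _XI_ZERO:
        out = np.exp(-s / beta)
    else:
        z = 1.0 + xi * s / beta
        with np.errstate(divide="ignore", over="ignore", under="ignore"):
            out = np.where(z > 0, np.power(np.maximum(z, 1e-300), -1.0 / xi), 0.0)
    return float(out) if scalar and out.ndim == 0 else out


def gpd_df(params: GPDParams, s) -> np.ndarray | float:
    """G(s) = P(S <= s); 1 beyond the endpoint when xi < 0."""
    return 1.0 - gpd_sf(params, s)


def gpd_pdf(params: GPDParams, s) -> np.ndarray | float:
    scalar = np.isscalar(s)
    s = _as_s(s)
    xi, beta = params.shape, params.scale
    if abs(xi) < _XI_ZERO:
        out = np.exp(-s / beta) / beta
    else:
        z = 1.0 + xi * s / beta
        with np.errstate(divide="ignore", over="ignore", under="ignore"):
            out = np.where(z > 0, np.power(np.maximum(z, 1e-300), -1.0 / xi - 1.0) / beta, 0.0)
    return float(out) if scalar and out.ndim == 0 else out


def gpd_quantile(params: GPDParams, p) -> np.ndarray | float:
    """Exact inverse of ``gpd_df`` on (0, 1); p=1 maps to the endpoint."""
    scalar = np.isscalar(p)
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise DomainError("quantile level must be in [0, 1]")
    xi, beta = params.shape, params.scale
    with np.errstate(divide="ignore"):
        if abs(xi) < _XI_ZERO:
            out = -beta * np.log1p(-p)
        else:
            out = beta / xi * (np.power(1.0 - p, -xi) - 1.0)
    return float(out) if scalar and out.ndim == 0 else out


@dataclass(frozen=True)
class TailModel:
    """A fitted GPD over shortfalls beneath threshold u in image space."""

    threshold: float
    params: GPDParams
    tail_fraction: float
    n_tail: int
    se_shape: float
    se_scale: float
    mode: str
    se_method: str = "observed_information"
    fingerprint: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.tail_fraction <= 1.0:
            raise DomainError("tail_fraction must lie in (0, 1]")
        if self.mode not in ("constrained", "free"):
            raise DomainError(f"unknown fit mode {self.mode!r}")


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


def _negloglik(xi: float, beta: float, s: np.ndarray) -> float:
    n = s.size
    if beta <= 0:
        return np.inf
    if abs(xi) < _XI_ZERO:
        return n * np.log(beta) + float(np.sum(s)) / beta
    z = 1.0 + xi * s / beta
    if np.any(z <= 0):
        return np.inf
    return n * np.log(beta) + (1.0 + 1.0 / xi) * float(np.sum(np.log(z)))


def _fit_constrained(s: np.ndarray, u: float) -> tuple[GPDParams, float]:
    """One-parameter fit with the support endpoint pinned at u (beta=-xi*u)."""

    def nll(xi: float) -> float:
        v = _negloglik(xi, -xi * u, s)
        return v if np.isfinite(v) else 1e12

    res = minimize_scalar(nll, bounds=(-5.0, -1e-4), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success or not np.isfinite(res.fun):
        raise FitConvergenceError("constrained GPD fit did not converge")
    xi = float(res.x)
    return GPDParams(xi, -xi * u), float(res.fun)


def _moment_start(s: np.ndarray) -> tuple[float, float]:
    m, v = float(np.mean(s)), float(np.var(s))
    if v <= 0:
        return 0.0, max(m, 1e-12)
    xi0 = 0.5 * (1.0 - m * m / v)
    beta0 = 0.5 * m * (m * m / v + 1.0)
    return float(np.clip(xi0, -0.95, 0.95)), max(beta0, 1e-12)


def _fit_free(s: np.ndarray, u: float) -> tuple[GPDParams, float]:
    """Joint (xi, log beta) fit; bounded quasi-Newton, deterministic restarts.

    Restarts: the moment estimator, a near-exponential start, and an
    endpoint-tied start from the constrained profile — the latter rescues
    short-tailed samples (xi < -0.5) whose optimum hugs the sample maximum.
    Ties are broken by likelihood, then smallest |xi|.
    """
    smax = float(np.max(s))

    def nll_vec(theta: np.ndarray) -> float:
        v = _negloglik(theta[0], np.exp(theta[1]), s)
        return v if np.isfinite(v) else 1e12  # finite wall keeps L-BFGS-B quiet

    starts = []
    xi0, beta0 = _moment_start(s)
    starts.append((xi0, beta0))
    starts.append((0.1, max(float(np.mean(s)), 1e-12)))
    try:
        cpar, _ = _fit_constrained(s, smax * (1.0 + 1e-3))
        starts.append((cpar.shape, cpar.scale))
    except FitConvergenceError:
        pass

    best = None
    for xi_s, beta_s in starts:
        res = minimize(
            nll_vec,
            np.array([xi_s, np.log(beta_s)]),
            method="L-BFGS-B",
            bounds=[(-5.0, 5.0), (None, None)],
        )
        if not np.isfinite(res.fun):
            continue
        cand = (float(res.fun), abs(float(res.x[0])), float(res.x[0]), float(np.exp(res.x[1])))
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        raise FitConvergenceError("free GPD fit did not converge from any restart")
    _, _, xi, beta = best
    return GPDParams(xi, beta), best[0]


def _numeric_hessian(fun, x0: np.ndarray, steps: np.ndarray) -> np.ndarray:
    k = x0.size
    H = np.empty((k, k))
    f0 = fun(x0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            if i == j:
                H[i, i] = (fun(x0 + ei) - 2 * f0 + fun(x0 - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    fun(x0 + ei + ej) - fun(x0 + ei - ej)
                    - fun(x0 - ei + ej) + fun(x0 - ei - ej)
                ) / (4 * steps[i] * steps[j])
    return H


def _profile_halfwidth(fun, x0: float, scale: float, target: float = 0.5) -> float:
    """Distance from x0 at which the (profile) nll rises by ``target``.

    Expands geometrically on both sides and returns the smaller excursion at
    which the rise reaches ``target``; used when the observed information is
    not positive definite (e.g. short tails with shape < -1/2, where the
    likelihood is non-quadratic and no asymptotic-normal SE exists).
    """
    f0 = fun(x0)
    step = max(abs(x0), scale) * 1e-4
    for _ in range(80):
        if min(fun(x0 + step), fun(x0 - step)) - f0 >= target:
            return step
        step *= 1.5
    return step


def _profile_nll_xi(xi: float, s: np.ndarray, beta_ref: float) -> float:
    """Negative log-likelihood at xi, maximised over the scale."""
    lo, hi = np.log(beta_ref) - 6.0, np.log(beta_ref) + 6.0

    def inner(logb: float) -> float:
        v = _negloglik(xi, np.exp(logb), s)
        return v if np.isfinite(v) else 1e12

    res = minimize_scalar(inner, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.fun)


def _profile_nll_beta(beta: float, s: np.ndarray, xi_ref: float) -> float:
    """Negative log-likelihood at beta, maximised over the shape."""

    def inner(xi: float) -> float:
        v = _negloglik(xi, beta, s)
        return v if np.isfinite(v) else 1e12

    res = minimize_scalar(inner, bounds=(-5.0, 5.0), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.fun)


def _standard_errors(
    s: np.ndarray, params: GPDParams, u: float, mode: str
) -> tuple[float, float, str]:
    xi, beta = params.shape, params.scale
    if mode == "constrained":
        def nll1(x):
            return _negloglik(x, -x * u, s)
        h = max(abs(xi), 1e-3) * 1e-4
        d2 = (nll1(xi + h) - 2 * nll1(xi) + nll1(xi - h)) / (h * h)
        if np.isfinite(d2) and d2 > 0:
            se_xi = 1.0 / np.sqrt(d2)
            return se_xi, abs(u) * se_xi, "observed_information"
        se_xi = _profile_halfwidth(nll1, xi, 0.1)
        return se_xi, abs(u) * se_xi, "profile"

    def nll2(theta):
        return _negloglik(theta[0], theta[1], s)

    x0 = np.array([xi, beta])
    steps = np.array([max(abs(xi), 1e-3) * 1e-4, beta * 1e-4])
    H = _numeric_hessian(nll2, x0, steps)
    if np.all(np.isfinite(H)):
        try:
            cov = np.linalg.inv(H)
            if cov[0, 0] > 0 and cov[1, 1] > 0:
                return float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1])), "observed_information"
        except np.linalg.LinAlgError:
            pass
    se_xi = _profile_halfwidth(lambda x: _profile_nll_xi(x, s, beta), xi, 0.1)
    se_beta = _profile_halfwidth(lambda b: _profile_nll_beta(b, s, xi), beta, beta)
    return se_xi, se_beta, "profile"


def fit_tail(
    sample: ImageSample | np.ndarray,
    u: float,
    mode: str = "free",
    min_tail_size: int = MIN_TAIL_SIZE,
) -> TailModel:
    """Maximum-likelihood GPD fit to the shortfalls beneath u.

    The image values strictly below u enter as depths s_i = u - y_i.
    """
    if mode not in ("constrained", "free"):
        raise DomainError(f"unknown fit mode {mode!r}")
    if isinstance(sample, ImageSample):
        values, fp = sample.values, sample.fingerprint
    else:
        values, fp = np.asarray(sample, dtype=float).ravel(), None
    tail_vals = values[values < u]
    if tail_vals.size < min_tail_size:
        raise InsufficientDataError(
            f"only {tail_vals.size} tail points below u={u!r}; need at least {min_tail_size}"
        )
    # shortfall depths beneath the threshold; depths at exactly u (image
    # value 0, a legal underflow) are nudged inside to keep the constrained
    # likelihood finite
    s = np.minimum(u - tail_vals, u * (1.0 - 1e-15))
    if mode == "constrained":
        params, _ = _fit_constrained(s, u)
    else:
        params, _ = _fit_free(s, u)
    se_xi, se_beta, se_method = _standard_errors(s, params, u, mode)
    return TailModel(
        threshold=float(u),
        params=params,
        tail_fraction=s.size / values.size,
        n_tail=int(s.size),
        se_shape=se_xi,
        se_scale=se_beta,
        mode=mode,
        se_method=se_method,
        fingerprint=fp,
    )


def tail_df_estimate(tail: TailModel, y) -> np.ndarray | float:
    """Scaled tail estimator G_hat_Y(y) = (N_u/N) * SF(u - y), y in [0, u]."""
    scalar = np.isscalar(y)
    y = np.asarray(y, dtype=float)
    u = tail.threshold
    if np.any(y < -1e-12) or np.any(y > u * (1 + 1e-9) + 1e-300):
        raise DomainError("tail_df_estimate requires 0 <= y <= u")
    out = tail.tail_fraction * np.asarray(gpd_sf(tail.params, np.maximum(u - y, 0.0)))
    return float(out) if scalar and out.ndim == 0 else out


# ---------------------------------------------------------------------------
# the extended GPD over data space


def extended_gpd_gaussian(
    points: np.ndarray, model: GaussianDensity, tail: TailModel
) -> np.ndarray:
    """Closed-form F^e(x) = (1 + xi f(x)/beta)^(-1/xi) via Mahalanobis radius.

    0 in the normal region f(x) >= u; tends to 1 as the radius grows.
    """
    if tail.fingerprint is not None and tail.fingerprint != model_fingerprint(model):
        raise DomainError("tail model was fitted on a different density model")
    m = model.mahalanobis(points)
    with np.errstate(under="ignore"):
        y = np.exp(-model.log_partition - 0.5 * m * m)
    out = np.asarray(gpd_sf(tail.params, y), dtype=float)
    out[y >= tail.threshold] = 0.0
    return out


@dataclass(frozen=True)
class GridSpec:
    """Bounded rectangular quadrature grid: per-axis bounds and point counts."""

    lower: tuple[float, ...]
    upper: tuple[float, ...]
    shape: tuple[int, ...]

    def __post_init__(self) -> None:
        lo = tuple(float(v) for v in np.atleast_1d(self.lower))
        hi = tuple(float(v) for v in np.atleast_1d(self.upper))
        sh = tuple(int(v) for v in np.atleast_1d(self.shape))
        if not len(lo) == len(hi) == len(sh):
            raise DomainError("grid lower/upper/shape must have equal length")
        if any(h <= l for l, h in zip(lo, hi)) or any(s < 2 for s in sh):
            raise DomainError("grid bounds must be increasing with >= 2 points per axis")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        object.__setattr__(self, "shape", sh)

    def axes(self) -> list[np.ndarray]:
        return [np.linspace(l, h, s) for l, h, s in zip(self.lower, self.upper, self.shape)]


def _grid_integral(field: np.ndarray, axes: list[np.ndarray]) -> float:
    out = field
    for ax in reversed(range(len(axes))):
        out = np.trapezoid(out, x=axes[ax], axis=ax)
    return float(out)


@dataclass(frozen=True)
class ExtendedGPDField:
    """Numerically normalised extended GPD f^e on a grid, plus phi = 1-log f^e."""

    grid: GridSpec
    density: np.ndarray
    phi: np.ndarray
    partition: float
    mass_captured: float


def extended_gpd_numeric(
    model: DensityModel, tail: TailModel, grid: GridSpec, min_mass: float = 0.99
) -> ExtendedGPDField:
    """f^e(x) = Z^-1 G^e(f(x)), G^e clamped to 1 in the normal region f(x) > u.

    Z comes from trapezoid quadrature over the grid; the grid must capture at
    least ``min_mass`` of the model's own probability mass.
    """
    if model.dim > 3:
        raise DomainError("numeric extended GPD supports model dimension <= 3")
    if len(grid.shape) != model.dim:
        raise DimensionMismatchError("grid dimensionality does not match the model")
    axes = grid.axes()
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    with np.errstate(under="ignore"):
        y = np.exp(log_density(model, pts)).reshape(grid.shape)
    mass = _grid_integral(y, axes)
    if mass < min_mass:
        raise GridCoverageError(
            f"grid captures only {mass:.4f} of the model mass (< {min_mass}); widen the grid"
        )
    h = np.asarray(gpd_df(tail.params, np.minimum(y, tail.threshold)), dtype=float)
    h[y > tail.threshold] = 1.0
    Z = _grid_integral(h, axes)
    density = h / Z
    with np.errstate(divide="ignore"):
        phi = 1.0 - np.log(density)
    return ExtendedGPDField(grid=grid, density=density, phi=phi,
                            partition=Z, mass_captured=mass)


# ---------------------------------------------------------------------------
# serialization


def save_tail_model(tail: TailModel, path) -> None:
    payload = {
        "threshold": tail.threshold,
        "shape": tail.params.shape,
        "scale": tail.params.scale,
        "location": tail.params.location,
        "convention": "internal-v1",
        "tail_fraction": tail.tail_fraction,
        "n_tail": tail.n_tail,
        "se_shape": tail.se_shape,
        "se_scale": tail.se_scale,
        "mode": tail.mode,
        "se_method": tail.se_method,
        "fingerprint": tail.fingerprint,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def load_tail_model(path) -> TailModel:
    with open(path, "r", encoding="utf-8") as fh:
        d = json.load(fh)
    if d.get("convention") != "internal-v1":
        raise DomainError(f"unsupported tail-model convention {d.get('convention')!r}")
    return TailModel(
        threshold=d["threshold"],
        params=GPDParams(d["shape"], d["scale"], d.get("location", 0.0)),
        tail_fraction=d["tail_fraction"],
        n_tail=d["n_tail"],
        se_shape=d["se_shape"],
        se_scale=d["se_scale"],
        mode=d["mode"],
        se_method=d.get("se_method", "observed_information"),
        fingerprint=d.get("fingerprint"),
    )
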