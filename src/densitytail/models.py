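"""Models of normality: multivariate Gaussians and finite Gaussian mixtures.

The "model of normality" f_X is the estimated density of normal behaviour
over the n-dimensional data space.  Everything downstream (the probability
image space, the GPD tail, novelty scores) only ever sees data through
``log_density`` and ``modal_density``, so these two operations carry the
numerical burden: log-domain evaluation throughout, log-sum-exp across
mixture components, and a clean ``-inf`` on underflow.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.special import logsumexp

from .errors import DimensionMismatchError, ModelValidationError

__all__ = [
    "GaussianDensity",
    "MixtureDensity",
    "DensityModel",
    "log_density",
    "sample",
    "modal_density",
    "mahalanobis",
    "fit_parzen",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "model_fingerprint",
]


@dataclass(frozen=True)
class GaussianDensity:
    """Multivariate Gaussian N(x | mean, covariance).

    The normalising (partition) constant is C_n = (2*pi)^(n/2) |Sigma|^(1/2);
    the modal density is 1/C_n and log f(x) = -log C_n - M(x)^2 / 2 with M
    the Mahalanobis radius.
    """

    mean: np.ndarray
    covariance: np.ndarray
    _chol: np.ndarray = field(init=False, repr=False, compare=False)
    _log_det: float = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        if mean.ndim != 1 or cov.shape != (mean.size, mean.size):
            raise ModelValidationError(
                f"covariance shape {cov.shape} incompatible with mean of length {mean.size}"
            )
        if not np.allclose(cov, cov.T, rtol=1e-10, atol=1e-12):
            raise ModelValidationError("covariance matrix is not symmetric")
        try:
            chol = cholesky(cov, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises its own
            raise ModelValidationError(f"covariance is not positive definite: {exc}") from exc
        except Exception as exc:
            raise ModelValidationError(f"covariance is not positive definite: {exc}") from exc
        log_det = 2.0 * float(np.sum(np.log(np.diag(chol))))
        if not np.isfinite(log_det):
            raise ModelValidationError("log-determinant of covariance is not finite")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        object.__setattr__(self, "_chol", chol)
        object.__setattr__(self, "_log_det", log_det)

    @property
    def dim(self) -> int:
        return self.mean.size

    @property
    def log_partition(self) -> float:
        """log C_n = (n/2) log(2 pi) + (1/2) log |Sigma|."""
        return 0.5 * self.dim * np.log(2.0 * np.pi) + 0.5 * self._log_det

    @property
    def det_covariance(self) -> float:
        return float(np.exp(self._log_det))

    def _check_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] != self.dim:
            raise DimensionMismatchError(
                f"points have dimension {pts.shape[1]}, model has dimension {self.dim}"
            )
        return pts

    def mahalanobis(self, points: np.ndarray) -> np.ndarray:
        """Mahalanobis radius M(x) = sqrt((x-mu)' Sigma^-1 (x-mu)) per row."""
        pts = self._check_points(points)
        z = solve_triangular(self._chol, (pts - self.mean).T, lower=True)
        return np.sqrt(np.sum(z * z, axis=0))

    def log_density(self, points: np.ndarray) -> np.ndarray:
        m = self.mahalanobis(points)
        return -self.log_partition - 0.5 * m * m

    def log_density_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """(log f(x), d log f / dx) at a single point, for modal ascent."""
        x = np.asarray(x, dtype=float)
        diff = x - self.mean
        z = solve_triangular(self._chol, diff, lower=True)
        siginv_diff = solve_triangular(self._chol.T, z, lower=False)
        return float(-self.log_partition - 0.5 * z @ z), -siginv_diff

    def sample(self, count: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(size=(count, self.dim))
        return self.mean + z @ self._chol.T


@dataclass(frozen=True)
class MixtureDensity:
    """Finite Gaussian mixture with strictly positive weights summing to 1."""

    weights: np.ndarray
    components: tuple[GaussianDensity, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float).ravel()
        comps = tuple(self.components)
        if len(comps) < 1:
            raise ModelValidationError("mixture needs at least one component")
        if w.size != len(comps):
            raise ModelValidationError("one weight per component required")
        if np.any(w <= 0):
            raise ModelValidationError("mixture weights must be strictly positive")
        if abs(float(w.sum()) - 1.0) > 1e-12:
            raise ModelValidationError(
                f"mixture weights sum to {w.sum()!r}, not 1 within 1e-12"
            )
        dims = {c.dim for c in comps}
        if len(dims) != 1:
            raise ModelValidationError("mixture components have differing dimensionality")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "components", comps)

    @property
    def dim(self) -> int:
        return self.components[0].dim

    def log_density(self, points: np.ndarray) -> np.ndarray:
        pts = self.components[0]._check_points(points)
        comp_ld = np.stack([c.log_density(pts) for c in self.components], axis=0)
        return logsumexp(comp_ld + np.log(self.weights)[:, None], axis=0)

    def log_density_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        x = np.asarray(x, dtype=float)
        lds, grads = zip(*(c.log_density_grad(x) for c in self.components))
        lw = np.asarray(lds) + np.log(self.weights)
        total = logsumexp(lw)
        resp = np.exp(lw - total)
        return float(total), np.sum(resp[:, None] * np.asarray(grads), axis=0)

    def sample(self, count: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.choice(len(self.components), size=count, p=self.weights)
        out = np.empty((count, self.dim))
        for k, comp in enumerate(self.components):
            rows = np.nonzero(idx == k)[0]
            if rows.size:
                out[rows] = comp.sample(rows.size, rng)
        return out


DensityModel = Union[GaussianDensity, MixtureDensity]


def log_density(model: DensityModel, points: np.ndarray) -> np.ndarray:
    """log f_X(x_i) per row; mixtures use a stable log-sum-exp."""
    return model.log_density(points)


def sample(model: DensityModel, count: int, seed: int) -> np.ndarray:
    """``count`` i.i.d. rows from the model; identical seed, identical matrix."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    return model.sample(count, rng)


def mahalanobis(model: GaussianDensity, points: np.ndarray) -> np.ndarray:
    if not isinstance(model, GaussianDensity):
        raise ModelValidationError("mahalanobis is defined for GaussianDensity models")
    return model.mahalanobis(points)


_MODAL_CACHE: dict[int, float] = {}


def modal_density(model: DensityModel) -> float:
    """Supremum of f_X.

    Gaussian: exactly 1/C_n.  Mixture: multi-start local ascent (L-BFGS-B on
    -log f with analytic gradient) launched from every component mean; the
    returned value is a certified lower bound on sup f, refined numerically,
    and never below the best density over the component means.
    """
    if isinstance(model, GaussianDensity):
        return float(np.exp(-model.log_partition))
    key = id(model)
    if key in _MODAL_CACHE:
        return _MODAL_CACHE[key]
    means = np.stack([c.mean for c in model.components])
    ld_at_means = model.log_density(means)
    best = float(np.max(ld_at_means))
    # ascent from every mean for small mixtures; for large kernel mixtures
    # only the highest-density means can carry the global mode, so the ascent
    # is launched from the 16 best (result stays >= density at every mean)
    if len(model.components) > 16:
        starts = means[np.argsort(ld_at_means)[-16:]]
    else:
        starts = means
    for mu in starts:
        res = minimize(
            lambda x: _neg_logdens_grad(model, x),
            mu,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 200},
        )
        if np.isfinite(res.fun):
            best = max(best, -float(res.fun))
    value = float(np.exp(best))
    _MODAL_CACHE[key] = value
    return value


def _neg_logdens_grad(model: MixtureDensity, x: np.ndarray) -> tuple[float, np.ndarray]:
    ld, g = model.log_density_grad(x)
    return -ld, -g


def fit_parzen(
    train: np.ndarray,
    n_kernels: int,
    bandwidth_rule: str = "silverman",
    seed: int = 0,
    bandwidth: float | None = None,
    n_init: int = 10,
) -> MixtureDensity:
    """Equal-weight isotropic Parzen-style mixture on k-means centres.

    ``bandwidth_rule`` is ``"silverman"`` (multivariate Silverman factor on
    the mean marginal standard deviation) or ``"fixed"`` (uses ``bandwidth``).
    """
    train = np.atleast_2d(np.asarray(train, dtype=float))
    m, d = train.shape
    if n_kernels < 1 or n_kernels > m:
        raise ValueError(f"n_kernels must be in [1, {m}], got {n_kernels}")
    stds = train.std(axis=0, ddof=1) if m > 1 else np.zeros(d)
    if bandwidth_rule == "silverman":
        if np.any(stds <= 0):
            raise ValueError("degenerate zero-variance training column")
        h = float((4.0 / (d + 2)) ** (1.0 / (d + 4)) * m ** (-1.0 / (d + 4)) * stds.mean())
    elif bandwidth_rule == "fixed":
        if bandwidth is None or bandwidth <= 0:
            raise ValueError("fixed bandwidth_rule requires a positive bandwidth")
        h = float(bandwidth)
    else:
        raise ValueError(f"unknown bandwidth_rule {bandwidth_rule!r}")
    if n_kernels == m:
        centres = train.copy()
    else:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=n_kernels, random_state=int(seed), n_init=n_init)
        km.fit(train)
        centres = km.cluster_centers_
    cov = (h * h) * np.eye(d)
    comps = tuple(GaussianDensity(c, cov) for c in centres)
    w = np.full(n_kernels, 1.0 / n_kernels)
    w[-1] = 1.0 - w[:-1].sum()  # exact unit sum
    return MixtureDensity(w, comps)


# ---------------------------------------------------------------------------
# serialization


def model_to_dict(model: DensityModel) -> dict:
    if isinstance(model, GaussianDensity):
        return {
            "type": "gaussian",
            "mean": model.mean.tolist(),
            "covariance": model.covariance.tolist(),
        }
    return {
        "type": "mixture",
        "components": [
            {
                "weight": float(w),
                "mean": c.mean.tolist(),
                "covariance": c.covariance.tolist(),
            }
            for w, c in zip(model.weights, model.components)
        ],
    }


def model_from_dict(spec: dict) -> DensityModel:
    try:
        kind = spec["type"]
        if kind == "gaussian":
            return GaussianDensity(np.asarray(spec["mean"]), np.asarray(spec["covariance"]))
        if kind == "mixture":
            comps = spec["components"]
            w = np.array([c["weight"] for c in comps])
            parts = tuple(
                GaussianDensity(np.asarray(c["mean"]), np.asarray(c["covariance"]))
                for c in comps
            )
            return MixtureDensity(w, parts)
    except KeyError as exc:
        raise ModelValidationError(f"model specification missing key {exc}") from exc
    raise ModelValidationError(f"unknown model type {spec.get('type')!r}")


def save_model(model: DensityModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def load_model(path) -> DensityModel:
    with open(path, "r", encoding="utf-8") as fh:
        return model_from_dict(json.load(fh))


def model_fingerprint(model: DensityModel) -> str:
    """Short stable hash of the model's canonical JSON form."""
    payload = json.dumps(model_to_dict(model), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
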