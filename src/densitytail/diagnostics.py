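"""Quality-of-fit and assumption diagnostics for image-space tail models.

Four tools, all emitting plot-ready tables rather than figures:

* QQ tables of tail data against a fitted GPD;
* the mean excess (mean shortfall magnitude), whose linearity in the
  threshold is characteristic of a GPD tail — the slope is xi/(1-xi) in the
  exceedance orientation and -xi/(1-xi) in the image-space shortfall
  orientation (same magnitude, mirrored axis);
* threshold-stability sweeps of the fitted shape and scale;
* the record-counting i.i.d. diagnostic: in an i.i.d. sequence the expected
  number of running-minimum records after i observations is the harmonic sum
  H_i, with E[N_i] - log i -> Euler's gamma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

from .errors import DomainError, FitConvergenceError, InsufficientDataError
from .gpd import GPDParams, TailModel, fit_tail, gpd_quantile, MIN_TAIL_SIZE
from .image import ImageSample

__all__ = [
    "QQTable",
    "MeanExcessCurve",
    "StabilityProfile",
    "RecordSummary",
    "RecordCalibration",
    "qq_table",
    "mean_excess_empirical",
    "mean_excess_curve",
    "mean_excess_theoretical",
    "default_threshold_grid",
    "stability_sweep",
    "find_records",
    "record_expectation",
    "iid_record_calibration",
]

EULER_GAMMA = 0.5772156649015329


# ---------------------------------------------------------------------------
# QQ


@dataclass(frozen=True)
class QQTable:
    percentiles: np.ndarray
    model_quantiles: np.ndarray
    empirical_quantiles: np.ndarray
    max_abs_deviation: float
    correlation: float
    flags: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "percentile": self.percentiles,
                "model_quantile": self.model_quantiles,
                "empirical_quantile": self.empirical_quantiles,
            }
        )


def _empirical_quantiles(sorted_vals: np.ndarray, p: np.ndarray) -> np.ndarray:
    # type-1 rule: order statistic at ceil(p*n); the 1e-9 backoff guards
    # against p*n landing a hair above an integer in floating point
    n = sorted_vals.size
    idx = np.clip(np.ceil(p * n - 1e-9).astype(int) - 1, 0, n - 1)
    return sorted_vals[idx]


def qq_table(tail_values: np.ndarray, params: GPDParams) -> QQTable:
    """Empirical vs model quantiles at percentiles i/100 (coarsened if n<100)."""
    vals = np.sort(np.asarray(tail_values, dtype=float).ravel())
    n = vals.size
    if n == 0:
        raise InsufficientDataError("qq_table needs at least one tail value")
    flags: list[str] = []
    if n < 100:
        m = n
        flags.append("percentile grid coarsened to sample size")
    else:
        m = 100
    p = np.arange(1, m + 1) / m
    model_q = np.asarray(gpd_quantile(params, p), dtype=float)
    if not np.isfinite(model_q[-1]):
        # unbounded support: pin the top percentile just inside
        model_q[-1] = float(gpd_quantile(params, (n - 0.5) / n))
        flags.append("top percentile evaluated inside the support (unbounded model)")
    emp_q = _empirical_quantiles(vals, p)
    dev = float(np.max(np.abs(emp_q - model_q)))
    if np.ptp(emp_q) == 0.0 or np.ptp(model_q) == 0.0:
        flags.append("degenerate-flat")
        corr = math.nan
    else:
        corr = float(np.corrcoef(emp_q, model_q)[0, 1])
    return QQTable(p, model_q, emp_q, dev, corr, tuple(flags))


# ---------------------------------------------------------------------------
# mean excess


def _values_of(sample) -> np.ndarray:
    if isinstance(sample, ImageSample):
        return sample.values
    return np.asarray(sample, dtype=float).ravel()


def mean_excess_empirical(sample, u: float) -> float:
    """Mean shortfall magnitude mean(u - y | y < u)."""
    v = _values_of(sample)
    short = u - v[v < u]
    if short.size == 0:
        raise InsufficientDataError(f"no data strictly below u={u!r}")
    return float(short.mean())


@dataclass(frozen=True)
class MeanExcessCurve:
    thresholds: np.ndarray
    mean_excess: np.ndarray
    counts: np.ndarray
    side: str = "below"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "mean_excess": self.mean_excess,
             "count": self.counts}
        )


def mean_excess_curve(sample, thresholds, side: str = "below") -> MeanExcessCurve:
    """Mean excess over a threshold grid.

    ``side="below"`` (image space): mean(u - y | y < u).
    ``side="above"`` (classical exceedances): mean(y - u | y > u), the
    orientation in which a GPD tail gives slope xi/(1-xi).
    Grid points with no qualifying data get NaN and count 0.
    """
    if side not in ("below", "above"):
        raise DomainError(f"side must be 'below' or 'above', got {side!r}")
    v = _values_of(sample)
    thresholds = np.asarray(thresholds, dtype=float).ravel()
    e = np.full(thresholds.size, np.nan)
    counts = np.zeros(thresholds.size, dtype=int)
    for j, u in enumerate(thresholds):
        exc = (u - v[v < u]) if side == "below" else (v[v > u] - u)
        counts[j] = exc.size
        if exc.size:
            e[j] = exc.mean()
    return MeanExcessCurve(thresholds, e, counts, side)


def mean_excess_theoretical(params: GPDParams, u) -> np.ndarray | float:
    """GPD mean excess e(u) = (beta + xi*u)/(1 - xi); linear with slope xi/(1-xi)."""
    if params.shape >= 1.0:
        raise DomainError("mean excess requires shape < 1")
    u = np.asarray(u, dtype=float)
    out = (params.scale + params.shape * u) / (1.0 - params.shape)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# threshold stability


@dataclass(frozen=True)
class StabilityProfile:
    u_grid: np.ndarray
    shape_hat: np.ndarray
    scale_hat: np.ndarray
    se_shape: np.ndarray
    se_scale: np.ndarray
    n_tail: np.ndarray
    admissible: np.ndarray
    flags: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "u": self.u_grid,
                "shape_hat": self.shape_hat,
                "scale_hat": self.scale_hat,
                "se_shape": self.se_shape,
                "se_scale": self.se_scale,
                "n_tail": self.n_tail,
                "admissible": self.admissible,
            }
        )


def default_threshold_grid(sample, n: int = 25, lo_q: float = 0.005,
                           hi_q: float = 0.20) -> np.ndarray:
    """25 log-spaced thresholds between the 0.5% and 20% image quantiles."""
    v = np.sort(_values_of(sample))
    lo = v[min(int(np.ceil(lo_q * v.size)), v.size - 1)]
    hi = v[min(int(np.ceil(hi_q * v.size)), v.size - 1)]
    lo = max(lo, np.finfo(float).tiny)
    if hi <= lo:
        hi = lo * 10
    return np.geomspace(lo, hi, n)


def stability_sweep(
    sample, u_grid, mode: str = "free", min_tail_size: int = MIN_TAIL_SIZE
) -> StabilityProfile:
    """fit_tail at each admissible threshold; inadmissible points are flagged."""
    u_grid = np.asarray(u_grid, dtype=float).ravel()
    if np.any(np.diff(u_grid) < 0):
        raise DomainError("u_grid must be sorted ascending")
    m = u_grid.size
    shp = np.full(m, np.nan); scl = np.full(m, np.nan)
    se_s = np.full(m, np.nan); se_b = np.full(m, np.nan)
    ntl = np.zeros(m, dtype=int)
    adm = np.zeros(m, dtype=bool)
    flags: list[str] = []
    for j, u in enumerate(u_grid):
        try:
            tm = fit_tail(sample, u, mode=mode, min_tail_size=min_tail_size)
        except (InsufficientDataError, FitConvergenceError) as exc:
            flags.append(f"u={u:.6g}: {exc}")
            continue
        shp[j], scl[j] = tm.params.shape, tm.params.scale
        se_s[j], se_b[j] = tm.se_shape, tm.se_scale
        ntl[j] = tm.n_tail
        adm[j] = True
    return StabilityProfile(u_grid, shp, scl, se_s, se_b, ntl, adm, tuple(flags))


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class RecordSummary:
    record_indices: np.ndarray  # 1-based positions of records
    counting_path: np.ndarray   # N_i for every index i
    expected: np.ndarray        # E[N_i] under i.i.d.
    variance: np.ndarray        # var[N_i] under i.i.d.


def find_records(values) -> RecordSummary:
    """Running-minimum records: y_i < min(y_1..y_{i-1}); y_1 is a record."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise InsufficientDataError("record scan needs a non-empty sequence")
    running = np.minimum.accumulate(v)
    is_rec = np.empty(v.size, dtype=bool)
    is_rec[0] = True
    is_rec[1:] = v[1:] < running[:-1]  # strict: a repeated minimum is no record
    idx = np.arange(1.0, v.size + 1.0)
    expected = np.cumsum(1.0 / idx)
    variance = expected - np.cumsum(1.0 / (idx * idx))
    return RecordSummary(
        record_indices=np.nonzero(is_rec)[0] + 1,
        counting_path=np.cumsum(is_rec).astype(int),
        expected=expected,
        variance=variance,
    )


def record_expectation(i: int) -> tuple[float, float]:
    """(E[N_i], var[N_i]) for an i.i.d. sequence of length i.

    E = H_i via the digamma identity H_i = psi(i+1) + gamma; var = H_i - H_i^(2)
    with the second-order harmonic number from the trigamma function.
    """
    if i < 1:
        raise DomainError("index must be >= 1")
    e = float(digamma(i + 1) + EULER_GAMMA)
    h2 = float(np.pi**2 / 6.0 - polygamma(1, i + 1))
    return e, e - h2


@dataclass(frozen=True)
class RecordCalibration:
    table: pd.DataFrame
    fraction_within: float
    consistent: bool
    k_sd: float


def iid_record_calibration(values, k_sd: float = 2.0) -> RecordCalibration:
    """Compare each observed record count with its i.i.d. expectation.

    For the j-th record, occurring at index i_j, the observed count is j and
    the i.i.d. expectation is E[N_{i_j}] with sd sqrt(var[N_{i_j}]).  The
    sequence is flagged consistent with i.i.d. iff at least 95% of records
    fall within the +/- k_sd band.
    """
    summary = find_records(values)
    idx = summary.record_indices
    j = np.arange(1, idx.size + 1)
    e = summary.expected[idx - 1]
    sd = np.sqrt(summary.variance[idx - 1])
    within = np.abs(j - e) <= k_sd * sd + 1e-12
    frac = float(np.mean(within))
    table = pd.DataFrame(
        {"record_number": j, "index": idx, "expected_count": e,
         "sd": sd, "within_band": within}
    )
    return RecordCalibration(table, frac, bool(frac >= 0.95), float(k_sd))
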