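"""Two-stage novelty scoring.

Stage 1 is the conventional density-threshold gate: a point is "extreme"
when its novelty score z(x) = -log f_X(x) exceeds kappa_z, equivalently when
its image value y = f_X(x) falls below kappa_y = exp(-kappa_z).  Stage 2
scores the extreme points with the fitted tail model: the estimated df mass
below the point, G_hat_Y(y) in [0, tail_fraction] — smaller means deeper in
the tail.  This is the quantity that separates extreme-but-normal from
extreme-and-abnormal observations beyond the conventional decision boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .errors import DomainError, InsufficientDataError
from .gpd import GPDParams, TailModel, tail_df_estimate
from .image import to_image
from .models import DensityModel, log_density, model_fingerprint
from .diagnostics import QQTable, qq_table

__all__ = [
    "NoveltyResult",
    "ComparisonReport",
    "novelty_score",
    "map_threshold",
    "inverse_map_threshold",
    "classify",
    "compare_tail_populations",
]


@dataclass(frozen=True)
class NoveltyResult:
    """Per-point scoring record; stage2_score is None for stage-1-normal points."""

    score: float          # z = -log f_X(x)
    image_value: float    # y = f_X(x)
    stage1_label: str     # "normal" | "extreme"
    stage2_score: float | None


def novelty_score(model: DensityModel, points) -> np.ndarray:
    """z(x) = -log f_X(x); anti-monotone with density."""
    return -log_density(model, points)


def map_threshold(kappa_z: float) -> float:
    """Score threshold to density threshold: kappa_y = exp(-kappa_z)."""
    return float(np.exp(-kappa_z))


def inverse_map_threshold(kappa_y: float) -> float:
    if kappa_y <= 0:
        raise DomainError("kappa_y must be positive")
    return float(-np.log(kappa_y))


def classify(
    model: DensityModel, tail: TailModel, points, kappa_z: float
) -> pd.DataFrame:
    """Score points; returns a frame with columns z, y, stage1, stage2_score.

    Stage 1 uses the strict gate z > kappa_z (a point exactly on the
    boundary is normal).  Stage 2 applies only where y < u; the tail must
    have been fitted at u <= exp(-kappa_z) on the same model.
    """
    if tail.fingerprint is not None and tail.fingerprint != model_fingerprint(model):
        raise DomainError("tail model was fitted on a different density model")
    kappa_y = map_threshold(kappa_z)
    if tail.threshold > kappa_y * (1 + 1e-9):
        raise DomainError(
            f"tail threshold u={tail.threshold!r} exceeds kappa_y={kappa_y!r}"
        )
    sample = to_image(model, points)
    y = sample.values
    with np.errstate(divide="ignore"):
        z = -np.log(y)
    extreme = z > kappa_z
    stage2 = np.full(y.size, np.nan)
    in_tail = y < tail.threshold
    if np.any(in_tail):
        stage2[in_tail] = tail_df_estimate(tail, y[in_tail])
    return pd.DataFrame(
        {
            "z": z,
            "y": y,
            "stage1": np.where(extreme, "extreme", "normal"),
            "stage2_score": stage2,
        }
    )


def classify_records(model, tail, points, kappa_z) -> list[NoveltyResult]:
    """``classify`` as a list of :class:`NoveltyResult`."""
    frame = classify(model, tail, points, kappa_z)
    return [
        NoveltyResult(
            score=row.z,
            image_value=row.y,
            stage1_label=row.stage1,
            stage2_score=None if np.isnan(row.stage2_score) else row.stage2_score,
        )
        for row in frame.itertuples()
    ]


@dataclass(frozen=True)
class ComparisonReport:
    """Side-by-side tail-population diagnostics; a report, not a verdict."""

    qq_a: QQTable
    qq_b: QQTable
    max_dev_a: float
    max_dev_b: float
    ks_distance: float
    ks_pvalue: float

    def summary(self) -> dict:
        return {
            "max_qq_deviation_a": self.max_dev_a,
            "max_qq_deviation_b": self.max_dev_b,
            "ks_distance": self.ks_distance,
            "ks_pvalue": self.ks_pvalue,
        }


def compare_tail_populations(
    tail_a, tail_b, params: GPDParams
) -> ComparisonReport:
    """QQ both populations against the fitted GPD and report their KS distance."""
    a = np.asarray(tail_a, dtype=float).ravel()
    b = np.asarray(tail_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both tail populations must be non-empty")
    qa = qq_table(a, params)
    qb = qq_table(b, params)
    ks = ks_2samp(a, b)
    return ComparisonReport(
        qq_a=qa,
        qq_b=qb,
        max_dev_a=qa.max_abs_deviation,
        max_dev_b=qb.max_abs_deviation,
        ks_distance=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    )
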