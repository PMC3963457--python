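"""Seeded synthetic-data generators.

Every fixture is reproducible bit-for-bit from (name, parameters, seed); the
numeric constants live in ``data/fixtures_config.json``, not in code.  The
fixtures emulate the *statistical structure* of the experiments the method
was designed around — standard Gaussians of several dimensions, a bimodal
8-component bivariate mixture, a two-regime vital-sign stream, and direct
GPD samples — without claiming to reproduce any unpublished dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import DomainError
from .gpd import GPDParams, gpd_quantile
from .models import (
    DensityModel,
    GaussianDensity,
    MixtureDensity,
    fit_parzen,
)

__all__ = [
    "FixtureSpec",
    "load_fixture_config",
    "standard_gaussian_fixture",
    "bivariate_mixture_fixture",
    "vitalsign_fixture",
    "gpd_fixture",
]


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    parameters: dict
    seed: int

    def to_dict(self) -> dict:
        return {"name": self.name, "parameters": self.parameters, "seed": self.seed}


def load_fixture_config() -> dict:
    path = resources.files("densitytail").joinpath("data/fixtures_config.json")
    with path.open() as fh:
        return json.load(fh)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def _mixture_from(components: list[dict]) -> MixtureDensity:
    w = np.array([c["weight"] for c in components], dtype=float)
    w = w / w.sum()
    w[-1] = 1.0 - w[:-1].sum()  # exact unit sum despite decimal config values
    comps = tuple(
        GaussianDensity(np.asarray(c["mean"]), np.asarray(c["covariance"]))
        for c in components
    )
    return MixtureDensity(w, comps)


def standard_gaussian_fixture(
    dim: int, count: int = 100_000, seed: int = 0
) -> tuple[GaussianDensity, np.ndarray]:
    """Standard Gaussian of the given dimension plus i.i.d. samples."""
    if dim < 1:
        raise DomainError("dimension must be >= 1")
    model = GaussianDensity(np.zeros(dim), np.eye(dim))
    obs = model.sample(count, _rng(seed, 0))
    return model, obs


def bivariate_mixture_fixture(
    seed: int = 0, count: int | None = None
) -> tuple[MixtureDensity, np.ndarray]:
    """Bimodal 8-component bivariate mixture and N = 1e5 samples (default)."""
    cfg = load_fixture_config()["bivariate_mixture"]
    model = _mixture_from(cfg["components"])
    n = int(cfg["default_count"]) if count is None else int(count)
    obs = model.sample(n, _rng(seed, 1))
    return model, obs


def vitalsign_fixture(
    n_normal: int, n_abnormal: int, seed: int = 0
) -> tuple[MixtureDensity, pd.DataFrame]:
    """Two-regime 4-D vital-sign stream with labels.

    The normal model is a 400-kernel Parzen mixture built from seeded draws
    of the documented physiological base distribution; normal rows are drawn
    from that model itself, abnormal rows from the documented abnormal
    mixture (respiration and heart rate up, SpO2 down, plus a
    jointly-improbable-but-individually-moderate sub-regime).
    """
    if n_normal < 0 or n_abnormal < 0:
        raise DomainError("counts must be >= 0")
    cfg = load_fixture_config()["vitalsign"]
    base_cfg = cfg["normal_base"]
    base = MixtureDensity(
        np.asarray(base_cfg["weights"], dtype=float),
        tuple(
            GaussianDensity(np.asarray(m), np.asarray(c))
            for m, c in zip(base_cfg["means"], base_cfg["covariances"])
        ),
    )
    train = base.sample(int(cfg["n_train"]), _rng(seed, 2))
    model = fit_parzen(
        train,
        n_kernels=int(cfg["n_kernels"]),
        bandwidth_rule=cfg["bandwidth_rule"],
        seed=int(seed) % (2**31),
        n_init=2,
    )
    parts = []
    if n_normal:
        normal = model.sample(n_normal, _rng(seed, 3))
        parts.append((normal, "normal"))
    if n_abnormal:
        ab_cfg = cfg["abnormal"]
        abnormal_model = MixtureDensity(
            np.asarray(ab_cfg["weights"], dtype=float),
            tuple(
                GaussianDensity(np.asarray(m), np.asarray(c))
                for m, c in zip(ab_cfg["means"], ab_cfg["covariances"])
            ),
        )
        abnormal = abnormal_model.sample(n_abnormal, _rng(seed, 4))
        parts.append((abnormal, "abnormal"))
    columns = cfg["variables"]
    frames = [
        pd.DataFrame(data, columns=columns).assign(label=label)
        for data, label in parts
    ]
    if frames:
        obs = pd.concat(frames, ignore_index=True)
    else:
        obs = pd.DataFrame(columns=[*columns, "label"])
    return model, obs


def gpd_fixture(
    params: GPDParams,
    u: float | None,
    count: int,
    seed: int = 0,
    allow_truncation: bool = False,
) -> np.ndarray:
    """Inverse-cdf GPD samples; with a threshold u they must fit inside [0, u].

    ``u=None`` skips the range restriction (useful for unbounded shapes).
    If the support endpoint exceeds u, values are only truncated to [0, u]
    when ``allow_truncation`` is set; otherwise this raises.
    """
    if count < 1:
        raise DomainError("count must be >= 1")
    p = _rng(seed, 5).uniform(size=count)
    draws = np.asarray(gpd_quantile(params, p), dtype=float)
    if u is not None and params.endpoint > u:
        if not allow_truncation:
            raise DomainError(
                f"GPD endpoint {params.endpoint!r} exceeds u={u!r}; "
                "pass allow_truncation=True to clip"
            )
        draws = np.minimum(draws, u)
    return draws
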