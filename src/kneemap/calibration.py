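"""HU-to-BMD calibration from a solid calcium-hydroxyapatite phantom.

A multi-rod reference phantom scanned alongside the knee provides
samples of known volumetric density (mg/cc of hydroxyapatite
equivalent) at measured mean HU.  Ordinary least squares on those
samples yields the linear correspondence

    density [mg/cc] = slope * HU + intercept

which is then applied voxel-wise to the CT volume.  Rod ROI extraction
is accepted as precomputed :class:`PhantomSample` input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .io import CtVolume

__all__ = [
    "PhantomSample",
    "CalibrationModel",
    "LinearCalibration",
    "fit_calibration",
    "apply_calibration",
    "read_samples_csv",
]


@dataclass
class PhantomSample:
    """Mean HU of a rod ROI with its known density."""

    mean_hu: float
    known_density: float  # mg/cc
    n_voxels: int = 1

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if self.known_density < 0:
            raise ValueError("known_density must be >= 0")


@dataclass
class CalibrationModel:
    slope: float  # mg/cc per HU
    intercept: float  # mg/cc
    r_squared: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or self.slope == 0:
            raise ValueError("slope must be finite and nonzero")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")

    def __call__(self, hu: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(hu, float) + self.intercept


class LinearCalibration(BaseEstimator, RegressorMixin):
    """Ordinary least-squares line mapping HU to mg/cc.

    ``fit`` accepts X of shape (n, 1) (or (n,)) mean-HU values and y the
    known rod densities.  Fitted attributes follow sklearn convention.
    """

    def fit(self, X, y) -> "LinearCalibration":
        hu = np.asarray(X, float).reshape(-1)
        dens = np.asarray(y, float).reshape(-1)
        if hu.size != dens.size:
            raise ValueError("X and y lengths differ")
        if np.unique(hu).size < 2:
            raise ValueError(
                "need at least 2 samples with distinct mean HU to fit a line"
            )
        # closed-form normal equations for the univariate line
        mx, my = hu.mean(), dens.mean()
        sxx = float(((hu - mx) ** 2).sum())
        sxy = float(((hu - mx) * (dens - my)).sum())
        slope = sxy / sxx
        intercept = my - slope * mx
        resid = dens - (slope * hu + intercept)
        sst = float(((dens - my) ** 2).sum())
        r2 = 1.0 if sst == 0 else 1.0 - float((resid**2).sum()) / sst
        self.slope_ = slope
        self.intercept_ = intercept
        self.r_squared_ = max(0.0, min(1.0, r2))
        self.model_ = CalibrationModel(self.slope_, self.intercept_, self.r_squared_)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise AttributeError("LinearCalibration is not fitted")
        return self.model_(np.asarray(X, float).reshape(-1))


def fit_calibration(samples: list[PhantomSample]) -> CalibrationModel:
    """Fit the HU -> mg/cc line to phantom rod samples."""
    if len(samples) < 2:
        raise ValueError("need at least 2 phantom samples")
    hu = np.array([s.mean_hu for s in samples], float)
    dens = np.array([s.known_density for s in samples], float)
    return LinearCalibration().fit(hu, dens).model_


def apply_calibration(volume: CtVolume, model: CalibrationModel) -> CtVolume:
    """Convert an HU volume to mg/cc; geometry metadata is unchanged."""
    return volume.with_voxels(model(volume.voxels))


def read_samples_csv(path) -> list[PhantomSample]:
    """Load rod samples from a CSV with columns rod_id, mean_hu,
    known_density_mgcc, n_voxels."""
    df = pd.read_csv(path)
    required = {"mean_hu", "known_density_mgcc"}
    if not required.issubset(df.columns):
        raise ValueError(f"samples CSV must have columns {sorted(required)}")
    n_vox = df["n_voxels"] if "n_voxels" in df.columns else [1] * len(df)
    return [
        PhantomSample(float(h), float(d), int(n))
        for h, d, n in zip(df["mean_hu"], df["known_density_mgcc"], n_vox)
    ]
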