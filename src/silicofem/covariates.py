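"""Areal-BMD surrogate and correlated anthropometric covariates.

Synthetic subjects come out of the atlas with a geometry and a density
field but no anthropometrics.  This module (i) measures an areal bone
mineral density (aBMD) surrogate directly on the model's own density field
by projecting a neck region of interest, and (ii) assigns weight and height
by regression on aBMD with a controlled error variance, so that the
synthetic covariates reproduce a prescribed Pearson correlation with aBMD.

For a simple regression ``y = a + b x + ε`` with independent zero-mean
Gaussian ε, the error variance that yields Pearson correlation r between
y and x is

    Var(ε) = Var(x) · b² · (1 − r²) / r².

The two-predictor (bilinear) height model uses the same construction with
``Var(ŷ)`` — the variance of the fitted values — in place of ``b²·Var(x)``,
which reduces to the formula above in the single-predictor case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RoiBox",
    "neck_roi",
    "compute_abmd",
    "error_variance",
    "CovariateModel",
    "fit_covariate_models",
    "assign_covariates",
]


# ---------------------------------------------------------------------------
# aBMD surrogate


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned region of interest with a projection axis.

    The areal density is the ROI's bone mass divided by the area of the box
    projected along ``projection_axis``.
    """

    lower: tuple[float, float, float]
    upper: tuple[float, float, float]
    projection_axis: int = 1

    def projected_area_mm2(self) -> float:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        ext = hi - lo
        axes = [i for i in range(3) if i != self.projection_axis]
        return float(ext[axes[0]] * ext[axes[1]])


def neck_roi(landmark_coords: np.ndarray, width_factor: float = 0.15) -> RoiBox:
    """Neck ROI box derived from the head-centre and trochanter landmarks.

    Centred midway between the two landmarks, spanning ``width_factor``
    times their distance in the in-plane axes and generously in the
    projection (antero-posterior, y) axis so the whole bone cross-section
    is captured.
    """
    head_centre = np.asarray(landmark_coords[0], dtype=float)
    trochanter = np.asarray(landmark_coords[2], dtype=float)
    centre = 0.5 * (head_centre + trochanter)
    d = float(np.linalg.norm(head_centre - trochanter))
    half = width_factor * d
    lo = centre - np.array([half, 2.0 * d, half])
    hi = centre + np.array([half, 2.0 * d, half])
    return RoiBox(tuple(lo), tuple(hi), projection_axis=1)


def compute_abmd(
    node_coords: np.ndarray,
    tets: np.ndarray,
    rho_app: np.ndarray,
    roi: RoiBox,
) -> float:
    """Areal BMD surrogate in g/cm².

    Sums ρ·V over elements whose centroid lies in the ROI box and divides
    by the box area projected along the ROI's projection axis.  With ρ in
    g/cm³ and the mesh in mm, ``Σ ρV / A`` carries a factor 1/10 to g/cm²
    (a 10 mm slab of 1 g/cm³ projects to 1 g/cm²).
    """
    from . import meshing  # local import to avoid a cycle at module load

    lo = np.asarray(roi.lower)
    hi = np.asarray(roi.upper)
    centroids = node_coords[tets].mean(axis=1)
    inside = np.all((centroids >= lo) & (centroids <= hi), axis=1)
    if not np.any(inside):
        raise ValueError("ROI box does not intersect the mesh")
    vols = meshing.tet_volumes(node_coords, tets)[inside]
    mass = float(np.sum(rho_app[inside] * vols))  # g·mm³/cm³
    return mass / roi.projected_area_mm2() / 10.0


# ---------------------------------------------------------------------------
# regression with controlled error


def error_variance(var_x: float, b: float, r: float) -> float:
    """Error variance giving Pearson correlation ``r`` in ``y = a + b x + ε``."""
    if not (0.0 < r <= 1.0):
        raise ValueError("target correlation r must lie in (0, 1]")
    if var_x < 0:
        raise ValueError("variance must be >= 0")
    return var_x * b * b * (1.0 - r * r) / (r * r)


@dataclass
class CovariateModel:
    """Fitted linear (or bilinear) covariate model with a noise budget."""

    intercept: float
    slopes: np.ndarray  # one entry per predictor
    predictors: tuple[str, ...]
    target_r: float
    error_var: float
    reference_abmd_mean: float = 0.858  # g/cm², young-adult femoral neck
    reference_abmd_sd: float = 0.120

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.atleast_2d(X) @ self.slopes


def _fit_ols(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    design = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("degenerate design matrix: predictors are collinear")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    return float(beta[0]), beta[1:], fitted


def fit_covariate_models(
    cohort_table: pd.DataFrame,
    target_r: float | None = None,
    reference_abmd: tuple[float, float] = (0.858, 0.120),
) -> tuple[CovariateModel, CovariateModel]:
    """Fit ``weight ~ aBMD`` and ``height ~ aBMD + weight`` on a source cohort.

    ``target_r`` defaults to the correlation measured on the source cohort
    (weight model: Pearson r(weight, aBMD); height model: the multiple
    correlation between height and its fitted values).  Error variances for
    covariate assignment follow the controlled-correlation construction.
    """
    required = {"abmd_neck", "weight_kg", "height_cm"}
    missing = required - set(cohort_table.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    if len(cohort_table) < 3:
        raise ValueError("need at least 3 subjects to fit covariate models")
    abmd = cohort_table["abmd_neck"].to_numpy(dtype=float)
    weight = cohort_table["weight_kg"].to_numpy(dtype=float)
    height = cohort_table["height_cm"].to_numpy(dtype=float)

    a_w, b_w, fitted_w = _fit_ols(abmd[:, None], weight)
    resid_w = weight - fitted_w
    if np.var(fitted_w) > 0 and np.var(weight) > 0 and np.var(resid_w) > 1e-12:
        r_w = float(np.corrcoef(weight, abmd)[0, 1])
    else:
        r_w = 1.0  # noiseless / collinear data
    r_w_eff = target_r if target_r is not None else abs(r_w)
    var_eps_w = (
        0.0
        if np.var(resid_w) <= 1e-12 and target_r is None
        else error_variance(float(np.var(abmd)), float(b_w[0]), max(r_w_eff, 1e-6))
    )
    weight_model = CovariateModel(
        intercept=a_w,
        slopes=b_w,
        predictors=("abmd_neck",),
        target_r=r_w_eff,
        error_var=var_eps_w,
        reference_abmd_mean=reference_abmd[0],
        reference_abmd_sd=reference_abmd[1],
    )

    try:
        a_h, b_h, fitted_h = _fit_ols(np.column_stack([abmd, weight]), height)
        h_predictors: tuple[str, ...] = ("abmd_neck", "weight_kg")
    except ValueError:
        # weight exactly linear in aBMD: the second predictor is redundant,
        # fall back to the single-predictor height model
        a_h, b1, fitted_h = _fit_ols(abmd[:, None], height)
        b_h = np.array([b1[0], 0.0])
        h_predictors = ("abmd_neck", "weight_kg")
    resid_h = height - fitted_h
    if np.var(fitted_h) > 0 and np.var(resid_h) > 1e-12:
        r_h = float(np.corrcoef(height, fitted_h)[0, 1])
    else:
        r_h = 1.0
    r_h_eff = target_r if target_r is not None else max(abs(r_h), 1e-6)
    # bilinear analogue: Var(eps) = Var(fitted) (1 - r^2) / r^2
    var_eps_h = (
        0.0
        if np.var(resid_h) <= 1e-12 and target_r is None
        else float(np.var(fitted_h)) * (1.0 - r_h_eff**2) / r_h_eff**2
    )
    height_model = CovariateModel(
        intercept=a_h,
        slopes=b_h,
        predictors=h_predictors,
        target_r=r_h_eff,
        error_var=var_eps_h,
        reference_abmd_mean=reference_abmd[0],
        reference_abmd_sd=reference_abmd[1],
    )
    return weight_model, height_model


def assign_covariates(
    abmd_values: np.ndarray,
    weight_model: CovariateModel,
    height_model: CovariateModel,
    seed: int | None = 0,
    max_retries: int = 100,
) -> pd.DataFrame:
    """Assign weight, height, BMI and T-score to synthetic subjects.

    Weight is drawn from the aBMD regression with Gaussian error of the
    model's controlled variance; height from the bilinear (aBMD, weight)
    model likewise.  Non-physical draws (non-positive weight or height) are
    re-drawn up to ``max_retries`` times and logged.
    """
    rng = np.random.default_rng(seed)
    abmd = np.asarray(abmd_values, dtype=float)
    n = len(abmd)

    def draw(mean: np.ndarray, sd: float) -> np.ndarray:
        x = rng.normal(mean, sd)
        bad = x <= 0
        tries = 0
        while np.any(bad) and tries < max_retries:
            x[bad] = rng.normal(mean[bad], sd)
            bad = x <= 0
            tries += 1
        if np.any(bad):
            logger.warning("%d draws still non-positive after retries", int(bad.sum()))
            x[bad] = np.maximum(mean[bad], 1.0)
        if tries:
            logger.debug("re-drew implausible covariates in %d rounds", tries)
        return x

    w_mean = weight_model.predict(abmd[:, None])
    weight = draw(w_mean, float(np.sqrt(weight_model.error_var)))
    h_mean = height_model.predict(np.column_stack([abmd, weight]))
    height = draw(h_mean, float(np.sqrt(height_model.error_var)))
    bmi = weight / (height / 100.0) ** 2
    t_score = (abmd - weight_model.reference_abmd_mean) / weight_model.reference_abmd_sd
    return pd.DataFrame(
        dict(
            abmd_neck=abmd,
            weight_kg=weight,
            height_cm=height,
            bmi=bmi,
            t_score=t_score,
        ),
        index=pd.RangeIndex(n),
    )
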