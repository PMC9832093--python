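"""Cohort up-sampling by inverse-transform sampling of atlas scores.

Each principal component's training scores define an empirical cumulative
distribution function; its inverse is approximated by piecewise-linear
interpolation over Hazen plotting positions p_i = (i − 0.5)/n.  Uniform
random numbers — restricted by default to the central band (0.025, 0.975),
the ±2 SD band of a Gaussian — are pushed through the inverse CDFs
component by component (PCA scores are mutually uncorrelated, so the
components are sampled independently).  The synthesized subjects are then
reconstructed from the atlas and pass through mesh quality control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree  # noqa: F401  (re-exported for callers)

from . import meshing
from .atlas import AtlasModel, disassemble_vector, reconstruct
from .covariates import CovariateModel, assign_covariates, compute_abmd, neck_roi
from .phantom import (
    LABEL_UNKNOWN,
    Covariates,
    MaterialField,
    MeshTemplate,
    SubjectGeometry,
    SubjectInstance,
)

__all__ = [
    "SamplingConfig",
    "QCResult",
    "empirical_inverse_cdf",
    "sample_component_weights",
    "qc_mesh",
    "synthesize_cohort",
]


@dataclass(frozen=True)
class SamplingConfig:
    n_synthetic: int = 1080
    u_range: tuple[float, float] = (0.025, 0.975)
    seed: int | None = 0
    aspect_threshold: float = 20.0

    def validate(self) -> None:
        low, high = self.u_range
        if not (0.0 <= low < high <= 1.0):
            raise ValueError("u_range must satisfy 0 <= low < high <= 1")
        if self.n_synthetic < 0:
            raise ValueError("n_synthetic must be >= 0")


def empirical_inverse_cdf(scores: np.ndarray, u) -> np.ndarray | float:
    """Piecewise-linear empirical quantile function of one component.

    Sorted scores are paired with Hazen plotting positions
    ``p_i = (i − 0.5)/n``; ``u`` below ``p_1`` or above ``p_n`` clamps to
    the sample minimum/maximum, so sampled values never leave the training
    support.  Monotone non-decreasing in ``u``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score sample")
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr < 0) | (u_arr > 1)):
        raise ValueError("u must lie in [0, 1]")
    s = np.sort(scores)
    n = s.size
    p = (np.arange(1, n + 1) - 0.5) / n
    out = np.interp(u_arr, p, s)  # np.interp clamps outside [p_1, p_n]
    return float(out) if np.isscalar(u) else out


def sample_component_weights(
    atlas: AtlasModel, config: SamplingConfig
) -> np.ndarray:
    """Draw an (n_synthetic, K) score matrix by inverse-transform sampling."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    low, high = config.u_range
    U = rng.uniform(low, high, size=(config.n_synthetic, atlas.n_components))
    W = np.empty_like(U)
    for k in range(atlas.n_components):
        W[:, k] = empirical_inverse_cdf(atlas.training_scores[:, k], U[:, k])
    return W


@dataclass
class QCResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)

    @property
    def status(self) -> str:
        return "pass" if self.passed else "fail:" + ";".join(self.reasons)


def qc_mesh(
    node_coords: np.ndarray,
    tets: np.ndarray,
    aspect_threshold: float = 20.0,
) -> QCResult:
    """Mesh quality control: positive volumes and bounded aspect ratios."""
    reasons = []
    vols = meshing.tet_volumes(node_coords, tets)
    if np.any(vols <= 0):
        reasons.append("non-positive volume")
        ratios = meshing.aspect_ratios(node_coords, tets[vols > 0])
        if ratios.size and np.nanmax(ratios) > aspect_threshold:
            reasons.append("aspect ratio")
    else:
        ratios = meshing.aspect_ratios(node_coords, tets)
        if np.max(ratios) > aspect_threshold:
            reasons.append("aspect ratio")
    return QCResult(passed=not reasons, reasons=reasons)


def synthesize_cohort(
    atlas: AtlasModel,
    score_matrix: np.ndarray,
    template: MeshTemplate,
    covariate_models: tuple[CovariateModel, CovariateModel] | None,
    config: SamplingConfig,
    density_law: tuple[float, float] = (6850.0, 1.49),
    covariate_seed: int | None = None,
) -> tuple[list[SubjectInstance], pd.DataFrame]:
    """Reconstruct synthetic subjects from sampled scores and QC them.

    Each score row is pushed through the atlas, split back into geometry
    and moduli, and converted to a :class:`SubjectInstance`.  Apparent
    density is recovered by inverting the density–modulus power law
    (moduli are floored at a small positive value first, since a linear
    atlas can extrapolate slightly negative moduli).  QC failures are kept
    in the cohort with an explicit status, never dropped silently.
    """
    config.validate()
    score_matrix = np.atleast_2d(np.asarray(score_matrix, dtype=float))
    if score_matrix.shape[1] != atlas.n_components:
        raise ValueError(
            f"score rows have {score_matrix.shape[1]} components, "
            f"atlas has {atlas.n_components}"
        )
    a_law, b_law = density_law
    subjects: list[SubjectInstance] = []
    rows = []
    abmds = np.empty(len(score_matrix))
    for i, w in enumerate(score_matrix):
        vec = reconstruct(atlas, w)
        coords, landmarks, moduli = disassemble_vector(
            vec, atlas.topology, atlas.block_scale
        )
        moduli = np.clip(moduli, 1.0, None)  # MPa floor for solvability
        rho = (moduli / a_law) ** (1.0 / b_law)
        qc = qc_mesh(coords, template.tets, config.aspect_threshold)
        geom = SubjectGeometry(coords, landmarks, degenerate=not qc.passed)
        mats = MaterialField(rho_app=rho, young_modulus=moduli)
        try:
            abmd = compute_abmd(coords, template.tets, rho, neck_roi(landmarks))
        except ValueError:
            abmd = np.nan
            qc = QCResult(False, qc.reasons + ["empty neck ROI"])
        abmds[i] = abmd
        subjects.append(
            SubjectInstance(
                subject_id=f"S{i:04d}",
                pair_id=-1,
                geometry=geom,
                materials=mats,
                covariates=Covariates(np.nan, np.nan, np.nan, np.nan, abmd, np.nan),
                label=LABEL_UNKNOWN,
                qc_status=qc.status,
            )
        )
        rows.append(
            dict(subject_id=f"S{i:04d}", pair_id=-1, label=LABEL_UNKNOWN,
                 age=np.nan, abmd_neck=abmd, qc_status=qc.status)
        )
    table = pd.DataFrame(
        rows,
        columns=["subject_id", "pair_id", "label", "age", "abmd_neck", "qc_status"],
    )
    if covariate_models is not None and len(table):
        wm, hm = covariate_models
        seed = covariate_seed if covariate_seed is not None else config.seed
        filled = np.where(np.isfinite(abmds), abmds, np.nanmean(abmds))
        cov = assign_covariates(filled, wm, hm, seed=seed)
        table["weight_kg"] = cov["weight_kg"]
        table["height_cm"] = cov["height_cm"]
        table["bmi"] = cov["bmi"]
        table["t_score"] = cov["t_score"]
        for subj, (_, row) in zip(subjects, cov.iterrows()):
            subj.covariates.weight_kg = float(row["weight_kg"])
            subj.covariates.height_cm = float(row["height_cm"])
            subj.covariates.bmi = float(row["bmi"])
            subj.covariates.t_score = float(row["t_score"])
    order = [
        "subject_id", "pair_id", "label", "age", "height_cm", "weight_kg",
        "bmi", "abmd_neck", "t_score", "qc_status",
    ]
    for col in order:
        if col not in table.columns:
            table[col] = np.nan
    return subjects, table[order]
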