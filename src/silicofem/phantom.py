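"""Parametric proximal-femur phantom cohorts.

The downstream atlas/expansion/strength machinery only requires a cohort of
*isotopological* subjects: identical mesh connectivity, per-subject node
coordinates, four anatomical landmarks and an element-wise material field.
This module supplies such cohorts synthetically, from a parametric
femur-like solid (spherical head on a tapered neck on a shaft segment,
lateral head offset applied as a volume-preserving shear), so that every
stage of the pipeline can be exercised with known ground truth and without
any imaging data.

Pair matching mirrors a case-control osteoporosis cohort: each fractured
subject shares age, height and weight with a non-fractured control, while
her bone density field is multiplied by a deficit factor below one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.spatial import cKDTree

from . import meshing
from .covariates import compute_abmd, neck_roi

logger = logging.getLogger(__name__)

LABEL_FRACTURED = "fractured"
LABEL_CONTROL = "non-fractured"
LABEL_UNKNOWN = "unknown"


class MeshingError(RuntimeError):
    """Raised when a template parameter combination cannot be meshed."""


# ---------------------------------------------------------------------------
# template


@dataclass(frozen=True)
class TemplateConfig:
    """Geometric and resolution parameters of the phantom template (mm)."""

    head_radius: float = 24.0
    neck_radius: float = 18.0
    shaft_radius: float = 17.0
    trochanter_flare: float = 1.18  # shaft-radius multiplier at the trochanter level
    shaft_length: float = 90.0
    neck_length: float = 26.0
    head_offset: float = 28.0  # lateral offset of the head centre
    knee_distance: float = 360.0  # distal cut -> knee rotation centre
    nx: int = 4
    ny: int = 4
    nz: int = 20

    def validate(self) -> None:
        for name in (
            "head_radius",
            "neck_radius",
            "shaft_radius",
            "trochanter_flare",
            "shaft_length",
            "neck_length",
            "knee_distance",
        ):
            if getattr(self, name) <= 0:
                raise MeshingError(f"template parameter {name!r} must be positive")
        if self.head_offset < 0:
            raise MeshingError("template parameter 'head_offset' must be >= 0")
        if min(self.nx, self.ny, self.nz) < 1:
            raise MeshingError("lattice divisions nx, ny, nz must be >= 1")
        if 6 * self.nx * self.ny * self.nz < 50:
            raise MeshingError(
                "resolution too coarse: target element count "
                f"{6 * self.nx * self.ny * self.nz} < 50"
            )


@dataclass
class MeshTemplate:
    """Reference mesh shared by every subject of a cohort.

    Landmarks, in order: head centre, head-direction point, greater-trochanter
    point, knee rotation centre.
    """

    node_coords: np.ndarray  # (N, 3) mm
    tets: np.ndarray  # (M, 4)
    surface_node_ids: np.ndarray
    landmark_coords: np.ndarray  # (4, 3) mm
    config: TemplateConfig

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_elements(self) -> int:
        return len(self.tets)


def _square_to_disc(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Smooth bijection [-1,1]^2 -> unit disc (elliptical mapping)."""
    return a * np.sqrt(1.0 - 0.5 * b * b), b * np.sqrt(1.0 - 0.5 * a * a)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def make_template(config: TemplateConfig | None = None) -> MeshTemplate:
    """Mesh the parametric proximal-femur solid.

    The solid is a profile of revolution around the axial (z) coordinate —
    shaft, trochanteric flare, tapered neck, spherical head — with the head
    sheared laterally (+x) by ``head_offset``.  A shear leaves the Jacobian
    determinant untouched, so element orientation depends only on the radius
    profile and the square-to-disc map, which keeps all signed volumes
    positive at the supported resolutions.
    """
    cfg = config or TemplateConfig()
    cfg.validate()

    head_length = 1.8 * cfg.head_radius
    L = cfg.shaft_length + cfg.neck_length + head_length
    t_troch = cfg.shaft_length / L
    t_neck = (cfg.shaft_length + cfg.neck_length) / L
    t_head = (cfg.shaft_length + cfg.neck_length + 0.9 * cfg.head_radius) / L

    knots_t = np.array([0.0, t_troch, 0.5 * (t_troch + t_neck), t_neck, t_head, 1.0])
    knots_r = np.array(
        [
            cfg.shaft_radius,
            cfg.shaft_radius * cfg.trochanter_flare,
            cfg.neck_radius,
            1.05 * cfg.neck_radius,
            cfg.head_radius,
            0.45 * cfg.head_radius,
        ]
    )
    radius_of_t = PchipInterpolator(knots_t, knots_r)

    lattice, tets = meshing.structured_unit_lattice(cfg.nx, cfg.ny, cfg.nz)
    a = 2.0 * lattice[:, 0] - 1.0
    b = 2.0 * lattice[:, 1] - 1.0
    t = lattice[:, 2]
    u, v = _square_to_disc(a, b)
    r = radius_of_t(t)
    shear = cfg.head_offset * _smoothstep((t - t_troch) / (t_head - t_troch))
    coords = np.column_stack([r * u + shear, r * v, L * t])

    vols = meshing.tet_volumes(coords, tets)
    if not np.all(vols > 0):
        raise MeshingError(
            "degenerate template: parameter combination produced "
            f"{int(np.sum(vols <= 0))} non-positive tet volumes "
            "(head_offset/neck_radius likely too extreme for the resolution)"
        )

    head_centre = np.array([cfg.head_offset, 0.0, L * t_head])
    landmarks = np.array(
        [
            head_centre,
            head_centre + np.array([0.0, 0.0, 2.0 * cfg.head_radius]),
            [-cfg.shaft_radius * cfg.trochanter_flare, 0.0, L * t_troch],
            [0.0, 0.0, -cfg.knee_distance],
        ]
    )
    return MeshTemplate(
        node_coords=coords,
        tets=tets,
        surface_node_ids=meshing.surface_node_ids(tets),
        landmark_coords=landmarks,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# per-subject deformation


@dataclass
class ShapeParams:
    """Smooth deformation parameters: anisotropic scale + quadratic warp.

    ``warp`` holds dimensionless coefficients of the quadratic monomials
    (x², y², z², xy, yz, xz) of the centred, normalised coordinates, one row
    per displacement component.  All-zero warp and unit scale is the
    identity.
    """

    scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    warp: np.ndarray = field(default_factory=lambda: np.zeros((3, 6)))


@dataclass
class SubjectGeometry:
    """Isotopological node coordinates + landmarks for one subject."""

    node_coords: np.ndarray
    landmark_coords: np.ndarray
    degenerate: bool = False


def draw_shape_params(
    rng: np.random.Generator,
    scale_range: float = 0.06,
    warp_range: float = 0.04,
    axial_scale: float = 1.0,
) -> ShapeParams:
    """Random anatomical variation within configured half-ranges."""
    scale = 1.0 + rng.uniform(-scale_range, scale_range, size=3)
    scale[2] *= axial_scale
    warp = rng.uniform(-warp_range, warp_range, size=(3, 6))
    return ShapeParams(scale=scale, warp=warp)


def deform_instance(
    template: MeshTemplate, shape_params: ShapeParams | None = None
) -> SubjectGeometry:
    """Apply the smooth deformation to nodes and landmarks identically.

    Order of operations: quadratic warp about the mesh centroid, then the
    anisotropic scale about the origin (so a pure uniform scale ``s`` maps
    every coordinate to ``s`` times the template coordinate).  A deformation
    that inverts any element is flagged degenerate, not raised.
    """
    params = shape_params or ShapeParams()

    def transform(points: np.ndarray, centre: np.ndarray, h: float) -> np.ndarray:
        xi = (points - centre) / h
        monomials = np.column_stack(
            [
                xi[:, 0] ** 2,
                xi[:, 1] ** 2,
                xi[:, 2] ** 2,
                xi[:, 0] * xi[:, 1],
                xi[:, 1] * xi[:, 2],
                xi[:, 0] * xi[:, 2],
            ]
        )
        warped = points + h * monomials @ np.asarray(params.warp).T
        return warped * np.asarray(params.scale)

    centre = template.node_coords.mean(axis=0)
    h = float(np.max(np.linalg.norm(template.node_coords - centre, axis=1)))
    coords = transform(template.node_coords, centre, h)
    landmarks = transform(template.landmark_coords, centre, h)
    vols = meshing.tet_volumes(coords, template.tets)
    return SubjectGeometry(
        node_coords=coords,
        landmark_coords=landmarks,
        degenerate=bool(np.any(vols <= 0)),
    )


# ---------------------------------------------------------------------------
# materials


@dataclass(frozen=True)
class DensityParams:
    """Apparent-density field parameters (g/cm³ unless noted).

    The density–modulus power law ``E = a ρ^b`` (MPa) defaults to a widely
    used femoral relation; any monotone law preserves the pipeline's
    structure and both constants are configurable.
    """

    rho_cortical: float = 1.8
    rho_trabecular: float = 0.35
    cortical_thickness: float = 3.6  # mm, band below the surface taken as cortical
    noise_level: float = 0.05  # SD of the smooth random field
    noise_wavelength: float = 30.0  # mm
    n_noise_modes: int = 8
    density_scale: float = 1.0  # per-subject multiplicative scale
    deficit: float = 1.0  # < 1 for fractured members
    modulus_a: float = 6850.0  # MPa at ρ = 1 g/cm³
    modulus_b: float = 1.49

    def validate(self) -> None:
        if not (0.0 < self.deficit <= 1.0):
            raise ValueError("deficit factor must lie in (0, 1]")
        for name in ("rho_cortical", "rho_trabecular", "density_scale", "modulus_a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"density parameter {name!r} must be positive")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")


@dataclass
class MaterialField:
    """Element-wise apparent density (g/cm³) and Young's modulus (MPa)."""

    rho_app: np.ndarray
    young_modulus: np.ndarray


def modulus_from_density(
    rho: np.ndarray, a: float = 6850.0, b: float = 1.49
) -> np.ndarray:
    """Density–modulus power law ``E = a ρ^b`` (MPa)."""
    return a * np.asarray(rho, dtype=float) ** b


def assign_materials(
    template: MeshTemplate,
    geometry: SubjectGeometry,
    params: DensityParams,
    rng: np.random.Generator,
) -> MaterialField:
    """Cortical shell / trabecular core density plus a smooth random field.

    Elements whose centroid lies within ``cortical_thickness`` of the
    surface receive the cortical density, interior elements the trabecular
    one.  A smooth zero-mean random field (a handful of random cosine modes
    at the configured wavelength) is added, negative values are clipped to
    zero, and the whole field is multiplied by ``density_scale * deficit``
    so the fracture deficit acts multiplicatively on the entire field.
    """
    params.validate()
    coords = geometry.node_coords
    centroids = coords[template.tets].mean(axis=1)
    surf = coords[template.surface_node_ids]
    dist, _ = cKDTree(surf).query(centroids)
    base = np.where(
        dist < params.cortical_thickness, params.rho_cortical, params.rho_trabecular
    )

    k = 2.0 * np.pi / params.noise_wavelength
    n_modes = params.n_noise_modes
    dirs = rng.normal(size=(n_modes, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_modes)
    amps = rng.normal(size=n_modes)
    waves = np.cos(k * centroids @ dirs.T + phases)  # (M, n_modes)
    noise = params.noise_level * (waves @ amps) / np.sqrt(0.5 * n_modes)

    rho = base + noise
    n_clipped = int(np.sum(rho < 0))
    if n_clipped:
        logger.warning("clipped %d negative element densities to zero", n_clipped)
        rho = np.clip(rho, 0.0, None)
    rho = rho * params.density_scale * params.deficit
    return MaterialField(
        rho_app=rho,
        young_modulus=modulus_from_density(rho, params.modulus_a, params.modulus_b),
    )


# ---------------------------------------------------------------------------
# cohort


@dataclass
class Covariates:
    age: float
    height_cm: float
    weight_kg: float
    bmi: float
    abmd_neck: float
    t_score: float


@dataclass
class SubjectInstance:
    subject_id: str
    pair_id: int
    geometry: SubjectGeometry
    materials: MaterialField
    covariates: Covariates
    label: str = LABEL_UNKNOWN
    qc_status: str = "pass"


@dataclass(frozen=True)
class CohortConfig:
    """Generating distributions of the pair-matched phantom cohort.

    The covariate marginals default to the summary statistics of a
    94-subject post-menopausal case-control population (age 75 ± 9 y,
    height 158 ± 6 cm, weight 63.6 ± 13.4 kg); pairs share age, height and
    weight, and the fractured member's density field is multiplied by a
    deficit drawn from ``deficit_range``.
    """

    template: TemplateConfig = field(default_factory=TemplateConfig)
    density: DensityParams = field(default_factory=DensityParams)
    age_mean: float = 75.0
    age_sd: float = 9.0
    age_range: tuple[float, float] = (55.0, 91.0)
    height_mean: float = 158.0
    height_sd: float = 6.0
    height_range: tuple[float, float] = (145.0, 173.0)
    weight_mean: float = 63.6
    weight_sd: float = 13.4
    weight_range: tuple[float, float] = (31.0, 101.0)
    weight_abmd_r: float = 0.4  # Pearson correlation weight ~ aBMD
    density_scale_sd: float = 0.08
    deficit_range: tuple[float, float] = (0.72, 0.90)
    scale_range: float = 0.06
    warp_range: float = 0.04
    tscore_ref_mean: float = 0.858  # g/cm², young-adult femoral-neck reference
    tscore_ref_sd: float = 0.120


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def generate_paired_cohort(
    n_pairs: int,
    config: CohortConfig | None = None,
    seed: int | None = 0,
) -> tuple[list[SubjectInstance], pd.DataFrame, MeshTemplate]:
    """Generate ``2 n_pairs`` subjects as fractured/control matched pairs.

    Within each pair, age, height and weight are identical; the fractured
    member's density field carries a multiplicative deficit.  Weights are
    drawn correlated with the control member's areal BMD (target Pearson r
    from the config), which lets the covariate regression stage recover a
    realistic weight–aBMD relation from the cohort table.

    Returns the subject list, the cohort table and the shared template.
    Identical ``(config, seed)`` reproduce the cohort bitwise.
    """
    cfg = config or CohortConfig()
    template = make_template(cfg.template)
    ss = np.random.SeedSequence(seed)
    pair_seeds = ss.spawn(max(n_pairs, 1))

    subjects: list[SubjectInstance] = []
    pair_info = []
    for p in range(n_pairs):
        rng = np.random.default_rng(pair_seeds[p])
        age = _truncated_normal(rng, cfg.age_mean, cfg.age_sd, *cfg.age_range)
        height = _truncated_normal(
            rng, cfg.height_mean, cfg.height_sd, *cfg.height_range
        )
        eta_w = rng.normal()
        scale_ctrl = max(float(rng.normal(1.0, cfg.density_scale_sd)), 0.4)
        deficit = float(rng.uniform(*cfg.deficit_range))
        members = []
        for label in (LABEL_CONTROL, LABEL_FRACTURED):
            shape = draw_shape_params(
                rng,
                scale_range=cfg.scale_range,
                warp_range=cfg.warp_range,
                axial_scale=height / cfg.height_mean,
            )
            geom = deform_instance(template, shape)
            dens = replace(
                cfg.density,
                density_scale=scale_ctrl,
                deficit=deficit if label == LABEL_FRACTURED else 1.0,
            )
            mats = assign_materials(template, geom, dens, rng)
            roi = neck_roi(geom.landmark_coords)
            abmd = compute_abmd(geom.node_coords, template.tets, mats.rho_app, roi)
            members.append((label, geom, mats, abmd))
        pair_info.append((age, height, eta_w, members))

    # weights correlated with the control member's aBMD: standardise the
    # control aBMDs empirically, then w = mu + r sd z + sqrt(1-r^2) sd eta
    ctrl_abmd = np.array([info[3][0][3] for info in pair_info]) if n_pairs else np.array([])
    if n_pairs >= 2 and np.std(ctrl_abmd) > 0:
        z = (ctrl_abmd - ctrl_abmd.mean()) / ctrl_abmd.std()
    else:
        z = np.zeros(n_pairs)
    r = cfg.weight_abmd_r

    rows = []
    for p, (age, height, eta_w, members) in enumerate(pair_info):
        weight = cfg.weight_mean + cfg.weight_sd * (
            r * z[p] + np.sqrt(1.0 - r * r) * eta_w
        )
        weight = float(np.clip(weight, *cfg.weight_range))
        bmi = weight / (height / 100.0) ** 2
        for label, geom, mats, abmd in members:
            sid = f"P{p:03d}{'F' if label == LABEL_FRACTURED else 'C'}"
            t_score = (abmd - cfg.tscore_ref_mean) / cfg.tscore_ref_sd
            qc = "fail:non-positive volume" if geom.degenerate else "pass"
            cov = Covariates(age, height, weight, bmi, abmd, t_score)
            subjects.append(
                SubjectInstance(sid, p, geom, mats, cov, label=label, qc_status=qc)
            )
            rows.append(
                dict(
                    subject_id=sid,
                    pair_id=p,
                    label=label,
                    age=age,
                    height_cm=height,
                    weight_kg=weight,
                    bmi=bmi,
                    abmd_neck=abmd,
                    t_score=t_score,
                    qc_status=qc,
                )
            )
    columns = [
        "subject_id",
        "pair_id",
        "label",
        "age",
        "height_cm",
        "weight_kg",
        "bmi",
        "abmd_neck",
        "t_score",
        "qc_status",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return subjects, table, template
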