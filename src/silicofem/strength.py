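"""Side-fall femoral strength via a linear-elastic FE surrogate.

A full side-fall simulation uses non-linear frictionless contact against a
rigid plane and a knee hinge.  Here that boundary-value problem is replaced
by a *linear* surrogate that preserves the strain-criterion and
orientation-grid logic while making 28 load cases per subject run in well
under a second: constant-strain 4-node tetrahedra, a distributed load on
the femoral-head surface nodes, the distal shaft band pinned (hinge
stand-in), and the surface patch furthest along the load direction
constrained against motion along that direction (contact stand-in, imposed
by penalty).

Failure for a given orientation is the load magnitude at which the
3 mm-sphere-averaged principal surface strain first reaches the tensile
limit 0.73% or the compressive limit 1.04%, whichever comes first.  Since
the model is linear, strains scale with the applied magnitude and the
failure load is obtained in closed form from a single unit solve per
orientation.  The minimum over the 7 × 4 orientation grid (antero-posterior
−30°..30°, medio-lateral 0°..30°, 10° steps) is the minimum side-fall
strength (MSF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from . import meshing

__all__ = [
    "StrengthConfig",
    "LoadCase",
    "FailureLoadGrid",
    "FESystem",
    "SolverFailure",
    "assemble_system",
    "solve_case",
    "element_strain_tensors",
    "load_direction_grid",
    "averaged_principal_strains",
    "failure_load",
    "failure_surface",
]


class SolverFailure(RuntimeError):
    """Linear system could not be solved (flagged as a QC failure upstream)."""


@dataclass(frozen=True)
class StrengthConfig:
    magnitude: float = 1000.0  # N, trial load
    poisson: float = 0.3
    tensile_limit: float = 0.0073  # principal tensile strain at failure
    compressive_limit: float = 0.0104  # |principal compressive strain| at failure
    averaging_radius: float = 3.0  # mm, spherical strain averaging
    ap_angles: tuple[int, ...] = (-30, -20, -10, 0, 10, 20, 30)
    ml_angles: tuple[int, ...] = (0, 10, 20, 30)
    distal_band: float = 6.0  # mm, pinned band at the distal cut
    support_depth: float = 5.0  # mm, depth of the lateral support patch
    head_capture: float = 1.35  # capture radius / min head-surface distance
    exclusion_radius: float = 8.0  # mm around BC/load nodes excluded from criterion
    distal_criterion_margin: float = 15.0  # mm below the trochanter level
    penalty_factor: float = 1e8


@dataclass(frozen=True)
class LoadCase:
    ap_angle: float
    ml_angle: float
    direction: np.ndarray  # unit vector


@dataclass
class FailureLoadGrid:
    ap_angles: np.ndarray
    ml_angles: np.ndarray
    loads: np.ndarray  # (n_ap, n_ml), N

    @property
    def msf(self) -> float:
        """Minimum side-fall strength: the grid minimum."""
        return float(np.min(self.loads))


# ---------------------------------------------------------------------------
# element core


def _shape_gradients(coords: np.ndarray, tets: np.ndarray):
    """Per-element shape-function gradients and volumes for CST tets."""
    p = coords[tets]  # (M, 4, 3)
    J = p[:, 1:] - p[:, :1]  # rows: edge vectors from node 0
    vol = np.linalg.det(J) / 6.0
    Jinv = np.linalg.inv(J)
    # x = p0 + lambda @ J  =>  d(lambda_i)/d(x_j) = (J^{-1})_{ji}:
    # grad(lambda_i) is column i of J^{-1}
    g123 = np.swapaxes(Jinv, 1, 2)  # (M, 3, 3)
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)  # (M, 4, 3)
    return grads, vol


def _b_matrices(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices, engineering-shear Voigt order
    (xx, yy, zz, xy, yz, xz)."""
    M = grads.shape[0]
    B = np.zeros((M, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    return B


def _elasticity(E: np.ndarray, nu: float) -> np.ndarray:
    """Isotropic elasticity matrices (M, 6, 6) for engineering shear."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((len(E), 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] += 2 * mu
        D[:, 3 + i, 3 + i] = mu
    return D


@dataclass
class FESystem:
    """Assembled stiffness plus the element operators needed for strains."""

    coords: np.ndarray
    tets: np.ndarray
    K: sparse.csr_matrix
    B: np.ndarray  # (M, 6, 12)
    volumes: np.ndarray
    centroids: np.ndarray

    @property
    def n_dof(self) -> int:
        return 3 * len(self.coords)


def assemble_system(
    coords: np.ndarray, tets: np.ndarray, E: np.ndarray, nu: float = 0.3
) -> FESystem:
    """Assemble the global stiffness for linear tetrahedral elasticity."""
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise ValueError("Young's moduli must be positive for the solve")
    grads, vol = _shape_gradients(coords, tets)
    if np.any(vol <= 0):
        raise SolverFailure("mesh contains non-positive element volumes")
    B = _b_matrices(grads)
    D = _elasticity(E, nu)
    Ke = np.einsum("mji,mjk,mkl,m->mil", B, D, B, vol)  # (M, 12, 12)
    dof = (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K = sparse.coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(3 * len(coords), 3 * len(coords))
    ).tocsr()
    centroids = coords[tets].mean(axis=1)
    return FESystem(coords=coords, tets=tets, K=K, B=B, volumes=vol,
                    centroids=centroids)


def solve_case(
    system: FESystem,
    forces: np.ndarray,
    pinned_nodes: np.ndarray,
    directional_constraints: tuple[np.ndarray, np.ndarray] | None = None,
    penalty_factor: float = 1e8,
) -> np.ndarray:
    """Solve K u = f with pinned nodes (eliminated) and optional
    single-direction constraints (penalty).

    ``directional_constraints`` is ``(node_ids, direction)``: each listed
    node is restrained against motion along the unit ``direction``.
    Returns the full displacement vector (zero at pinned dofs).
    """
    ndof = system.n_dof
    f = np.asarray(forces, dtype=float).reshape(ndof)
    K = system.K
    if directional_constraints is not None:
        nodes, d = directional_constraints
        d = np.asarray(d, dtype=float)
        d = d / np.linalg.norm(d)
        pen = penalty_factor * K.diagonal().max()
        block = pen * np.outer(d, d)
        dof = (3 * np.asarray(nodes)[:, None] + np.arange(3)).astype(int)
        rows = np.repeat(dof, 3, axis=1).ravel()
        cols = np.tile(dof, (1, 3)).ravel()
        K = K + sparse.coo_matrix(
            (np.tile(block.ravel(), len(nodes)), (rows, cols)), shape=K.shape
        ).tocsr()
    fixed = (3 * np.asarray(pinned_nodes, dtype=int)[:, None] + np.arange(3)).ravel()
    free = np.setdiff1d(np.arange(ndof), fixed)
    try:
        lu = splu(K[free][:, free].tocsc())
        u_free = lu.solve(f[free])
    except RuntimeError as exc:  # singular factorization
        raise SolverFailure(str(exc)) from exc
    if not np.all(np.isfinite(u_free)):
        raise SolverFailure("non-finite displacements")
    u = np.zeros(ndof)
    u[free] = u_free
    return u


def element_strain_tensors(system: FESystem, u: np.ndarray) -> np.ndarray:
    """Per-element symmetric strain tensors (M, 3, 3) from displacements."""
    ue = u.reshape(-1, 3)[system.tets].reshape(len(system.tets), 12)
    voigt = np.einsum("mij,mj->mi", system.B, ue)  # engineering shear
    T = np.empty((len(voigt), 3, 3))
    T[:, 0, 0] = voigt[:, 0]
    T[:, 1, 1] = voigt[:, 1]
    T[:, 2, 2] = voigt[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = 0.5 * voigt[:, 3]
    T[:, 1, 2] = T[:, 2, 1] = 0.5 * voigt[:, 4]
    T[:, 0, 2] = T[:, 2, 0] = 0.5 * voigt[:, 5]
    return T


# ---------------------------------------------------------------------------
# orientation grid


def _local_frame(landmarks: np.ndarray):
    """Right-handed local frame from the landmarks.

    z: superior axis (head centre -> head-direction point);
    x: lateral axis (component of head centre -> trochanter orthogonal to z);
    y = z × x: antero-posterior axis.
    """
    hc, hd, gt, _ = np.asarray(landmarks, dtype=float)
    z = hd - hc
    z = z / np.linalg.norm(z)
    lat = gt - hc
    lat = lat - (lat @ z) * z
    x = lat / np.linalg.norm(lat)
    y = np.cross(z, x)
    return x, y, z


_CANONICAL_LANDMARKS = np.array(
    [[40.0, 0.0, 146.0], [40.0, 0.0, 192.0], [-17.0, 0.0, 90.0], [0.0, 0.0, -360.0]]
)


def reference_fall_axis(landmarks: np.ndarray) -> np.ndarray:
    """Zero-angle load direction: from the head centre toward the trochanter."""
    hc, _, gt, _ = np.asarray(landmarks, dtype=float)
    d = gt - hc
    return d / np.linalg.norm(d)


def load_direction_grid(
    landmarks: np.ndarray | None = None,
    ap_angles: tuple[int, ...] = (-30, -20, -10, 0, 10, 20, 30),
    ml_angles: tuple[int, ...] = (0, 10, 20, 30),
) -> list[LoadCase]:
    """The 7 × 4 side-fall orientation grid (28 load cases).

    Convention: the reference axis (head centre toward greater trochanter)
    is first rotated by the antero-posterior angle about the lateral (x)
    axis, then by the medio-lateral angle about the antero-posterior (y)
    axis, both in the subject's local frame.
    """
    lms = _CANONICAL_LANDMARKS if landmarks is None else np.asarray(landmarks)
    x, y, _ = _local_frame(lms)
    d0 = reference_fall_axis(lms)
    cases = []
    for ap in ap_angles:
        for ml in ml_angles:
            rot = Rotation.from_rotvec(np.deg2rad(ml) * y) * Rotation.from_rotvec(
                np.deg2rad(ap) * x
            )
            d = rot.apply(d0)
            cases.append(
                LoadCase(ap_angle=float(ap), ml_angle=float(ml),
                         direction=d / np.linalg.norm(d))
            )
    return cases


# ---------------------------------------------------------------------------
# failure criterion


def averaged_principal_strains(
    tensors: np.ndarray,
    centroids: np.ndarray,
    points: np.ndarray,
    radius: float = 3.0,
    neighbor_lists: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sphere-averaged principal strains at the given surface points.

    For every point, the strain *tensors* of elements whose centroid lies
    within ``radius`` are averaged first, then the principal values of the
    averaged tensor are taken (tensor-first averaging).  A point with no
    centroid in its sphere — including the degenerate ``radius = 0`` — gets
    its nearest element's tensor.  Returns (ε1, ε3): the maximum (tensile)
    and minimum (compressive) principal strains per point.
    """
    if radius < 0:
        raise ValueError("averaging radius must be >= 0")
    tree = cKDTree(centroids)
    if neighbor_lists is None:
        neighbor_lists = strain_neighbors(centroids, points, radius)
    avg = np.empty((len(points), 3, 3))
    nearest = None
    for i, idx in enumerate(neighbor_lists):
        if len(idx) == 0:
            if nearest is None:
                _, nearest = tree.query(points)
            avg[i] = tensors[nearest[i]]
        else:
            avg[i] = tensors[idx].mean(axis=0)
    principal = np.linalg.eigvalsh(avg)  # ascending
    return principal[:, 2], principal[:, 0]


def strain_neighbors(
    centroids: np.ndarray, points: np.ndarray, radius: float
) -> list[np.ndarray]:
    """Element-centroid neighbour lists reused across the 28 load cases."""
    if radius == 0:
        return [np.empty(0, dtype=int) for _ in range(len(points))]
    tree = cKDTree(centroids)
    return [np.asarray(ix, dtype=int) for ix in
            tree.query_ball_point(points, radius)]


def failure_load(
    eps1: np.ndarray,
    eps3: np.ndarray,
    applied_magnitude: float = 1000.0,
    tensile_limit: float = 0.0073,
    compressive_limit: float = 0.0104,
) -> float:
    """Failure load from a linear solve at ``applied_magnitude``.

    Per node the limiting scale is ``min(t_lim/ε1, c_lim/|ε3|)`` over the
    active sides (tension only if ε1 > 0, compression only if ε3 < 0); the
    failure load is the applied magnitude times the minimum scale over all
    nodes — linearity makes strains proportional to load, so the first
    limit reached anywhere defines failure.
    """
    eps1 = np.asarray(eps1, dtype=float)
    eps3 = np.asarray(eps3, dtype=float)
    with np.errstate(divide="ignore"):
        t_scale = np.where(eps1 > 0, tensile_limit / eps1, np.inf)
        c_scale = np.where(eps3 < 0, compressive_limit / (-eps3), np.inf)
    node_scale = np.minimum(t_scale, c_scale)
    s = np.min(node_scale)
    if not np.isfinite(s):
        raise ValueError("unloaded surface: all averaged strains are zero")
    return float(applied_magnitude * s)


# ---------------------------------------------------------------------------
# per-subject orientation sweep


def failure_surface(
    coords: np.ndarray,
    tets: np.ndarray,
    young_modulus: np.ndarray,
    landmarks: np.ndarray,
    surface_ids: np.ndarray,
    config: StrengthConfig | None = None,
) -> FailureLoadGrid:
    """Failure loads over the full orientation grid for one subject.

    Node sets: the distal pinned band is the ``distal_band`` mm of surface
    nodes at the bottom of the shaft along the superior axis; the head load
    is spread evenly over surface nodes within ``head_capture`` times the
    minimum head-centre-to-surface distance; the per-case support patch is
    the ``support_depth`` mm of surface nodes furthest along the load
    direction.  The failure criterion is evaluated on the proximal surface
    only (above the trochanter level minus ``distal_criterion_margin``) and
    surface nodes within ``exclusion_radius`` of any constrained or loaded
    node are excluded, so the surrogate's artificial boundary
    concentrations — in particular the clamped distal cut, which carries
    the peak cantilever moment — cannot define failure.  Raises
    :class:`SolverFailure` on a singular system.
    """
    cfg = config or StrengthConfig()
    system = assemble_system(coords, tets, young_modulus, cfg.poisson)
    surface_ids = np.asarray(surface_ids, dtype=int)
    surf = coords[surface_ids]
    _, _, z_axis = _local_frame(landmarks)
    hc = np.asarray(landmarks[0], dtype=float)

    proj_z = surf @ z_axis
    pinned = surface_ids[proj_z <= proj_z.min() + cfg.distal_band]

    head_dist = np.linalg.norm(surf - hc, axis=1)
    capture = cfg.head_capture * head_dist.min()
    head_mask = head_dist <= capture
    if head_mask.sum() < 6:
        head_mask = np.zeros_like(head_mask)
        head_mask[np.argsort(head_dist)[:6]] = True
    head_nodes = surface_ids[head_mask]

    cases = load_direction_grid(landmarks, cfg.ap_angles, cfg.ml_angles)
    neighbor_lists = strain_neighbors(system.centroids, surf, cfg.averaging_radius)
    surf_tree = cKDTree(surf)

    base_excluded = np.zeros(len(surf), dtype=bool)
    fixed_pts = np.vstack([coords[pinned], coords[head_nodes]])
    for ix in surf_tree.query_ball_point(fixed_pts, cfg.exclusion_radius):
        base_excluded[ix] = True
    # restrict the criterion to the proximal region (head, neck, trochanter):
    # the clamped distal shaft carries the surrogate's artificial peak moment
    trochanter_level = float(np.asarray(landmarks[2]) @ z_axis)
    base_excluded |= proj_z < trochanter_level - cfg.distal_criterion_margin

    loads = np.full((len(cfg.ap_angles), len(cfg.ml_angles)), np.nan)
    for case in cases:
        d = case.direction
        proj_d = surf @ d
        support_mask = proj_d >= proj_d.max() - cfg.support_depth
        support = surface_ids[support_mask]

        f = np.zeros(system.n_dof)
        per_node = cfg.magnitude / len(head_nodes)
        f.reshape(-1, 3)[head_nodes] += per_node * d
        u = solve_case(
            system,
            f,
            pinned_nodes=pinned,
            directional_constraints=(support, d),
            penalty_factor=cfg.penalty_factor,
        )
        tensors = element_strain_tensors(system, u)

        excluded = base_excluded.copy()
        for ix in surf_tree.query_ball_point(coords[support], cfg.exclusion_radius):
            excluded[ix] = True
        keep = ~excluded
        if not np.any(keep):
            keep = np.ones(len(surf), dtype=bool)
        eps1, eps3 = averaged_principal_strains(
            tensors,
            system.centroids,
            surf[keep],
            cfg.averaging_radius,
            [neighbor_lists[i] for i in np.flatnonzero(keep)],
        )
        fl = failure_load(
            eps1, eps3, cfg.magnitude, cfg.tensile_limit, cfg.compressive_limit
        )
        i = cfg.ap_angles.index(int(case.ap_angle))
        j = cfg.ml_angles.index(int(case.ml_angle))
        loads[i, j] = fl
    return FailureLoadGrid(
        ap_angles=np.asarray(cfg.ap_angles, dtype=float),
        ml_angles=np.asarray(cfg.ml_angles, dtype=float),
        loads=loads,
    )
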