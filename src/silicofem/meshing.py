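"""Low-level linear tetrahedral mesh utilities.

Every mesh in this package is an (N, 3) float array of node coordinates in
millimetres plus an (M, 4) integer array of tetrahedron node indices.
Structured solids are produced by mapping a regular hexahedral lattice
through a smooth orientation-preserving map and splitting each cell into
six tetrahedra (Kuhn/Freudenthal subdivision).  Using the identical split
in every cell makes the subdivision conforming, so the image mesh is
watertight by construction.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "tet_volumes",
    "boundary_faces",
    "surface_node_ids",
    "is_closed_surface",
    "aspect_ratios",
    "structured_unit_lattice",
    "box_mesh",
]


def tet_volumes(coords: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volume of each tetrahedron (positive for right-handed ordering)."""
    a, b, c, d = (coords[tets[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


def boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Triangular faces that belong to exactly one tetrahedron."""
    face_ix = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    faces = tets[:, face_ix].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def surface_node_ids(tets: np.ndarray) -> np.ndarray:
    """Sorted ids of nodes lying on the boundary faces of the mesh."""
    return np.unique(boundary_faces(tets))


def is_closed_surface(tets: np.ndarray) -> bool:
    """True when every boundary edge is shared by exactly two boundary faces."""
    faces = boundary_faces(tets)
    if len(faces) == 0:
        return False
    edges = np.sort(faces[:, [(0, 1), (1, 2), (0, 2)]].reshape(-1, 2), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool(np.all(counts == 2))


def aspect_ratios(coords: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Longest edge over (2 sqrt(6) r_in); equals 1 for a regular tetrahedron.

    ``r_in = 3 V / A_total`` is the inradius.  Degenerate elements (zero or
    negative volume) get ``inf``.
    """
    p = coords[tets]  # (M, 4, 3)
    pairs = list(itertools.combinations(range(4), 2))
    edge_len = np.linalg.norm(
        p[:, [i for i, _ in pairs]] - p[:, [j for _, j in pairs]], axis=2
    )
    longest = edge_len.max(axis=1)
    vol = tet_volumes(coords, tets)
    face_ix = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    area = 0.0
    areas = np.zeros(len(tets))
    for i, j, k in face_ix:
        areas += 0.5 * np.linalg.norm(
            np.cross(p[:, j] - p[:, i], p[:, k] - p[:, i]), axis=1
        )
    del area
    with np.errstate(divide="ignore", invalid="ignore"):
        r_in = np.where(vol > 0, 3.0 * vol / areas, 0.0)
        ratio = np.where(r_in > 0, longest / (2.0 * np.sqrt(6.0) * r_in), np.inf)
    return ratio


# The six tetrahedra of the Kuhn subdivision of the unit cube: each follows a
# monotone vertex path (0,0,0) -> +e_a -> +e_b -> +e_c for a permutation
# (a, b, c) of the axes.  Odd permutations get their last two vertices swapped
# so that every tetrahedron is positively oriented.
def _kuhn_offsets() -> np.ndarray:
    eye = np.eye(3, dtype=int)
    tets = []
    for perm in itertools.permutations(range(3)):
        v0 = np.zeros(3, dtype=int)
        v1 = v0 + eye[perm[0]]
        v2 = v1 + eye[perm[1]]
        v3 = v2 + eye[perm[2]]
        sign = np.linalg.det(eye[list(perm)])
        if sign < 0:
            v2, v3 = v3, v2
        tets.append([v0, v1, v2, v3])
    return np.asarray(tets)  # (6, 4, 3)


_KUHN = _kuhn_offsets()


def structured_unit_lattice(nx: int, ny: int, nz: int) -> tuple[np.ndarray, np.ndarray]:
    """Regular lattice on the unit cube split into ``6 nx ny nz`` tetrahedra.

    Returns ``(coords, tets)`` with coords in ``[0, 1]^3`` and all signed
    volumes positive.
    """
    if min(nx, ny, nz) < 1:
        raise ValueError("lattice divisions must be >= 1")
    gx = np.linspace(0.0, 1.0, nx + 1)
    gy = np.linspace(0.0, 1.0, ny + 1)
    gz = np.linspace(0.0, 1.0, nz + 1)
    X, Y, Z = np.meshgrid(gx, gy, gz, indexing="ij")
    coords = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def node_id(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    ci, cj, ck = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    origins = np.stack([ci.ravel(), cj.ravel(), ck.ravel()], axis=1)  # (C, 3)
    # (C, 6, 4, 3) lattice indices of all tet vertices
    verts = origins[:, None, None, :] + _KUHN[None, :, :, :]
    tets = node_id(verts[..., 0], verts[..., 1], verts[..., 2]).reshape(-1, 4)
    return coords, tets


def box_mesh(
    lengths: tuple[float, float, float], divisions: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned box ``[0, lx] x [0, ly] x [0, lz]`` meshed with tets."""
    coords, tets = structured_unit_lattice(*divisions)
    return coords * np.asarray(lengths, dtype=float), tets
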