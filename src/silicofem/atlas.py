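"""Combined statistical shape-and-appearance atlas (PCA).

Each subject of an isotopological cohort is flattened into a single vector:
node coordinates (x, y, z interleaved, node order), then the four landmark
points, then the element-wise Young's moduli multiplied by ``block_scale``.
Principal component analysis of the n stacked vectors (mean-centred, no
per-feature standardisation) yields the atlas: a mean vector, orthonormal
variation modes, per-mode variances, and the component scores of the
training subjects.  With n subjects the atlas carries at most n − 1
components; components with variance below 1e-12 of the leading one are
dropped as numerical noise.

The PCA is computed by thin SVD of the centred n × p matrix, which for
p ≫ n is equivalent to the eigendecomposition of the n × n Gram matrix and
never forms the p × p covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np

__all__ = [
    "AtlasTopology",
    "AtlasModel",
    "vector_length",
    "assemble_vector",
    "disassemble_vector",
    "build_atlas",
    "explained_variance",
    "reconstruct",
    "save_atlas",
    "load_atlas",
]

_EIGENVALUE_FLOOR_REL = 1e-12


@dataclass(frozen=True)
class AtlasTopology:
    n_nodes: int
    n_landmarks: int
    n_elements: int

    @property
    def shape_len(self) -> int:
        return 3 * (self.n_nodes + self.n_landmarks)


def vector_length(topology: AtlasTopology) -> int:
    """Length of the combined shape+appearance vector."""
    return topology.shape_len + topology.n_elements


def assemble_vector(
    node_coords: np.ndarray,
    landmark_coords: np.ndarray,
    young_modulus: np.ndarray,
    topology: AtlasTopology,
    block_scale: float = 1.0,
) -> np.ndarray:
    """Flatten one subject into the combined vector.

    Raises on any topology mismatch, naming the offending counts.
    """
    node_coords = np.asarray(node_coords, dtype=float)
    landmark_coords = np.asarray(landmark_coords, dtype=float)
    young_modulus = np.asarray(young_modulus, dtype=float)
    if node_coords.shape != (topology.n_nodes, 3):
        raise ValueError(
            f"node count mismatch: got {node_coords.shape}, "
            f"expected ({topology.n_nodes}, 3)"
        )
    if landmark_coords.shape != (topology.n_landmarks, 3):
        raise ValueError(
            f"landmark count mismatch: got {landmark_coords.shape}, "
            f"expected ({topology.n_landmarks}, 3)"
        )
    if young_modulus.shape != (topology.n_elements,):
        raise ValueError(
            f"element count mismatch: got {young_modulus.shape}, "
            f"expected ({topology.n_elements},)"
        )
    return np.concatenate(
        [node_coords.ravel(), landmark_coords.ravel(), block_scale * young_modulus]
    )


def disassemble_vector(
    vector: np.ndarray, topology: AtlasTopology, block_scale: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`assemble_vector` (exact round trip at scale 1)."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (vector_length(topology),):
        raise ValueError(
            f"vector length {vector.shape} does not match topology "
            f"({vector_length(topology)},)"
        )
    n3 = 3 * topology.n_nodes
    l3 = 3 * topology.n_landmarks
    coords = vector[:n3].reshape(topology.n_nodes, 3)
    landmarks = vector[n3 : n3 + l3].reshape(topology.n_landmarks, 3)
    moduli = vector[n3 + l3 :] / block_scale
    return coords, landmarks, moduli


@dataclass
class AtlasModel:
    """Mean, modes, variances and training scores of the combined PCA."""

    mean: np.ndarray  # (p,)
    modes: np.ndarray  # (p, K), orthonormal columns
    eigenvalues: np.ndarray  # (K,), descending
    training_scores: np.ndarray  # (n, K), one row per training subject
    block_scale: float
    topology: AtlasTopology

    @property
    def n_components(self) -> int:
        return self.modes.shape[1]

    @property
    def n_training(self) -> int:
        return self.training_scores.shape[0]


def build_atlas(
    vectors: np.ndarray,
    topology: AtlasTopology,
    block_scale: float = 1.0,
    equalize_blocks: bool = False,
) -> AtlasModel:
    """Fit the PCA atlas from an (n, p) matrix of assembled vectors.

    ``vectors`` must already carry the appearance block scaled by
    ``block_scale`` (as produced by :func:`assemble_vector`).  With
    ``equalize_blocks`` the appearance block is re-scaled so that the two
    blocks contribute equal total centred variance before the PCA; the
    effective scale is stored on the model so reconstruction undoes it.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 subject vectors")
    if X.shape[1] != vector_length(topology):
        raise ValueError(
            f"vector length {X.shape[1]} does not match topology "
            f"({vector_length(topology)})"
        )
    n = X.shape[0]
    if equalize_blocks:
        s = topology.shape_len
        var_shape = float(np.sum(np.var(X[:, :s], axis=0)))
        var_app = float(np.sum(np.var(X[:, s:], axis=0)))
        if var_app > 0 and var_shape > 0:
            factor = np.sqrt(var_shape / var_app)
            X = X.copy()
            X[:, s:] *= factor
            block_scale = block_scale * factor

    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = S**2 / (n - 1)
    # relative to the data magnitude, so identical-up-to-rounding inputs
    # are recognised as zero-variance
    data_scale = float(np.mean(mean**2))
    if eigenvalues[0] <= 1e-24 * max(data_scale, 1e-300):
        warnings.warn("all training vectors identical: atlas has 0 components")
        keep = np.zeros(0, dtype=int)
    else:
        keep = np.flatnonzero(eigenvalues > _EIGENVALUE_FLOOR_REL * eigenvalues[0])
    modes = Vt[keep].T
    scores = U[:, keep] * S[keep]
    return AtlasModel(
        mean=mean,
        modes=modes,
        eigenvalues=eigenvalues[keep],
        training_scores=scores,
        block_scale=block_scale,
        topology=topology,
    )


def explained_variance(atlas: AtlasModel, k: int) -> float:
    """Fraction of total variance captured by the first ``k`` components."""
    if not (0 <= k <= atlas.n_components):
        raise ValueError(f"k must lie in [0, {atlas.n_components}]")
    total = float(np.sum(atlas.eigenvalues))
    if total == 0.0 or k == 0:
        return 0.0
    return float(np.sum(atlas.eigenvalues[:k]) / total)


def reconstruct(atlas: AtlasModel, weights: np.ndarray) -> np.ndarray:
    """Synthesize a combined vector from component scores: mean + modes·w."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (atlas.n_components,):
        raise ValueError(
            f"expected {atlas.n_components} component weights, got {weights.shape}"
        )
    return atlas.mean + atlas.modes @ weights


def save_atlas(path, atlas: AtlasModel) -> None:
    """Persist the atlas to a single HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("mean", data=atlas.mean)
        f.create_dataset("modes", data=atlas.modes)
        f.create_dataset("eigenvalues", data=atlas.eigenvalues)
        f.create_dataset("training_scores", data=atlas.training_scores)
        f.attrs["block_scale"] = atlas.block_scale
        f.attrs["n_nodes"] = atlas.topology.n_nodes
        f.attrs["n_landmarks"] = atlas.topology.n_landmarks
        f.attrs["n_elements"] = atlas.topology.n_elements


def load_atlas(path) -> AtlasModel:
    with h5py.File(path, "r") as f:
        topology = AtlasTopology(
            n_nodes=int(f.attrs["n_nodes"]),
            n_landmarks=int(f.attrs["n_landmarks"]),
            n_elements=int(f.attrs["n_elements"]),
        )
        return AtlasModel(
            mean=f["mean"][:],
            modes=f["modes"][:],
            eigenvalues=f["eigenvalues"][:],
            training_scores=f["training_scores"][:],
            block_scale=float(f.attrs["block_scale"]),
            topology=topology,
        )
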