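"""Rigid-body superposition and RMSD machinery.

All superpositions are proper rotations (determinant +1, no reflections),
least-squares optimal in the Kabsch sense, with equal atom weights.  RMSD
between two corresponded point sets always means the residual after that
optimal fit unless a function says otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryWarning

__all__ = [
    "Transform",
    "CoordSet",
    "superpose",
    "rmsd_fitted",
    "iterative_consensus",
    "pairwise_rmsd_matrix",
]

CONSENSUS_TOL = 1e-4  # Angstrom; max consensus-point displacement to stop
CONSENSUS_MAX_ITER = 100


@dataclass(frozen=True)
class Transform:
    """A proper rigid motion x -> R @ x + t, coordinates in Angstrom."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation is not proper (det != +1)")

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "Transform":
        return Transform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "Transform") -> "Transform":
        """self after other: (self o other)(x) = self(other(x))."""
        return Transform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class CoordSet:
    """Ordered, labelled 3D points (Angstrom) ready for superposition."""

    coords: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if not self.labels:
            self.labels = [f"p{i}" for i in range(len(self.coords))]
        if len(self.labels) != len(self.coords):
            raise ValueError("labels and coords length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    def __len__(self) -> int:
        return len(self.coords)

    def transformed(self, t: Transform) -> "CoordSet":
        return CoordSet(t.apply(self.coords), list(self.labels))


def _as_coords(x) -> np.ndarray:
    if isinstance(x, CoordSet):
        return x.coords
    return np.atleast_2d(np.asarray(x, dtype=float))


def superpose(mobile, target) -> tuple[Transform, float]:
    """Optimally fit ``mobile`` onto ``target`` (positional correspondence).

    Returns the proper rigid motion minimizing the RMSD and the RMSD it
    achieves.  Near-collinear inputs emit :class:`DegenerateGeometryWarning`
    (the in-line rotation component is arbitrary) but still return a result.
    """
    P = _as_coords(mobile)
    Q = _as_coords(target)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    n = len(P)
    if n < 3:
        raise ValueError("superposition needs at least 3 points")

    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq

    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2 or np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        warnings.warn(
            "superposition of (near-)collinear points: rotation not unique",
            DegenerateGeometryWarning,
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(Qc, Pc)
    R = rot.as_matrix()
    t = cq - R @ cp
    # residual from the fitted coordinates themselves: the solver's reported
    # rssd loses precision to cancellation near zero
    rmsd = float(np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1))))
    return Transform(R, t), rmsd


def rmsd_fitted(a, b) -> float:
    """Best-fit RMSD between two corresponded point sets (symmetric)."""
    return superpose(a, b)[1]


def rmsd_raw(a, b) -> float:
    """RMSD without refitting: positions compared in the current frame."""
    A, B = _as_coords(a), _as_coords(b)
    if A.shape != B.shape:
        raise ValueError(f"point sets differ in shape: {A.shape} vs {B.shape}")
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def iterative_consensus(
    sites: Sequence[CoordSet],
    tol: float = CONSENSUS_TOL,
    max_iter: int = CONSENSUS_MAX_ITER,
) -> tuple[CoordSet, list[CoordSet], int]:
    """Iteratively superpose homologous sites and converge on their mean.

    All sites are first fitted onto the first one and averaged; then each is
    re-fitted onto the running mean and the mean recomputed, until the mean
    moves by less than ``tol`` (max point displacement, Angstrom) or
    ``max_iter`` rounds pass.  Returns the consensus, the aligned copies, and
    the number of refinement iterations performed.
    """
    if len(sites) < 2:
        raise ValueError("consensus needs at least 2 sites")
    n = len(sites[0])
    if any(len(s) != n for s in sites):
        raise ValueError("all sites must have equal length")
    labels = list(sites[0].labels)

    aligned = []
    for s in sites:
        t, _ = superpose(s, sites[0])
        aligned.append(t.apply(_as_coords(s)))
    mean = np.mean(aligned, axis=0)

    iterations = 0
    for _ in range(max_iter):
        iterations += 1
        aligned = []
        for s in sites:
            t, _ = superpose(s, mean)
            aligned.append(t.apply(_as_coords(s)))
        new_mean = np.mean(aligned, axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        if shift < tol:
            break

    consensus = CoordSet(mean, labels)
    aligned_sets = [CoordSet(a, labels) for a in aligned]
    return consensus, aligned_sets, iterations


def pairwise_rmsd_matrix(
    sites: Sequence[CoordSet], fit: str = "pair"
) -> np.ndarray:
    """Symmetric matrix of RMSDs between all site pairs.

    ``fit="pair"`` (default) refits every pair independently, so the matrix
    is invariant to each site's frame.  ``fit="consensus"`` aligns all sites
    to their iterative consensus once and compares coordinates in that common
    frame, mirroring how a dendrogram over a single joint superposition would
    see them.
    """
    n = len(sites)
    m = len(sites[0]) if n else 0
    if any(len(s) != m for s in sites):
        raise ValueError("all sites must have equal length")
    M = np.zeros((n, n), dtype=float)
    if fit == "pair":
        for i in range(n):
            for j in range(i + 1, n):
                M[i, j] = M[j, i] = rmsd_fitted(sites[i], sites[j])
    elif fit == "consensus":
        _, aligned, _ = iterative_consensus(sites)
        for i in range(n):
            for j in range(i + 1, n):
                M[i, j] = M[j, i] = rmsd_raw(aligned[i], aligned[j])
    else:
        raise ValueError(f"unknown fit mode {fit!r}")
    return M
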