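"""Orientation parameterization and sampling.

Orientations are zyz intrinsic Euler triples (α, β, γ) with the X-ray beam
along +z: R(α, β, γ) = Rz(α) · Ry(β) · Rz(γ).  The direction R·ẑ (set by
α, β) selects the Ewald-slice plane; γ is a pure in-plane rotation of the
detector image, which is what lets the matcher resolve it with a polar FFT.

Friedel symmetry of intensities, I(q) = I(−q), makes the flat-detector slice
centrosymmetric, so R and R·Rz(π) produce the same pattern (a γ ambiguity of
π).  It does *not* relate the two hemispheres of slice normals: a slice with
normal −n is the mirror image of a northern slice, which an in-plane-rotation
search cannot reach.  The sampling grid therefore covers the full sphere
β ∈ [0, π]; the residual {R, R·Rz(π)} ambiguity is handled by the evaluation
metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Orientation",
    "OrientationGrid",
    "euler_to_matrix",
    "matrix_to_euler",
    "sample_grid",
    "sample_random",
    "friedel_mate",
    "geodesic_distance",
]


def euler_to_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation matrix for intrinsic zyz Euler angles (radians)."""
    return Rotation.from_euler("ZYZ", [alpha, beta, gamma]).as_matrix()


def matrix_to_euler(matrix: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`euler_to_matrix`; β ∈ [0, π], α/γ ∈ [0, 2π).

    At gimbal lock (β = 0 or π) the split between α and γ is degenerate;
    the γ = 0 representative is returned.
    """
    a, b, g = Rotation.from_matrix(matrix).as_euler("ZYZ")
    return (float(a % (2 * np.pi)), float(b), float(g % (2 * np.pi)))


@dataclass(frozen=True)
class Orientation:
    """An SO(3) element stored as zyz Euler angles with a cached matrix."""

    alpha: float
    beta: float
    gamma: float
    _matrix: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_matrix",
                           euler_to_matrix(self.alpha, self.beta, self.gamma))

    @property
    def matrix(self) -> np.ndarray:
        return self._matrix

    @property
    def euler(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "Orientation":
        return cls(*matrix_to_euler(matrix))


@dataclass
class OrientationGrid:
    """Quasi-uniform (α, β) slice-normal directions at angular step δ.

    γ is not enumerated here: the matcher resolves it as a cyclic polar shift.
    """

    alphas: np.ndarray     # (M,) radians
    betas: np.ndarray      # (M,) radians
    step: float            # δ, radians

    def __len__(self) -> int:
        return len(self.alphas)

    def directions(self) -> np.ndarray:
        """(M, 3) unit vectors R(α, β, 0)·ẑ."""
        sa, ca = np.sin(self.alphas), np.cos(self.alphas)
        sb, cb = np.sin(self.betas), np.cos(self.betas)
        return np.stack([ca * sb, sa * sb, cb], axis=1)

    def matrices(self) -> np.ndarray:
        """(M, 3, 3) rotation matrices at γ = 0."""
        zeros = np.zeros_like(self.alphas)
        eul = np.stack([self.alphas, self.betas, zeros], axis=1)
        return Rotation.from_euler("ZYZ", eul).as_matrix()


def sample_grid(step: float) -> OrientationGrid:
    """Ring construction covering the full sphere of slice normals.

    β rings at spacing δ from pole to pole; ring at β carries
    ``max(1, round(2π sin β / δ))`` equally spaced α samples (poles carry a
    single sample).  Nearest-neighbour spacing stays within a small factor
    of δ, giving the quasi-uniform coverage the matcher needs.
    """
    if not 0 < step <= np.pi / 2:
        raise ValueError("angular step must lie in (0, pi/2]")
    n_beta = max(2, int(round(np.pi / step)))
    alphas, betas = [], []
    for j in range(n_beta + 1):
        beta = j * np.pi / n_beta
        n_alpha = max(1, int(round(2 * np.pi * np.sin(beta) / step)))
        offset = 0.5 * (j % 2)  # stagger rings to avoid aligned seams
        for k in range(n_alpha):
            alphas.append(2 * np.pi * (k + offset) / n_alpha)
            betas.append(beta)
    return OrientationGrid(np.array(alphas), np.array(betas), step)


def sample_random(n: int, rng: np.random.Generator) -> list[Orientation]:
    """Haar-uniform orientations: α, γ ~ U[0, 2π), cos β ~ U[−1, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    alpha = rng.uniform(0, 2 * np.pi, n)
    gamma = rng.uniform(0, 2 * np.pi, n)
    beta = np.arccos(rng.uniform(-1, 1, n))
    return [Orientation(a, b, g) for a, b, g in zip(alpha, beta, gamma)]


_RZ_PI = np.diag([-1.0, -1.0, 1.0])


def friedel_mate(matrix: np.ndarray) -> np.ndarray:
    """The orientation producing the same flat-Ewald pattern: R · Rz(π)."""
    return matrix @ _RZ_PI


def geodesic_distance(r1: np.ndarray, r2: np.ndarray,
                      friedel: bool = True) -> float:
    """Geodesic SO(3) distance arccos((tr(R1ᵀR2) − 1)/2), optionally
    minimized over the Friedel-equivalent mate of ``r2``."""
    def _dist(a, b):
        c = (np.trace(a.T @ b) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))

    d = _dist(r1, r2)
    if friedel:
        d = min(d, _dist(r1, friedel_mate(r2)))
    return d
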