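"""Forward model: atomic model → 3D diffraction intensity → noisy 2D
patterns at random orientations.

Physics
-------
A detector pixel at in-plane radius r sees scattering angle 2θ = atan(r/D).
Its reciprocal vector (crystallographic convention, |q| = 2 sin θ / λ) is
q = (k_s − k_in)/λ·λ = (sin2θ cosφ, sin2θ sinφ, cos2θ − 1)/λ, which lies on
the Ewald sphere of radius 1/λ centred at (0, 0, −1/λ).  The expected photon
count in the pixel is

    μ = J · r_e² · Ω · |F(R·q)|²

with J the incident photon fluence (photons per unit area of the focal
spot), r_e the classical electron radius, Ω = (p/D)²·cos³(2θ) the pixel's
solid angle, F the structure factor in electrons and R the particle
orientation.  Recorded counts are Poisson draws of μ; a central beam-stop
block is masked.

Each atom is a Gaussian peak of width ``atom_sigma`` carrying Z electrons,
so F has the closed form  Σ_j Z_j · exp(−2π²σ²|q|²) · exp(2πi q·r_j) — the
non-uniform Fourier transform of the density evaluated exactly at the
off-grid Ewald q-points, with no interpolation or gridding error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AtomicModel, IntensityVolume, PatternSet, RunConfig
from .orientations import Orientation, sample_random

__all__ = [
    "R_E_M",
    "DetectorGeometry",
    "EwaldMap",
    "BeamModel",
    "model_to_density",
    "structure_factors",
    "ewald_map",
    "intensity_volume",
    "default_dq",
    "simulate_pattern",
    "simulate_mixture",
]

#: classical electron radius, metres
R_E_M = 2.8179403e-15


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectorGeometry:
    """Flat detector normal to the beam, beam centre at pixel (H//2, W//2)."""

    wavelength_A: float
    distance_m: float
    shape: tuple[int, int]          # (H, W) pixels
    pixel_um: float
    beam_stop_px: int = 0           # side of the masked central block

    def __post_init__(self) -> None:
        for name in ("wavelength_A", "distance_m", "pixel_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "DetectorGeometry":
        return cls(cfg.wavelength_A, cfg.distance_m, tuple(cfg.detector_px),
                   cfg.pixel_um, cfg.beam_stop_px)

    @property
    def beam_center(self) -> tuple[int, int]:
        return (self.shape[0] // 2, self.shape[1] // 2)

    def pixel_radii_m(self) -> np.ndarray:
        """In-plane distance of each pixel from the beam centre, metres."""
        cy, cx = self.beam_center
        p = self.pixel_um * 1e-6
        y = (np.arange(self.shape[0]) - cy) * p
        x = (np.arange(self.shape[1]) - cx) * p
        return np.hypot(y[:, None], x[None, :])

    def edge_resolution_A(self) -> float:
        """Resolution d = 1/|q| at the outermost recorded pixel centre along
        the detector half-width (the number quoted as the pattern's
        resolution).  With the beam centre on pixel W//2 that pixel sits
        W//2 − 1 pixels out."""
        r = (self.shape[1] // 2 - 1) * self.pixel_um * 1e-6
        theta = 0.5 * np.arctan2(r, self.distance_m)
        return self.wavelength_A / (2.0 * np.sin(theta))

    def q_edge(self) -> float:
        """|q| at the half-width edge, Å⁻¹."""
        return 1.0 / self.edge_resolution_A()

    def valid_mask(self) -> np.ndarray:
        """True for usable pixels (outside the central beam-stop block)."""
        mask = np.ones(self.shape, dtype=bool)
        if self.beam_stop_px > 0:
            cy, cx = self.beam_center
            h = self.beam_stop_px
            y0, x0 = cy - h // 2, cx - h // 2
            mask[y0:y0 + h, x0:x0 + h] = False
        return mask

    def downsampled(self, factor: int = 2) -> "DetectorGeometry":
        """Geometry after ``factor``× pixel binning (edge |q| unchanged)."""
        if any(d % factor for d in self.shape):
            raise ValueError("detector shape not divisible by binning factor")
        return DetectorGeometry(
            self.wavelength_A, self.distance_m,
            (self.shape[0] // factor, self.shape[1] // factor),
            self.pixel_um * factor,
            max(1, self.beam_stop_px // factor) if self.beam_stop_px else 0,
        )


@dataclass(frozen=True)
class EwaldMap:
    """Per-pixel reciprocal vectors (lab frame, Å⁻¹) and solid angles (sr)."""

    q: np.ndarray                   # (H, W, 3)
    solid_angle: np.ndarray         # (H, W)

    @property
    def q_length(self) -> np.ndarray:
        return np.linalg.norm(self.q, axis=-1)


def ewald_map(geometry: DetectorGeometry) -> EwaldMap:
    """Map each pixel to its Ewald-sphere q-vector and solid angle."""
    cy, cx = geometry.beam_center
    p = geometry.pixel_um * 1e-6
    y = (np.arange(geometry.shape[0]) - cy) * p
    x = (np.arange(geometry.shape[1]) - cx) * p
    yy, xx = np.meshgrid(y, x, indexing="ij")
    r = np.hypot(yy, xx)
    two_theta = np.arctan2(r, geometry.distance_m)
    phi = np.arctan2(yy, xx)
    inv_lam = 1.0 / geometry.wavelength_A
    s2t, c2t = np.sin(two_theta), np.cos(two_theta)
    q = np.stack([s2t * np.cos(phi), s2t * np.sin(phi), c2t - 1.0],
                 axis=-1) * inv_lam
    omega = (p / geometry.distance_m) ** 2 * c2t ** 3
    return EwaldMap(q=q, solid_angle=omega)


# --------------------------------------------------------------------------
# beam
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BeamModel:
    """Pulse photon budget focused on a circular spot, with shot-to-shot
    Gaussian fluence jitter (non-positive draws are resampled)."""

    photons_per_pulse: float
    focus_um: float
    jitter: float = 0.10

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "BeamModel":
        return cls(cfg.photons_per_pulse, cfg.focus_um, cfg.fluence_jitter)

    @property
    def mean_fluence(self) -> float:
        """Photons per m² of the focal spot."""
        area = np.pi * (0.5 * self.focus_um * 1e-6) ** 2
        return self.photons_per_pulse / area

    def sample_fluence(self, rng: np.random.Generator) -> float:
        if self.jitter == 0:
            return self.mean_fluence
        for _ in range(1000):
            f = self.mean_fluence * (1.0 + self.jitter * rng.standard_normal())
            if f > 0:
                return f
        raise RuntimeError("fluence sampling failed to draw a positive value")


# --------------------------------------------------------------------------
# density and structure factors
# --------------------------------------------------------------------------

def model_to_density(model: AtomicModel, voxel: float, box: int,
                     atom_sigma: float = 1.0) -> np.ndarray:
    """Rasterize the model as a sum of Z-weighted isotropic Gaussians.

    Returns electron density in e/Å³ on a ``box``³ grid with the origin at
    voxel ``box // 2``; the model is centred first.  Raises if any atom
    (plus 3σ padding) falls outside the box.
    """
    m = model.centered()
    half = box // 2
    extent = (half - 1) * voxel
    if np.any(np.abs(m.coords) + 3 * atom_sigma > extent):
        raise ValueError("model (plus 3 sigma padding) does not fit the box")
    w = m.electron_counts
    density = np.zeros((box, box, box))
    norm = (2 * np.pi * atom_sigma ** 2) ** -1.5
    # 8σ patch: truncated tail < 1e-12 of the peak
    reach = int(np.ceil(8 * atom_sigma / voxel)) + 1
    axes = np.arange(box)
    for xyz, wj in zip(m.coords, w):
        idx = np.round(xyz / voxel).astype(int) + half
        sl = [slice(max(0, i - reach), min(box, i + reach + 1)) for i in idx]
        local = [(axes[s] - half) * voxel - c for s, c in zip(sl, xyz)]
        g = [np.exp(-0.5 * (d / atom_sigma) ** 2) for d in local]
        density[sl[0], sl[1], sl[2]] += (wj * norm) * (
            g[0][:, None, None] * g[1][None, :, None] * g[2][None, None, :])
    return density


def structure_factors(source: AtomicModel | np.ndarray,
                      qpoints: np.ndarray,
                      *,
                      atom_sigma: float = 1.0,
                      voxel: float | None = None,
                      chunk: int = 16384) -> np.ndarray:
    """Complex structure factors F(q) at arbitrary q-points (Å⁻¹).

    With an :class:`AtomicModel`, F is the exact transform of the
    Gaussian-atom density:  Σ_j Z_j e^{−2π²σ²|q|²} e^{2πi q·r_j}.
    With a gridded density (``voxel`` required, origin at the centre voxel),
    F is the direct non-uniform discrete Fourier sum Σ_v ρ_v Δv e^{2πi q·r_v};
    q beyond the grid's band limit 1/(2·voxel) raises.
    """
    q = np.atleast_2d(np.asarray(qpoints, dtype=float))
    if isinstance(source, AtomicModel):
        coords = source.coords
        w = source.electron_counts
        decay_coef = 2.0 * np.pi ** 2 * atom_sigma ** 2
        out = np.empty(len(q), dtype=complex)
        for lo in range(0, len(q), chunk):
            qc = q[lo:lo + chunk]
            phase = qc @ coords.T                       # (c, n_atoms)
            out[lo:lo + chunk] = np.exp(2j * np.pi * phase) @ w
            out[lo:lo + chunk] *= np.exp(-decay_coef * (qc ** 2).sum(1))
        return out
    density = np.asarray(source, dtype=float)
    if voxel is None:
        raise ValueError("gridded densities require the voxel size")
    band = 1.0 / (2.0 * voxel)
    if np.any(np.linalg.norm(q, axis=1) > band * (1 + 1e-9)):
        raise ValueError("q beyond the density grid's band limit")
    box = density.shape[0]
    r = (np.stack(np.meshgrid(*[np.arange(s) for s in density.shape],
                              indexing="ij"), axis=-1).reshape(-1, 3)
         - box // 2) * voxel
    rho = density.reshape(-1) * voxel ** 3
    out = np.empty(len(q), dtype=complex)
    for lo in range(0, len(q), max(1, chunk // 64)):
        qc = q[lo:lo + max(1, chunk // 64)]
        out[lo:lo + len(qc)] = np.exp(2j * np.pi * (qc @ r.T)) @ rho
    return out


# --------------------------------------------------------------------------
# 3D intensity on a cubic grid
# --------------------------------------------------------------------------

def default_dq(geometry: DetectorGeometry, grid_n: int) -> float:
    """Grid step so the volume covers the ball |q| ≤ q_edge with room for
    trilinear neighbours after one 2× downsampling."""
    return geometry.q_edge() / (grid_n // 2 - 3)


def intensity_volume(model: AtomicModel, geometry: DetectorGeometry,
                     grid_n: int = 128, atom_sigma: float = 1.0,
                     dq: float | None = None) -> IntensityVolume:
    """Ground-truth 3D diffraction intensity |F(q)|² on a cubic grid.

    The structure factors are evaluated in closed form at every grid point,
    so this equals the template built from the same model by the templates
    module (shared forward transform).
    """
    if dq is None:
        dq = default_dq(geometry, grid_n)
    half = grid_n // 2
    ax = (np.arange(grid_n) - half) * dq
    qpts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    f = structure_factors(model.centered(), qpts, atom_sigma=atom_sigma)
    data = (np.abs(f) ** 2).reshape(grid_n, grid_n, grid_n)
    return IntensityVolume(data, dq)


# --------------------------------------------------------------------------
# pattern simulation
# --------------------------------------------------------------------------

def expected_counts(model: AtomicModel, orientation: Orientation,
                    geometry: DetectorGeometry, fluence: float,
                    ewald: EwaldMap | None = None,
                    atom_sigma: float = 1.0) -> np.ndarray:
    """Noiseless expected photon counts μ = J r_e² Ω |F(R·q)|² (beam-stop
    pixels set to 0)."""
    if ewald is None:
        ewald = ewald_map(geometry)
    qrot = ewald.q.reshape(-1, 3) @ orientation.matrix.T
    f = structure_factors(model.centered(), qrot, atom_sigma=atom_sigma)
    mu = fluence * R_E_M ** 2 * ewald.solid_angle * \
        (np.abs(f) ** 2).reshape(geometry.shape)
    mu[~geometry.valid_mask()] = 0.0
    return mu


def simulate_pattern(model: AtomicModel, orientation: Orientation,
                     geometry: DetectorGeometry, beam: BeamModel,
                     rng: np.random.Generator | int | None = None,
                     poisson: bool = True,
                     ewald: EwaldMap | None = None,
                     atom_sigma: float = 1.0) -> tuple[np.ndarray, float]:
    """One diffraction pattern: (counts, applied fluence).

    Fluence is drawn once per pattern from the jittered beam; counts are a
    Poisson draw of the expected map unless ``poisson`` is off, in which
    case the (float) expected map is returned unchanged.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    fluence = beam.sample_fluence(rng)
    mu = expected_counts(model, orientation, geometry, fluence,
                         ewald=ewald, atom_sigma=atom_sigma)
    if np.any(mu > 2 ** 63):
        raise OverflowError("expected photon counts overflow")
    if not poisson:
        return mu, fluence
    return rng.poisson(mu).astype(np.uint32), fluence


def simulate_mixture(models: list[AtomicModel], counts: list[int],
                     geometry: DetectorGeometry, beam: BeamModel,
                     seed: int = 0, poisson: bool = True,
                     atom_sigma: float = 1.0) -> PatternSet:
    """Simulate a shuffled mixed-species pattern set.

    Orientations are Haar-uniform on SO(3); species labels and true
    orientations go only into the hidden metadata.  Orientation draws,
    fluence jitter and Poisson noise use independent streams spawned from
    ``seed``, so the set is reproducible.
    """
    if len(models) != len(counts):
        raise ValueError("one count per species model is required")
    if any(c <= 0 for c in counts):
        raise ValueError("every species needs a positive pattern count")
    ss = np.random.SeedSequence(seed)
    rng_orient, rng_beam, rng_noise, rng_shuffle = \
        (np.random.default_rng(s) for s in ss.spawn(4))
    ew = ewald_map(geometry)

    labels = np.repeat(np.arange(len(models)), counts)
    rng_shuffle.shuffle(labels)
    total = len(labels)
    orients = sample_random(total, rng_orient)

    stack = np.zeros((total, *geometry.shape),
                     dtype=np.uint32 if poisson else float)
    fluences = np.empty(total)
    eulers = np.empty((total, 3))
    centered = [m.centered() for m in models]
    for i, (lab, ori) in enumerate(zip(labels, orients)):
        fl = beam.sample_fluence(rng_beam)
        mu = expected_counts(centered[lab], ori, geometry, fl,
                             ewald=ew, atom_sigma=atom_sigma)
        stack[i] = rng_noise.poisson(mu).astype(np.uint32) if poisson else mu
        fluences[i] = fl
        eulers[i] = ori.euler
    return PatternSet(patterns=stack, mask=geometry.valid_mask(),
                      species=labels, euler=eulers, fluence=fluences)
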