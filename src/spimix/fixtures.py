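"""Deterministic toy inputs: pseudo-atom blob species, template
perturbation, and a matching run configuration.

The toy mixture mirrors the monomer/dimer/tetramer study design at desk
scale: a 50-atom carbon blob "monomer", a dimer built from two rigid
monomer copies and a tetramer from two rigid dimer copies, imaged on a
96×96 detector with ≈5 Å edge resolution.  The beam delivers a strong-hit
photon budget (~10⁴–10⁵ detected photons per pattern) so that a few hundred
patterns per species carry enough signal for classification; template
imperfection is emulated by smooth random displacement fields scaled to a
prescribed coordinate RMSD, standing in for predicted-versus-true model
discrepancies.
"""

from __future__ import annotations

import numpy as np

from .io_formats import AtomicModel, RunConfig
from .orientations import euler_to_matrix

__all__ = ["toy_species", "perturb_model", "toy_config", "rmsd"]

_N_MONOMER = 50
_BLOB_SCALE = 8.0          # Å, Gaussian spread of pseudo-atom positions


def toy_species(kind: str, seed: int = 0) -> AtomicModel:
    """Toy pseudo-atom assembly: ``monomer`` (50 atoms), ``dimer`` (two
    displaced rigid monomer copies, 100 atoms) or ``tetramer`` (two
    displaced rigid dimer copies, 200 atoms).  Same seed → identical
    models; all species derive from the same monomer blob."""
    rng = np.random.default_rng(np.random.SeedSequence([20240828, seed]))
    coords = rng.normal(scale=_BLOB_SCALE, size=(_N_MONOMER, 3))
    mono = AtomicModel(elements=np.full(_N_MONOMER, "C"),
                       coords=coords,
                       occupancy=np.ones(_N_MONOMER))
    if kind == "monomer":
        return mono
    rot_d = euler_to_matrix(0.7, 1.1, -0.4)    # fixed relative rotations
    dimer_coords = np.concatenate([
        mono.coords - [11.0, 0.0, 0.0],
        mono.coords @ rot_d.T + [11.0, 0.0, 0.0],
    ])
    dimer = AtomicModel(elements=np.full(2 * _N_MONOMER, "C"),
                        coords=dimer_coords,
                        occupancy=np.ones(2 * _N_MONOMER))
    if kind == "dimer":
        return dimer
    if kind != "tetramer":
        raise ValueError(f"unknown toy species kind: {kind!r}")
    rot_t = euler_to_matrix(-1.3, 0.9, 2.1)
    tet_coords = np.concatenate([
        dimer.coords - [0.0, 13.0, 6.0],
        dimer.coords @ rot_t.T + [0.0, 13.0, 6.0],
    ])
    return AtomicModel(elements=np.full(4 * _N_MONOMER, "C"),
                       coords=tet_coords,
                       occupancy=np.ones(4 * _N_MONOMER))


def rmsd(a: AtomicModel, b: AtomicModel) -> float:
    """Coordinate RMSD between two models with identical atom order (Å)."""
    if a.n_atoms != b.n_atoms:
        raise ValueError("models must have the same number of atoms")
    return float(np.sqrt(np.mean(np.sum((a.coords - b.coords) ** 2, axis=1))))


def perturb_model(model: AtomicModel, rmsd_target: float,
                  seed: int = 0) -> AtomicModel:
    """Deform a model with a smooth correlated displacement field scaled so
    the realized coordinate RMSD equals ``rmsd_target`` (Å).

    The field is a sum of a few random long-wavelength sinusoids (wavelength
    of order the object size), emulating the low-frequency errors typical of
    predicted models rather than independent per-atom jitter.
    """
    if rmsd_target < 0:
        raise ValueError("rmsd_target must be >= 0")
    if rmsd_target == 0:
        return model
    rng = np.random.default_rng(np.random.SeedSequence([57110, seed]))
    xyz = model.coords
    extent = max(np.ptp(xyz, axis=0).max(), 1.0)
    disp = np.zeros_like(xyz)
    for _ in range(6):
        k = rng.normal(size=3)
        k *= (2 * np.pi / extent) * rng.uniform(0.5, 1.5) / np.linalg.norm(k)
        phase = rng.uniform(0, 2 * np.pi)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        disp += np.sin(xyz @ k + phase)[:, None] * direction
    realized = np.sqrt(np.mean(np.sum(disp ** 2, axis=1)))
    disp *= rmsd_target / realized
    return AtomicModel(elements=model.elements, coords=xyz + disp,
                       occupancy=model.occupancy, b_factors=model.b_factors,
                       chains=model.chains, residue_ids=model.residue_ids)


def toy_config(seed: int = 0) -> RunConfig:
    """Run configuration for the toy mixture.

    96×96 detector, λ = 1 Å, 300 µm pixels, D = 0.072 m (edge resolution
    ≈ 5.2 Å), 18×18 beam stop (sized to blank the forward-scattering
    envelope the species share, which at toy speckle sizes spans several
    pixels), ~10⁵ photons per pattern (1e17 photons/pulse on a 0.1 µm
    focus) with 10% jitter, 300/200/100 patterns for monomer/dimer/
    tetramer, CC threshold 0.02, 10 iterations, δ = 10° orientation grid,
    128 polar angular bins, 96³ template grid.
    """
    return RunConfig(
        wavelength_A=1.0,
        distance_m=0.072,
        detector_px=(96, 96),
        pixel_um=300.0,
        beam_stop_px=18,
        photons_per_pulse=1e17,
        focus_um=0.1,
        fluence_jitter=0.10,
        pattern_counts=(300, 200, 100),
        cc_threshold=0.02,
        max_iterations=10,
        stop_tol=0.001,
        angular_step_deg=10.0,
        n_theta=128,
        volume_grid=96,
        seed=seed,
    )
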