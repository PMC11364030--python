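"""Shared fixtures: small geometries for unit tests and one session-scoped
end-to-end toy run reused by the expensive integration checks."""

from __future__ import annotations

import numpy as np
import pytest

from spimix.classify_reconstruct import run
from spimix.fixtures import perturb_model, toy_config, toy_species
from spimix.simulate import (BeamModel, DetectorGeometry, intensity_volume,
                             simulate_mixture)
from spimix.templates import build_template, downsample_volume

#: template perturbation RMSDs (Å) per toy species, mimicking the growing
#: predicted-model error with assembly size
TOY_PERTURB_A = (1.0, 2.0, 3.0)


@pytest.fixture(scope="session")
def toy_models():
    return [toy_species(k) for k in ("monomer", "dimer", "tetramer")]


@pytest.fixture(scope="session")
def toy_cfg():
    return toy_config(seed=0)


@pytest.fixture(scope="session")
def toy_geom(toy_cfg):
    return DetectorGeometry.from_config(toy_cfg)


@pytest.fixture(scope="session")
def toy_beam(toy_cfg):
    return BeamModel.from_config(toy_cfg)


@pytest.fixture(scope="session")
def small_geom():
    """Cheap 32×32 detector for unit tests (same λ/pixel family as the toy)."""
    return DetectorGeometry(wavelength_A=1.0, distance_m=0.024,
                            shape=(32, 32), pixel_um=300.0, beam_stop_px=6)


@pytest.fixture(scope="session")
def e2e_run(toy_models, toy_cfg, toy_geom, toy_beam):
    """Full toy pipeline: simulate 600 noisy mixed patterns, build perturbed
    templates, run the iterative loop; also returns downsampled truth
    volumes for resolution scoring."""
    patterns = simulate_mixture(toy_models, list(toy_cfg.pattern_counts),
                                toy_geom, toy_beam, seed=toy_cfg.seed)
    templates = [
        build_template(perturb_model(m, r, seed=i), toy_geom,
                       grid_n=toy_cfg.volume_grid)
        for i, (m, r) in enumerate(zip(toy_models, TOY_PERTURB_A))
    ]
    final, history = run(patterns, templates, toy_cfg)
    truth = [downsample_volume(intensity_volume(m, toy_geom,
                                                grid_n=toy_cfg.volume_grid), 2)
             for m in toy_models]
    return {
        "patterns": patterns,
        "final": final,
        "history": history,
        "truth_volumes": truth,
        "config": toy_cfg,
        "geometry": toy_geom,
    }
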