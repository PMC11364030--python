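# spimix

Classification and multi-reconstruction of **mixed-species XFEL
single-particle diffraction patterns**, guided by 3D intensity templates
built from predicted atomic models.

## The problem

In X-ray free-electron-laser single-particle imaging (SPI), isolated
particles in random orientations are hit by intense femtosecond pulses and
each hit leaves one noisy 2D diffraction pattern — a curved Ewald-sphere
slice through the particle's 3D diffraction intensity |F(**q**)|².
Reconstructing the 3D intensity requires recovering the unknown orientation
of every pattern.  Real samples are rarely homogeneous: monomers coexist
with dimers and higher assemblies, or complexes dissociate after
purification, so the recorded stream mixes patterns from several species and
orientation-recovery algorithms that assume identical particles break down.

`spimix` implements a template-aided one-step answer: build an initial 3D
intensity template per candidate species from predicted structures, then
iteratively and simultaneously **classify** each pattern, **orient** it, and
**merge** each class into an improved 3D intensity that replaces its
template.

## The algorithm

For detector pixel at scattering angle 2θ the expected photon count is

    μ = J · r_e² · Ω · |F(R·q)|²,     |q| = 2 sin θ / λ,  d = 1/|q|

with J the photon fluence, r_e the classical electron radius, Ω the pixel
solid angle and R the particle orientation (zyz Euler angles α, β, γ; beam
along +z).  Each iteration:

1. Patterns and templates are downsampled 2× (sum-binned counts,
   mean-binned volumes).
2. Every template is sliced along the Ewald sphere on a quasi-uniform
   (α, β) grid; γ is an in-plane rotation, resolved exactly for all values
   at once by FFT over the angular axis of polar-resampled images.
3. The similarity of pattern *n* and template *m* is
   CC_max(n, m) — the maximum masked Pearson correlation over all slices —
   computed with per-shift renormalization so beam-stop and missing-data
   bins are excluded exactly.
4. A pattern is assigned to its best class only when the top-two margin
   CC¹_max − CC²_max exceeds a rejection threshold (default 0.02);
   otherwise it stays unclassified for this round.  All patterns are
   re-evaluated every iteration, so early mistakes are corrected.
5. Each class's patterns are merged at their best orientations into a new
   3D intensity (trilinear scatter, weighted voxel mean, Friedel
   symmetrization), which becomes the next template.

Evaluation utilities score classification accuracy (correct / successfully
classified), orientation error (geodesic SO(3) distance modulo the Friedel
ambiguity R ~ R·Rz(π)) and reconstruction resolution (per-shell Pearson CC
against the true intensity; resolution where the curve first drops to 0.5).

A forward simulator (closed-form Gaussian-atom structure factors evaluated
exactly at the off-grid Ewald q-points, Poisson photon noise, 10% pulse
fluence jitter, central beam stop) and a deterministic toy-species module
make the whole pipeline testable without downloading any data.

## Worked example

```python
import numpy as np
from spimix import (DetectorGeometry, BeamModel, simulate_mixture,
                    build_template, run, confusion, orientation_error)
from spimix.fixtures import toy_species, perturb_model, toy_config

cfg   = toy_config(seed=0)
geom  = DetectorGeometry.from_config(cfg)     # 96×96 px, λ=1 Å, D=0.072 m
beam  = BeamModel.from_config(cfg)            # 1e17 ph/pulse, 0.1 µm focus
truth = [toy_species(k) for k in ("monomer", "dimer", "tetramer")]

# 600 mixed patterns (300/200/100), Poisson noise, hidden true labels
patterns = simulate_mixture(truth, list(cfg.pattern_counts), geom, beam,
                            seed=cfg.seed)

# templates from imperfect models (1/2/3 Å RMSD displacement fields)
templates = [build_template(perturb_model(m, r, seed=i), geom, grid_n=96)
             for i, (m, r) in enumerate(zip(truth, (1.0, 2.0, 3.0)))]

final, history = run(patterns, templates, cfg)
for state in history:
    acc = confusion(state.assignment, patterns.species).accuracy
    print(f"iter {state.iteration:2d}  accuracy {100*acc:6.2f}%  "
          f"unclassified {state.assignment.n_unclassified:3d}")
err = orientation_error(final.assignment, patterns.euler)
print(f"median orientation error {np.degrees(np.nanmedian(err)):.1f} deg")
```

Output (seed 0):

```
iter  1  accuracy  94.53%  unclassified  52
iter  2  accuracy  99.83%  unclassified   3
iter  3  accuracy 100.00%  unclassified   0
...
iter 10  accuracy 100.00%  unclassified   0
median orientation error 5.3 deg
```

Accuracy rises while the unclassified pool shrinks — the signature
trajectory of the iterative scheme: poor templates reject ambiguous
patterns at first, each merge sharpens the templates, and the margins grow.
The final median orientation error sits below the 10° orientation-grid
step.

The same pipeline is scriptable from the shell:

```sh
spi fixtures  --out toydata
spi simulate  --config toydata/run.yaml --models toydata/true_*.pdb \
              --out patterns.h5 --truth-volumes truth/
spi templates --config toydata/run.yaml --models toydata/pred_*.pdb \
              --out tmpl_%d.mrc
spi run       --patterns patterns.h5 --templates tmpl_*.mrc \
              --config toydata/run.yaml --out results/
spi evaluate  --results results/ --truth patterns.h5 \
              --truth-volumes truth/ --out report.json
```

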