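# Methods

## Forward model

A particle with electron density ρ(**r**) scatters a pulse of fluence J
(photons per unit area of the focal spot) into expected pixel counts

    μ(pixel) = J · r_e² · Ω(pixel) · |F(R·q(pixel))|²

* **q(pixel)** — reciprocal vector of the pixel in the crystallographic
  convention |q| = 2 sin θ/λ (resolution d = 1/|q|), lying on the Ewald
  sphere of radius 1/λ centred at (0, 0, −1/λ); the beam runs along +z and
  q = 0 sits exactly on the beam-centre pixel (index H//2, W//2).
* **Ω = (p/D)²·cos³ 2θ** — flat-detector solid angle (pixel pitch p,
  distance D); exact enough at the few-degree scattering angles used here.
* **r_e = 2.8179403×10⁻¹⁵ m** — classical electron radius.
* **R** — particle orientation, intrinsic zyz Euler triple
  R(α, β, γ) = Rz(α)·Ry(β)·Rz(γ).  (α, β) select the Ewald-slice plane; γ
  is a pure in-plane rotation of the detector image.
* An unpolarized beam is assumed; a polarization factor would multiply μ by
  a smooth, orientation-independent map and cancels from every Pearson
  correlation, so none is applied.

Each atom is a Z-electron isotropic Gaussian of width `atom_sigma`
(default 1.0 Å — far below the ≥5 Å resolutions of interest, so no
element-specific form factors).  Its Fourier transform is closed-form, so
structure factors are evaluated **exactly at the off-grid Ewald q-points**:

    F(q) = Σ_j Z_j · exp(−2π²σ²|q|²) · exp(2πi q·r_j)

This is the non-uniform Fourier evaluation of the Gaussian-atom density
with zero gridding/interpolation error; a direct non-uniform DFT over a
rasterized density grid is provided as an alternative input path and as the
oracle target in the tests.  Recorded counts are Poisson draws of μ; the
fluence is drawn once per pattern from a 10% Gaussian jitter (non-positive
draws resampled); a central beam-stop block is masked and excluded from
every correlation downstream.  The quoted "edge resolution" of a geometry
is 1/|q| at the outermost recorded pixel centre, (W/2 − 1) pixels from the
beam centre.

## Templates and preprocessing

Templates are |F(q)|² of the (predicted) model on a cubic grid whose step
is Δq = q_edge/(N/2 − 3), leaving trilinear head-room after the 2×
downsampling that the algorithm applies to everything first (patterns:
2×2 sum-binning, preserving counts and Poisson statistics, a binned pixel
masked if any constituent is; volumes: 2×2×2 mean-binning with Δq doubled).
Volumes are Friedel-symmetrized, I ← (I(q)+I(−q))/2 — exact for |F|² of a
real density, and during merging the averaging doubles as completion:
a voxel whose inversion mate was measured inherits its value.

## Matching

Slices are trilinear interpolations of the volume at R·q(pixel); pixels
reaching outside the grid or touching missing voxels are invalid, never an
error.  Pattern and slice are resampled onto a polar lattice (radii
i + 0.5 pixels, `n_theta` angles, power of two) by bilinear interpolation;
a polar bin touching any invalid pixel is invalid.

γ shifts the polar image cyclically, so one slice per (α, β) covers all γ.
The Pearson correlation at **every** shift is assembled from six circular
cross-correlations along θ (validity indicators, masked images, their
squares, and the cross term), giving the exact masked Pearson coefficient
per shift — identical to an explicit per-shift loop to float precision,
which the test suite asserts at 1e-10.  Per-shift masked renormalization is
the faithful reading of a plain Pearson r under masks; single-normalization
FFT correlation would be biased wherever the joint mask varies with shift.
All nine field products come from one batched matmul over θ-frequencies;
the arithmetic runs in float64 by default and float32 inside the iteration
loop (CC error ~1e-6, three orders below the classification margins).
Radial bins are unweighted, as the plain Pearson formula implies; ties in
the argmax resolve to the lowest grid index, then the smallest shift.

### Orientation sampling covers the full sphere

Friedel symmetry I(q) = I(−q) makes a flat-limit slice centrosymmetric:
R and R·Rz(π) produce the same pattern, a γ ambiguity of π that the γ-FFT
resolves at no cost.  It does **not** fold the sphere of slice normals: a
slice with normal −n is the *mirror image* of a northern-hemisphere slice,
and a rotation-only search cannot reach a reflection.  (Numerically,
restricting the grid to β ≤ π/2 leaves patterns with β > π/2 ~130° from
any reachable orientation.)  The (α, β) grid therefore rings the full
sphere at spacing δ (default 6°; 10° in the toy), ⌈2π sin β/δ⌉ α-samples
per ring, poles included; the residual {R, R·Rz(π)} ambiguity is handled
only in the evaluation metric.  A consequence worth stating: intensities
carry no chirality information, so reconstructions are determined up to the
enantiomorph inherent to losing the phases.

## Classification and merging

Per pattern the CC_max values over classes are sorted; the pattern joins
the argmax class iff CC¹_max − CC²_max > threshold (strict comparison;
default 0.02), else it is unclassified this round and excluded from
merging.  Merging scatters each classified pattern's photon counts at its
best orientation into the voxel grid with trilinear weights and takes the
weighted mean per voxel — a mean, not a sum, so classes of very different
sizes stay on a common scale (Pearson is scale-invariant regardless).  No
per-pattern fluence correction is applied by default (available as an
option); the solid-angle factor is likewise left in the counts — it is a
smooth radial modulation of a few percent that shell-wise and pattern-wise
correlations ignore.  Untouched voxels are zero and flagged missing;
slices treat them as invalid rather than fabricating intensity in the
missing region near the beam axis.  A class that receives no patterns
keeps its previous template, preventing collapse in early iterations.

The loop stops when the fraction of patterns whose class or orientation
changed drops below `stop_tol` (default 0.001) or after `max_iterations`
(default 10).  A fixed threshold is used throughout; a per-iteration
schedule (e.g. start high, decay) is accepted as an optional argument and
off by default.  If an iteration classifies nothing the run aborts with a
diagnostic rather than merging nothing.

## Evaluation

* **Accuracy** = correctly classified / successfully classified
  (unclassified patterns excluded from the denominator).
* **Orientation error** = geodesic SO(3) distance
  arccos((tr(R₁ᵀR₂) − 1)/2), minimized over the Friedel mate.
* **Shell CC** — Pearson correlation per spherical shell (default 50 shells
  over [0, q_max]), missing voxels excluded pairwise, shells with fewer
  than 10 valid pairs undefined.  The **resolution** is d = 1/q at the
  first linear-interpolated crossing below 0.5, searched from the first
  shell at or above 0.5 — shells bordering the beam-stop hole are sparsely
  covered and may sit low without meaning a loss of resolution.  A curve
  that never drops below 0.5 is band-limited by the detector edge.

## The toy study and what it shows

`fixtures` builds three pseudo-atom species from one 50-atom carbon blob
(positions ~N(0, (8 Å)²)): the dimer is two rigid monomer copies 22 Å
apart, the tetramer two rigid dimer copies ~28 Å apart — sizes ≈35/50/70 Å,
so the species span roughly 4/5/6 speckles across the measured band, the
same several-speckles regime as full-scale SPI data.  Geometry: 96×96
detector, λ = 1 Å, 300 µm pixels, D = 0.072 m (edge resolution ≈5.2 Å),
beam stop 18×18 (blanking the forward-scattering envelope the species
share, proportionally larger than on a 512-pixel detector because the toy
speckles are proportionally larger).  The beam (10¹⁷ photons/pulse on a
0.1 µm focus, 10% jitter) deposits ~10⁴–10⁵ photons per pattern — a strong
hit — chosen so that 600 patterns (300/200/100 per species) carry enough
information for the statistics the tests assert.  Template imperfection is
a smooth random sinusoidal displacement field scaled to exactly 1/2/3 Å
RMSD for monomer/dimer/tetramer, emulating the growing error of predicted
models with assembly size; a correlated field, not atomic jitter, because
prediction errors are low-frequency.  Orientation grid δ = 10°, 128 polar
angles, 96³ template grid (48³ after downsampling).

Under these conditions the loop converges the way the full-scale method
does — accuracy ≈94% → 100%, unclassified 9% → 0 within three iterations,
median orientation error ≈5° (below δ) — and every species reconstructs to
the detector band limit.  Two honest caveats about what passing does *not*
show.  First, the toy is photon-rich: at full scale each pattern carries
orders of magnitude fewer photons, the first-iteration unclassified
fraction is far larger, and convergence rests on the 10⁴-pattern statistics
the toy does not have.  Second, because nothing here is photon-limited,
reconstruction quality is ordered by pattern count (monomer best), not by
particle size — the opposite of the photon-starved full-scale study, where
the largest species wins through its stronger per-pattern signal.  The toy
also omits detector point-spread, background scattering, polarization,
multi-particle hits and conformational heterogeneity within a species.

## Numerical choices

* Trilinear interpolation for slicing and volume scatter, bilinear for
  polar resampling; the simulator alone is interpolation-free.
* Degenerate correlations (fewer than two jointly valid bins, zero
  variance) evaluate to −inf so they can never win a maximization; an
  all-invalid pair raises.
* Gimbal lock in matrix→Euler conversion resolves to the γ = 0
  representative.
* Volume files are CCP4/MRC maps whose cell edge stores N·Δq (Å⁻¹);
  missing voxels are NaN on disk.  Pattern sets are HDF5
  (`/patterns` uint32, `/mask` bool, `/meta/{species,euler,fluence}`).
* Every stochastic stage (orientations, fluence jitter, Poisson noise,
  mixture shuffling) draws from independent streams spawned from one seed;
  identical seeds give bit-identical pattern sets and histories.
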