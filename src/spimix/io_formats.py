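"""Readers and writers for atomic models, 3D intensity volumes, pattern sets
and run configurations.

Conventions
-----------
* Real space is measured in Å; reciprocal space in Å⁻¹ with the
  crystallographic convention ``|q| = 2 sin(θ)/λ`` so that resolution is
  ``d = 1/|q|``.
* 3D intensity volumes are cubic grids with the ``q = 0`` voxel at index
  ``N // 2`` on every axis.  On disk they are CCP4/MRC maps whose cell edge
  stores ``N · Δq`` (the full reciprocal box edge, in Å⁻¹); voxels flagged
  as missing (never touched by any pattern during merging) are stored as NaN.
* Pattern sets are HDF5 containers with datasets ``/patterns`` (uint32,
  N×H×W), ``/mask`` (bool, H×W, True = valid pixel) and per-pattern metadata
  under ``/meta``: ``species`` (int), ``euler`` (N×3 radians, zyz intrinsic)
  and ``fluence`` (photons/m², the jittered value actually applied).  The
  metadata records the simulation ground truth and is read only by the
  evaluation stage, never by the classification algorithm itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import gemmi
import h5py
import numpy as np
import yaml

__all__ = [
    "AtomicModel",
    "IntensityVolume",
    "PatternSet",
    "RunConfig",
    "read_model",
    "write_model",
    "read_volume",
    "write_volume",
    "save_patterns",
    "load_patterns",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class AtomicModel:
    """A set of atoms: element symbols, Cartesian coordinates in Å,
    occupancies and (optionally) isotropic B-factors, with chain/residue
    labels retained for subsetting."""

    elements: np.ndarray          # (n,) unicode element symbols
    coords: np.ndarray            # (n, 3) float, Å
    occupancy: np.ndarray         # (n,) float
    b_factors: np.ndarray | None = None
    chains: np.ndarray | None = None      # (n,) chain name per atom
    residue_ids: np.ndarray | None = None  # (n,) residue sequence number

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.elements = np.asarray(self.elements)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if len(self.coords) == 0:
            raise ValueError("an atomic model needs at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        # every symbol must resolve in the periodic table
        for sym in np.unique(self.elements):
            if gemmi.Element(str(sym)).atomic_number == 0:
                raise ValueError(f"unknown element symbol: {sym!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def electron_counts(self) -> np.ndarray:
        """Electrons per atom: atomic number scaled by occupancy."""
        z = np.array([gemmi.Element(str(s)).atomic_number for s in self.elements],
                     dtype=float)
        return z * self.occupancy

    def n_residues(self) -> int:
        """Number of distinct (chain, residue id) labels."""
        if self.chains is None or self.residue_ids is None:
            return self.n_atoms
        return len({(c, r) for c, r in zip(self.chains, self.residue_ids)})

    def centered(self) -> "AtomicModel":
        """Copy with the electron-weighted centroid moved to the origin."""
        w = self.electron_counts
        if w.sum() > 0:
            com = (self.coords * w[:, None]).sum(0) / w.sum()
        else:  # zero-occupancy degenerate model: plain centroid
            com = self.coords.mean(0)
        return replace(self, coords=self.coords - com)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "AtomicModel":
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation).T
        if translation is not None:
            xyz = xyz + np.asarray(translation)
        return replace(self, coords=xyz)


@dataclass
class IntensityVolume:
    """3D diffraction intensity |F(q)|² on a cubic reciprocal grid.

    ``data[i, j, k]`` lives at ``q = (i - N//2, j - N//2, k - N//2) · dq``
    with axis order (qx, qy, qz).  ``missing`` marks voxels that carry no
    measurement (e.g. never touched during merging); they are excluded from
    correlations and stored as NaN on disk.
    """

    data: np.ndarray              # (N, N, N) float
    dq: float                     # grid step, Å⁻¹
    missing: np.ndarray | None = None  # (N, N, N) bool, True = no data

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError("intensity volume must be a cubic 3D grid")
        if not self.dq > 0:
            raise ValueError("voxel spacing dq must be positive")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def q_max(self) -> float:
        """Largest |q| on an axis, Å⁻¹."""
        return (self.n - self.n // 2 - 1) * self.dq

    def valid_mask(self) -> np.ndarray:
        if self.missing is None:
            return np.ones(self.data.shape, dtype=bool)
        return ~self.missing


@dataclass
class PatternSet:
    """A stack of photon-count diffraction patterns with one shared validity
    mask and hidden per-pattern ground truth."""

    patterns: np.ndarray          # (N, H, W) uint32 photon counts
    mask: np.ndarray              # (H, W) bool, True = valid pixel
    species: np.ndarray           # (N,) int true class label
    euler: np.ndarray             # (N, 3) float true zyz Euler angles
    fluence: np.ndarray           # (N,) float photons/m² actually applied

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.patterns.ndim != 3:
            raise ValueError("patterns must be a (N, H, W) stack")
        if len(self.patterns) == 0:
            raise ValueError("a pattern set must contain at least one pattern")
        if self.patterns.shape[1:] != self.mask.shape:
            raise ValueError("mask shape must match pattern shape")
        if np.issubdtype(self.patterns.dtype, np.integer):
            if self.patterns.min() < 0:
                raise ValueError("photon counts must be non-negative")
        n = len(self.patterns)
        for name in ("species", "euler", "fluence"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"metadata '{name}' length mismatch")

    def __len__(self) -> int:
        return len(self.patterns)


_CONFIG_FIELDS = """wavelength_A distance_m detector_px pixel_um beam_stop_px
photons_per_pulse focus_um fluence_jitter pattern_counts cc_threshold
max_iterations stop_tol angular_step_deg n_theta volume_grid seed""".split()


@dataclass
class RunConfig:
    """Full run configuration; mirrors the YAML file field-for-field.

    Physical quantities follow the units in the field names.  ``pattern_counts``
    is the number of simulated patterns per species; ``cc_threshold`` is the
    CC¹−CC² rejection margin; ``angular_step_deg`` the orientation grid
    spacing δ; ``n_theta`` the number of polar angular bins (power of two);
    ``volume_grid`` the cubic template grid size before 2× downsampling.
    """

    wavelength_A: float = 1.0
    distance_m: float = 0.5
    detector_px: tuple[int, int] = (512, 512)
    pixel_um: float = 300.0
    beam_stop_px: int = 10
    photons_per_pulse: float = 2e12
    focus_um: float = 0.1
    fluence_jitter: float = 0.10
    pattern_counts: tuple[int, ...] = (20000, 10000, 5000)
    cc_threshold: float = 0.02
    max_iterations: int = 10
    stop_tol: float = 0.001
    angular_step_deg: float = 6.0
    n_theta: int = 256
    volume_grid: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        self.detector_px = tuple(int(v) for v in np.atleast_1d(self.detector_px))
        if len(self.detector_px) == 1:
            self.detector_px = (self.detector_px[0], self.detector_px[0])
        self.pattern_counts = tuple(int(v) for v in self.pattern_counts)
        for name in ("wavelength_A", "distance_m", "pixel_um",
                     "photons_per_pulse", "focus_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.cc_threshold < 0:
            raise ValueError("cc_threshold must be >= 0")
        if any(d % 2 for d in self.detector_px):
            raise ValueError("detector dimensions must be even (2x binning)")
        if self.volume_grid % 2:
            raise ValueError("volume_grid must be even (2x binning)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        unknown = set(raw) - set(_CONFIG_FIELDS)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        with open(path, "w") as fh:
            yaml.safe_dump(out, fh, sort_keys=False)


# --------------------------------------------------------------------------
# atomic models (PDB / mmCIF via gemmi)
# --------------------------------------------------------------------------

def read_model(path: str | Path, selector: str | None = None) -> AtomicModel:
    """Read a PDB or mmCIF file into an :class:`AtomicModel`.

    ``selector`` currently supports ``"chain X"`` (case-sensitive chain
    name).  Hydrogens are kept if present.  Raises if the file cannot be
    parsed or the selector matches zero atoms.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    chain_filter = None
    if selector is not None:
        parts = selector.split()
        if len(parts) != 2 or parts[0].lower() != "chain":
            raise ValueError(f"unsupported selector: {selector!r}")
        chain_filter = parts[1]

    elements, coords, occ, bfac, chains, resids = [], [], [], [], [], []
    model = st[0]
    for chain in model:
        if chain_filter is not None and chain.name != chain_filter:
            continue
        for residue in chain:
            for atom in residue:
                elements.append(atom.element.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                occ.append(atom.occ)
                bfac.append(atom.b_iso)
                chains.append(chain.name)
                resids.append(residue.seqid.num)
    if not coords:
        raise ValueError(f"selector {selector!r} matched zero atoms in {path}")
    return AtomicModel(
        elements=np.array(elements),
        coords=np.array(coords, dtype=float),
        occupancy=np.array(occ, dtype=float),
        b_factors=np.array(bfac, dtype=float),
        chains=np.array(chains),
        residue_ids=np.array(resids, dtype=int),
    )


def write_model(path: str | Path, model: AtomicModel) -> None:
    """Write an :class:`AtomicModel` as a PDB file (one atom per residue if
    no residue labels are present)."""
    st = gemmi.Structure()
    st.name = "spimix"
    md = gemmi.Model("1")
    chains = model.chains if model.chains is not None else np.full(model.n_atoms, "A")
    resids = (model.residue_ids if model.residue_ids is not None
              else np.arange(1, model.n_atoms + 1))
    bfacs = model.b_factors if model.b_factors is not None else np.zeros(model.n_atoms)
    for cname in dict.fromkeys(chains):  # preserve order
        ch = gemmi.Chain(str(cname))
        sel = np.where(chains == cname)[0]
        cur_res = None
        cur_id = None
        for i in sel:
            rid = int(resids[i])
            if cur_res is None or rid != cur_id:
                cur_res = gemmi.Residue()
                cur_res.name = "DUM"
                cur_res.seqid = gemmi.SeqId(rid, " ")
                ch.add_residue(cur_res)
                cur_res = ch[-1]
                cur_id = rid
            at = gemmi.Atom()
            at.name = str(model.elements[i])
            at.element = gemmi.Element(str(model.elements[i]))
            at.pos = gemmi.Position(*model.coords[i])
            at.occ = float(model.occupancy[i])
            at.b_iso = float(bfacs[i])
            cur_res.add_atom(at)
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# --------------------------------------------------------------------------
# intensity volumes (MRC/CCP4 via gemmi)
# --------------------------------------------------------------------------

def write_volume(path: str | Path, volume: IntensityVolume) -> None:
    """Write a cubic intensity volume as a CCP4/MRC map.

    Convention: the unit-cell edge stores ``N · dq`` so readers recover the
    reciprocal grid step as ``cell.a / N`` (in Å⁻¹, despite the format's
    nominal Å).  Missing voxels become NaN.
    """
    data = volume.data.astype(np.float32)  # astype always copies here
    if volume.missing is not None:
        data[volume.missing] = np.nan
    n = volume.n
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(data))
    ccp4.grid.unit_cell = gemmi.UnitCell(n * volume.dq, n * volume.dq,
                                         n * volume.dq, 90, 90, 90)
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def read_volume(path: str | Path) -> IntensityVolume:
    """Read a cubic CCP4/MRC intensity volume written by :func:`write_volume`."""
    ccp4 = gemmi.read_ccp4_map(str(path))
    arr = np.array(ccp4.grid, copy=True, dtype=float)
    if arr.ndim != 3 or len(set(arr.shape)) != 1:
        raise ValueError(f"{path}: volume grid is not cubic: {arr.shape}")
    cell = ccp4.grid.unit_cell
    dq = cell.a / arr.shape[0]
    if not dq > 0:
        raise ValueError(f"{path}: missing voxel spacing in header")
    missing = np.isnan(arr)
    if missing.any():
        arr = np.where(missing, 0.0, arr)
        return IntensityVolume(arr, dq, missing=missing)
    return IntensityVolume(arr, dq)


# --------------------------------------------------------------------------
# pattern sets (HDF5)
# --------------------------------------------------------------------------

def save_patterns(path: str | Path, patterns: PatternSet) -> None:
    """Write a :class:`PatternSet` to an HDF5 container (lossless)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("patterns", data=patterns.patterns.astype(np.uint32),
                          compression="gzip", compression_opts=4)
        fh.create_dataset("mask", data=patterns.mask)
        meta = fh.create_group("meta")
        meta.create_dataset("species", data=np.asarray(patterns.species, dtype=np.int32))
        meta.create_dataset("euler", data=np.asarray(patterns.euler, dtype=float))
        meta.create_dataset("fluence", data=np.asarray(patterns.fluence, dtype=float))


def load_patterns(path: str | Path) -> PatternSet:
    with h5py.File(path, "r") as fh:
        try:
            return PatternSet(
                patterns=fh["patterns"][...],
                mask=fh["mask"][...].astype(bool),
                species=fh["meta/species"][...],
                euler=fh["meta/euler"][...],
                fluence=fh["meta/fluence"][...],
            )
        except KeyError as exc:
            raise ValueError(f"{path}: not a spimix pattern container") from exc
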