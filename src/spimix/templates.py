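"""Initial 3D intensity templates from (predicted) atomic models, plus the
2× downsampling used to precondition patterns and volumes.

A template is |F(q)|² sampled on the same reciprocal grid the simulation
uses, built from the predicted model's Gaussian-atom density via the exact
closed-form transform, then Friedel-symmetrized.  Because Pearson matching
is scale-invariant, templates need no fluence/solid-angle prefactor.
"""

from __future__ import annotations

import numpy as np

from .io_formats import AtomicModel, IntensityVolume
from .simulate import DetectorGeometry, default_dq, intensity_volume

__all__ = [
    "build_template",
    "friedel_symmetrize",
    "downsample_volume",
    "downsample_pattern",
]


def friedel_symmetrize(volume: IntensityVolume) -> IntensityVolume:
    """Enforce I(q) = I(−q) by averaging each voxel with its inversion mate.

    The inversion centre is the q = 0 voxel at index N//2; the hull voxels
    without a mate (index 0 on an even grid) are left as they are.  Where
    exactly one of a voxel pair is missing, the measured mate fills it in —
    Friedel completion shrinks the missing wedge.
    """
    n = volume.n
    inv = np.zeros_like(volume.data)
    inv[1:, 1:, 1:] = volume.data[:0:-1, :0:-1, :0:-1]
    if volume.missing is None:
        data = 0.5 * (volume.data + inv)
        data[0, :, :] = volume.data[0, :, :]
        data[:, 0, :] = volume.data[:, 0, :]
        data[:, :, 0] = volume.data[:, :, 0]
        return IntensityVolume(data, volume.dq)
    # hull slices (index 0) have no inversion mate; inv/inv_have stay zero
    # there, so the weighted mean below reduces to the original values.
    have = ~volume.missing
    inv_have = np.zeros_like(have)
    inv_have[1:, 1:, 1:] = have[:0:-1, :0:-1, :0:-1]
    weight = have.astype(float) + inv_have.astype(float)
    total = np.where(have, volume.data, 0.0) + np.where(inv_have, inv, 0.0)
    data = np.where(weight > 0, total / np.maximum(weight, 1.0), 0.0)
    return IntensityVolume(data, volume.dq, missing=weight == 0)


def build_template(predicted: AtomicModel, geometry: DetectorGeometry,
                   grid_n: int = 128, atom_sigma: float = 1.0,
                   dq: float | None = None) -> IntensityVolume:
    """3D intensity template |F(q)|² for a predicted model on the cubic grid
    matched to the detector band limit (see :func:`simulate.default_dq`)."""
    if dq is None:
        dq = default_dq(geometry, grid_n)
    half_extent = (grid_n // 2 - 1) * dq
    if half_extent < geometry.q_edge():
        raise ValueError("template grid too coarse for the detector band limit")
    vol = intensity_volume(predicted, geometry, grid_n=grid_n,
                           atom_sigma=atom_sigma, dq=dq)
    return friedel_symmetrize(vol)


def downsample_volume(volume: IntensityVolume, factor: int = 2) -> IntensityVolume:
    """Mean-bin a volume by ``factor`` per axis; dq scales by ``factor``.

    Missing voxels are excluded from each bin's mean; a bin with no valid
    constituent stays missing.
    """
    n = volume.n
    if n % factor:
        raise ValueError("volume size not divisible by the binning factor")
    m = n // factor
    blocks = volume.data.reshape(m, factor, m, factor, m, factor)
    if volume.missing is None:
        data = blocks.mean(axis=(1, 3, 5))
        return IntensityVolume(data, volume.dq * factor)
    valid = (~volume.missing).reshape(m, factor, m, factor, m, factor)
    cnt = valid.sum(axis=(1, 3, 5))
    tot = (blocks * valid).sum(axis=(1, 3, 5))
    data = np.where(cnt > 0, tot / np.maximum(cnt, 1), 0.0)
    return IntensityVolume(data, volume.dq * factor, missing=cnt == 0)


def downsample_pattern(pattern: np.ndarray, mask: np.ndarray | None = None,
                       factor: int = 2) -> tuple[np.ndarray, np.ndarray | None]:
    """Sum-bin photon counts by ``factor``×``factor`` (total counts and
    Poisson statistics preserved); a binned pixel is valid only if every
    constituent pixel is valid.

    Accepts a single image (H, W) or a stack (N, H, W); returns the binned
    array and the binned mask (or None if no mask was given).
    """
    arr = np.asarray(pattern)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    _, h, w = arr.shape
    if h % factor or w % factor:
        raise ValueError("pattern shape not divisible by the binning factor")
    binned = arr.reshape(arr.shape[0], h // factor, factor,
                         w // factor, factor).sum(axis=(2, 4))
    out_mask = None
    if mask is not None:
        out_mask = np.asarray(mask, bool).reshape(
            h // factor, factor, w // factor, factor).all(axis=(1, 3))
    return (binned[0] if squeeze else binned), out_mask
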