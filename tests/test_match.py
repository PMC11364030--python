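"""Slicing, polar transform and the masked-Pearson γ-search — including the
central FFT-equals-brute-force property."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spimix.fixtures import toy_species
from spimix.io_formats import IntensityVolume, PatternSet
from spimix.match import (PolarImage, ccmax_over_gamma, compute_cc_table,
                          pearson_cc, slice_volume, to_polar)
from spimix.orientations import Orientation, OrientationGrid, sample_random
from spimix.simulate import (BeamModel, ewald_map, expected_counts,
                             intensity_volume)


def brute_force_ccmax(pattern: PolarImage, sl: PolarImage):
    """Independent oracle: explicit masked Pearson at every cyclic shift."""
    best_cc, best_k = -np.inf, 0
    for k in range(sl.values.shape[1]):
        rolled = np.roll(sl.values, -k, axis=1)    # slice rotated by +k bins
        rolled_mask = np.roll(sl.valid, -k, axis=1)
        joint = pattern.valid & rolled_mask
        cc = pearson_cc(pattern.values, rolled, joint)
        if cc > best_cc:
            best_cc, best_k = cc, k
    return best_cc, best_k


class TestSliceVolume:
    def test_isotropic_volume_gives_radial_slice(self, small_geom):
        n = 32
        ax = np.arange(n) - n // 2
        r = np.sqrt(ax[:, None, None]**2 + ax[None, :, None]**2 +
                    ax[None, None, :]**2)
        vol = IntensityVolume(np.exp(-r / 4.0), dq=small_geom.q_edge() / 13)
        ew = ewald_map(small_geom)
        sl, valid = slice_volume(vol, Orientation(0, 0, 0), ew)
        # bins at the same |q| must agree regardless of azimuth
        qlen = ew.q_length
        ring = np.abs(qlen - 0.5 * small_geom.q_edge()) < 0.02 * small_geom.q_edge()
        vals = sl[ring & valid]
        assert vals.std() < 0.05 * vals.mean()  # trilinear anisotropy

    def test_rotation_equivariance_quarter_turn(self, small_geom):
        # slicing a volume at Rz(90°) equals slicing the (exactly permuted)
        # rotated volume at identity
        rng = np.random.default_rng(0)
        vol_data = rng.random((32, 32, 32))
        dq = small_geom.q_edge() / 13
        ew = ewald_map(small_geom)
        sl_rot, v1 = slice_volume(IntensityVolume(vol_data, dq),
                                  Orientation(np.pi / 2, 0, 0), ew)
        # Rz(+90°): (x, y, z) -> (-y, x, z); on the grid (centred even grids
        # lose one hull slice, so compare away from the hull)
        rotated = np.rot90(vol_data, k=1, axes=(1, 0))
        rotated = np.roll(rotated, 1, axis=1)
        sl_id, v2 = slice_volume(IntensityVolume(rotated, dq),
                                 Orientation(0, 0, 0), ew)
        sel = v1 & v2
        assert np.allclose(sl_rot[sel], sl_id[sel], atol=1e-9)

    def test_out_of_volume_pixels_invalid_not_error(self, small_geom):
        vol = IntensityVolume(np.ones((8, 8, 8)), dq=small_geom.q_edge() / 50)
        sl, valid = slice_volume(vol, Orientation(0, 0, 0),
                                 ewald_map(small_geom))
        assert not valid.all()
        assert valid[small_geom.beam_center]

    def test_missing_voxels_invalidate_pixels(self, small_geom):
        data = np.ones((32, 32, 32))
        missing = np.zeros((32, 32, 32), bool)
        missing[16, 16, 16] = True      # q = 0 voxel
        vol = IntensityVolume(data, dq=small_geom.q_edge() / 13,
                              missing=missing)
        sl, valid = slice_volume(vol, Orientation(0, 0, 0),
                                 ewald_map(small_geom))
        assert not valid[small_geom.beam_center]


class TestToPolar:
    def test_constant_image_constant_polar(self):
        img = np.full((32, 32), 7.0)
        p = to_polar(img, np.ones((32, 32), bool), n_r=12, n_theta=32)
        assert np.allclose(p.values[p.valid], 7.0)

    def test_ring_image_single_radial_row(self):
        n = 64
        ax = np.arange(n) - n // 2
        r = np.hypot(ax[:, None], ax[None, :])
        img = np.where(np.abs(r - 10.0) < 1.0, 1.0, 0.0)
        p = to_polar(img, np.ones((n, n), bool), n_r=20, n_theta=64)
        row_mass = p.values.sum(axis=1)
        assert row_mass.argmax() in (9, 10)
        assert row_mass[[9, 10]].sum() > 0.7 * row_mass.sum()

    def test_smooth_rotation_is_cyclic_shift(self):
        # f(r, θ) = g(r)·cos(4(θ − θ0)): rotating θ0 by one angular bin
        # cyclically shifts the polar image
        n, n_theta = 64, 32
        ax = np.arange(n) - n // 2
        yy, xx = np.meshgrid(ax, ax, indexing="ij")
        r = np.hypot(yy, xx)
        th = np.arctan2(yy, xx)
        g = np.exp(-((r - 12) / 6) ** 2)
        d_theta = 2 * np.pi / n_theta
        img0 = g * np.cos(4 * th)
        img1 = g * np.cos(4 * (th - d_theta))
        mask = np.ones((n, n), bool)
        p0 = to_polar(img0, mask, n_r=20, n_theta=n_theta)
        p1 = to_polar(img1, mask, n_r=20, n_theta=n_theta)
        shifted = np.roll(p0.values, 1, axis=1)
        sel = p0.valid & np.roll(p0.valid, 1, axis=1) & (g[32, 32 + np.arange(20)] > 0.3)[:, None]
        assert np.allclose(p1.values[sel], shifted[sel], atol=0.05)

    def test_masked_pixels_invalidate_bins(self):
        mask = np.ones((32, 32), bool)
        mask[16, 20] = False
        p = to_polar(np.ones((32, 32)), mask, n_r=12, n_theta=64)
        assert not p.valid.all()

    def test_n_r_beyond_half_width_rejected(self):
        with pytest.raises(ValueError):
            to_polar(np.ones((32, 32)), np.ones((32, 32), bool),
                     n_r=20, n_theta=64)


class TestPearson:
    def test_hand_computed_values(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_cc(x, 2 * x) == pytest.approx(1.0)
        assert pearson_cc(x, x[::-1]) == pytest.approx(-1.0)
        assert pearson_cc(x, np.array([1.0, 3.0, 2.0, 4.0])) == pytest.approx(0.8)

    @given(st.floats(0.1, 10), st.floats(-5, 5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b):
        x = np.array([0.3, 1.9, -2.0, 4.4, 0.0])
        assert pearson_cc(x, a * x + b) == pytest.approx(1.0, abs=1e-9)
        assert pearson_cc(x, -a * x + b) == pytest.approx(-1.0, abs=1e-9)

    def test_degenerate_inputs_return_neg_inf(self):
        x = np.arange(4.0)
        assert pearson_cc(x, np.ones(4)) == -np.inf
        assert pearson_cc(x[:1], x[:1]) == -np.inf
        mask = np.zeros(4, bool)
        assert pearson_cc(x, x, mask) == -np.inf


class TestCCMaxOverGamma:
    def _random_polar(self, rng, n_r=12, n_theta=32, mask_frac=0.1):
        values = rng.random((n_r, n_theta))
        valid = rng.random((n_r, n_theta)) > mask_frac
        return PolarImage(values=values, valid=valid)

    def test_identical_images_give_unit_cc_at_zero_shift(self):
        rng = np.random.default_rng(0)
        p = self._random_polar(rng)
        cc, k = ccmax_over_gamma(p, p)
        assert cc == pytest.approx(1.0, abs=1e-12)
        assert k == 0

    def test_shift_recovery(self):
        rng = np.random.default_rng(1)
        base = self._random_polar(rng, mask_frac=0.0)
        # rolling by +5 moves features to larger θ, i.e. the slice appears
        # rotated by −5 bins; the matcher must rotate it by +5 to line up
        shifted = PolarImage(values=np.roll(base.values, 5, axis=1),
                             valid=base.valid)
        cc, k = ccmax_over_gamma(base, shifted)
        assert cc == pytest.approx(1.0, abs=1e-12)
        assert k == 5

    def test_matches_brute_force_loop_on_100_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = self._random_polar(rng)
            s = self._random_polar(rng)
            cc_fft, k_fft = ccmax_over_gamma(p, s)
            cc_ref, k_ref = brute_force_ccmax(p, s)
            assert abs(cc_fft - cc_ref) < 1e-10
            assert k_fft == k_ref

    def test_all_invalid_raises(self):
        p = PolarImage(values=np.zeros((4, 8)), valid=np.zeros((4, 8), bool))
        with pytest.raises(ValueError):
            ccmax_over_gamma(p, p)



@pytest.fixture(scope="module")
def cc_table_setup(small_geom):
    monomer = toy_species("monomer")
    dimer = toy_species("dimer")
    vols = [intensity_volume(m, small_geom, grid_n=32)
            for m in (monomer, dimer)]
    rng = np.random.default_rng(7)
    orients = sample_random(3, rng)
    beam_fluence = 3e30
    ew = ewald_map(small_geom)
    stack = np.stack([
        np.random.default_rng(i).poisson(
            expected_counts(m, o, small_geom, beam_fluence, ewald=ew)
        ).astype(np.uint32)
        for i, (m, o) in enumerate(zip([monomer, dimer, dimer], orients))
    ])
    patterns = PatternSet(stack, small_geom.valid_mask(),
                          species=np.array([0, 1, 1]),
                          euler=np.array([o.euler for o in orients]),
                          fluence=np.full(3, beam_fluence))
    grid_rng = np.random.default_rng(3)
    grid = OrientationGrid(alphas=grid_rng.uniform(0, 2 * np.pi, 30),
                           betas=np.arccos(grid_rng.uniform(-1, 1, 30)),
                           step=0.5)
    return patterns, vols, grid


class TestCCTable:
    def test_equals_exhaustive_direct_correlation(self, small_geom,
                                                  cc_table_setup):
        patterns, vols, grid = cc_table_setup
        n_theta = 32
        table = compute_cc_table(patterns, vols, grid, small_geom,
                                 n_theta=n_theta)
        # oracle: polar images once, then explicit per-orientation,
        # per-shift masked Pearson maximisation
        n_r = min(small_geom.shape) // 2
        det_mask = patterns.mask & small_geom.valid_mask()
        ew = ewald_map(small_geom)
        pat_polar = [to_polar(p.astype(float), det_mask, n_r, n_theta)
                     for p in patterns.patterns]
        for m, vol in enumerate(vols):
            for n, pp in enumerate(pat_polar):
                best = (-np.inf, 0, 0)
                for d in range(len(grid)):
                    sl, valid = slice_volume(
                        vol, Orientation(grid.alphas[d], grid.betas[d], 0.0),
                        ew, det_mask)
                    sp = to_polar(sl, valid, n_r, n_theta)
                    cc, k = brute_force_ccmax(pp, sp)
                    if cc > best[0]:
                        best = (cc, d, k)
                assert table.cc[n, m] == pytest.approx(best[0], abs=1e-10)
                exp_euler = (grid.alphas[best[1]], grid.betas[best[1]],
                             2 * np.pi * best[2] / n_theta)
                assert np.allclose(table.euler[n, m], exp_euler, atol=1e-12)

    def test_invariant_to_template_rescaling(self, small_geom, cc_table_setup):
        patterns, vols, grid = cc_table_setup
        table = compute_cc_table(patterns, vols, grid, small_geom, n_theta=32)
        scaled = [IntensityVolume(17.3 * v.data, v.dq) for v in vols]
        table2 = compute_cc_table(patterns, scaled, grid, small_geom, n_theta=32)
        assert np.allclose(table.cc, table2.cc, atol=1e-9)

    def test_noiseless_self_slices_recover_exact_orientation(self, small_geom):
        # patterns that ARE slices of template 0 at grid orientations
        vol = intensity_volume(toy_species("monomer"), small_geom, grid_n=32)
        other = intensity_volume(toy_species("dimer"), small_geom, grid_n=32)
        ew = ewald_map(small_geom)
        grid = OrientationGrid(alphas=np.array([0.5, 2.0, 4.0]),
                               betas=np.array([0.4, 1.3, 2.2]), step=0.5)
        det_mask = small_geom.valid_mask()
        slices = []
        for a, b in zip(grid.alphas, grid.betas):
            sl, _ = slice_volume(vol, Orientation(a, b, 0.0), ew, det_mask)
            slices.append(sl)
        patterns = PatternSet(np.stack(slices), det_mask,
                              species=np.zeros(3, int),
                              euler=np.zeros((3, 3)),
                              fluence=np.ones(3))
        table = compute_cc_table(patterns, [vol, other], grid, small_geom,
                                 n_theta=32)
        assert np.all(table.cc[:, 0] > 0.9999)
        assert np.all(np.argmax(table.cc, axis=1) == 0)
        for i in range(3):
            assert table.euler[i, 0, 0] == pytest.approx(grid.alphas[i])
            assert table.euler[i, 0, 1] == pytest.approx(grid.betas[i])
            assert table.euler[i, 0, 2] == pytest.approx(0.0)
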