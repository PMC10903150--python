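"""Euler characteristic, windowed Minkowski maps and interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tprm.prm import CLASS_CODES
from tprm.synthetic import PhantomSpec, generate_phantom, shape_phantoms
from tprm.topology import (
    compute_tprm,
    euler_characteristic,
    interpolate_to_grid,
    minkowski_window_maps,
)

from conftest import chi_bruteforce


class TestEulerCharacteristic:
    @pytest.mark.parametrize("name", list(shape_phantoms()))
    def test_canonical_shapes(self, name):
        vol, expected = shape_phantoms()[name]
        assert euler_characteristic(vol) == expected
        assert chi_bruteforce(vol) == expected

    def test_two_isolated_voxels_additive(self):
        vol = np.zeros((5, 5, 5), dtype=bool)
        vol[0, 0, 0] = vol[3, 3, 3] = True
        assert euler_characteristic(vol) == 2

    def test_matches_bruteforce_on_random_volumes(self):
        rng = np.random.default_rng(42)
        for shape, p in [((7, 7, 7), 0.2), ((9, 6, 8), 0.4), ((11, 11, 11), 0.6)]:
            for _ in range(3):
                vol = rng.random(shape) < p
                assert euler_characteristic(vol) == chi_bruteforce(vol)

    def test_additivity_over_disjoint_union(self):
        rng = np.random.default_rng(3)
        a = rng.random((6, 6, 6)) < 0.4
        b = rng.random((6, 6, 6)) < 0.4
        combined = np.zeros((14, 6, 6), dtype=bool)
        combined[:6] = a
        combined[8:] = b
        assert euler_characteristic(combined) == (
            euler_characteristic(a) + euler_characteristic(b)
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 3), st.integers(0, 3),
           st.integers(0, 3))
    def test_translation_invariance(self, seed, ox, oy, oz):
        rng = np.random.default_rng(seed)
        vol = rng.random((5, 5, 5)) < 0.4
        emb = np.zeros((10, 10, 10), dtype=bool)
        emb[ox:ox + 5, oy:oy + 5, oz:oz + 5] = vol
        assert euler_characteristic(emb) == euler_characteristic(vol)

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            euler_characteristic(np.full((3, 3, 3), 2.0))
        with pytest.raises(ValueError):
            euler_characteristic(np.ones((3, 3)))


class TestWindowMaps:
    def test_class_equals_lung_gives_unit_v(self):
        lung = np.zeros((45, 45, 45), dtype=bool)
        lung[5:40, 5:40, 5:40] = True
        v, chi, _ = minkowski_window_maps(lung, lung)
        assert np.nanmax(v) == pytest.approx(1.0)
        assert np.nanmin(v) == pytest.approx(1.0)
        # a fully interior window of a solid block has chi = 1
        interior = chi[4, 4, 4]
        assert interior == pytest.approx(1.0 / 21**3)

    def test_empty_class_gives_zero(self):
        lung = np.ones((45, 45, 45), dtype=bool)
        v, chi, _ = minkowski_window_maps(np.zeros_like(lung), lung)
        assert np.nanmax(np.abs(v)) == 0
        assert np.nanmax(np.abs(chi)) == 0

    def test_single_isolated_voxel_normalization(self):
        lung = np.ones((45, 45, 45), dtype=bool)
        cls = np.zeros_like(lung)
        cls[22, 22, 22] = True
        v, chi, coords = minkowski_window_maps(cls, lung)
        # the grid node at (20,20,20) has the voxel in its (fully interior) window
        gi = (4, 4, 4)
        m = 21**3
        assert chi[gi] == pytest.approx(1.0 / m)
        assert v[gi] == pytest.approx(1.0 / m)

    def test_windowed_chi_equals_bruteforce_per_window(self):
        rng = np.random.default_rng(9)
        lung = np.ones((45, 45, 45), dtype=bool)
        cls = rng.random(lung.shape) < 0.3
        window, stride = 21, 5
        v, chi, coords = minkowski_window_maps(cls, lung, window, stride)
        h = window // 2
        for gi, gj, gk in [(0, 0, 0), (4, 4, 4), (8, 8, 8), (2, 6, 3)]:
            ci, cj, ck = coords[0][gi], coords[1][gj], coords[2][gk]
            sl = tuple(slice(max(c - h, 0), c + h + 1) for c in (ci, cj, ck))
            sub = cls[sl]
            lung_cnt = lung[sl].sum()
            assert chi[gi, gj, gk] * lung_cnt == pytest.approx(chi_bruteforce(sub))
            assert v[gi, gj, gk] * lung_cnt == pytest.approx(sub.sum())

    def test_v_bounds_and_class_decomposition(self, three_class_phantom):
        _, ct, truth = three_class_phantom
        lung = ct.lung_mask
        vs = []
        for cls in ("Norm", "fSAD", "Emph"):
            v, _, _ = minkowski_window_maps(truth.labels == CLASS_CODES[cls], lung)
            assert np.nanmin(v) >= 0 and np.nanmax(v) <= 1
            vs.append(v)
        # no Unclassified voxels planted: class volume densities partition 1
        valid = np.isfinite(vs[0])
        total = vs[0][valid] + vs[1][valid] + vs[2][valid]
        assert np.allclose(total, 1.0)

    def test_input_validation(self):
        lung = np.ones((45, 45, 45), dtype=bool)
        with pytest.raises(ValueError):
            minkowski_window_maps(lung, lung, window_vox=20)
        with pytest.raises(ValueError):
            minkowski_window_maps(lung, np.zeros_like(lung))


class TestInterpolation:
    def test_constant_grid_gives_constant_field(self):
        lung = np.ones((45, 45, 45), dtype=bool)
        coords = tuple(np.arange(0, 45, 5) for _ in range(3))
        grid = np.full((9, 9, 9), 0.37)
        out = interpolate_to_grid(grid, coords, lung)
        assert np.allclose(out[lung], 0.37)

    def test_node_values_preserved_and_midpoint_linear(self):
        lung = np.ones((45, 45, 45), dtype=bool)
        # stride 4 puts voxel 18 exactly halfway between nodes 16 and 20
        coords = tuple(np.arange(0, 45, 4) for _ in range(3))
        grid = np.zeros((12, 12, 12))
        grid[5, 5, 5] = 1.0
        out = interpolate_to_grid(grid, coords, lung)
        assert out[20, 20, 20] == pytest.approx(1.0)
        assert out[18, 20, 20] == pytest.approx(0.5)
        assert out[24, 20, 20] == pytest.approx(0.0)

    def test_all_invalid_grid_raises(self):
        lung = np.ones((45, 45, 45), dtype=bool)
        coords = tuple(np.arange(0, 45, 5) for _ in range(3))
        with pytest.raises(ValueError):
            interpolate_to_grid(np.full((9, 9, 9), np.nan), coords, lung)


class TestWholeLungMeans:
    def test_v_mean_matches_planted_fractions(self, three_class_phantom):
        _, ct, truth = three_class_phantom
        maps = compute_tprm(truth.labels, ct.lung_mask, CLASS_CODES,
                            classes=("Norm", "fSAD", "Emph"))
        assert maps.whole_lung_means["Norm"][0] == pytest.approx(0.60, abs=0.02)
        assert maps.whole_lung_means["fSAD"][0] == pytest.approx(0.30, abs=0.02)
        assert maps.whole_lung_means["Emph"][0] == pytest.approx(0.10, abs=0.02)

    def test_class_equal_to_lung_has_unit_mean(self):
        spec = PhantomSpec(class_fractions={"Norm": 1.0}, seed=0)
        ct, truth = generate_phantom(spec)
        maps = compute_tprm(truth.labels, ct.lung_mask, CLASS_CODES,
                            classes=("Norm",))
        assert maps.whole_lung_means["Norm"][0] == pytest.approx(1.0)

    def test_chi_sign_tracks_pocket_vs_mesh(self):
        sparse = PhantomSpec(n_fsad_pockets=8, coalescence=0.0,
                             pocket_radius_vox=3, seed=5)
        mesh = PhantomSpec(class_fractions={"fSAD": 0.35}, coalescence=0.6,
                           pocket_radius_vox=3, seed=5)
        chis = {}
        for name, spec in (("sparse", sparse), ("mesh", mesh)):
            ct, truth = generate_phantom(spec)
            fsad = truth.labels == CLASS_CODES["fSAD"]
            maps = compute_tprm(truth.labels, ct.lung_mask, CLASS_CODES,
                                classes=("fSAD",))
            chis[name] = maps.whole_lung_means["fSAD"][1]
            # whole-mask chi agrees in sign with the windowed mean
            global_chi = euler_characteristic(fsad)
            assert np.sign(global_chi) == np.sign(chis[name])
        assert chis["sparse"] > 0 > chis["mesh"]
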