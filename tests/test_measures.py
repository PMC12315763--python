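import numpy as np
import pytest
from scipy import stats as sps

from calvaria import compute_all, generate_phantom, make_retest_pair
from calvaria.atlas import OCCIPITAL, build_atlas_for_grid
from calvaria.io import HEAD, WM, TissueSegmentation, VolumeGrid
from calvaria.measures import (
    GaussianMixtureFit,
    MeasureConfig,
    ReferenceError,
    WmReference,
    bone_intensity,
    fit_head_gmm,
    iap,
    proxy_bmd,
    tap,
    wm_reference,
)
from calvaria.thickness import head_thickness_map
from conftest import small_closed_spec


class TestWmReference:
    def test_noise_free_exact(self, clean_phantom):
        t1, seg, truth = clean_phantom
        wm = wm_reference(t1, seg)
        assert wm.wm_intensity == truth.spec.tissue_means["wm"]

    def test_with_noise_close_to_planted_mean(self):
        spec = small_closed_spec(noise_sd=10.0, seed=17)
        t1, seg, _ = generate_phantom(spec)
        wm = wm_reference(t1, seg)
        assert wm.wm_intensity == pytest.approx(400.0, abs=1.0)

    def test_empty_wm_raises(self, clean_phantom):
        t1, seg, _ = clean_phantom
        labels = seg.labels().copy()
        labels[labels == WM] = HEAD
        bad = TissueSegmentation.from_labels(labels, seg.affine)
        with pytest.raises(ReferenceError):
            wm_reference(t1, bad)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ReferenceError):
            WmReference(wm_intensity=0.0)


class TestBoneIntensity:
    def test_normalization_identity(self, clean_phantom):
        t1, seg, truth = clean_phantom
        atlas = build_atlas_for_grid(seg.grid, truth.skull_mask)
        flat = t1.with_data(np.where(truth.skull_mask, 400.0, t1.data))
        table = bone_intensity(flat, seg, atlas, WmReference(400.0))
        nonempty = table[table.n_voxels > 0]
        assert np.allclose(nonempty["mean_intensity"], 1.0)

    def test_scale_invariance(self, clean_phantom):
        t1, seg, truth = clean_phantom
        atlas = build_atlas_for_grid(seg.grid, truth.skull_mask)
        wm1 = wm_reference(t1, seg)
        t2 = t1.with_data(t1.data * 2.0)
        wm2 = wm_reference(t2, seg)
        a = bone_intensity(t1, seg, atlas, wm1)
        b = bone_intensity(t2, seg, atlas, wm2)
        assert np.allclose(
            a["mean_intensity"].to_numpy(float),
            b["mean_intensity"].to_numpy(float),
            equal_nan=True,
        )

    def test_monotone_in_diploe_intensity(self):
        vals = []
        for di in (300.0, 500.0):
            t1, seg, truth = generate_phantom(small_closed_spec(diploe_intensity=di))
            atlas = build_atlas_for_grid(seg.grid, truth.skull_mask)
            wm = wm_reference(t1, seg)
            table = bone_intensity(t1, seg, atlas, wm).set_index("region_id")
            vals.append(table.loc[0, "mean_intensity"])
        assert vals[0] < vals[1]


class TestProxyBmd:
    def test_negation(self):
        assert proxy_bmd(0.8) == -0.8

    def test_equal_inputs_equal_outputs(self):
        assert proxy_bmd(0.71) == proxy_bmd(0.71)

    def test_strictly_decreasing_ladder(self):
        values = []
        for di in (450.0, 400.0, 350.0, 300.0, 250.0):  # decreasing marrow intensity
            t1, seg, truth = generate_phantom(
                small_closed_spec(diploe_intensity=di, noise_sd=5.0, seed=19)
            )
            atlas = build_atlas_for_grid(seg.grid, truth.skull_mask)
            wm = wm_reference(t1, seg)
            table = bone_intensity(t1, seg, atlas, wm).set_index("region_id")
            values.append(proxy_bmd(table.loc[OCCIPITAL, "mean_intensity"]))
        assert np.all(np.diff(values) > 0)


def synthetic_head_volume(values: np.ndarray, shape=(40, 40, 40)):
    """A segmentation whose head class holds exactly ``values``; WM elsewhere."""
    data = np.full(shape, 400.0)
    labels = np.full(shape, WM, np.uint8)
    n = values.size
    flat_idx = np.arange(n)
    data.flat[flat_idx] = values
    labels_flat = labels.ravel()
    labels_flat[flat_idx] = HEAD
    seg = TissueSegmentation.from_labels(labels_flat.reshape(shape), np.eye(4))
    return VolumeGrid(data, np.eye(4)), seg


class TestGmm:
    def test_single_gaussian_recovery(self):
        rng = np.random.default_rng(0)
        values = rng.normal(300.0, 25.0, size=50_000)
        t1, seg = synthetic_head_volume(values)
        fit = fit_head_gmm(t1, seg, K=1, seed=0)
        assert fit.means[0] == pytest.approx(300.0, rel=0.01)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(1)
        n = 50_000
        comp = rng.random(n) < 0.7
        values = np.where(comp, rng.normal(500, 30, n), rng.normal(100, 30, n))
        t1, seg = synthetic_head_volume(values)
        fit = fit_head_gmm(t1, seg, K=2, seed=0)
        assert fit.weights[0] == pytest.approx(0.3, abs=0.02)
        assert fit.weights[1] == pytest.approx(0.7, abs=0.02)
        assert fit.means[0] == pytest.approx(100, abs=10)
        assert fit.means[1] == pytest.approx(500, abs=10)

    def test_determinism(self):
        rng = np.random.default_rng(2)
        values = rng.normal(300.0, 40.0, size=30_000)
        t1, seg = synthetic_head_volume(values)
        a = fit_head_gmm(t1, seg, K=3, seed=5)
        b = fit_head_gmm(t1, seg, K=3, seed=5)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.weights, b.weights)

    def test_components_sorted(self):
        rng = np.random.default_rng(3)
        n = 30_000
        comp = rng.random(n) < 0.5
        values = np.where(comp, rng.normal(450, 20, n), rng.normal(150, 20, n))
        t1, seg = synthetic_head_volume(values)
        fit = fit_head_gmm(t1, seg, K=2, seed=0)
        assert np.all(np.diff(fit.means) >= 0)

    def test_too_few_head_voxels(self):
        t1, seg = synthetic_head_volume(np.full(100, 300.0))
        with pytest.raises(ReferenceError):
            fit_head_gmm(t1, seg, K=2, seed=0)

    def test_invalid_fit_parameters_rejected(self):
        with pytest.raises(ValueError):
            GaussianMixtureFit(means=[1.0], sds=[0.0], weights=[1.0])
        with pytest.raises(ValueError):
            GaussianMixtureFit(means=[1.0, 2.0], sds=[1.0, 1.0], weights=[0.7, 0.7])


class TestIap:
    def test_single_component(self):
        fit = GaussianMixtureFit(means=[300.0], sds=[10.0], weights=[1.0])
        assert iap(fit, WmReference(400.0)) == pytest.approx(0.75)

    def test_weighted_mean(self):
        fit = GaussianMixtureFit(means=[200.0, 600.0], sds=[10.0, 10.0], weights=[0.25, 0.75])
        assert iap(fit, WmReference(400.0)) == pytest.approx(1.25)

    def test_k1_equals_plain_mean(self):
        rng = np.random.default_rng(4)
        values = rng.normal(320.0, 30.0, size=30_000)
        t1, seg = synthetic_head_volume(values)
        fit = fit_head_gmm(t1, seg, K=1, seed=0)
        wm = WmReference(400.0)
        head_mean = t1.data[seg.mask(HEAD)].mean() / 400.0
        assert iap(fit, wm) == pytest.approx(head_mean, rel=1e-3)

    def test_increasing_in_fat_fraction(self):
        values = []
        for f in (0.1, 0.2, 0.3, 0.4, 0.5):
            t1, seg, _ = generate_phantom(
                small_closed_spec(fat_fraction=f, noise_sd=5.0, seed=23)
            )
            wm = wm_reference(t1, seg)
            fit = fit_head_gmm(t1, seg, K=4, seed=0)
            values.append(iap(fit, wm))
        assert np.all(np.diff(values) > 0)
        assert sps.spearmanr(np.arange(5), values).statistic == pytest.approx(1.0)


class TestTap:
    def test_uniform_scalp(self):
        t1, seg, truth = generate_phantom(small_closed_spec(scalp_mm=6.0))
        atlas = build_atlas_for_grid(seg.grid, truth.skull_mask)
        ht = head_thickness_map(seg)
        value, flags = tap(
            ht, atlas.labels.data, atlas.bone_mask.data.astype(bool), truth.skull_mask
        )
        assert value == pytest.approx(6.0, abs=0.5)
        assert not flags

    def test_all_excluded_flagged(self):
        t1, seg, truth = generate_phantom(small_closed_spec())
        atlas = build_atlas_for_grid(seg.grid, truth.skull_mask)
        ht = head_thickness_map(seg, max_skull_distance_mm=0.0)  # degenerate rule
        value, flags = tap(
            ht, atlas.labels.data, atlas.bone_mask.data.astype(bool), truth.skull_mask
        )
        assert np.isnan(value)
        assert flags

    def test_increasing_in_scalp_thickness(self):
        values = []
        for s in (3.0, 4.5, 6.0, 7.5, 9.0):
            _, seg, truth = generate_phantom(
                small_closed_spec(scalp_mm=s, brain_radii=(14.0, 13.5, 13.0))
            )
            atlas = build_atlas_for_grid(seg.grid, truth.skull_mask)
            ht = head_thickness_map(seg)
            v, _ = tap(
                ht, atlas.labels.data, atlas.bone_mask.data.astype(bool), truth.skull_mask
            )
            values.append(v)
        assert np.all(np.diff(values) > 0)


class TestComputeAll:
    def test_smoke_all_finite(self, open_phantom):
        t1, seg, _ = open_phantom
        m = compute_all(t1, seg, config=MeasureConfig(seed=0))
        for v in m.scalar_dict().values():
            assert np.isfinite(v)
        assert not any("failed" in f for f in m.qc_flags)

    def test_determinism(self, open_phantom):
        t1, seg, _ = open_phantom
        a = compute_all(t1, seg, config=MeasureConfig(seed=0))
        b = compute_all(t1, seg, config=MeasureConfig(seed=0))
        assert a.scalar_dict() == b.scalar_dict()
        assert a.region_table.equals(b.region_table)

    def test_retest_stability(self):
        spec = small_closed_spec(noise_sd=15.0, seed=29, open_inferior=True)
        (t1a, sega, _), (t1b, segb, _) = make_retest_pair(spec, seeds=(101, 202))
        ma = compute_all(t1a, sega, config=MeasureConfig(seed=0))
        mb = compute_all(t1b, segb, config=MeasureConfig(seed=0))
        assert abs(ma.bone_thickness_mm - mb.bone_thickness_mm) < 0.5

    def test_scale_invariance(self):
        spec = small_closed_spec(noise_sd=10.0, seed=31, open_inferior=True)
        t1, seg, _ = generate_phantom(spec)
        m1 = compute_all(t1, seg, config=MeasureConfig(seed=1))
        m2 = compute_all(t1.with_data(t1.data * 3.7), seg, config=MeasureConfig(seed=1))
        for k in ("proxy_bmd", "bone_thickness_mm", "iap", "tap_mm"):
            a, b = m1.scalar_dict()[k], m2.scalar_dict()[k]
            assert abs(a - b) <= 1e-6 * max(abs(a), abs(b))

    def test_probability_input_path(self):
        spec = small_closed_spec(noise_sd=5.0, seed=37)
        t1, seg, _ = generate_phantom(spec, seg_kind="probability")
        m = compute_all(t1, seg, config=MeasureConfig(seed=0))
        assert np.isfinite(m.proxy_bmd)

    def test_region_table_contract(self, open_phantom):
        t1, seg, _ = open_phantom
        m = compute_all(t1, seg, config=MeasureConfig(seed=0))
        assert set(m.region_table.columns) == {
            "region_id",
            "region_name",
            "mean_intensity",
            "mean_thickness_mm",
            "n_voxels",
            "n_vertices",
        }
        assert (m.region_table["n_voxels"] >= 0).all()
        occ = m.region_table.set_index("region_id").loc[OCCIPITAL]
        assert occ["n_voxels"] > 0
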