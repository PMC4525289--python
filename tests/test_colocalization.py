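import numpy as np
import pytest

import knobkit as kk
from knobkit.colocalization import normalize_image, overlap


def overlap_oracle(g, b, padding_factor=250):
    """Direct-formula oracle: materialize the zero-padded arrays."""
    g = np.asarray(g, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    pad = np.zeros((padding_factor - 1) * g.size)
    gp = np.concatenate([g, pad])
    bp = np.concatenate([b, pad])
    cov = ((gp - gp.mean()) * (bp - bp.mean())).mean()
    return cov / np.sqrt(gp.var() * bp.var())


class TestNormalize:
    def test_plain_scaling_to_max3(self):
        out = normalize_image(np.array([0.0, 5.0, 10.0, 10.0, 10.0]))
        np.testing.assert_allclose(out.values, [0.0, 0.5, 1.0, 1.0, 1.0])
        assert out.max3 == 10.0

    def test_threshold_subtracted_before_scaling(self):
        out = normalize_image(np.array([0.0, 5.0, 10.0, 10.0, 10.0]), t=5.0)
        np.testing.assert_allclose(out.values, [0.0, 0.0, 1.0, 1.0, 1.0])

    def test_top_pixel_may_exceed_one(self):
        out = normalize_image(np.array([8.0, 10.0, 12.0]))
        assert out.max3 == pytest.approx(10.0)
        assert out.values.max() == pytest.approx(1.2)

    def test_degenerate_when_max3_not_above_threshold(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_image(np.array([1.0, 1.0, 1.0, 2.0]), t=5.0)


class TestOverlap:
    def test_identical_images_give_perfect_overlap(self):
        rng = np.random.default_rng(0)
        img = rng.random((4, 6, 6)) * 100
        res = overlap(img, img.copy(), mode="unthresholded")
        assert res.n == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_supports_give_zero(self):
        g = np.zeros((2, 4, 4))
        b = np.zeros((2, 4, 4))
        g[0, :2] = 5.0
        b[1, 2:] = 7.0
        res = overlap(g, b, mode="unthresholded")
        assert res.n <= 0.005

    def test_four_voxel_toy_matches_materialized_oracle(self):
        g = np.array([1.0, 1.0, 0.0, 0.0]).reshape(1, 2, 2)
        b = np.array([1.0, 0.0, 1.0, 0.0]).reshape(1, 2, 2)
        res = overlap(g, b, mode="unthresholded", padding_factor=250)
        # same normalization the pipeline applies (max3 over 4 voxels)
        gn = normalize_image(g).values
        bn = normalize_image(b).values
        assert res.n == pytest.approx(overlap_oracle(gn, bn), abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        g = rng.random((3, 5, 5))
        b = rng.random((3, 5, 5))
        n1 = overlap(g, b, mode="unthresholded").n
        n2 = overlap(123.4 * g, b * 0.01, mode="unthresholded").n
        assert n1 == pytest.approx(n2, abs=1e-10)

    def test_symmetry_in_g_and_b(self):
        rng = np.random.default_rng(2)
        g = rng.random((3, 5, 5))
        b = rng.random((3, 5, 5))
        assert overlap(g, b, "unthresholded").n == pytest.approx(
            overlap(b, g, "unthresholded").n, abs=1e-12
        )

    def test_overlap_decreases_as_focus_translates_away(self):
        from scipy import ndimage

        base = np.zeros((1, 1, 64))
        base[0, 0, 20:26] = 1.0
        base = ndimage.gaussian_filter(base, (0, 0, 1.5))
        ns = []
        for shift_vox in range(0, 12):  # 40 nm steps at dx=40
            moved = np.roll(base, shift_vox, axis=2)
            ns.append(overlap(moved, base, mode="unthresholded").n)
        assert all(ns[i + 1] <= ns[i] + 1e-9 for i in range(len(ns) - 1))
        assert ns[-1] < 0.05  # supports disjoint by 480 nm

    def test_zero_variance_rejected(self):
        flat = np.ones((2, 3, 3))
        peak = flat.copy()
        peak[0, 0, 0] = 2.0
        with pytest.raises(ValueError):
            overlap(peak, peak.copy(), mode="thresholded", d=0.0)


class TestOverlapTable:
    def test_marker_equal_to_dapi_scores_one_everywhere(self, default_nucleus):
        stacks, _, nucleus = default_nucleus
        crops, mask, _ = kk.crop_nucleus(stacks, nucleus, margin_nm=200.0)
        crops = {"DAPI": crops["DAPI"], "self": crops["DAPI"].copy(channel="self")}
        table = kk.overlap_table([crops], masks=[mask])
        for _, row in table.iterrows():
            assert row["mean_overlap"] == pytest.approx(1.0, abs=1e-9)
            assert row["sd_overlap"] == 0.0
            assert row["single_nucleus"]

    def test_weight_ordering_preserved_in_both_modes(self):
        """Markers simulated at w=0.9 vs w=0.3 keep their order in n."""
        per_nucleus = []
        for seed in range(8):
            stacks, _ = kk.generate_nucleus_scene(
                kk.SceneParams(marker_weights={"hi": 0.9, "lo": 0.3}), seed=seed
            )
            nuclei = kk.segment_nuclei(stacks["DAPI"])
            crops, mask, _ = kk.crop_nucleus(stacks, nuclei[0], margin_nm=200.0)
            per_nucleus.append(crops)
        table = kk.overlap_table(per_nucleus)
        for mode in ("thresholded", "unthresholded"):
            sub = table[table["mode"] == mode].set_index("marker")
            assert (
                sub.loc["hi", "mean_overlap"] > sub.loc["lo", "mean_overlap"]
            )
        # background dilutes contrast: unthresholded differences are smaller
        t = table[table["mode"] == "thresholded"].set_index("marker")["mean_overlap"]
        u = table[table["mode"] == "unthresholded"].set_index("marker")["mean_overlap"]
        assert (u["hi"] - u["lo"]) < (t["hi"] - t["lo"])
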