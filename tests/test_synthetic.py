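import numpy as np
import pandas as pd
import pytest

import knobkit as kk
from knobkit.registration import TransformParams


class TestSceneGenerator:
    def test_seeded_determinism(self):
        s1, t1 = kk.generate_nucleus_scene(kk.SceneParams(), seed=3)
        s2, t2 = kk.generate_nucleus_scene(kk.SceneParams(), seed=3)
        for ch in s1:
            np.testing.assert_array_equal(s1[ch].voxels, s2[ch].voxels)
        assert t1.nucleus_centers_nm == t2.nucleus_centers_nm

    def test_truth_lists_requested_knob_count(self):
        params = kk.SceneParams(knob_count=2, nucleus_radius_nm=1300.0, shape=(30, 110, 110))
        _, truth = kk.generate_nucleus_scene(params, seed=1)
        assert truth.knob_count() == 2

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            kk.generate_nucleus_scene(kk.SceneParams(marker_weights={"m": 1.5}), seed=0)
        with pytest.raises(ValueError):
            kk.generate_nucleus_scene(kk.SceneParams(nucleus_radius_nm=-5), seed=0)

    def test_perfect_weight_without_noise_gives_near_unit_overlap(self):
        params = kk.SceneParams(
            marker_weights={"m": 1.0}, poisson_photons=0.0, read_noise_sd=0.0
        )
        stacks, _ = kk.generate_nucleus_scene(params, seed=2)
        nucleus = kk.segment_nuclei(stacks["DAPI"])[0]
        crops, mask, _ = kk.crop_nucleus(stacks, nucleus, margin_nm=200.0)
        res = kk.overlap(crops["m"], crops["DAPI"], mode="thresholded", object_mask=mask)
        assert res.n >= 0.99

    def test_planted_knob_survives_blur_as_local_maximum(self):
        """Mean DAPI inside the planted knob exceeds the nuclear median."""
        for seed in range(5):
            stacks, truth = kk.generate_nucleus_scene(kk.SceneParams(), seed=seed)
            dapi = stacks["DAPI"]
            vs = np.asarray(dapi.voxel_size)
            zz, yy, xx = np.meshgrid(
                *[(np.arange(n) + 0.5) * s for n, s in zip(dapi.shape, vs)], indexing="ij"
            )
            c = truth.knob_centers_nm[0][0]
            knob = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= truth.knob_radius_nm**2
            cn = truth.nucleus_centers_nm[0]
            nuc = (zz - cn[0]) ** 2 + (yy - cn[1]) ** 2 + (xx - cn[2]) ** 2 <= truth.nucleus_radius_nm**2
            assert dapi.voxels[knob].mean() > np.median(dapi.voxels[nuc])

    def test_expected_overlap_monotone_in_weight(self):
        ns = []
        for w in (0.0, 0.25, 0.5, 0.75, 1.0):
            stacks, _ = kk.generate_nucleus_scene(
                kk.SceneParams(marker_weights={"m": w}), seed=4
            )
            nucleus = kk.segment_nuclei(stacks["DAPI"])[0]
            crops, mask, _ = kk.crop_nucleus(stacks, nucleus, margin_nm=200.0)
            ns.append(kk.overlap(crops["m"], crops["DAPI"], "thresholded", object_mask=mask).n)
        assert all(b > a for a, b in zip(ns, ns[1:]))


class TestBeadGenerator:
    def test_identity_zero_noise_gives_identical_stacks(self):
        ref, mov, _ = kk.generate_bead_field(TransformParams.identity(), n_beads=20, seed=0)
        np.testing.assert_allclose(ref.voxels, mov.voxels, atol=1e-12)

    def test_seeded_determinism(self):
        p = TransformParams(tx=80.0)
        a = kk.generate_bead_field(p, n_beads=20, seed=5, snr=20.0)
        b = kk.generate_bead_field(p, n_beads=20, seed=5, snr=20.0)
        np.testing.assert_array_equal(a[0].voxels, b[0].voxels)
        np.testing.assert_array_equal(a[1].voxels, b[1].voxels)

    def test_transform_moving_all_beads_out_of_frame_rejected(self):
        with pytest.raises(ValueError, match="out of frame"):
            kk.generate_bead_field(
                TransformParams(tx=50_000.0), n_beads=5, seed=0,
            )

    def test_too_few_beads_rejected(self):
        with pytest.raises(ValueError):
            kk.generate_bead_field(TransformParams.identity(), n_beads=2, seed=0)


class TestArrayGenerator:
    def test_seeded_determinism(self):
        a = kk.generate_probe_table(kk.ArrayParams(), seed=9)
        b = kk.generate_probe_table(kk.ArrayParams(), seed=9)
        pd.testing.assert_frame_equal(a[0]["control"][0], b[0]["control"][0])
        assert a[2].up_genes == b[2].up_genes

    def test_alpha_zero_perfect_match_probes_equal_truth(self):
        params = kk.ArrayParams(alpha=0.0, noise_cv=0.0, n_genes=60, n_up=2)
        tables, ann, truth = kk.generate_probe_table(params, seed=3)
        probes = kk.summarize_probes(tables["control"][0])
        pm = ann[ann["probe_type"] == "pm"]
        for _, row in pm.iterrows():
            expected = truth.abundance["control"][row["gene"]] * row["copy_number"]
            assert probes.loc[row["probe_id"], "intensity"] == pytest.approx(expected)

    def test_zero_noise_paralog_correction_recovers_truth(self):
        params = kk.ArrayParams(noise_cv=0.0, n_genes=80, n_up=2, alpha=0.2)
        tables, ann, truth = kk.generate_probe_table(params, seed=5)
        probes = kk.summarize_probes(tables["control"][0])
        values, fits = kk.paralog_correct(probes["intensity"], ann, alpha="fit")
        for a, b in truth.pair_genes:
            assert values[a] == pytest.approx(truth.abundance["control"][a], rel=1e-9)
            assert values[b] == pytest.approx(truth.abundance["control"][b], rel=1e-9)
        assert np.allclose(fits["alpha"], 0.2)

    def test_alpha_of_one_rejected(self):
        with pytest.raises(ValueError):
            kk.generate_probe_table(kk.ArrayParams(alpha=1.0), seed=0)
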