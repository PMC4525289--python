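import numpy as np
import pandas as pd
import pytest

import knobkit as kk
from knobkit.expression import correct_pair, category_analysis


def spots_frame(rows):
    return pd.DataFrame(rows, columns=["probe_id", "gProcessedSignal", "gIsWellAboveBG"])


class TestSummarize:
    def test_median_of_spots(self):
        spots = spots_frame([("p1", 100, 1), ("p1", 200, 1), ("p1", 300, 1)])
        out = kk.summarize_probes(spots)
        assert out.loc["p1", "intensity"] == 200

    def test_even_spot_count_uses_mean_of_middle_two(self):
        spots = spots_frame([("p1", 100, 1), ("p1", 300, 1)])
        assert kk.summarize_probes(spots).loc["p1", "intensity"] == 200

    @pytest.mark.parametrize("flags,detected", [((0, 1), False), ((1, 1, 1, 0, 0), True)])
    def test_detection_cutoff_strictly_above_055(self, flags, detected):
        spots = spots_frame([("p1", 10, f) for f in flags])
        assert bool(kk.summarize_probes(spots).loc["p1", "detected"]) is detected


class TestPercentileNormalize:
    def test_anchor_at_2500(self, rng):
        v = rng.lognormal(6, 1, 500)
        out = kk.percentile_normalize(v)
        assert np.percentile(out, 75) == pytest.approx(2500.0, rel=1e-12)

    def test_constant_vector_maps_to_target(self):
        out = kk.percentile_normalize(np.full(10, 7.0))
        np.testing.assert_allclose(out, 2500.0)

    def test_ratios_unchanged_and_idempotent(self, rng):
        v = rng.lognormal(6, 1, 100)
        out = kk.percentile_normalize(v)
        np.testing.assert_allclose(out / out[0], v / v[0])
        np.testing.assert_allclose(kk.percentile_normalize(out), out)

    def test_zero_percentile_rejected(self):
        with pytest.raises(ValueError):
            kk.percentile_normalize(np.zeros(8))


class TestParalogCorrection:
    def test_alpha_zero_is_identity(self):
        res = correct_pair(1000.0, 500.0, m_ab=3, alpha=0.0)
        assert (res.s_a, res.s_b) == (1000.0, 500.0)

    @pytest.mark.parametrize("alpha", [0.0, 0.05, 0.2, 0.5])
    @pytest.mark.parametrize("m", [1, 2, 3, 4, 5])
    def test_exact_inversion_of_forward_model(self, alpha, m):
        s_a, s_b = 1000.0, 500.0
        i_pa = s_a + alpha**m * s_b
        i_pb = s_b + alpha**m * s_a
        i_ca = alpha * s_a + alpha ** (m + 1) * s_b
        res = correct_pair(i_pa, i_pb, m_ab=m, i_corr_a=i_ca)
        assert res.s_a == pytest.approx(s_a, rel=1e-9)
        assert res.s_b == pytest.approx(s_b, rel=1e-9)
        assert res.alpha == pytest.approx(alpha, abs=1e-12)

    def test_zero_mismatch_singular(self):
        with pytest.raises(ValueError, match="singular"):
            correct_pair(10.0, 10.0, m_ab=0, alpha=0.5)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            correct_pair(10.0, 10.0, m_ab=2, alpha=1.0)

    def test_negative_solution_floored_and_flagged(self):
        # i_pb far below what cross-hybridization alone would produce
        res = correct_pair(1000.0, 1.0, m_ab=1, alpha=0.9)
        assert res.floored
        assert res.s_a >= 0 and res.s_b >= 0


class TestCopyNumber:
    def test_division_and_identity(self):
        v = pd.Series({"g1": 3000.0, "g2": 700.0})
        cn = pd.Series({"g1": 2, "g2": 1})
        out = kk.copy_number_adjust(v, cn)
        assert out["g1"] == 1500.0 and out["g2"] == 700.0

    def test_non_integer_copy_number_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            kk.copy_number_adjust(pd.Series({"g": 10.0}), pd.Series({"g": 1.5}))

    def test_copy_number_below_one_rejected(self):
        with pytest.raises(ValueError):
            kk.copy_number_adjust(pd.Series({"g": 10.0}), pd.Series({"g": 0}))


class TestDifferentialRatios:
    def test_geometric_mean_of_replicates(self):
        strain = pd.DataFrame({"r1": [100.0], "r2": [400.0]}, index=["g"])
        control = pd.DataFrame({"r1": [200.0], "r2": [200.0]}, index=["g"])
        out = kk.differential_ratios(strain, control)
        assert out.loc["g", "combined_strain"] == pytest.approx(200.0)
        assert out.loc["g", "ratio"] == pytest.approx(1.0)
        assert out.loc["g", "log2_ratio"] == pytest.approx(0.0)

    def test_scaling_equivariance(self, rng):
        strain = pd.DataFrame(rng.lognormal(5, 1, (20, 2)), columns=["r1", "r2"])
        control = pd.DataFrame(rng.lognormal(5, 1, (20, 2)), columns=["r1", "r2"])
        base = kk.differential_ratios(strain, control)
        scaled = kk.differential_ratios(strain * 3.0, control)
        np.testing.assert_allclose(scaled["ratio"], base["ratio"] * 3.0)

    def test_zero_control_flagged_undefined(self):
        strain = pd.DataFrame({"r1": [10.0]}, index=["g"])
        control = pd.DataFrame({"r1": [0.0]}, index=["g"])
        out = kk.differential_ratios(strain, control)
        assert bool(out.loc["g", "undefined"])
        assert np.isnan(out.loc["g", "ratio"])


class TestFoldChangeSets:
    def test_strict_inequality_across_strains(self):
        ratios = pd.DataFrame(
            {"s1": [2.1, 2.1, 2.0, 0.4], "s2": [2.5, 1.9, 2.5, 0.4], "s3": [3.0, 2.2, 3.0, 0.45]},
            index=["up_all", "weak_one", "at_exactly_two", "down_all"],
        )
        sets = kk.fold_change_sets(ratios)
        assert sets["up"] == {"up_all"}
        assert sets["down"] == {"down_all"}


class TestCategoryAnalysis:
    def test_published_gene_class_percentages(self):
        labels = ["coding"] * 89 + ["ncRNA"] * 44 + ["pseudogene"] * 9
        res = category_analysis(
            labels, {"coding": 0.8, "ncRNA": 0.15, "pseudogene": 0.05}
        )
        assert res["percent"] == {"coding": 63, "ncRNA": 31, "pseudogene": 6}
        assert res["total"] == 142

    def test_chi2_zero_when_observed_matches_expectation(self):
        labels = ["a"] * 50 + ["b"] * 50
        res = category_analysis(labels, {"a": 0.5, "b": 0.5})
        assert res["chi2"] == 0.0

    def test_hand_computed_chi2(self):
        res = category_analysis(["a"] * 10, {"a": 0.5, "b": 0.5})
        assert res["chi2"] == pytest.approx(10.0)
        assert res["df"] == 1

    def test_zero_expectation_rejected(self):
        with pytest.raises(ValueError):
            category_analysis(["a"], {"a": 1.0, "b": 0.0})


def test_full_chain_recovers_planted_folds_exactly():
    """Noise-free spot tables through the whole chain reproduce the
    generator's planted strain/control fold changes."""
    params = kk.ArrayParams(noise_cv=0.0, n_genes=400, n_up=30)
    tables, ann, truth = kk.generate_probe_table(params, seed=7)
    frames = {
        name: pd.DataFrame(
            {
                f"rep{i}": kk.probe_to_gene_values(rep, ann, alpha="fit")["value"]
                for i, rep in enumerate(reps)
            }
        )
        for name, reps in tables.items()
    }
    for strain in params.strains:
        res = kk.differential_ratios(frames[strain], frames["control"])
        rel = (res["ratio"] / truth.expected_ratio[strain] - 1.0).abs().max()
        assert rel < 1e-6
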