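import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xenoduct.mirna import (
    CtMatrix,
    MirnaDifferential,
    detection_filter,
    merge_technical_duplicates,
    pca_qc,
    preprocess,
    quantile_normalize,
    remove_controls,
)


class TestMergeDuplicates:
    def test_truth_table(self, raw_duplicate_ct):
        merged = merge_technical_duplicates(raw_duplicate_ct)
        assert merged.values.loc["miR-1", "d1_rifampin"] == pytest.approx(34.7)
        assert merged.values.loc["miR-1", "d1_vehicle"] == pytest.approx(33.0)
        assert merged.values.loc["miR-2", "d1_rifampin"] == 40.0
        assert not merged.values.isna().any().any()

    def test_more_than_two_replicates_fatal(self, raw_duplicate_ct):
        extra = raw_duplicate_ct.values.copy()
        extra["d1_rifampin_r3"] = 30.0
        samples = pd.concat(
            [
                raw_duplicate_ct.samples,
                pd.DataFrame(
                    {"donor": ["d1"], "treatment": ["rifampin"], "replicate": [3]},
                    index=["d1_rifampin_r3"],
                ),
            ]
        )
        bad = CtMatrix(values=extra, samples=samples)
        with pytest.raises(ValueError, match="exactly 2"):
            merge_technical_duplicates(bad)


class TestRemoveControls:
    def test_control_prefixes_removed_case_insensitively(self, make_merged_ct):
        m = make_merged_ct(
            {"U6": dict.fromkeys([], 0), "rnu44": {}, "miR-21": {}},
            donors=("d1",),
        )
        m.values[:] = 30.0
        out = remove_controls(m)
        assert list(out.values.index) == ["miR-21"]

    def test_no_match_is_identity(self, make_merged_ct):
        m = make_merged_ct({"miR-1": {}, "miR-2": {}}, donors=("d1",))
        m.values[:] = 30.0
        assert list(remove_controls(m).values.index) == ["miR-1", "miR-2"]


class TestDetectionFilter:
    def _matrix(self, veh_detected, rif_detected, make_merged_ct):
        """Feature detected (Ct 30) in the given numbers of samples per arm,
        Ct 39 elsewhere."""
        donors = [f"d{i}" for i in range(1, 8)]
        vals = {}
        for i, d in enumerate(donors):
            vals[f"{d}_vehicle"] = {"f": 30.0 if i < veh_detected else 39.0}
            vals[f"{d}_rifampin"] = {"f": 30.0 if i < rif_detected else 39.0}
        m = make_merged_ct({"f": {}})
        for c in m.values.columns:
            m.values.loc["f", c] = vals[c]["f"]
        return m

    @pytest.mark.parametrize(
        "veh,rif,kept",
        [(4, 0, True), (3, 3, False), (0, 4, True), (0, 0, False), (7, 7, True)],
    )
    def test_four_of_seven_rule(self, veh, rif, kept, make_merged_ct):
        out = detection_filter(self._matrix(veh, rif, make_merged_ct))
        assert ("f" in out.values.index) == kept

    def test_all_at_ceiling_dropped(self, make_merged_ct):
        m = make_merged_ct({"f": {}})
        m.values[:] = 40.0
        assert detection_filter(m).values.empty


class TestQuantileNormalize:
    def _ct(self, frame):
        samples = pd.DataFrame(
            {
                "donor": ["d1"] * frame.shape[1],
                "treatment": ["rifampin"] + ["vehicle"] * (frame.shape[1] - 1),
            },
            index=frame.columns,
        )
        return CtMatrix(values=frame, samples=samples)

    def test_two_by_two_worked_example(self):
        out = quantile_normalize(
            self._ct(pd.DataFrame({"s1": [1.0, 3.0], "s2": [2.0, 8.0]}, index=["f1", "f2"]))
        )
        assert out.values["s1"].tolist() == [1.5, 5.5]
        assert out.values["s2"].tolist() == [1.5, 5.5]

    def test_ties_get_mean_of_would_be_quantiles(self):
        # frozen against limma::normalizeQuantiles(ties=TRUE)
        out = quantile_normalize(
            self._ct(pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]}))
        )
        assert out.values["a"].tolist() == [2.0, 2.0, 5.5]
        assert out.values["b"].tolist() == [1.5, 2.5, 5.5]

    def test_idempotent_and_identical_column_distributions(self, rng):
        frame = pd.DataFrame(rng.uniform(20, 35, size=(30, 6)),
                             columns=[f"s{i}" for i in range(6)])
        once = quantile_normalize(self._ct(frame))
        twice = quantile_normalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)
        ref = np.sort(once.values.iloc[:, 0].to_numpy())
        for col in once.values.columns:
            np.testing.assert_allclose(np.sort(once.values[col].to_numpy()), ref)

    def test_permutation_equivariant_in_samples(self, rng):
        frame = pd.DataFrame(rng.uniform(20, 35, size=(20, 4)),
                             columns=list("abcd"))
        base = quantile_normalize(self._ct(frame))
        shuffled = quantile_normalize(self._ct(frame[["c", "a", "d", "b"]]))
        pd.testing.assert_frame_equal(
            base.values[["c", "a", "d", "b"]], shuffled.values
        )


class TestPcaQc:
    def test_rank_one_matrix_explained_by_pc1(self, make_merged_ct):
        m = make_merged_ct({f"f{i}": {} for i in range(5)}, donors=("d1", "d2", "d3"))
        loadings = np.arange(5)
        for j, c in enumerate(m.values.columns):
            m.values[c] = 25 + (j + 1) * loadings
        qc = pca_qc(m)
        assert qc["variance_explained"][0] == pytest.approx(1.0)

    def test_duplicated_samples_share_scores(self, make_merged_ct, rng):
        m = make_merged_ct({f"f{i}": {} for i in range(6)}, donors=("d1", "d2"))
        col = rng.uniform(20, 35, size=6)
        for c in m.values.columns:
            m.values[c] = col  # all identical columns
        qc = pca_qc(m)
        assert np.allclose(qc["scores"].to_numpy() - qc["scores"].to_numpy()[0], 0)


class TestPipelineOrder:
    def test_feature_count_non_increasing_through_stages(self, raw_duplicate_ct):
        merged = merge_technical_duplicates(raw_duplicate_ct)
        no_ctl = remove_controls(merged)
        detected = detection_filter(no_ctl, min_samples=1)
        assert len(merged.values) >= len(no_ctl.values) >= len(detected.values)

    def test_preprocess_runs_end_to_end(self, raw_duplicate_ct):
        out = preprocess(raw_duplicate_ct, min_samples=1)
        assert not out.values.isna().any().any()
        assert "U6" not in out.values.index


class TestDifferential:
    def _paired(self, diffs: np.ndarray, make_merged_ct, base=30.0):
        """diffs: features x donors array of planted Ct differences."""
        donors = [f"d{i}" for i in range(1, diffs.shape[1] + 1)]
        m = make_merged_ct({f"f{i}": {} for i in range(diffs.shape[0])}, donors=tuple(donors))
        for j, d in enumerate(donors):
            m.values[f"{d}_vehicle"] = base
            m.values[f"{d}_rifampin"] = base + diffs[:, j]
        return m

    def test_zero_differences_give_p_one(self, make_merged_ct):
        m = self._paired(np.zeros((2, 7)), make_merged_ct)
        res = MirnaDifferential(m).fit()
        assert (res.frame["p"] == 1.0).all()
        assert (res.frame["delta_delta_ct"] == 0).all()

    def test_constant_nonzero_difference_degenerate(self, make_merged_ct):
        m = self._paired(np.full((1, 7), -1.0), make_merged_ct)
        with pytest.warns(UserWarning, match="zero variance"):
            res = MirnaDifferential(m).fit()
        assert res.frame["p"].iloc[0] == np.finfo(float).tiny
        assert res.frame["log2fc"].iloc[0] == pytest.approx(1.0)

    def test_single_donor_fatal(self, make_merged_ct):
        m = self._paired(np.zeros((1, 1)), make_merged_ct)
        with pytest.raises(ValueError, match="2 donors"):
            MirnaDifferential(m)

    def test_planted_shift_power_above_90_percent(self, rng):
        """Monte-Carlo oracle: -2-cycle shift, sigma 0.3, 7 donors."""
        n_sim, n = 500, 7
        diffs = rng.normal(-2.0, 0.3, size=(n_sim, n))
        t = diffs.mean(1) / (diffs.std(1, ddof=1) / np.sqrt(n))
        power = (2 * stats.t.sf(np.abs(t), n - 1) < 0.05).mean()
        assert power > 0.9

    def test_model_p_matches_paired_ttest(self, make_merged_ct, rng):
        diffs = rng.normal(-1.0, 0.5, size=(3, 7))
        m = self._paired(diffs, make_merged_ct)
        res = MirnaDifferential(m).fit()
        for i in range(3):
            expected = stats.ttest_1samp(diffs[i], 0).pvalue
            assert res.frame["p"].iloc[i] == pytest.approx(expected)
        assert (res.frame["q"] >= res.frame["p"] - 1e-15).all()

    def test_null_pvalues_uniform(self, make_merged_ct, rng):
        diffs = rng.normal(0.0, 0.3, size=(1000, 7))
        m = self._paired(diffs, make_merged_ct)
        res = MirnaDifferential(m).fit()
        assert stats.kstest(res.frame["p"], "uniform").pvalue > 0.01

    def test_orientation_controls_effect_vectors(self, make_merged_ct):
        diffs = np.tile(np.linspace(-1, 1, 7), (1, 1))
        m = self._paired(diffs, make_merged_ct)
        ab = MirnaDifferential(m, orientation="abundance").fit().effect_vectors()
        ct = MirnaDifferential(m, orientation="ct").fit().effect_vectors()
        np.testing.assert_allclose(ab.to_numpy(), -ct.to_numpy())
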