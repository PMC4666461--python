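"""Synthetic-cohort generator: determinism, planted structure, noise models."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cnvsig
from cnvsig import cohort


class TestCloneMap:
    def test_even_spacing_and_count(self):
        cm = cnvsig.build_clone_map([100, 100, 100], spacing_mb=1.0)
        assert len(cm) == 300
        assert cm.frame["position_mb"].max() == pytest.approx(100.0)
        chr2 = cm.chromosome_frame(2)["position_mb"].to_numpy()
        assert np.allclose(np.diff(chr2), 1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cnvsig.build_clone_map([10], spacing_mb=0.0)
        with pytest.raises(ValueError):
            cnvsig.build_clone_map([], spacing_mb=1.0)

    def test_deterministic(self):
        a = cnvsig.build_clone_map([10, 20], 0.5)
        b = cnvsig.build_clone_map([10, 20], 0.5)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_positions_must_increase(self):
        bad = pd.DataFrame({"clone_id": ["a", "b"], "chromosome": [1, 1],
                            "position_mb": [2.0, 1.0]})
        with pytest.raises(ValueError):
            cnvsig.CloneMap(bad)


class TestCopyNumber:
    def test_zero_noise_thresholded_calls_equal_truth(self, small_clone_map,
                                                      small_regions):
        matrix, carriers = cnvsig.simulate_copy_number(
            small_clone_map, small_regions, n_samples=20, seed=5,
            noise_sd=0.0, missing_rate=0.0)
        calls = cnvsig.threshold_calls(matrix)
        for region in small_regions:
            in_region = small_clone_map.clones_in(
                region.chromosome, region.start_mb, region.end_mb)["clone_id"]
            for sample in matrix.columns:
                expected = (region.alteration_type
                            if carriers.at[region.label, sample] else cnvsig.NORMAL)
                assert (calls.loc[in_region, sample] == expected).all()

    def test_carrier_count_within_binomial_interval(self, small_clone_map):
        region = cnvsig.RegionSpec(1, 5.0, 12.0, cnvsig.LOSS, prevalence=0.3,
                                   effect_log_odds=1.0)
        _, carriers = cnvsig.simulate_copy_number(
            small_clone_map, [region], n_samples=53, seed=7)
        lo, hi = stats.binom.ppf([0.005, 0.995], 53, 0.3)
        assert lo <= carriers.sum(axis=1).iloc[0] <= hi

    def test_same_seed_identical(self, small_clone_map, small_regions):
        m1, c1 = cnvsig.simulate_copy_number(small_clone_map, small_regions, 15, seed=3)
        m2, c2 = cnvsig.simulate_copy_number(small_clone_map, small_regions, 15, seed=3)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(c1, c2)

    def test_region_outside_map_rejected(self, small_clone_map):
        outside = cnvsig.RegionSpec(9, 5.0, 12.0, cnvsig.GAIN, 0.5, 1.0)
        with pytest.raises(ValueError):
            cnvsig.simulate_copy_number(small_clone_map, [outside], 5, seed=0)

    def test_missingness_rate(self, small_clone_map, small_regions):
        matrix, _ = cnvsig.simulate_copy_number(
            small_clone_map, small_regions, 50, seed=1, missing_rate=0.1)
        frac = matrix.isna().to_numpy().mean()
        assert 0.07 < frac < 0.13


class TestExpression:
    @pytest.fixture()
    def setup(self, small_clone_map, small_regions):
        annotation, dosage = cnvsig.build_probe_annotation(
            small_clone_map, small_regions, probes_per_chrom=10,
            dosage_probes_per_region=3)
        baseline = pd.Series(8.0, index=annotation["probe_id"])
        rng = np.random.default_rng(0)
        carriers = cohort.draw_carriers(small_regions,
                                        [f"S{i}" for i in range(20)], rng)
        return annotation, dosage, baseline, carriers

    def test_noiseless_fold_change_exact(self, setup, small_regions):
        annotation, dosage, baseline, carriers = setup
        expr = cnvsig.simulate_expression(small_regions, carriers, annotation,
                                          dosage, baseline, dosage_fold=2.0,
                                          noise_sd=0.0)
        region = small_regions[1]  # gain
        probe = dosage[region.label][0]
        car = carriers.loc[region.label]
        linear = np.exp2(expr.loc[probe])
        fold = linear[car[car].index].mean() / linear[car[~car].index].mean()
        assert fold == pytest.approx(2.0)

    def test_loss_direction_down(self, setup, small_regions):
        annotation, dosage, baseline, carriers = setup
        expr = cnvsig.simulate_expression(small_regions, carriers, annotation,
                                          dosage, baseline, dosage_fold=2.0,
                                          noise_sd=0.0)
        region = small_regions[0]  # loss
        probe = dosage[region.label][0]
        car = carriers.loc[region.label]
        assert expr.loc[probe, car[car].index].mean() \
            < expr.loc[probe, car[~car].index].mean()

    def test_non_dosage_probe_unshifted(self, setup, small_regions):
        annotation, dosage, baseline, carriers = setup
        expr = cnvsig.simulate_expression(small_regions, carriers, annotation,
                                          dosage, baseline, noise_sd=0.0)
        all_dosage = {p for ids in dosage.values() for p in ids}
        background = [p for p in expr.index if p not in all_dosage]
        assert np.allclose(expr.loc[background].to_numpy(), 8.0)

    def test_dosage_fold_below_one_rejected(self, setup, small_regions):
        annotation, dosage, baseline, carriers = setup
        with pytest.raises(ValueError):
            cnvsig.simulate_expression(small_regions, carriers, annotation,
                                       dosage, baseline, dosage_fold=0.5)


class TestBatchEffect:
    def _expr(self):
        return pd.DataFrame(np.arange(12, dtype=float).reshape(3, 4),
                            index=["g1", "g2", "g3"],
                            columns=["s1", "s2", "s3", "s4"])

    def test_identity_factors_leave_matrix_unchanged(self):
        expr = self._expr()
        factors = pd.Series(1.0, index=expr.index)
        out = cnvsig.apply_batch_effect(expr, factors)
        pd.testing.assert_frame_equal(out, expr)

    def test_factor_two_doubles_linear_median(self):
        expr = self._expr()
        factors = pd.Series([2.0, 1.0, 1.0], index=expr.index)
        out = cnvsig.apply_batch_effect(expr, factors)
        before = np.exp2(expr.loc["g1"]).median()
        after = np.exp2(out.loc["g1"]).median()
        assert after == pytest.approx(2 * before)

    def test_subset_of_samples_only(self):
        expr = self._expr()
        factors = pd.Series(2.0, index=expr.index)
        out = cnvsig.apply_batch_effect(expr, factors, samples=["s3", "s4"])
        pd.testing.assert_frame_equal(out[["s1", "s2"]], expr[["s1", "s2"]])
        assert (out["s3"] == expr["s3"] + 1.0).all()

    def test_nonpositive_factor_rejected(self):
        expr = self._expr()
        with pytest.raises(ValueError):
            cnvsig.apply_batch_effect(expr, pd.Series(0.0, index=expr.index))


class TestOutcomes:
    def _carriers(self, flags, label="chr1:5-12:loss"):
        return pd.DataFrame({f"P{i}": [f] for i, f in enumerate(flags)},
                            index=[label])

    def test_infinite_effect_all_carriers_poor(self):
        region = cnvsig.RegionSpec(1, 5.0, 12.0, cnvsig.LOSS, 0.5, math.inf)
        carriers = self._carriers([True] * 7 + [False] * 10, region.label)
        records = cnvsig.simulate_outcomes(carriers, [region], 0.10, seed=2)
        carried = carriers.loc[region.label]
        assert records.loc[carried[carried].index,
                           "death_from_disease_flag"].all()

    def test_null_effect_matches_baseline_rate(self):
        region = cnvsig.RegionSpec(1, 5.0, 12.0, cnvsig.LOSS, 0.5, 0.0)
        rng = np.random.default_rng(4)
        carriers = cohort.draw_carriers([region], [f"P{i}" for i in range(2000)], rng)
        records = cnvsig.simulate_outcomes(carriers, [region], 0.25, seed=4)
        assert records["death_from_disease_flag"].mean() == pytest.approx(0.25, abs=0.03)

    def test_seed_reproducible(self):
        region = cnvsig.RegionSpec(1, 5.0, 12.0, cnvsig.GAIN, 0.4, 1.0)
        carriers = self._carriers([True, False, True, False], region.label)
        r1 = cnvsig.simulate_outcomes(carriers, [region], 0.2, seed=9)
        r2 = cnvsig.simulate_outcomes(carriers, [region], 0.2, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_bad_baseline_rejected(self):
        region = cnvsig.RegionSpec(1, 5.0, 12.0, cnvsig.GAIN, 0.4, 1.0)
        carriers = self._carriers([True])
        with pytest.raises(ValueError):
            cnvsig.simulate_outcomes(carriers, [region], 0.0, seed=1)


class TestOutcomeRecords:
    def test_frame_record_round_trip(self):
        region = cnvsig.RegionSpec(1, 5.0, 12.0, cnvsig.LOSS, 0.5, 2.0)
        carriers = pd.DataFrame({f"P{i}": [i % 2 == 0] for i in range(6)},
                                index=[region.label])
        frame = cnvsig.simulate_outcomes(carriers, [region], 0.3, seed=1)
        records = cohort.frame_to_records(frame)
        assert len(records) == 6
        back = cohort.records_to_frame(records)
        pd.testing.assert_frame_equal(
            back[frame.columns].astype(frame.dtypes), frame)

    def test_negative_followup_rejected(self):
        with pytest.raises(ValueError):
            cnvsig.OutcomeRecord("p", -1.0, False, False, False, None,
                                 "good", "train")


class TestStudy:
    def test_same_seed_byte_identical(self):
        s1 = cnvsig.simulate_study(seed=3)
        s2 = cnvsig.simulate_study(seed=3)
        pd.testing.assert_frame_equal(s1.train_cn, s2.train_cn)
        pd.testing.assert_frame_equal(s1.val_expr, s2.val_expr)
        pd.testing.assert_frame_equal(s1.train_outcomes, s2.train_outcomes)

    def test_shapes_and_batches(self, default_study):
        s = default_study
        cfg = s.config
        assert s.train_cn.shape == (cfg.clones_per_chrom * cfg.n_chromosomes,
                                    cfg.n_train)
        assert s.val_expr.shape[1] == cfg.n_val
        assert set(s.val_batches.unique()) == {"val1", "val2"}
        assert s.normal_expr.shape[1] == cfg.n_normals

    def test_batch_effect_applied_to_val2_only(self, default_study):
        s = default_study
        val1 = s.val_batches[s.val_batches == "val1"].index
        val2 = s.val_batches[s.val_batches == "val2"].index
        pd.testing.assert_frame_equal(s.val_expr[list(val1)],
                                      s.val_expr_clean[list(val1)])
        assert not np.allclose(s.val_expr[list(val2)].to_numpy(),
                               s.val_expr_clean[list(val2)].to_numpy())

    def test_config_roundtrip(self):
        cfg = cnvsig.StudyConfig()
        again = cnvsig.StudyConfig.from_dict(cfg.to_dict())
        assert again == cfg
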