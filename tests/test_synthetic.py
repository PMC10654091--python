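"""Synthetic cohort generator: determinism, label exactness, planted
parameter and signal structure, round-trip IO."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import vaxbiome as vb
from vaxbiome.synthetic import CohortConfig, generate_cohort, read_cohort, write_cohort


class TestConfigValidation:
    def test_non_psd_correlation_names_parameters(self):
        with pytest.raises(ValueError, match="cross_panel_correlation"):
            CohortConfig(intra_pcv_correlation=0.05,
                         intra_dtap_correlation=0.05,
                         cross_panel_correlation=0.9)

    def test_panel_partition_enforced(self):
        with pytest.raises(ValueError, match="partition"):
            CohortConfig(antigen_panel=("DT",) * 19)

    def test_zip_parameters_bounded(self):
        with pytest.raises(ValueError):
            CohortConfig(zip_pi=(1.2, 0.5))
        with pytest.raises(ValueError):
            CohortConfig(zip_lambda=(0.0, 10.0))


class TestDeterminism:
    def test_same_seed_identical_tables(self, small_config):
        a = generate_cohort(small_config)
        b = generate_cohort(small_config)
        pd.testing.assert_frame_equal(a.titers, b.titers)
        pd.testing.assert_frame_equal(a.exposures, b.exposures)
        for assay in a.features:
            pd.testing.assert_frame_equal(a.features[assay], b.features[assay])
        assert a.ground_truth.responder_1yr == b.ground_truth.responder_1yr

    def test_same_seed_identical_files(self, small_config, tmp_path):
        write_cohort(generate_cohort(small_config), tmp_path / "a")
        write_cohort(generate_cohort(small_config), tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_different_seed_differs(self, small_config):
        other = small_config.model_copy(update={"seed": 99})
        a, b = generate_cohort(small_config), generate_cohort(other)
        assert not a.titers.value.equals(b.titers.value)


class TestLabels:
    def test_lvr_count_within_binomial_band(self):
        # exact assignment: 72 subjects at rate 12/72 must produce
        # exactly 12, comfortably inside the 3-SD band [4, 20].
        config = CohortConfig(n_subjects=72, lvr_rate=12 / 72,
                              assessed_1yr_rate=1.0, pcv_missing_rate=0.0,
                              seed=21)
        cohort = generate_cohort(config)
        n_lvr = sum(1 for v in cohort.ground_truth.responder_1yr.values()
                    if v == "LVR")
        assert 4 <= n_lvr <= 20
        assert n_lvr == 12

    def test_classifier_reproduces_planted_labels(self, default_cohort):
        outcomes, _ = vb.compute_outcomes(default_cohort.titers)
        got = dict(zip(outcomes.subject_id, outcomes.category))
        for subject, label in default_cohort.ground_truth.responder_1yr.items():
            assert got[subject] == label

    def test_year2_labels_reproduced(self, default_cohort):
        outcomes, _ = vb.compute_outcomes(default_cohort.titers, timepoint="2yr")
        got = dict(zip(outcomes.subject_id, outcomes.category))
        for subject, label in default_cohort.ground_truth.responder_2yr.items():
            assert got[subject] == label


class TestExposures:
    def test_zip_medians_recovered_at_large_n(self):
        # non-zero medians of the configured Poisson components (10 and
        # 28 days) recovered within +-1 at n=1000 per group; Monte-Carlo
        # oracle over replicate draws.
        medians = {"NVR": [], "LVR": []}
        for seed in range(10):
            config = CohortConfig(n_subjects=2000, lvr_rate=0.5,
                                  assessed_1yr_rate=1.0, birth_use_prob=(0, 0),
                                  dropout_rate=1.0, n_metabolites=0, seed=seed)
            cohort = generate_cohort(config)
            cum = vb.cumulative_oral_days(cohort.exposures).reindex(
                cohort.ground_truth.responder_1yr.keys(), fill_value=0)
            for grp in ("NVR", "LVR"):
                members = [s for s, v in cohort.ground_truth.responder_1yr.items()
                           if v == grp]
                pos = cum[members][cum[members] > 0]
                medians[grp].append(float(pos.median()))
        assert np.median(medians["NVR"]) == pytest.approx(10, abs=1)
        assert np.median(medians["LVR"]) == pytest.approx(28, abs=1)

    def test_zip_fit_recovers_generator_parameters(self):
        config = CohortConfig(n_subjects=2000, lvr_rate=0.0,
                              assessed_1yr_rate=1.0, birth_use_prob=(0, 0),
                              dropout_rate=1.0, n_metabolites=0, seed=7)
        cohort = generate_cohort(config)
        cum = vb.cumulative_oral_days(cohort.exposures).reindex(
            [f"S{i+1:03d}" for i in range(2000)], fill_value=0)
        model = vb.zip_fit(cum.to_numpy())
        # 3 Monte-Carlo SEs at n=2000
        assert model.pi == pytest.approx(config.zip_pi[0], abs=3 * 0.013)
        assert model.lam == pytest.approx(config.zip_lambda[0], abs=3 * 0.10)

    def test_exposure_days_union_consistent(self, default_cohort):
        # non-overlapping placement: union of oral days up to day 365
        # equals the per-course sum clipped at the cutoff
        log = default_cohort.exposures
        oral = log[log.route == "oral"]
        union = vb.cumulative_oral_days(log)
        for subject, grp in oral.groupby("subject_id"):
            days = set()
            for r in grp.itertuples():
                days.update(d for d in range(r.start_day,
                                             r.start_day + r.duration_days)
                            if d < 365)
            assert union[subject] == len(days)


class TestPlantedSignals:
    def test_null_effect_gives_no_correlation(self):
        config = CohortConfig(n_subjects=72, assessed_1yr_rate=1.0,
                              planted_ko_effect=0.0, seed=13)
        cohort = generate_cohort(config)
        outcomes, _ = vb.compute_outcomes(cohort.titers)
        out = outcomes.set_index("subject_id")["median_cross"]
        meta = cohort.feature_meta("stool_ko")
        window = meta[(meta.age_days >= 46) & (meta.age_days <= 75)]
        picked = window.groupby("subject_id").head(1)
        vals = cohort.features["stool_ko"].loc[picked.index]
        vals.index = picked["subject_id"].to_numpy()
        common = vals.index.intersection(out.index)
        rhos = [stats.spearmanr(vals.loc[common, k], out[common])[0]
                for k in cohort.ground_truth.planted_kos]
        assert np.median(np.abs(rhos)) < 0.2

    def test_planted_identifiers_exist_in_tables(self, default_cohort):
        gt = default_cohort.ground_truth
        assert set(gt.planted_kos) <= set(default_cohort.features["stool_ko"].columns)
        assert gt.planted_metabolite in default_cohort.metabolites.columns
        in_module = default_cohort.module_map.query(
            "module_id == @gt.planted_module").ko_id
        assert set(in_module) == set(gt.planted_kos)

    def test_planted_ko_correlates_with_configured_sign(self, default_cohort):
        outcomes, _ = vb.compute_outcomes(default_cohort.titers)
        out = outcomes.set_index("subject_id")["median_cross"]
        meta = default_cohort.feature_meta("stool_ko")
        picked = meta.groupby("subject_id").head(1)
        vals = default_cohort.features["stool_ko"].loc[picked.index]
        vals.index = picked["subject_id"].to_numpy()
        common = vals.index.intersection(out.index)
        rhos = [stats.spearmanr(vals.loc[common, k], out[common])[0]
                for k in default_cohort.ground_truth.planted_kos]
        assert np.median(rhos) > 0.2  # positive, as configured


class TestWriteReadCohort:
    def test_round_trip(self, small_config, tmp_path):
        cohort = generate_cohort(small_config)
        write_cohort(cohort, tmp_path)
        back = read_cohort(tmp_path, config=small_config)
        pd.testing.assert_frame_equal(cohort.titers, back.titers)
        pd.testing.assert_frame_equal(cohort.samples, back.samples)
        for assay in cohort.features:
            pd.testing.assert_frame_equal(cohort.features[assay],
                                          back.features[assay])
        assert back.ground_truth.responder_1yr == cohort.ground_truth.responder_1yr

    def test_empty_cohort_headers_only(self, tmp_path):
        cohort = generate_cohort(CohortConfig(n_subjects=0, seed=0))
        manifest = write_cohort(cohort, tmp_path)
        assert (manifest.rows[manifest.file.str.endswith(".tsv")] >= 0).all()
        titers = pd.read_csv(tmp_path / "titers.tsv", sep="\t")
        assert titers.empty and list(titers.columns)[:4] == [
            "subject_id", "antigen", "timepoint", "value"]

    def test_titer_row_count_bound(self):
        config = CohortConfig(n_subjects=10, assessed_1yr_rate=1.0,
                              assessed_2yr_rate=0.0, pcv_missing_rate=0.0,
                              seed=2)
        cohort = generate_cohort(config)
        one_tp = cohort.titers[cohort.titers.timepoint == "1yr"]
        assert len(one_tp) <= 10 * 19
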