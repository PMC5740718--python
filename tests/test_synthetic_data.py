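import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinewas.methylation import CELL_TYPES, beta_to_m
from twinewas.standardization import standardize_cohort
from twinewas.synthetic_data import (
    CohortConfig,
    PlantedEffect,
    generate_cell_reference_panel,
    generate_cohort,
    generate_genesets,
    generate_lms_table,
    generate_manifest,
    generate_methylomes,
    simulate_bundle,
)


class TestCohortConfig:
    def test_defaults_match_cohort_size(self):
        cfg = CohortConfig()
        assert cfg.n_male_pairs == 86 and cfg.n_female_pairs == 83

    def test_zero_pairs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_male_pairs=0)

    def test_bad_age_range_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(age_range=(79.0, 56.0))

    def test_followup_mean_outside_range_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(followup_years=(15.0, 9.6, 13.4))


class TestGenerateCohort:
    def test_default_pair_counts(self, lms_table):
        cohort = generate_cohort(CohortConfig(seed=1), lms_table)
        by_sex = cohort.groupby("sex")["pair_id"].nunique()
        assert by_sex["M"] == 86 and by_sex["F"] == 83
        assert len(cohort) == 2 * 169

    def test_mz_constraints_exact(self, small_cohort):
        for _, grp in small_cohort.groupby("pair_id"):
            assert grp["sex"].nunique() == 1
            assert grp["age_baseline"].diff().dropna().abs().max() == 0.0
            assert grp["age_followup"].diff().dropna().abs().max() == 0.0

    def test_same_seed_byte_identical(self, lms_table):
        cfg = CohortConfig(n_male_pairs=5, n_female_pairs=5, seed=42)
        c1 = generate_cohort(cfg, lms_table)
        c2 = generate_cohort(cfg, lms_table)
        pd.testing.assert_frame_equal(c1, c2)
        assert c1.to_csv() == c2.to_csv()

    def test_zero_smoking_discordance(self, lms_table):
        cfg = CohortConfig(n_male_pairs=60, n_female_pairs=60, seed=2,
                           smoking_discordance={"M": 0.0, "F": 0.0})
        cohort = generate_cohort(cfg, lms_table)
        diffs = cohort.groupby("pair_id")["pack_years_total"].agg(
            lambda v: abs(v.iloc[0] - v.iloc[1]))
        assert diffs.mean() == pytest.approx(0.0, abs=1e-12)

    def test_discordance_parameter_scales_difference(self, lms_table):
        cfg = CohortConfig(n_male_pairs=150, n_female_pairs=150, seed=3,
                           smoking_discordance={"M": 14.0, "F": 8.0})
        cohort = generate_cohort(cfg, lms_table)
        mean_diff = {}
        for sex in ("M", "F"):
            sub = cohort[cohort["sex"] == sex]
            diffs = sub.groupby("pair_id")["pack_years_total"].agg(
                lambda v: abs(v.iloc[0] - v.iloc[1]))
            mean_diff[sex] = diffs.mean()
        assert mean_diff["M"] > mean_diff["F"] > 0

    def test_demographics_near_targets(self, lms_table):
        cohort = generate_cohort(CohortConfig(seed=4), lms_table)
        male = cohort[cohort["sex"] == "M"]
        female = cohort[cohort["sex"] == "F"]
        assert abs(male["height_followup_cm"].median() - 174.0) < 3.0
        assert abs(female["height_followup_cm"].median() - 161.9) < 3.0
        assert male["pack_years_total"].mean() > female["pack_years_total"].mean()
        gap = cohort["age_followup"] - cohort["age_baseline"]
        assert gap.min() >= 9.6 and gap.max() <= 13.4

    def test_smoking_status_levels(self, small_cohort):
        assert set(small_cohort["smoking_status"]) <= {
            "never", "non-current", "current"}
        never = small_cohort[small_cohort["smoking_status"] == "never"]
        assert (never["pack_years_total"] == 0).all()

    def test_restandardization_recovers_unit_variance(self, lms_table):
        cohort = generate_cohort(CohortConfig(seed=5), lms_table)
        panel = standardize_cohort(cohort, lms_table)
        assert 0.9 < panel.scores["zFVC_followup"].std() < 1.1


class TestGenerateLmsTable:
    def test_single_age_grid_constant(self):
        table = generate_lms_table(age_grid=np.array([60.0]))
        b = table.blocks[("FEV1", "M")]
        assert b.ages.size == 1

    def test_non_monotone_grid_errors(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            generate_lms_table(age_grid=np.array([50.0, 45.0, 60.0]))

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_s_positive_any_seed(self, seed):
        table = generate_lms_table(seed=seed)
        for b in table.blocks.values():
            assert (b.S > 0).all()
            assert (b.M > 0).all()

    def test_m_decreasing_in_age(self):
        table = generate_lms_table(seed=0)
        for b in table.blocks.values():
            assert (np.diff(b.M) < 0).all()

    def test_round_trip_through_standardization_module(self, tmp_path):
        from twinewas.standardization import LMSCoefficientTable
        table = generate_lms_table(seed=2)
        table.to_tsv(tmp_path / "lms.tsv")
        again = LMSCoefficientTable.from_tsv(tmp_path / "lms.tsv")
        for key, b in table.blocks.items():
            np.testing.assert_array_equal(again.blocks[key].L, b.L)
            np.testing.assert_array_equal(again.blocks[key].M, b.M)
            np.testing.assert_array_equal(again.blocks[key].S, b.S)


class TestGenerateManifest:
    def test_probe_ids_unique(self, small_manifest):
        assert small_manifest.index.is_unique

    def test_na_fraction_one_errors(self):
        with pytest.raises(ValueError):
            generate_manifest(100, 10, na_fraction=1.0)

    def test_zero_genes_errors(self):
        with pytest.raises(ValueError, match="annotatable"):
            generate_manifest(100, 0, na_fraction=0.2)

    def test_na_fraction_binomial_ci(self):
        manifest = generate_manifest(1000, 100, na_fraction=0.2, seed=5)
        n_na = manifest["gene"].isna().sum()
        half = 2.576 * np.sqrt(0.2 * 0.8 * 1000)
        assert abs(n_na - 200) < half

    def test_intergenic_probes_get_igr_context(self, small_manifest):
        na_rows = small_manifest[small_manifest["gene"].isna()]
        assert na_rows["cgi_feature"].str.startswith("IGR-").all()
        genic = small_manifest[small_manifest["gene"].notna()]
        assert not genic["cgi_feature"].str.startswith("IGR-").any()

    def test_island_contexts_valid(self, small_manifest):
        suffixes = small_manifest["cgi_feature"].str.split("-").str[-1]
        assert set(suffixes) <= {"island", "shore", "shelf", "open sea"}


class TestGenerateCellReferencePanel:
    def test_columns_distinct_and_bounded(self, small_panel):
        vals = small_panel.reference_betas.to_numpy()
        assert vals.min() >= 0 and vals.max() <= 1
        for i in range(5):
            for j in range(i + 1, 5):
                assert np.mean(np.abs(vals[:, i] - vals[:, j])) > 0

    def test_deterministic(self, small_manifest):
        p1 = generate_cell_reference_panel(small_manifest.index, seed=12)
        p2 = generate_cell_reference_panel(small_manifest.index, seed=12)
        pd.testing.assert_frame_equal(p1.reference_betas, p2.reference_betas)


class TestGenerateMethylomes:
    def test_null_betas_open_interval_and_shapes(self, small_cohort,
                                                 small_manifest, small_panel,
                                                 lms_table):
        ds, frac = generate_methylomes(
            small_cohort, small_manifest, [], small_panel, seed=1,
            lms_table=lms_table)
        vals = ds.beta.to_numpy()
        assert vals.min() > 0 and vals.max() < 1
        assert ds.beta.shape == (len(small_manifest), len(small_cohort))
        np.testing.assert_allclose(frac.sum(axis=1), 1.0, atol=1e-9)

    def test_planted_probe_absent_errors_with_name(self, small_cohort,
                                                   small_manifest, small_panel,
                                                   lms_table):
        eff = PlantedEffect(probe_id="cg99999999", metric="zFEV1", slope=-0.1)
        with pytest.raises(KeyError, match="cg99999999"):
            generate_methylomes(small_cohort, small_manifest, [eff],
                                small_panel, seed=1, lms_table=lms_table)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            PlantedEffect(probe_id="cg0", metric="zPEF", slope=0.1)

    def test_deterministic_given_seed(self, small_cohort, small_manifest,
                                      small_panel, lms_table):
        a, fa = generate_methylomes(small_cohort, small_manifest, [],
                                    small_panel, seed=9, lms_table=lms_table)
        b, fb = generate_methylomes(small_cohort, small_manifest, [],
                                    small_panel, seed=9, lms_table=lms_table)
        pd.testing.assert_frame_equal(a.beta, b.beta)
        pd.testing.assert_frame_equal(a.detection_p, b.detection_p)
        pd.testing.assert_frame_equal(fa, fb)

    def test_pair_correlation_monotone(self, small_cohort, small_manifest,
                                       small_panel, lms_table):
        # within-pair M correlation increases over 3 settings
        cors = []
        subj = small_cohort.sort_values(["pair_id", "subject_id"])
        first = subj.groupby("pair_id")["subject_id"].first()
        second = subj.groupby("pair_id")["subject_id"].last()
        for rho in (0.1, 0.5, 0.9):
            ds, _ = generate_methylomes(
                small_cohort, small_manifest, [], small_panel,
                pair_correlation=rho, seed=3, lms_table=lms_table,
                noise_sd=0.5)
            m = beta_to_m(ds.beta)
            a = m[list(first)].to_numpy().ravel()
            b = m[list(second)].to_numpy().ravel()
            # correlation of within-probe deviations between co-twins
            a = a - m.mean(axis=1).to_numpy().repeat(len(first))
            b = b - m.mean(axis=1).to_numpy().repeat(len(first))
            cors.append(np.corrcoef(a, b)[0, 1])
        assert cors[0] < cors[1] < cors[2]

    def test_planted_effect_shifts_delta_m(self, small_cohort, small_manifest,
                                           small_panel, lms_table):
        probe = small_manifest.index[10]
        eff = PlantedEffect(probe_id=probe, metric="zFEV1", slope=-0.5)
        ds_null, _ = generate_methylomes(small_cohort, small_manifest, [],
                                         small_panel, seed=4,
                                         lms_table=lms_table)
        ds_eff, _ = generate_methylomes(small_cohort, small_manifest, [eff],
                                        small_panel, seed=4,
                                        lms_table=lms_table)
        m_null = beta_to_m(ds_null.beta.loc[probe])
        m_eff = beta_to_m(ds_eff.beta.loc[probe])
        zpanel = standardize_cohort(small_cohort, lms_table)
        z = zpanel.value("zFEV1")
        pairs = small_cohort.groupby("pair_id")["subject_id"].apply(list)
        for pid, (a, b) in pairs.items():
            sup, inf = (a, b) if z[a] > z[b] else (b, a)
            delta = abs(z[a] - z[b])
            expected = -0.5 * np.log(delta)
            observed = (m_eff[sup] - m_eff[inf]) - (m_null[sup] - m_null[inf])
            assert observed == pytest.approx(expected, abs=1e-9)

    def test_null_pipeline_pvalues_uniform(self, lms_table):
        # KS screen on the end-to-end null: planted = [] and the full
        # covariate model should give Uniform(0,1) p-values
        from twinewas.twin_design import build_design, difference_methylation
        from twinewas.ewas import run_ewas
        for seed in (11, 12):
            cfg = CohortConfig(n_male_pairs=30, n_female_pairs=30, seed=seed)
            cohort = generate_cohort(cfg, lms_table)
            manifest = generate_manifest(1500, 200, 0.2, seed=seed)
            panel = generate_cell_reference_panel(manifest.index, seed=seed)
            ds, frac = generate_methylomes(cohort, manifest, [], panel,
                                           seed=seed, lms_table=lms_table)
            zpanel = standardize_cohort(cohort, lms_table)
            design = build_design(cohort, zpanel, frac, "zFEV1",
                                  "cross-sectional")
            dm = difference_methylation(beta_to_m(ds.beta), design)
            run = run_ewas(dm, design)
            ks = stats.kstest(run.results["p"], "uniform")
            assert ks.pvalue > 0.01


class TestGenerateGenesets:
    def test_members_within_universe(self):
        genes = [f"G{i}" for i in range(50)]
        sets = generate_genesets(genes, 10, (3, 10), seed=1)
        for members in sets.values():
            assert set(members) <= set(genes)

    def test_zero_sets_valid_empty(self, tmp_path):
        from twinewas.enrichment import read_gmt, write_gmt
        sets = generate_genesets([f"G{i}" for i in range(5)], 0, (1, 3))
        assert sets == {}
        write_gmt(tmp_path / "empty.gmt", sets)
        assert read_gmt(tmp_path / "empty.gmt") == ({}, {})

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="empty"):
            generate_genesets([], 5, (1, 2))

    def test_size_range_exceeding_universe_errors(self):
        with pytest.raises(ValueError, match="size_range"):
            generate_genesets(["A", "B"], 1, (1, 3))

    def test_spiked_set_included(self):
        genes = [f"G{i}" for i in range(30)]
        sets = generate_genesets(genes, 3, (2, 5), seed=2,
                                 spiked_genes=["G1", "G2"])
        assert sets["SPIKED"] == ["G1", "G2"]


class TestSimulateBundle:
    def test_bundle_files_and_determinism(self, tmp_path):
        cfg = CohortConfig(n_male_pairs=4, n_female_pairs=4, seed=17)
        expected = ["phenotypes.tsv", "lms.tsv", "beta.tsv", "detection_p.tsv",
                    "bead_count.tsv", "manifest.tsv", "blacklist.txt",
                    "cell_panel.tsv", "cell_counts.tsv", "genesets.gmt",
                    "truth.json"]
        hashes = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            simulate_bundle(out, config=cfg, n_probes=50, n_genes=20,
                            n_missing_cell_counts=2)
            for name in expected:
                assert (out / name).exists(), name
            hashes.append({
                name: hashlib.sha256((out / name).read_bytes()).hexdigest()
                for name in expected
            })
        assert hashes[0] == hashes[1]

    def test_truth_sidecar_contents(self, tmp_path):
        cfg = CohortConfig(n_male_pairs=4, n_female_pairs=4, seed=18)
        truth = simulate_bundle(tmp_path / "x", config=cfg, n_probes=80,
                                n_genes=20, n_planted=5, planted_slope=-0.2,
                                n_missing_cell_counts=0)
        assert len(truth["planted"]) == 5
        assert truth["n_pairs"] == 8
        on_disk = json.loads((tmp_path / "x" / "truth.json").read_text())
        assert on_disk["planted"] == truth["planted"]
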