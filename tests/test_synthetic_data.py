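"""Generator contracts: determinism, planted structure, null behaviour."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from resistaxis.synthetic_data import (
    SynthConfig,
    generate_chip_counts,
    generate_clinical_cohort,
    generate_expression,
    generate_fragment_methylation,
    generate_reference_atlas,
    generate_variant_table,
    make_gene_annotation,
    make_series,
)


def with_overrides(cfg: SynthConfig, **kw) -> SynthConfig:
    return SynthConfig(**{**dataclasses.asdict(cfg), **kw})


class TestConfig:
    def test_default_series_matches_study_design(self):
        cfg = SynthConfig()
        series = make_series(cfg)
        assert series.sample_ids == ["Parental", "R100", "R500", "R1000",
                                     "R4000"]
        assert series.ec50[0] == 857.0 and series.ec50[-1] == 3446.0

    def test_nonincreasing_ec50_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            SynthConfig(ec50_values=(857, 1100, 1000, 2500, 3446))

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction_covarying"):
            SynthConfig(fraction_covarying=1.5)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SynthConfig(n_genes=123, n_k1=10, n_k2=10, n_other=10, seed=9)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SynthConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg


class TestExpression:
    def test_zero_noise_planted_gene_is_exact_ramp(self):
        cfg = SynthConfig(n_genes=50, fraction_covarying=0.2, noise_sd=0.0,
                          effect_size=1.0, n_k1=5, n_k2=5, n_other=5)
        fm, gt = generate_expression(cfg)
        gene, direction, effect = gt.planted_covarying_features[0]
        row = fm.values.loc[gene].to_numpy()
        assert np.allclose(row - row[0], direction * np.arange(5))

    def test_seed_determinism_byte_for_byte(self):
        a, _ = generate_expression(SynthConfig(n_genes=100, n_k1=10, n_k2=10, n_other=10, seed=3))
        b, _ = generate_expression(SynthConfig(n_genes=100, n_k1=10, n_k2=10, n_other=10, seed=3))
        pd.testing.assert_frame_equal(a.values, b.values)
        c, _ = generate_expression(SynthConfig(n_genes=100, n_k1=10, n_k2=10, n_other=10, seed=4))
        assert not a.values.equals(c.values)

    def test_planted_count_by_construction(self):
        cfg = SynthConfig(n_genes=2000, fraction_covarying=0.05)
        _, gt = generate_expression(cfg)
        assert len(gt.planted_covarying_features) == 100
        ids = {f for f, _, _ in gt.planted_covarying_features}
        assert len(ids) == 100  # no duplicates

    def test_tiny_fraction_warns_and_plants_nothing(self):
        cfg = SynthConfig(n_genes=50, fraction_covarying=0.001,
                          n_k1=5, n_k2=5, n_other=5)
        with pytest.warns(UserWarning, match="zero planted"):
            _, gt = generate_expression(cfg)
        assert gt.planted_covarying_features == []

    def test_ground_truth_ids_exist_in_matrix(self, small_config):
        fm, gt = generate_expression(small_config)
        for f, _, _ in gt.planted_covarying_features:
            assert f in fm.values.index


class TestFragmentsAndVariants:
    def test_methylation_values_bounded_and_planted_drift(self):
        cfg = SynthConfig(n_fragments=200, meth_precision=500.0)
        fm, cov, gt = generate_fragment_methylation(cfg)
        vals = fm.values.to_numpy()
        assert vals.min() >= 0 and vals.max() <= 1
        # planted positive fragments should end higher than they start
        pos = [f for f, d, _ in gt.planted_fragment_features if d > 0]
        diffs = fm.values.loc[pos].iloc[:, -1] - fm.values.loc[pos].iloc[:, 0]
        assert (diffs > 0).mean() > 0.9

    def test_fragment_determinism(self):
        a, _, _ = generate_fragment_methylation(SynthConfig(seed=5))
        b, _, _ = generate_fragment_methylation(SynthConfig(seed=5))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_variant_singletons_have_alt_in_exactly_one_sample(self):
        cfg = SynthConfig(n_variants=100, n_trend_variants=5,
                          n_singleton_artifacts=13)
        alt, ref, gt = generate_variant_table(cfg)
        assert len(gt.planted_variant_singletons) == 13
        for v in gt.planted_variant_singletons:
            assert (alt.loc[v] > 0).sum() == 1

    def test_variant_counts_nonnegative_and_deterministic(self):
        a1, r1, _ = generate_variant_table(SynthConfig(seed=2))
        a2, r2, _ = generate_variant_table(SynthConfig(seed=2))
        pd.testing.assert_frame_equal(a1, a2)
        assert (a1 >= 0).all().all() and (r1 >= 0).all().all()


class TestChip:
    def test_group_partition_counts_by_construction(self, small_config):
        _, gt = generate_chip_counts(small_config)
        counts = pd.Series(gt.planted_promoter_groups).value_counts()
        assert counts["K1"] == small_config.n_k1
        assert counts["K2"] == small_config.n_k2
        assert counts["other"] == small_config.n_other
        assert counts["K3"] == (small_config.n_genes - small_config.n_k1
                                - small_config.n_k2 - small_config.n_other)

    def test_k3_promoters_match_background_distribution(self, small_config,
                                                        annotation):
        tracks, gt = generate_chip_counts(small_config, annotation)
        k3 = [g for g, lab in gt.planted_promoter_groups.items()
              if lab == "K3"][:20]
        windows = annotation.promoter_windows(5000).loc[k3]
        bins = tracks["R100"][0].bins
        in_any = np.zeros(len(bins), dtype=bool)
        for _, w in windows.iterrows():
            in_any |= ((bins["start"] < w["end"])
                       & (bins["end"] > w["start"])).to_numpy()
        k3_mean = bins.loc[in_any, "ip"].mean()
        assert k3_mean == pytest.approx(small_config.ip_depth, rel=0.1)

    def test_unit_fold_is_null(self, annotation, small_config):
        import dataclasses

        cfg = SynthConfig(**{**dataclasses.asdict(small_config),
                             "enrichment_fold": 1.0})
        tracks, _ = generate_chip_counts(cfg, annotation)
        from resistaxis.chip_enrichment import build_promoter_matrix

        matrix = build_promoter_matrix(tracks, annotation,
                                       condition_order=make_series(cfg).sample_ids)
        assert matrix.calls.to_numpy().sum() == 0

    def test_track_determinism(self, small_config, annotation):
        t1, _ = generate_chip_counts(small_config, annotation)
        t2, _ = generate_chip_counts(small_config, annotation)
        pd.testing.assert_frame_equal(t1["R4000"][1].bins,
                                      t2["R4000"][1].bins)


class TestClinical:
    def test_patient_count_matches_cohort_design(self, small_config,
                                                 annotation):
        cohort, _ = generate_clinical_cohort(small_config, annotation, {})
        assert cohort.beta.shape[1] == 19
        assert len(cohort.responders) == 14
        assert len(cohort.progressors) == 5

    def test_null_cohort_plants_nothing(self, annotation, small_config):
        cfg = with_overrides(small_config, beta_shift=0.0)
        cohort, gt = generate_clinical_cohort(cfg, annotation, {})
        assert gt.planted_clinical_dmg == set()

    def test_planted_genes_have_shifted_cpgs(self, small_config, annotation):
        cohort, gt = generate_clinical_cohort(
            small_config, annotation,
            {"Tcf3": frozenset(list(annotation.gene_ids)[:50])},
        )
        assert gt.planted_clinical_dmg
        resp = cohort.beta[cohort.responders].mean(axis=1)
        prog = cohort.beta[cohort.progressors].mean(axis=1)
        # planted genes own the CpGs with the largest group shifts
        gene_of = pd.Series(
            {c: f"g{int(c[2:]) // small_config.cpgs_per_gene:05d}"
             for c in cohort.beta.index}
        )
        shift = (prog - resp).groupby(gene_of).max()
        planted_shift = shift[sorted(gt.planted_clinical_dmg)].median()
        null_shift = shift[~shift.index.isin(gt.planted_clinical_dmg)].median()
        assert planted_shift > null_shift + 0.1

    def test_cohort_determinism(self, small_config, annotation):
        c1, _ = generate_clinical_cohort(small_config, annotation, {})
        c2, _ = generate_clinical_cohort(small_config, annotation, {})
        pd.testing.assert_frame_equal(c1.beta, c2.beta)


class TestAtlas:
    def test_zero_noise_recovers_stage_order_and_line_order(self):
        cfg = SynthConfig(n_genes=400, n_k1=40, n_k2=40, n_other=20,
                          atlas_noise_sd=0.0)
        ref, stages, lines, gt = generate_reference_atlas(cfg)
        from resistaxis.developmental_axis import (
            combined_pca,
            find_developmental_pc,
            monotonicity_score,
        )

        proj = combined_pca(ref, lines)
        pc = find_developmental_pc(proj, stages)
        assert pc > 0  # the developmental axis is not the leading component
        mono = monotonicity_score(proj, make_series(cfg))
        assert mono.rho == pytest.approx(-1.0)

    def test_planted_placement_decreases_with_rank(self, small_config):
        _, _, _, gt = generate_reference_atlas(small_config)
        series = make_series(small_config)
        pos = [gt.planted_stage_positions[s] for s in series.sample_ids]
        assert all(a > b for a, b in zip(pos, pos[1:]))

    def test_atlas_determinism(self, small_config):
        r1, s1, l1, _ = generate_reference_atlas(small_config)
        r2, s2, l2, _ = generate_reference_atlas(small_config)
        pd.testing.assert_frame_equal(r1.values, r2.values)
        pd.testing.assert_frame_equal(l1.values, l2.values)


class TestGroundTruthMerge:
    def test_merge_combines_fields_and_checks_seed(self, small_config):
        _, gt_e = generate_expression(small_config)
        _, gt_c = generate_chip_counts(small_config)
        merged = gt_e.merge(gt_c)
        assert merged.planted_covarying_features
        assert merged.planted_promoter_groups
        other = with_overrides(small_config, seed=99)
        _, gt_x = generate_expression(other)
        with pytest.raises(ValueError, match="seed"):
            gt_e.merge(gt_x)

    def test_every_feature_classifiable(self, small_config):
        fm, gt = generate_expression(small_config)
        planted = {f for f, _, _ in gt.planted_covarying_features}
        assert planted <= set(fm.values.index)
        # everything not planted is, by construction, null
        assert len(planted) + len(set(fm.values.index) - planted) == len(
            fm.values.index
        )
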