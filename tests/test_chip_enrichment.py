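"""Poisson bin testing, promoter calls, pattern clustering, profiles."""
import numpy as np
import pandas as pd
import pytest

from resistaxis.chip_enrichment import (
    BIN_WIDTH,
    BinTrack,
    bin_poisson_pvalue,
    build_promoter_matrix,
    call_promoter_enrichment,
    combinatorial_cluster,
    default_k_labeler,
    metagene_profile,
    replicate_concordance,
)
from resistaxis.synthetic_data import generate_chip_counts, make_series
from resistaxis.types import GeneAnnotation

from conftest import oracle_poisson_upper_tail


def make_track(ip, inp, condition="c", replicate="r", start0=0,
               ip_total=None, input_total=None):
    n = len(ip)
    starts = start0 + np.arange(n) * BIN_WIDTH
    bins = pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + BIN_WIDTH,
         "ip": ip, "input": inp}
    )
    return BinTrack(condition=condition, replicate=replicate, bins=bins,
                    ip_total=ip_total, input_total=input_total)


def single_gene_annotation(tss=10_000, strand="+", length=8000):
    start = tss if strand == "+" else tss - length + 1
    end = tss + length if strand == "+" else tss + 1
    return GeneAnnotation(
        pd.DataFrame(
            {"chrom": ["chr1"], "start": [start], "end": [end],
             "strand": [strand], "tss": [tss]},
            index=pd.Index(["g1"], name="gene_id"),
        )
    )


class TestBinPoisson:
    def test_zero_ip_count_gives_p_one(self):
        for inp in (0, 5, 400):
            assert bin_poisson_pvalue(0, inp, 1e6, 1e6) == 1.0

    def test_lambda_one_example(self):
        # P(Poisson(1) >= 5) = 1 - e^-1 * sum_{i<5} 1/i!
        p = bin_poisson_pvalue(5, 1, 1e6, 1e6)
        assert p == pytest.approx(3.659846827343771e-3, rel=1e-12)

    def test_equal_large_counts_near_median(self):
        p = bin_poisson_pvalue(1000, 1000, 1e7, 1e7)
        assert 0.45 < p < 0.55

    def test_library_scaling_enters_rate(self):
        # ip_total twice input_total doubles the expected rate
        p_scaled = bin_poisson_pvalue(30, 10, 2e6, 1e6)
        p_flat = bin_poisson_pvalue(30, 20, 1e6, 1e6)
        assert p_scaled == pytest.approx(p_flat, rel=1e-12)

    def test_pseudocount_floors_zero_input(self):
        assert bin_poisson_pvalue(10, 0, 1e6, 1e6) == pytest.approx(
            oracle_poisson_upper_tail(10, 1.0), rel=1e-10
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            bin_poisson_pvalue(-1, 0, 1e6, 1e6)

    def test_matches_partial_sum_oracle_over_grid(self):
        rng = np.random.default_rng(5)
        lams = rng.uniform(0.2, 50, size=60)
        ks = rng.integers(0, 201, size=60)
        for lam, k in zip(lams, ks):
            p = bin_poisson_pvalue(int(k), lam, 1e6, 1e6, pseudocount=lam)
            # pseudocount=lam with input 0 makes the rate exactly lam
            assert p == pytest.approx(
                oracle_poisson_upper_tail(int(k), lam), rel=1e-10
            )


class TestPromoterCalls:
    def test_three_significant_bins_call_enrichment(self):
        # promoter [5000, 10000): bins 100; plant 3 very high-IP bins
        ip = np.zeros(240, dtype=int)
        inp = np.full(240, 10)
        region = np.arange(240) * BIN_WIDTH + 4000  # bins span [4000, 16000)
        in_promoter = (region >= 5000) & (region < 10_000)
        idx = np.flatnonzero(in_promoter)[:3]
        ip[idx] = 200
        track = make_track(ip, inp, start0=4000, ip_total=1e6,
                           input_total=1e6)
        calls, sig = call_promoter_enrichment(track,
                                              single_gene_annotation())
        assert calls["g1"] == 1 and sig["g1"] == 3

    def test_two_significant_bins_do_not(self):
        ip = np.zeros(240, dtype=int)
        inp = np.full(240, 10)
        region = np.arange(240) * BIN_WIDTH + 4000
        idx = np.flatnonzero((region >= 5000) & (region < 10_000))[:2]
        ip[idx] = 200
        track = make_track(ip, inp, start0=4000, ip_total=1e6,
                           input_total=1e6)
        calls, sig = call_promoter_enrichment(track,
                                              single_gene_annotation())
        assert calls["g1"] == 0 and sig["g1"] == 2

    def test_downstream_bins_ignored_for_plus_strand(self):
        ip = np.zeros(240, dtype=int)
        inp = np.full(240, 10)
        region = np.arange(240) * BIN_WIDTH + 4000
        idx = np.flatnonzero(region >= 10_000)[:5]  # downstream of TSS
        ip[idx] = 200
        track = make_track(ip, inp, start0=4000, ip_total=1e6,
                           input_total=1e6)
        calls, _ = call_promoter_enrichment(track, single_gene_annotation())
        assert calls["g1"] == 0

    def test_minus_strand_promoter_is_downstream_in_coordinates(self):
        anno = single_gene_annotation(strand="-")
        ip = np.zeros(240, dtype=int)
        inp = np.full(240, 10)
        region = np.arange(240) * BIN_WIDTH + 4000
        idx = np.flatnonzero(region > 10_000)[:3]
        ip[idx] = 200
        track = make_track(ip, inp, start0=4000, ip_total=1e6,
                           input_total=1e6)
        calls, _ = call_promoter_enrichment(track, anno)
        assert calls["g1"] == 1

    def test_both_mode_requires_call_in_each_replicate(self):
        ip_hot = np.zeros(240, dtype=int)
        inp = np.full(240, 10)
        region = np.arange(240) * BIN_WIDTH + 4000
        idx = np.flatnonzero((region >= 5000) & (region < 10_000))[:3]
        ip_hot[idx] = 200
        hot = make_track(ip_hot, inp, replicate="r1", start0=4000,
                         ip_total=1e6, input_total=1e6)
        cold = make_track(np.zeros(240, dtype=int), inp, replicate="r2",
                          start0=4000, ip_total=1e6, input_total=1e6)
        calls_both, _ = call_promoter_enrichment(
            [hot, cold], single_gene_annotation(), replicate_mode="both"
        )
        calls_pooled, _ = call_promoter_enrichment(
            [hot, cold], single_gene_annotation(), replicate_mode="pooled"
        )
        assert calls_both["g1"] == 0
        assert calls_pooled["g1"] == 1  # pooled counts stay far above input


class TestClustering:
    @pytest.mark.parametrize(
        "pattern, label",
        [
            ("11111", "K1"),
            ("00000", "K3"),
            ("01100", "K2"),
            ("01000", "K2"),
            ("00110", "K2"),
            ("01110", "K2"),
            ("00010", "other"),
            ("10000", "other"),
            ("01101", "other"),
            ("11110", "other"),
        ],
    )
    def test_default_rule(self, pattern, label):
        assert default_k_labeler(pattern) == label

    def test_patterns_partition_promoters(self, small_config, annotation):
        tracks, gt = generate_chip_counts(small_config, annotation)
        matrix = build_promoter_matrix(
            tracks, annotation,
            condition_order=make_series(small_config).sample_ids,
        )
        clusters = combinatorial_cluster(matrix)
        assert set(clusters.index) == set(annotation.gene_ids)
        assert clusters["pattern"].str.len().eq(5).all()
        assert clusters["label"].isin(["K1", "K2", "K3", "other"]).all()

    def test_planted_group_recovery(self, small_config, annotation):
        tracks, gt = generate_chip_counts(small_config, annotation)
        matrix = build_promoter_matrix(
            tracks, annotation,
            condition_order=make_series(small_config).sample_ids,
        )
        clusters = combinatorial_cluster(matrix)
        truth = pd.Series(gt.planted_promoter_groups)
        planted = truth[truth.isin(["K1", "K2", "K3"])]
        agree = (clusters.loc[planted.index, "label"] == planted).mean()
        assert agree >= 0.95

    def test_custom_rule_set_is_honored(self, small_config, annotation):
        tracks, _ = generate_chip_counts(small_config, annotation)
        matrix = build_promoter_matrix(
            tracks, annotation,
            condition_order=make_series(small_config).sample_ids,
        )
        clusters = combinatorial_cluster(matrix, labeler=lambda p: "X")
        assert (clusters["label"] == "X").all()


class TestMetagene:
    def test_uniform_equal_depth_counts_give_flat_zero_profile(self):
        ip = np.full(240, 7)
        track = make_track(ip, ip, start0=4000)
        profile = metagene_profile({"c": [track]}, single_gene_annotation(),
                                   ["g1"], flank=2000)
        assert np.allclose(profile["c"], 0.0)
        assert len(profile) == 2 * 2000 // BIN_WIDTH

    def test_single_gene_profile_is_its_own_signal(self):
        rng = np.random.default_rng(2)
        ip = rng.poisson(10, 240)
        inp = rng.poisson(10, 240)
        track = make_track(ip, inp, start0=4000)
        profile = metagene_profile({"c": [track]}, single_gene_annotation(),
                                   ["g1"], flank=1000)
        scale = track.ip_total / track.input_total
        # offset 0 bin = the bin starting at the TSS (10000 -> index 120)
        expected = np.log2((ip[120] + 1) / (inp[120] * scale + 1))
        assert profile.loc[0, "c"] == pytest.approx(expected, rel=1e-12)

    def test_empty_gene_set_rejected(self):
        track = make_track(np.ones(240, int), np.ones(240, int), start0=4000)
        with pytest.raises(ValueError):
            metagene_profile({"c": [track]}, single_gene_annotation(), [])

    def test_planted_k2_profile_ordering(self, small_config, annotation):
        tracks, gt = generate_chip_counts(small_config, annotation)
        k2 = [g for g, lab in gt.planted_promoter_groups.items()
              if lab == "K2"]
        profile = metagene_profile(tracks, annotation, k2, flank=5000)
        upstream = profile.loc[-4000:-1000]  # inside the planted window
        means = upstream.mean()
        assert means["R100"] > means["Parental"] + 0.5
        assert means["R500"] > means["R4000"] + 0.5
        assert abs(means["Parental"] - means["R4000"]) < 0.2


class TestReplicateConcordance:
    def test_identical_replicates_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        ip = rng.poisson(20, 500)
        t1 = make_track(ip, np.full(500, 10), replicate="r1")
        t2 = make_track(ip.copy(), np.full(500, 10), replicate="r2")
        assert replicate_concordance(t1, t2) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        t1 = make_track(rng.poisson(10, 20_000), np.full(20_000, 10))
        t2 = make_track(rng.poisson(10, 20_000), np.full(20_000, 10))
        assert abs(replicate_concordance(t1, t2)) < 0.05

    def test_anticorrelated_tracks_negative(self):
        x = np.arange(100)
        t1 = make_track(x, np.full(100, 10))
        t2 = make_track(x[::-1].copy(), np.full(100, 10))
        assert replicate_concordance(t1, t2) < 0

    def test_generator_replicates_concordant(self, small_config, annotation):
        tracks, _ = generate_chip_counts(small_config, annotation)
        r = replicate_concordance(*tracks["R100"])
        assert r > 0.5  # planted promoters drive shared structure
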