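import numpy as np
import pytest
from scipy import stats as sstats

from oracles import per_locus_fst, weir_cockerham_fst
from nerkascan.ld_stats import pairwise_r2
from nerkascan.synthetic_cohort import (
    AdmixtureCline,
    CohortDesign,
    PlantedFeature,
    attach_read_evidence,
    draw_population_frequencies,
    simulate_cohort,
    write_cohort,
)


def design(**kw):
    base = dict(
        pop_sizes=(25, 25),
        fst=(0.1, 0.1),
        n_loci=500,
        chrom_lengths=(5_000_000,),
        mean_depth=30,
        missing_rate=0.0,
        seed=0,
    )
    base.update(kw)
    return CohortDesign(**base)


class TestDesignValidation:
    def test_f_of_one_rejected(self):
        with pytest.raises(ValueError, match=r"\[0,1\)"):
            design(fst=(1.0, 0.5))

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            design(pop_sizes=(1,), fst=(0.1,))

    def test_missing_rate_capped(self):
        with pytest.raises(ValueError):
            design(missing_rate=0.2)

    def test_zero_loci_rejected(self):
        with pytest.raises(ValueError):
            design(n_loci=0)

    def test_cline_weight_count_checked(self):
        with pytest.raises(ValueError, match="weights"):
            design(admixture_cline=AdmixtureCline(0, 1, weights=(0.5,)))

    def test_haploblock_needs_two_loci(self):
        with pytest.raises(ValueError):
            PlantedFeature(kind="divergent_haploblock", chrom="c", start=1, end=9, params={"n_loci": 1})

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            PlantedFeature(kind="wibble")


class TestFrequencies:
    def test_drift_free_limit(self):
        d = design(fst=(0.0, 0.0))
        _, _, p, pk, _ = draw_population_frequencies(d)
        np.testing.assert_array_equal(pk[:, 0], p)
        np.testing.assert_array_equal(pk[:, 1], p)

    def test_positions_strictly_increasing(self):
        d = design(n_loci=2000, chrom_lengths=(1_000_000, 500_000))
        chrom, pos, *_ = draw_population_frequencies(d)
        for c in set(chrom):
            sel = chrom == c
            assert np.all(np.diff(pos[sel]) > 0)
        assert pos.min() >= 1

    def test_fst_recovery(self):
        d = design(pop_sizes=(50, 50), fst=(0.1, 0.1), n_loci=20_000, chrom_lengths=(100_000_000,))
        cohort = simulate_cohort(d)
        est = weir_cockerham_fst(cohort.genotypes.values, cohort.pop_labels)
        assert est == pytest.approx(0.1, abs=0.02)

    def test_planted_block_tops_per_locus_fst(self):
        d = design(pop_sizes=(50, 50), fst=(0.05, 0.05), n_loci=2000, chrom_lengths=(20_000_000,))
        feat = PlantedFeature(
            kind="divergent_haploblock", chrom="chr1", start=5_000_000, end=5_100_000,
            params={"n_loci": 4, "pop_freqs": [0.95, 0.05]},
        )
        cohort = simulate_cohort(d, [feat])
        fst = per_locus_fst(cohort.genotypes.values, cohort.pop_labels)
        cutoff = np.nanquantile(fst, 0.99)
        assert np.all(fst[cohort.truth_log[0]] >= cutoff)

    def test_planted_frequencies_verbatim(self):
        d = design()
        feat = PlantedFeature(
            kind="divergent_haploblock", chrom="chr1", start=100_000, end=200_000,
            params={"n_loci": 3, "pop_freqs": [0.9, 0.2]},
        )
        _, _, _, pk, truth = draw_population_frequencies(d, [feat])
        np.testing.assert_array_equal(pk[truth[0], 0], 0.9)
        np.testing.assert_array_equal(pk[truth[0], 1], 0.2)


class TestGenotypes:
    def test_zero_frequency_all_zero_dosage(self):
        d = design(fst=(0.0, 0.0), n_loci=50)
        chrom, pos, p, pk, truth = draw_population_frequencies(d)
        from nerkascan.synthetic_cohort import sample_genotypes

        rng = np.random.default_rng(0)
        dosages, labels, _ = sample_genotypes(d, np.zeros_like(pk), [], truth, rng, chrom, pos)
        assert (dosages.values == 0).all()

    def test_hardy_weinberg_aggregate(self):
        d = design(pop_sizes=(100,), fst=(0.0,), n_loci=400, seed=5)
        cohort = simulate_cohort(d)
        g = cohort.genotypes.values
        pvals = []
        for i in range(g.shape[0]):
            row = g[i][np.isfinite(g[i])]
            p_hat = row.sum() / (2 * len(row))
            if p_hat in (0.0, 1.0):
                continue
            exp = len(row) * np.array(
                [(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat), p_hat**2]
            )
            obs = np.array([(row == 0).sum(), (row == 1).sum(), (row == 2).sum()])
            stat = ((obs - exp) ** 2 / exp).sum()
            pvals.append(sstats.chi2.sf(stat, df=1))  # 1 df: p estimated
        # aggregate goodness of fit: p-values ~ Uniform under HW sampling
        stat, p = sstats.kstest(pvals, "uniform")
        assert p > 0.001

    def test_haploblock_internal_r2(self):
        d = design(pop_sizes=(60,), fst=(0.0,), n_loci=100)
        feat = PlantedFeature(
            kind="divergent_haploblock", chrom="chr1", start=1_000_000, end=1_500_000,
            params={"n_loci": 10, "pop_freqs": [0.5]},
        )
        cohort = simulate_cohort(d, [feat])
        block = cohort.truth_log[0]
        r2 = pairwise_r2(cohort.genotypes.values[block])
        off_diag = r2[~np.eye(len(block), dtype=bool)]
        assert np.nanmin(off_diag) >= 0.95

    def test_admixture_weight_one_matches_pop_a(self):
        n = 30
        weights = tuple([1.0] * n + [0.0] * n)
        d = design(
            pop_sizes=(n, n), fst=(0.3, 0.3), n_loci=3000,
            admixture_cline=AdmixtureCline(0, 1, weights=weights), seed=3,
        )
        cohort = simulate_cohort(d)
        # with w=1/0 the cline degenerates to the pure populations: mean
        # dosage per pop tracks its own p_k
        g = cohort.genotypes.values
        mean_a = g[:, cohort.pop_labels == 0].mean(axis=1)
        resid_a = mean_a - 2 * cohort.pop_freqs[:, 0]
        resid_cross = mean_a - 2 * cohort.pop_freqs[:, 1]
        assert np.abs(resid_a).mean() < np.abs(resid_cross).mean()

    def test_truth_log_matches_altered_loci(self):
        d = design(seed=9)
        feat = PlantedFeature(
            kind="divergent_haploblock", chrom="chr1", start=2_000_000, end=2_050_000,
            params={"n_loci": 5, "pop_freqs": [1.0, 0.0]},
        )
        cohort = simulate_cohort(d, [feat])
        loci = cohort.truth_log[0]
        # fixed difference planted: pop0 all dosage 2, pop1 all dosage 0
        g = cohort.genotypes.values[loci]
        assert np.all(g[:, cohort.pop_labels == 0] == 2)
        assert np.all(g[:, cohort.pop_labels == 1] == 0)


class TestReadEvidence:
    def test_hom_ref_ad(self):
        rng = np.random.default_rng(0)
        g = np.zeros((5, 4))
        g2, ad, dp = attach_read_evidence(g, 20, 0.0, np.array([], dtype=int), rng)
        assert (ad[:, :, 1] == 0).all()
        np.testing.assert_array_equal(ad[:, :, 0], dp)

    def test_no_missing_when_rate_zero(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.5, size=(50, 20)).astype(float)
        g2, ad, dp = attach_read_evidence(g, 25, 0.0, np.array([], dtype=int), rng)
        assert np.isfinite(g2).all()
        assert (dp >= 1).all()

    def test_artifact_site_binomial_tail(self):
        # at depth 60 and minor fraction 0.15, a single het fails the 0.2
        # balance threshold with prob ~0.86; 30 carriers fail jointly w.p.
        # > 0.99 (independent binomial tail computation)
        p_single = sstats.binom.cdf(np.floor(60 / 6), 60, 0.15)
        assert 1 - (1 - p_single) ** 30 > 0.99

    def test_artifact_sites_skewed(self):
        rng = np.random.default_rng(2)
        g = np.ones((4, 200))  # all het
        _, ad, dp = attach_read_evidence(g, 60, 0.0, np.array([0, 1]), rng)
        frac_art = ad[:2, :, 1].sum() / dp[:2].sum()
        frac_clean = ad[2:, :, 1].sum() / dp[2:].sum()
        assert frac_art == pytest.approx(0.15, abs=0.02)
        assert frac_clean == pytest.approx(0.5, abs=0.02)

    def test_bad_depth_rejected(self):
        with pytest.raises(ValueError):
            attach_read_evidence(np.zeros((1, 1)), 0, 0.0, np.array([], dtype=int), np.random.default_rng(0))

    def test_missing_rate_applied(self):
        rng = np.random.default_rng(3)
        g = np.ones((200, 100))
        g2, ad, dp = attach_read_evidence(g, 30, 0.08, np.array([], dtype=int), rng)
        frac = np.isnan(g2).mean()
        assert frac == pytest.approx(0.08, abs=0.01)
        assert (ad[np.isnan(g2)] == -1).all()
        assert (dp[np.isnan(g2)] == -1).all()


class TestDeterminismAndOutputs:
    def test_identical_seed_byte_identical_vcf(self, tmp_path):
        d = design(missing_rate=0.05, seed=123)
        feats = [
            PlantedFeature(kind="sex_marker", params={"negative_pop": 1}),
            PlantedFeature(
                kind="artifact_site", chrom="chr1", start=99_000, end=99_000,
                params={"n_loci": 1},
            ),
        ]
        pa = write_cohort(simulate_cohort(d, feats), tmp_path / "a")
        pb = write_cohort(simulate_cohort(d, feats), tmp_path / "b")
        assert pa["vcf"].read_bytes() == pb["vcf"].read_bytes()
        assert pa["samples"].read_text() == pb["samples"].read_text()
        assert pa["truth"].read_text() == pb["truth"].read_text()

    def test_frequency_recovery_ci_coverage(self):
        d = design(pop_sizes=(80,), fst=(0.0,), n_loci=2000, seed=17)
        cohort = simulate_cohort(d)
        g = cohort.genotypes.values
        n2 = 2 * g.shape[1]
        p_hat = np.nansum(g, axis=1) / n2
        se = np.sqrt(cohort.ancestral_freqs * (1 - cohort.ancestral_freqs) / n2)
        inside = np.abs(p_hat - cohort.ancestral_freqs) <= 1.96 * se
        assert inside.mean() >= 0.90

    def test_sex_marker_negative_pop(self):
        d = design(seed=6)
        feat = PlantedFeature(kind="sex_marker", params={"carrier_sex": "M", "negative_pop": 1})
        cohort = simulate_cohort(d, [feat])
        males0 = (cohort.sex == "M") & (cohort.pop_labels == 0)
        males1 = (cohort.sex == "M") & (cohort.pop_labels == 1)
        assert cohort.sdy_present[males0].all()
        assert not cohort.sdy_present[males1].any()
        assert not cohort.sdy_present[cohort.sex == "F"].any()

    def test_sample_sheet_columns(self, tmp_path):
        d = design()
        paths = write_cohort(simulate_cohort(d), tmp_path / "c")
        header = paths["samples"].read_text().splitlines()[0].split("\t")
        assert header == ["sample_id", "pop_label", "admixture_weight", "sex", "sdY_present"]
        t_header = paths["truth"].read_text().splitlines()[0].split("\t")
        assert t_header == ["feature_kind", "chrom", "start", "end", "locus_indices"]
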