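import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import pearson_r2
from nerkascan.ld_stats import (
    LDPair,
    block_around_lead,
    chromosome_pairs,
    genotype_r2,
    longrange_track,
    pairwise_r2,
)
from nerkascan.synthetic_cohort import CohortDesign, PlantedFeature, simulate_cohort
from nerkascan.variant_io import DosageMatrix


def dosage_matrix(values, positions=None, chrom="chr1"):
    values = np.asarray(values, dtype=float)
    m = values.shape[0]
    pos = np.asarray(positions if positions is not None else np.arange(1, m + 1) * 100)
    return DosageMatrix(
        values=values,
        chrom=np.array([chrom] * m, dtype=object),
        pos=pos.astype(np.int64),
        samples=[f"S{i}" for i in range(values.shape[1])],
        source_rows=np.arange(m),
    )


class TestGenotypeR2:
    def test_identity(self):
        x = np.array([0, 1, 2, 1, 0], dtype=float)
        assert genotype_r2(x, x) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.array([0, 1, 2, 0, 2], dtype=float)
        assert genotype_r2(x, 2 - x) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # frozen from an independent Pearson computation: r2 = 8/11
        x = np.array([0, 0, 1, 2], dtype=float)
        y = np.array([0, 1, 1, 2], dtype=float)
        assert genotype_r2(x, y) == pytest.approx(8 / 11, abs=1e-12)
        assert genotype_r2(x, y) == pytest.approx(pearson_r2(x, y), abs=1e-12)

    def test_constant_vector_undefined(self):
        x = np.array([1, 1, 1, 1], dtype=float)
        y = np.array([0, 1, 2, 1], dtype=float)
        assert np.isnan(genotype_r2(x, y))

    def test_too_few_shared_calls(self):
        x = np.array([0, np.nan, np.nan, 2])
        y = np.array([0, 1, 2, 2], dtype=float)
        assert np.isnan(genotype_r2(x, y))

    def test_complete_case_matches_oracle_under_missingness(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            x = rng.binomial(2, 0.4, 30).astype(float)
            y = rng.binomial(2, 0.6, 30).astype(float)
            x[rng.random(30) < 0.2] = np.nan
            y[rng.random(30) < 0.2] = np.nan
            ours = genotype_r2(x, y)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or len(set(x[ok])) < 2 or len(set(y[ok])) < 2:
                assert np.isnan(ours)
            else:
                assert ours == pytest.approx(pearson_r2(x, y), abs=1e-10)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_relabel_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.binomial(2, 0.5, 20).astype(float)
        y = rng.binomial(2, 0.5, 20).astype(float)
        a = genotype_r2(x, y)
        b = genotype_r2(2 - x, y)
        c = genotype_r2(y, x)
        if np.isnan(a):
            assert np.isnan(b) and np.isnan(c)
        else:
            assert a == pytest.approx(b, abs=1e-12)
            assert a == pytest.approx(c, abs=1e-12)
            assert 0.0 <= a <= 1.0


class TestPairwiseMatrix:
    def test_matches_elementwise(self):
        rng = np.random.default_rng(9)
        vals = rng.binomial(2, 0.5, size=(12, 40)).astype(float)
        vals[rng.random(vals.shape) < 0.1] = np.nan
        mat = pairwise_r2(vals)
        for i in range(12):
            for j in range(12):
                elem = genotype_r2(vals[i], vals[j])
                if np.isnan(elem):
                    assert np.isnan(mat[i, j])
                else:
                    assert mat[i, j] == pytest.approx(elem, abs=1e-10)


class TestChromosomePairs:
    def test_haploblock_complete_subgraph(self):
        design = CohortDesign(
            pop_sizes=(30, 30), fst=(0.05, 0.05), n_loci=60,
            chrom_lengths=(2_000_000,), seed=5,
        )
        feat = PlantedFeature(
            kind="divergent_haploblock", chrom="chr1", start=500_000, end=600_000,
            params={"n_loci": 8, "pop_freqs": [0.5, 0.5]},
        )
        cohort = simulate_cohort(design, [feat])
        pairs = chromosome_pairs(cohort.genotypes, "chr1", min_r2=0.95)
        block = set(cohort.truth_log[0].tolist())
        got = {(p.idx_a, p.idx_b) for p in pairs}
        for a in block:
            for b in block:
                if a < b:
                    assert (a, b) in got or (b, a) in got

    def test_single_variant_chromosome_empty(self):
        d = dosage_matrix([[0, 1, 2, 1]])
        assert chromosome_pairs(d, "chr1") == []

    def test_unknown_chromosome(self):
        d = dosage_matrix([[0, 1, 2, 1]])
        with pytest.raises(KeyError):
            chromosome_pairs(d, "chr9")

    def test_null_pair_count_tiny(self):
        rng = np.random.default_rng(17)
        vals = rng.binomial(2, 0.5, size=(50, 100)).astype(float)
        pairs = chromosome_pairs(dosage_matrix(vals), "chr1", min_r2=0.5)
        # null r2 ~ chi2(1)/n: P(r2 >= 0.5 | n=100) is astronomically small
        assert len(pairs) == 0

    def test_ordering_invariant(self):
        rng = np.random.default_rng(2)
        vals = np.repeat(rng.binomial(2, 0.5, size=(1, 30)).astype(float), 3, axis=0)
        pairs = chromosome_pairs(dosage_matrix(vals, positions=[100, 50, 200]), "chr1")
        for p in pairs:
            assert p.pos_a <= p.pos_b


class TestBlockAroundLead:
    def test_members_match_brute_force(self):
        rng = np.random.default_rng(23)
        base = rng.binomial(2, 0.5, 50).astype(float)
        vals = []
        for _ in range(20):
            v = base.copy()
            flip = rng.random(50) < rng.uniform(0, 0.5)
            v[flip] = rng.binomial(2, 0.5, flip.sum())
            vals.append(v)
        d = dosage_matrix(np.array(vals))
        block = block_around_lead(d, lead_idx=0, min_r2=0.3)
        expected = {0}
        for i in range(1, 20):
            r2 = pearson_r2(d.values[0], d.values[i])
            if r2 >= 0.3:
                expected.add(i)
        assert set(block.member_idx) == expected

    def test_lead_without_partners(self):
        rng = np.random.default_rng(1)
        vals = np.array(
            [[0, 1, 2, 0, 1, 2, 0, 1], rng.permutation([0, 0, 1, 1, 2, 2, 0, 1])],
            dtype=float,
        )
        d = dosage_matrix(vals)
        block = block_around_lead(d, 0, min_r2=0.99)
        if len(block.member_idx) == 1:
            assert block.span_length == 0
            assert block.member_idx == (0,)

    def test_monomorphic_lead_rejected(self):
        d = dosage_matrix([[1, 1, 1, 1], [0, 1, 2, 0]])
        with pytest.raises(ValueError, match="monomorphic"):
            block_around_lead(d, 0)

    def test_block_covers_planted_span(self):
        design = CohortDesign(
            pop_sizes=(40, 40), fst=(0.03, 0.03), n_loci=150,
            chrom_lengths=(3_000_000,), seed=13,
        )
        feat = PlantedFeature(
            kind="divergent_haploblock", chrom="chr1", start=1_000_000, end=1_500_000,
            params={"n_loci": 12, "pop_freqs": [0.9, 0.1]},
        )
        cohort = simulate_cohort(design, [feat])
        lead = int(cohort.truth_log[0][5])
        block = block_around_lead(cohort.genotypes, lead, min_r2=0.3)
        lo, hi = block.span
        covered = min(hi, 1_500_000) - max(lo, 1_000_000)
        assert covered >= 0.9 * 500_000


class TestLongrangeTrack:
    def _pair(self, pos_a, pos_b, chrom="chr1"):
        return LDPair(chrom=chrom, idx_a=0, idx_b=1, pos_a=pos_a, pos_b=pos_b, r2=0.8)

    def test_no_distant_pairs_zero_track(self):
        t = longrange_track([self._pair(100, 50_000)], "chr1", 3_000_000)
        assert (t["count"] == 0).all()
        assert (t["log10_count"] == 0).all()

    def test_variants_counted_not_pairs(self):
        pairs = [
            self._pair(500_000, 1_500_000 + k * 200_000) for k in range(3)
        ]  # one focal variant, three distant partners in the next window
        t = longrange_track(pairs, "chr1", 2_000_000)
        assert t.loc[0, "count"] == 1  # window 1: only the focal variant
        assert t.loc[0, "log10_count"] == pytest.approx(np.log10(2))
        assert t.loc[1, "count"] == 3  # each partner counts in its own window

    def test_windows_tile_without_overlap(self):
        t = longrange_track([], "chr1", 3_456_789)
        assert list(t["start"]) == [1, 1_000_001, 2_000_001, 3_000_001]
        assert list(t["end"])[:3] == [1_000_000, 2_000_000, 3_000_000]
        assert t["end"].iloc[-1] == 3_456_789

    def test_planted_distant_blocks_elevate_their_windows(self):
        rng = np.random.default_rng(77)
        n = 60
        hap = rng.binomial(2, 0.5, n).astype(float)
        vals, pos = [], []
        # two co-inherited clusters 2 Mbp apart
        for k in range(5):
            vals.append(hap.copy())
            pos.append(200_000 + k * 10_000)
        for k in range(5):
            vals.append(hap.copy())
            pos.append(2_200_000 + k * 10_000)
        # independent background
        for k in range(10):
            vals.append(rng.binomial(2, 0.5, n).astype(float))
            pos.append(1_100_000 + k * 10_000)
        d = dosage_matrix(np.array(vals), positions=pos)
        pairs = chromosome_pairs(d, "chr1", min_r2=0.5)
        t = longrange_track(pairs, "chr1", 3_000_000)
        assert t.loc[0, "count"] == 5
        assert t.loc[2, "count"] == 5
        assert t.loc[1, "count"] == 0
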