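"""t-tests, sign counts, cross-sectional contrasts and phenotype
correlations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fclong.atlas import network_partition
from fclong.errors import DataError
from fclong.netblocks import ScanPair
from fclong.stats import (
    block_ttest,
    cross_sectional_compare,
    phenotype_correlation,
    sign_counts,
)
from fclong.synthetic import (
    PhenotypeSpec,
    SynthConfig,
    cross_sectional_config,
    generate_cross_sectional,
    generate_fc_cohort,
    generate_phenotypes,
)


class TestBlockTTest:
    def test_toy_vector_closed_form(self):
        # mean 3, sd sqrt(2.5): t = 3 / (sqrt(2.5)/sqrt(5)) = 3*sqrt(2)
        res = block_ttest([1, 2, 3, 4, 5], m_comparisons=105)
        assert res.t == pytest.approx(4.242640687119285, abs=1e-9)
        assert res.p_raw == pytest.approx(0.01323559956368269, abs=1e-9)
        assert res.p_bonf == 1.0

    def test_all_zero_changes(self):
        res = block_ttest([0.0, 0.0, 0.0])
        assert res.t == 0.0
        assert res.p_raw == 1.0

    def test_bonferroni_cap(self):
        # p_raw = 0.02 with 105 comparisons caps at 1
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(0.3, 1, 20)
            res = block_ttest(x, m_comparisons=105)
            assert res.p_bonf == min(1.0, 105 * res.p_raw)

    def test_zero_variance_nonzero_mean_degenerate(self):
        res = block_ttest([0.2, 0.2, 0.2])
        assert res.degenerate
        assert res.p_raw == 0.0

    def test_too_few_observations(self):
        with pytest.raises(DataError):
            block_ttest([1.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=30), st.integers(0, 10**6))
    def test_agrees_with_direct_formula(self, values, salt):
        x = np.asarray(values) + np.random.default_rng(salt).normal(0, 1e-3, len(values))
        n = len(x)
        sd = np.std(x, ddof=1)
        if sd < 1e-12:
            return
        t_direct = np.mean(x) / (sd / np.sqrt(n))
        p_direct = 2 * sps.t.sf(abs(t_direct), df=n - 1)
        res = block_ttest(x, m_comparisons=7)
        assert res.t == pytest.approx(t_direct, abs=1e-10)
        assert res.p_raw == pytest.approx(p_direct, abs=1e-10)
        assert res.p_bonf == pytest.approx(min(1.0, 7 * p_direct), abs=1e-10)


def _toy_cohort(changes, sexes, n_rois=4):
    """Pairs whose every edge changes by the given per-subject amount."""
    rng = np.random.default_rng(0)
    n_edges = n_rois * (n_rois - 1) // 2
    pairs = []
    for i, (c, sex) in enumerate(zip(changes, sexes)):
        base = rng.uniform(-0.5, 0.5, n_edges)
        pairs.append(ScanPair(subject_id=f"s{i}", younger=base,
                              older=base + c, n_rois=n_rois, sex=sex,
                              age=50.0))
    return pairs


class TestSignCounts:
    def test_counts_and_percentages(self, two_net_atlas):
        part = network_partition(two_net_atlas)
        pairs = _toy_cohort([0.1, -0.2, 0.3], ["male"] * 3)
        table = sign_counts(pairs, part, block=(0, 1))
        male = table.loc["male"]
        assert (male.block_pos, male.block_neg) == (2, 1)
        assert male.block_pos_pct == pytest.approx(100 * 2 / 3)
        assert male.total_pos == 2

    def test_exact_zeros_counted_separately(self, two_net_atlas):
        part = network_partition(two_net_atlas)
        pairs = _toy_cohort([0.0, 0.1, -0.1, 0.0], ["female"] * 4)
        row = sign_counts(pairs, part, block=(0, 1)).loc["female"]
        assert row.block_zero == 2
        assert row.block_pos + row.block_neg + row.block_zero == row.n

    def test_positive_fraction_matches_gaussian_orthant(self):
        # per-subject block change ~ N(0.03, ~0.114) puts the positive
        # fraction near Phi(0.03/0.114) ~ 0.604
        cfg = SynthConfig(n_subjects=2000, networks=(0, 6),
                          max_rois_per_network=8,
                          sex_probs={"male": 1.0})
        cohort = generate_fc_cohort(cfg, seed=21)
        row = sign_counts(cohort.pairs, cohort.partition, block=(0, 6)).loc["male"]
        frac = row.block_pos / row.n
        sd_change = np.hypot(0.11, 0.26 / np.sqrt(8 * 8))
        expected = sps.norm.cdf(0.03 / sd_change)
        se = np.sqrt(expected * (1 - expected) / 2000)
        assert frac == pytest.approx(expected, abs=3 * se)

    def test_zero_noise_positive_shift_all_positive(self):
        cfg = SynthConfig(n_subjects=30, networks=(0, 6),
                          max_rois_per_network=3,
                          edge_change_sd=0.0, subject_block_sd=0.0,
                          subject_baseline_sd=0.0, edge_baseline_sd=0.0,
                          shift_blocks={(0, 6): 0.03},
                          sex_probs={"male": 1.0})
        cohort = generate_fc_cohort(cfg, seed=2)
        row = sign_counts(cohort.pairs, cohort.partition, block=(0, 6)).loc["male"]
        assert row.block_pos == row.n


class TestCrossSectional:
    def test_identical_groups_zero_difference(self, two_net_atlas, rng):
        from fclong.netblocks import SingleScan

        part = network_partition(two_net_atlas)
        scans = [SingleScan(subject_id=f"s{i}", fc=rng.uniform(-1, 1, 6),
                            n_rois=4) for i in range(5)]
        mirrored = [SingleScan(subject_id=f"t{i}", fc=s.fc.copy(), n_rois=4)
                    for i, s in enumerate(scans)]
        summ = cross_sectional_compare(scans, mirrored, part)
        assert np.allclose(summ.table["diff"], 0.0, atol=1e-12)

    def test_small_group_rejected(self, two_net_atlas, rng):
        from fclong.netblocks import SingleScan

        part = network_partition(two_net_atlas)
        one = [SingleScan(subject_id="a", fc=rng.uniform(-1, 1, 6), n_rois=4)]
        with pytest.raises(DataError):
            cross_sectional_compare(one, one * 3, part)

    def test_negative_vis_effect_recovered_negative(self):
        cfg = cross_sectional_config("male", networks=(0, 6),
                                     max_rois_per_network=6,
                                     n_young=400, n_old=400)
        cohort = generate_cross_sectional(cfg, seed=17)
        young = [s for s in cohort.scans if s.age_group == "younger"]
        old = [s for s in cohort.scans if s.age_group == "older"]
        summ = cross_sectional_compare(young, old, cohort.partition)
        assert summ.table.loc["6-6", "diff"] < 0  # VIS-VIS ages downward

    def test_zero_age_effect_gives_zero_difference(self):
        cfg = SynthConfig(networks=(0, 6), max_rois_per_network=6,
                          n_young=500, n_old=500, age_effects={},
                          age_effect_default=0.0, shift_blocks={})
        cohort = generate_cross_sectional(cfg, seed=19)
        young = [s for s in cohort.scans if s.age_group == "younger"]
        old = [s for s in cohort.scans if s.age_group == "older"]
        summ = cross_sectional_compare(young, old, cohort.partition)
        tol = 2 * 0.082 * np.sqrt(2 / 500)  # 2 SE at subject sd 0.08
        assert np.all(np.abs(summ.table["diff"].drop("total")) < tol)


@pytest.fixture(scope="module")
def cohort():
    cfg = SynthConfig(n_subjects=2000, networks=(0, 6),
                      max_rois_per_network=5)
    return generate_fc_cohort(cfg, seed=23)


class TestPhenotypeCorrelation:

    def test_self_correlation_is_one(self, cohort):
        generate_phenotypes(cohort, [PhenotypeSpec("self", (0, 6), r=1.0)],
                            seed=0)
        res = phenotype_correlation(cohort.pairs, (0, 6), cohort.partition,
                                    "self")
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_independent_phenotype_null_bound(self, cohort):
        generate_phenotypes(cohort, [PhenotypeSpec("null", (0, 6), r=0.0)],
                            seed=1)
        res = phenotype_correlation(cohort.pairs, (0, 6), cohort.partition,
                                    "null")
        assert abs(res.r) < 3 / np.sqrt(res.n)

    def test_target_correlation_recovered(self, cohort):
        generate_phenotypes(cohort, [PhenotypeSpec("grip", (0, 6), r=0.1)],
                            seed=2)
        res = phenotype_correlation(cohort.pairs, (0, 6), cohort.partition,
                                    "grip")
        se = 1 / np.sqrt(res.n)
        assert res.r == pytest.approx(0.1, abs=2 * se)

    def test_missingness_pairwise_deleted(self, cohort):
        generate_phenotypes(
            cohort, [PhenotypeSpec("sparse", (0, 6), r=0.1,
                                   missing_rate=0.3)], seed=3)
        res = phenotype_correlation(cohort.pairs, (0, 6), cohort.partition,
                                    "sparse")
        assert res.n < len(cohort.pairs)
        assert np.isfinite(res.r)

    def test_constant_phenotype_flagged(self, cohort):
        for p in cohort.pairs:
            p.phenotypes["flat"] = 1.0
        res = phenotype_correlation(cohort.pairs, (0, 6), cohort.partition,
                                    "flat")
        assert res.degenerate
        assert np.isnan(res.r)

    def test_absent_phenotype_rejected(self, cohort):
        with pytest.raises(DataError):
            phenotype_correlation(cohort.pairs, (0, 6), cohort.partition,
                                  "missing_entirely")
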