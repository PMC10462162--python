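"""The calibrated cohort generators: reproducibility, invariants and
parameter recovery."""

import numpy as np
import pytest

from fclong.errors import ConfigError
from fclong.fc import bandpass, devectorize_fc, fc_from_timeseries, vectorize_fc
from fclong.atlas import network_partition
from fclong.netblocks import block_average, cohort_change_summary
from fclong.synthetic import (
    SynthConfig,
    generate_cross_sectional,
    generate_fc_cohort,
    generate_timeseries_cohort,
)


class TestReproducibility:
    def test_bit_for_bit_from_seed(self):
        cfg = SynthConfig(n_subjects=20, networks=(0, 6),
                          max_rois_per_network=4)
        a = generate_fc_cohort(cfg, seed=3)
        b = generate_fc_cohort(cfg, seed=3)
        for pa, pb in zip(a.pairs, b.pairs):
            assert np.array_equal(pa.younger, pb.younger)
            assert np.array_equal(pa.older, pb.older)
        assert [p.sex for p in a.pairs] == [p.sex for p in b.pairs]

    def test_different_seed_changes_realization(self):
        cfg = SynthConfig(n_subjects=10, networks=(0, 6),
                          max_rois_per_network=4)
        a = generate_fc_cohort(cfg, seed=3)
        b = generate_fc_cohort(cfg, seed=4)
        assert not np.array_equal(a.pairs[0].younger, b.pairs[0].younger)


class TestInvariants:
    def test_scans_are_valid_correlation_structures(self):
        cfg = SynthConfig(n_subjects=5, networks=(0, 6),
                          max_rois_per_network=5)
        cohort = generate_fc_cohort(cfg, seed=8)
        for pair in cohort.pairs:
            for vec in (pair.younger, pair.older):
                m = devectorize_fc(vec, pair.n_rois).values
                assert np.array_equal(m, m.T)
                assert np.all(np.diag(m) == 1.0)
                assert np.all((m >= -1.0) & (m <= 1.0))

    def test_psd_repair_yields_psd_matrices(self):
        cfg = SynthConfig(n_subjects=3, networks=(0, 6),
                          max_rois_per_network=5, psd_repair=True)
        cohort = generate_fc_cohort(cfg, seed=8)
        for pair in cohort.pairs:
            m = devectorize_fc(pair.younger, pair.n_rois).values
            assert np.linalg.eigvalsh(m).min() >= -1e-8

    def test_zero_noise_zero_shift_identical_scans(self):
        cfg = SynthConfig(n_subjects=4, networks=(0, 6),
                          max_rois_per_network=4, shift_blocks={},
                          edge_change_sd=0.0, subject_block_sd=0.0,
                          subject_baseline_sd=0.0, edge_baseline_sd=0.0)
        cohort = generate_fc_cohort(cfg, seed=0)
        for pair in cohort.pairs:
            assert np.array_equal(pair.younger, pair.older)

    def test_infeasible_dispersion_split_rejected(self):
        cfg = SynthConfig(edge_change_sd=0.05, subject_block_sd=0.11)
        with pytest.raises(ConfigError, match="edge_change_sd"):
            cfg.validate()

    def test_block_mean_outside_open_interval_rejected(self):
        cfg = SynthConfig(n_subjects=2, networks=(0, 6),
                          max_rois_per_network=3,
                          baseline_blocks={(0, 6): 1.0})
        with pytest.raises(ConfigError, match=r"\(-1, 1\)"):
            generate_fc_cohort(cfg, seed=0)


@pytest.fixture(scope="module")
def summary():
    cfg = SynthConfig(n_subjects=700, networks=(0, 6))
    cohort = generate_fc_cohort(cfg, seed=31)
    return cohort_change_summary(cohort.pairs, cohort.partition)


class TestCalibrationRecovery:
    """Moderate-n recovery; the full calibrated sizes run in the acceptance
    suite."""

    def test_mean_change_recovered(self, summary):
        tol = 2 * 0.111 / np.sqrt(700)
        assert summary.table.loc["0-6", "mu"] == pytest.approx(0.03, abs=tol)

    def test_edge_change_dispersion_recovered(self, summary):
        tol = 2 * 0.26 / np.sqrt(2 * 699)
        assert summary.table.loc["0-6", "sigma_edge"] == \
            pytest.approx(0.26, abs=tol)

    def test_baseline_and_shifted_block_means(self, summary):
        tol = 2 * 0.14 / np.sqrt(700)
        assert summary.table.loc["0-6", "mean_younger"] == \
            pytest.approx(0.39, abs=tol)
        assert summary.table.loc["0-6", "mean_older"] == \
            pytest.approx(0.42, abs=tol)


class TestCrossSectionalGenerator:
    def test_age_effect_applied_to_old_group_only(self):
        cfg = SynthConfig(networks=(0, 6), max_rois_per_network=6,
                          n_young=300, n_old=300,
                          age_effects={(0, 6): 0.05}, age_effect_default=0.0,
                          shift_blocks={})
        cohort = generate_cross_sectional(cfg, seed=5)
        part = cohort.partition
        young_means = np.mean([
            block_average(s.fc, part)[(0, 6)]
            for s in cohort.scans if s.age_group == "younger"])
        old_means = np.mean([
            block_average(s.fc, part)[(0, 6)]
            for s in cohort.scans if s.age_group == "older"])
        tol = 2 * 0.082 * np.sqrt(2 / 300)
        assert old_means - young_means == pytest.approx(0.05, abs=tol)


class TestTimeseriesGenerator:
    def test_two_network_toy_hits_target_correlation(self):
        cfg = SynthConfig(n_subjects=1, networks=(0, 6),
                          max_rois_per_network=3, frames=20_000,
                          baseline_blocks={(0, 6): 0.4}, shift_blocks={})
        pair = generate_timeseries_cohort(cfg, seed=4)[0]
        fc = fc_from_timeseries(pair.younger)
        part = network_partition(cfg.resolved_atlas())
        means = block_average(vectorize_fc(fc), part)
        assert means[(0, 6)] == pytest.approx(0.4, abs=0.02)

    def test_pipeline_recovers_block_structure_end_to_end(self):
        cfg = SynthConfig(n_subjects=2, networks=(0, 6),
                          max_rois_per_network=4, frames=4000)
        pairs = generate_timeseries_cohort(cfg, seed=9)
        part = network_partition(cfg.resolved_atlas())
        for pair in pairs:
            fc = fc_from_timeseries(bandpass(pair.younger))
            means = block_average(vectorize_fc(fc), part)
            # generous sampling tolerance at 4000 frames of band-limited
            # signal (effective dof is well below the frame count)
            assert means[(0, 6)] == pytest.approx(0.39, abs=0.1)
            assert means[(0, 0)] == pytest.approx(0.45, abs=0.1)

    def test_shift_appears_in_older_scan(self):
        # keep the shifted cross-block mean below the within-block mean so
        # the older target stays positive semidefinite
        cfg = SynthConfig(n_subjects=3, networks=(0, 6),
                          max_rois_per_network=3, frames=8000,
                          baseline_blocks={(0, 6): 0.1},
                          shift_blocks={(0, 6): 0.3})
        pairs = generate_timeseries_cohort(cfg, seed=10)
        part = network_partition(cfg.resolved_atlas())
        diffs = []
        for pair in pairs:
            fy = block_average(vectorize_fc(fc_from_timeseries(pair.younger)),
                               part)[(0, 6)]
            fo = block_average(vectorize_fc(fc_from_timeseries(pair.older)),
                               part)[(0, 6)]
            diffs.append(fo - fy)
        assert np.mean(diffs) == pytest.approx(0.3, abs=0.12)

    def test_infeasible_targets_rejected(self):
        # three mutually entangled networks: rho(A,B)=rho(A,C)=0.9 with
        # rho(B,C)=-0.9 is not positive semidefinite
        cfg = SynthConfig(n_subjects=1, networks=(0, 4, 6),
                          max_rois_per_network=1, frames=200,
                          baseline_blocks={(0, 4): 0.9, (0, 6): 0.9,
                                           (4, 6): -0.9},
                          shift_blocks={})
        with pytest.raises(ConfigError, match="not realizable"):
            generate_timeseries_cohort(cfg, seed=0)

    def test_too_few_frames_rejected(self):
        cfg = SynthConfig(n_subjects=1, networks=(0,),
                          max_rois_per_network=2, frames=50)
        with pytest.raises(ConfigError, match="frames"):
            generate_timeseries_cohort(cfg, seed=0)
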