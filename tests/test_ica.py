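import dataclasses

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from rsnvar.errors import ConfigurationError, ValidationError
from rsnvar.ica import (ComponentSet, assign_networks, classify_neuronal,
                        compute_fingerprint, decompose, fingerprints,
                        goodness_of_fit)
from rsnvar.parcellation import ParcellatedSeries
from rsnvar.synthetic import SimulationConfig, make_atlas, simulate_run


class TestDecompose:
    def test_recovers_noiseless_sources(self):
        # sparse membership keeps the planted maps near-orthogonal;
        # dense disjoint supports are negatively correlated and cap
        # what any ICA can recover
        cfg = SimulationConfig(n_regions=60, n_networks=3,
                               regions_per_network=5, snr=np.inf,
                               n_artifact_sources=0)
        atlas = make_atlas(cfg)
        series, truth = simulate_run(atlas, cfg, seed=2)
        comps = decompose(series, k=3, seed=0)
        # Hungarian pairing on |correlation| between true and found maps
        corr = np.abs(np.corrcoef(truth.true_zmaps, comps.zmaps)[:3, 3:])
        rows, cols = linear_sum_assignment(-corr)
        assert np.all(corr[rows, cols] > 0.95)

    def test_seed_determinism(self, clean_run):
        _, series, _ = clean_run
        a = decompose(series, k=12, seed=5)
        b = decompose(series, k=12, seed=5)
        assert np.array_equal(a.zmaps, b.zmaps)
        assert np.array_equal(a.timecourses, b.timecourses)

    def test_k_exceeding_timepoints_rejected(self, clean_run):
        _, series, _ = clean_run
        with pytest.raises(ConfigurationError):
            decompose(series, k=series.n_timepoints + 1, seed=0)

    def test_k_exceeding_regions_rejected(self, clean_run):
        _, series, _ = clean_run
        with pytest.raises(ConfigurationError):
            decompose(series, k=series.n_regions + 1, seed=0)

    def test_zmaps_standardized_and_sign_fixed(self, clean_run):
        from scipy.stats import skew
        _, series, _ = clean_run
        comps = decompose(series, k=12, seed=0)
        assert np.allclose(comps.zmaps.mean(axis=1), 0, atol=1e-10)
        assert np.allclose(comps.zmaps.std(axis=1), 1, atol=1e-10)
        assert np.all(skew(comps.zmaps, axis=1) >= -1e-12)


class TestFingerprint:
    def test_sinusoid_band_power(self, rng):
        t = np.arange(480)
        tc = np.sin(2 * np.pi * 0.03 * t)
        fp = compute_fingerprint(rng.normal(size=60), tc, tr=1.0)
        assert fp.band_power_3 > 0.9  # 0.02-0.05 Hz

    def test_white_noise_autocorrelation_small(self):
        r = np.random.default_rng(0)
        fp = compute_fingerprint(r.normal(size=60),
                                 r.normal(size=10_000), tr=1.0)
        assert abs(fp.one_lag_autocorr) < 0.05

    def test_symmetric_zmap_zero_skewness(self, rng):
        z = np.concatenate([np.arange(1, 31), -np.arange(1, 31)])
        fp = compute_fingerprint(z, rng.normal(size=200), tr=1.0)
        assert fp.spatial_skewness == pytest.approx(0.0, abs=1e-12)

    def test_band_powers_sum_below_one(self, clean_run):
        _, series, _ = clean_run
        comps = decompose(series, k=12, seed=0)
        for fp in fingerprints(comps):
            bands = [fp.band_power_1, fp.band_power_2, fp.band_power_3,
                     fp.band_power_4, fp.band_power_5]
            assert all(b >= 0 for b in bands)
            assert sum(bands) <= 1.0 + 1e-12

    def test_band_powers_scale_invariant(self, rng):
        z = rng.normal(size=60)
        tc = rng.normal(size=480)
        a = compute_fingerprint(z, tc, tr=1.0)
        b = compute_fingerprint(z, 7.5 * tc, tr=1.0)
        for name in ("band_power_1", "band_power_2", "band_power_3",
                     "band_power_4", "band_power_5", "one_lag_autocorr"):
            assert getattr(a, name) == pytest.approx(getattr(b, name))

    def test_constant_timecourse_degenerate(self, rng):
        fp = compute_fingerprint(rng.normal(size=60),
                                 np.full(100, 2.0), tr=1.0)
        assert fp.degenerate
        assert fp.band_power_1 == fp.band_power_5 == 0.0
        assert fp.one_lag_autocorr == 0.0


class TestClassifyNeuronal:
    def test_simulated_neuronal_source(self, clean_run, rng):
        _, _, truth = clean_run
        fp = compute_fingerprint(rng.normal(size=60),
                                 truth.source_timecourses[0], tr=1.0)
        flag, score = classify_neuronal(fp)
        assert flag and score > 0

    def test_high_frequency_artifact(self, clean_run, rng):
        _, _, truth = clean_run
        fp = compute_fingerprint(rng.normal(size=60),
                                 truth.source_timecourses[-1], tr=1.0)
        flag, score = classify_neuronal(fp)
        assert not flag and score < 0

    def test_pure_02hz_sine_non_neuronal(self, rng):
        t = np.arange(480)
        fp = compute_fingerprint(rng.normal(size=60),
                                 np.sin(2 * np.pi * 0.2 * t), tr=1.0)
        assert not classify_neuronal(fp)[0]

    def test_score_antisymmetric_under_band_swap(self, clean_run, rng):
        _, _, truth = clean_run
        fp = compute_fingerprint(rng.normal(size=60),
                                 truth.source_timecourses[0], tr=1.0)
        swapped = dataclasses.replace(
            fp, neuronal_band_power=fp.artifact_band_power,
            artifact_band_power=fp.neuronal_band_power)
        assert classify_neuronal(fp)[1] == pytest.approx(
            -classify_neuronal(swapped)[1])

    def test_degenerate_warns_non_neuronal(self, rng):
        fp = compute_fingerprint(rng.normal(size=60), np.zeros(100), tr=1.0)
        with pytest.warns(UserWarning, match="degenerate"):
            flag, score = classify_neuronal(fp)
        assert not flag


class TestGoodnessOfFit:
    def test_hand_arithmetic(self):
        z = np.array([2.0, 1.0, -1.0, -2.0])
        assert goodness_of_fit(z, np.array([0, 1])) == pytest.approx(3.0)

    def test_indicator_self_match_is_maximal(self, rng):
        n, size = 40, 8
        template = np.arange(size)
        z = np.zeros(n)
        z[template] = 1.0
        z = (z - z.mean()) / z.std()
        self_gof = goodness_of_fit(z, template)
        for _ in range(50):
            other = rng.choice(n, size=size, replace=False)
            assert goodness_of_fit(z, other) <= self_gof + 1e-12

    def test_independent_zmap_near_zero(self):
        r = np.random.default_rng(3)
        z = r.normal(size=20_000)
        g = goodness_of_fit(z, np.arange(10_000))
        assert abs(g) < 0.05

    def test_linear_and_shift_invariant(self, rng):
        z = rng.normal(size=30)
        idx = np.array([1, 4, 7])
        g = goodness_of_fit(z, idx)
        assert goodness_of_fit(2.5 * z, idx) == pytest.approx(2.5 * g)
        assert goodness_of_fit(z + 3.0, idx) == pytest.approx(g)

    def test_empty_and_full_templates_rejected(self, rng):
        z = rng.normal(size=10)
        with pytest.raises(ValidationError):
            goodness_of_fit(z, np.array([], dtype=int))
        with pytest.raises(ValidationError):
            goodness_of_fit(z, np.arange(10))


class TestAssignNetworks:
    def test_clean_simulation_assigns_all_networks(self, clean_run):
        atlas, series, truth = clean_run
        comps = decompose(series, k=12, seed=0)
        assignment = assign_networks(comps, atlas)
        assert set(assignment.assigned) == set(truth.network_names)
        assert not assignment.unassigned
        # each assigned component is the generating one
        for net, (c, _, _) in assignment.assigned.items():
            k = truth.network_names.index(net)
            r = abs(np.corrcoef(comps.zmaps[c],
                                truth.true_zmaps[k])[0, 1])
            assert r > 0.8

    def test_more_networks_than_components(self, atlas, rng):
        comps = ComponentSet(zmaps=rng.normal(size=(1, 60)),
                             timecourses=rng.normal(size=(1, 100)), tr=1.0)
        assignment = assign_networks(comps, atlas,
                                     neuronal_flags=[True],
                                     networks=["DMN", "salience"])
        assert len(assignment.assigned) == 1
        assert len(assignment.unassigned) == 1

    def test_exclusive_components(self, clean_run):
        atlas, series, _ = clean_run
        comps = decompose(series, k=12, seed=0)
        assignment = assign_networks(comps, atlas)
        used = [c for c, _, _ in assignment.assigned.values()]
        assert len(used) == len(set(used))

    def test_non_neuronal_flag_propagates(self, clean_run):
        atlas, series, _ = clean_run
        comps = decompose(series, k=12, seed=0)
        flags = [False] * comps.k
        assignment = assign_networks(comps, atlas, neuronal_flags=flags)
        assert all(not neuronal
                   for _, _, neuronal in assignment.assigned.values())
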