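"""Resampling, DFT amplitude spectra, ensemble averaging and the K-S distance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oscspec as osc
from oscspec.spectral import AverageSpectrum
from oscspec.ssa import Trajectory

from test_ssa import birth_death


def make_series(values, dt=1.0):
    values = np.asarray(values, dtype=float)
    return osc.SampledSeries(values, osc.SamplingConfig(len(values), dt))


def brute_force_dft(x):
    """Direct double-loop evaluation of the transform definition."""
    N = len(x)
    out = np.empty(N, dtype=complex)
    for w in range(N):
        acc = 0.0 + 0.0j
        for n in range(N):
            acc += x[n] * np.exp(-2j * np.pi * w * n / N)
        out[w] = acc
    return out


class TestSamplingConfig:
    def test_grid_arithmetic_identities(self):
        cfg = osc.SamplingConfig(N=4000, dt=1.0)
        assert cfg.resolution * cfg.N * cfg.dt == 1.0
        assert cfg.max_frequency * 2.0 * cfg.dt == 1.0
        assert cfg.window == 4000.0

    def test_degenerate_configs_rejected(self):
        with pytest.raises(ValueError):
            osc.SamplingConfig(N=1, dt=1.0)
        with pytest.raises(ValueError):
            osc.SamplingConfig(N=10, dt=0.0)


class TestResample:
    def traj(self, times, values):
        return Trajectory(np.asarray(times, float),
                          np.asarray(values, np.int64).reshape(-1, 1),
                          ["A"], seed=0)

    def test_last_value_before_each_grid_point(self):
        traj = self.traj([0.0, 1.4], [5, 6])
        s = osc.resample(traj, osc.SamplingConfig(3, 1.0), "A")
        assert s.values.tolist() == [5.0, 5.0, 6.0]

    def test_single_event_gives_constant_series(self):
        traj = self.traj([0.0], [7])
        s = osc.resample(traj, osc.SamplingConfig(5, 2.0), "A")
        assert s.values.tolist() == [7.0] * 5

    def test_early_termination_carries_last_value_forward(self):
        traj = self.traj([0.0, 1.0, 2.5], [3, 2, 0])
        s = osc.resample(traj, osc.SamplingConfig(6, 1.0), "A")
        assert s.values.tolist() == [3, 2, 2, 0, 0, 0]

    def test_initial_sample_equals_initial_value(self):
        traj = osc.simulate(birth_death(a0=42), osc.SimConfig(30.0, seed=1))
        s = osc.resample(traj, osc.SamplingConfig(30, 1.0), "A")
        assert s.values[0] == 42

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_naive_per_sample_scan(self, seed):
        rng = np.random.default_rng(seed)
        n_ev = int(rng.integers(1, 40))
        times = np.concatenate([[0.0], np.sort(rng.uniform(0, 20, n_ev))])
        values = rng.integers(0, 100, size=len(times))
        traj = self.traj(times, values)
        cfg = osc.SamplingConfig(int(rng.integers(2, 30)), float(rng.uniform(0.1, 2)))
        got = osc.resample(traj, cfg, "A").values
        for n in range(cfg.N):
            t_n = n * cfg.dt
            expected = values[np.nonzero(times <= t_n)[0][-1]]
            assert got[n] == expected


class TestAmplitudeSpectrum:
    def test_constant_series_is_pure_dc(self):
        spec = osc.amplitude_spectrum(make_series([3.0] * 16))
        assert spec.amplitudes[0] == pytest.approx(48.0)
        assert np.max(np.abs(spec.amplitudes[1:])) < 1e-9 * 16

    def test_cosine_concentrates_at_its_bin(self):
        N, k = 64, 5
        x = np.cos(2 * np.pi * k * np.arange(N) / N)
        spec = osc.amplitude_spectrum(make_series(x))
        assert spec.amplitudes[k] == pytest.approx(N / 2, rel=1e-9)
        others = np.delete(spec.amplitudes, k)
        assert np.max(others) < 1e-9 * N

    def test_one_sided_bin_count(self):
        for N in (8, 9):
            spec = osc.amplitude_spectrum(make_series(np.arange(N)))
            assert len(spec.amplitudes) == N // 2 + 1

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            osc.amplitude_spectrum(make_series([1.0, np.nan, 2.0]))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.integers(min_value=2, max_value=64))
    def test_fft_path_equals_direct_dft(self, seed, N):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 50, size=N).astype(float)
        direct = brute_force_dft(x)
        keep = N // 2 + 1
        series = make_series(x)
        amps = osc.amplitude_spectrum(series).amplitudes
        assert np.allclose(amps, np.abs(direct[:keep]), rtol=1e-9, atol=1e-9 * N)
        phases, defined = osc.phase_spectrum(series)
        expected = np.angle(direct[:keep])
        # compare as angles: +pi and -pi are the same phase
        wrapped = np.angle(np.exp(1j * (phases[defined] - expected[defined])))
        assert np.allclose(wrapped, 0.0, atol=1e-8)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.integers(min_value=2, max_value=64))
    def test_parseval(self, seed, N):
        rng = np.random.default_rng(seed)
        x = rng.normal(10, 3, size=N)
        amps = osc.amplitude_spectrum(make_series(x)).amplitudes
        # reconstruct the two-sided power from the one-sided bins
        power = amps[0] ** 2 + amps[-1] ** 2 if N % 2 == 0 else amps[0] ** 2
        inner = amps[1: (N + 1) // 2]
        power += 2 * np.sum(inner**2)
        assert power == pytest.approx(N * np.sum(x**2), rel=1e-9)


class TestPhaseSpectrum:
    def test_cosine_has_zero_phase_at_its_bin(self):
        N, k = 32, 3
        x = np.cos(2 * np.pi * k * np.arange(N) / N)
        phases, defined = osc.phase_spectrum(make_series(x))
        assert defined[k]
        assert phases[k] == pytest.approx(0.0, abs=1e-9)

    def test_sine_has_minus_half_pi_phase(self):
        N, k = 32, 3
        x = np.sin(2 * np.pi * k * np.arange(N) / N)
        phases, defined = osc.phase_spectrum(make_series(x))
        assert defined[k]
        assert phases[k] == pytest.approx(-np.pi / 2, abs=1e-9)
        assert not defined[k + 2]  # empty bin flagged undefined


class TestAverageSpectrum:
    def test_average_of_identical_spectra_is_that_spectrum(self):
        spec = osc.amplitude_spectrum(make_series([1, 5, 2, 8]))
        avg = osc.average_spectrum([spec] * 7)
        assert avg.K == 7
        assert np.allclose(avg.means, spec.amplitudes)

    def test_two_spectrum_mean(self):
        cfg = osc.SamplingConfig(2, 1.0)
        a = osc.AmplitudeSpectrum(np.array([0.0, 2.0]), cfg)
        b = osc.AmplitudeSpectrum(np.array([2.0, 0.0]), cfg)
        assert osc.average_spectrum([a, b]).means.tolist() == [1.0, 1.0]

    def test_incremental_equals_batch_mean(self):
        rng = np.random.default_rng(0)
        cfg = osc.SamplingConfig(64, 1.0)
        spectra = [
            osc.AmplitudeSpectrum(rng.uniform(0, 100, 33), cfg) for _ in range(100)
        ]
        inc = AverageSpectrum(cfg)
        for s in spectra:
            inc.add(s)
        batch = np.mean([s.amplitudes for s in spectra], axis=0)
        assert np.allclose(inc.means, batch, rtol=1e-12)

    def test_mismatched_grids_rejected(self):
        a = osc.AmplitudeSpectrum(np.zeros(3), osc.SamplingConfig(4, 1.0))
        avg = AverageSpectrum(osc.SamplingConfig(4, 2.0))
        with pytest.raises(ValueError, match="grid"):
            avg.add(a)


class TestKSDistance:
    def test_identical_spectra_give_zero(self):
        assert osc.ks_distance([1.0, 2.0, 3.0], [2.0, 4.0, 6.0]).D == 0.0

    def test_disjoint_support_gives_one(self):
        assert osc.ks_distance([1.0, 0.0], [0.0, 1.0]).D == 1.0

    def test_hand_enumerated_three_bin_case(self):
        res = osc.ks_distance([1.0, 1.0, 2.0], [2.0, 1.0, 1.0])
        assert res.D == pytest.approx(0.25)
        assert res.cdf_a.tolist() == [0.25, 0.5, 1.0]
        assert res.cdf_b.tolist() == [0.5, 0.75, 1.0]

    def test_all_zero_spectrum_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            osc.ks_distance([0.0, 0.0], [1.0, 1.0])

    def test_grid_mismatch_rejected(self):
        a = osc.AmplitudeSpectrum(np.ones(3), osc.SamplingConfig(4, 1.0))
        b = osc.AmplitudeSpectrum(np.ones(3), osc.SamplingConfig(4, 0.5))
        with pytest.raises(ValueError, match="grid"):
            osc.ks_distance(a, b)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_symmetry_bounds_and_self_distance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        a = rng.uniform(0, 10, n)
        b = rng.uniform(0, 10, n)
        a[rng.integers(0, n)] += 1e-6  # ensure positive mass
        b[rng.integers(0, n)] += 1e-6
        d_ab = osc.ks_distance(a, b).D
        d_ba = osc.ks_distance(b, a).D
        assert d_ab == d_ba
        assert 0.0 <= d_ab <= 1.0
        assert osc.ks_distance(a, a).D == 0.0


class TestConvergenceCov:
    def test_identical_spectra_have_zero_cov(self):
        spec = osc.amplitude_spectrum(make_series([1, 5, 2, 8]))
        avg = osc.average_spectrum([spec] * 5)
        cov, ok = osc.convergence_cov(avg)
        assert np.allclose(cov[avg.means > 0], 0.0)
        assert ok

    def test_two_value_hand_case(self):
        cfg = osc.SamplingConfig(2, 1.0)
        avg = AverageSpectrum(cfg)
        avg.add(osc.AmplitudeSpectrum(np.array([1.0, 1.0]), cfg))
        avg.add(osc.AmplitudeSpectrum(np.array([3.0, 1.0]), cfg))
        cov, _ = osc.convergence_cov(avg)
        # mean 2, sample std sqrt(2); CoV of the mean = (sqrt2/sqrt2)/2
        assert cov[0] == pytest.approx(0.5)

    def test_cov_shrinks_as_one_over_sqrt_k(self):
        """Median bin CoV follows K^(-1/2) on a stochastic ensemble."""
        net = birth_death(kb=50.0, kd=1.0, a0=50)
        sampling = osc.SamplingConfig(256, 1.0)
        ks, covs = [4, 8, 16, 32, 64], []
        avg = AverageSpectrum(sampling)
        runs = osc.iter_ensemble(net, osc.SimConfig(sampling.window), 64, 31)
        for i, traj in enumerate(runs, start=1):
            avg.add(osc.amplitude_spectrum(osc.resample(traj, sampling, "A")))
            if i in ks:
                cov, _ = osc.convergence_cov(avg)
                relevant = avg.means > 0.01 * avg.means.max()
                covs.append(np.median(cov[relevant]))
        slope = np.polyfit(np.log(ks), np.log(covs), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_requires_two_runs(self):
        avg = AverageSpectrum(osc.SamplingConfig(4, 1.0))
        avg.add(osc.amplitude_spectrum(make_series([1, 2, 3, 4])))
        with pytest.raises(ValueError, match="K >= 2"):
            osc.convergence_cov(avg)


class TestProcedures:
    sampling = osc.SamplingConfig(128, 1.0)

    def test_single_run_average_is_that_runs_spectrum(self):
        net = birth_death()
        avgs = osc.procedure_A(net, osc.SimConfig(self.sampling.window),
                               self.sampling, K=1, base_seed=3)
        traj = osc.simulate(net, osc.SimConfig(self.sampling.window,
                                               seed=osc.derive_seed(3, 0)))
        spec = osc.amplitude_spectrum(osc.resample(traj, self.sampling, "A"))
        assert np.allclose(avgs["A"].means, spec.amplitudes)

    def test_procedure_a_deterministic(self):
        net = birth_death()
        a = osc.procedure_A(net, osc.SimConfig(128.0), self.sampling, 3, 5)
        b = osc.procedure_A(net, osc.SimConfig(128.0), self.sampling, 3, 5)
        assert np.array_equal(a["A"].means, b["A"].means)

    def test_incremental_extension_matches_single_pass(self):
        net = birth_death()
        whole = osc.procedure_A(net, osc.SimConfig(128.0), self.sampling, 6, 5)
        part = osc.procedure_A(net, osc.SimConfig(128.0), self.sampling, 4, 5)
        part = osc.procedure_A(net, osc.SimConfig(128.0), self.sampling, 2, 5,
                               averages=part, start_run=4)
        assert np.allclose(whole["A"].means, part["A"].means, rtol=1e-12)

    def test_birth_death_spectrum_dc_dominant_and_flat_tail(self):
        net = birth_death()
        avgs = osc.procedure_A(net, osc.SimConfig(256.0),
                               osc.SamplingConfig(256, 1.0), K=20, base_seed=9)
        means = avgs["A"].means
        assert np.argmax(means) == 0  # DC dominates
        # above the relaxation frequency kd/(2 pi) ~ 0.16 the spectrum is flat:
        # band means differ by far less than the DC/band contrast
        freqs = avgs["A"].frequencies
        band1 = means[(freqs > 0.2) & (freqs <= 0.35)].mean()
        band2 = means[freqs > 0.35].mean()
        assert abs(band1 - band2) < 0.2 * means[0]
        assert band1 < 0.2 * means[0]

    def test_unknown_species_named(self):
        with pytest.raises(KeyError, match="bogus"):
            osc.procedure_A(birth_death(), osc.SimConfig(10.0), self.sampling,
                            1, 0, ["bogus"])

    def test_renamed_network_with_shared_seeds_has_zero_distance(self):
        net_a = birth_death()
        net_b = birth_death()
        net_b.species[0].name = "B"
        net_b.reactions[0].products = {"B": 1}
        net_b.reactions[1].reactants = {"B": 1}
        avg_a = osc.procedure_A(net_a, osc.SimConfig(128.0), self.sampling, 3, 7)
        avg_b = osc.procedure_A(net_b, osc.SimConfig(128.0), self.sampling, 3, 7)
        assert osc.ks_distance(avg_a["A"], avg_b["B"]).D == 0.0

    def test_missing_species_in_either_network_is_named(self):
        net_a, net_b = birth_death(), birth_death()
        net_b.species[0].name = "B"
        net_b.reactions[0].products = {"B": 1}
        net_b.reactions[1].reactants = {"B": 1}
        with pytest.raises(KeyError, match="A"):
            osc.procedure_B(net_a, net_b, osc.SimConfig(16.0), self.sampling,
                            K=1, species_list=["A"])


class TestAveragingRationale:
    """Why amplitudes are averaged: the time-domain mean destroys oscillation."""

    @staticmethod
    def peak_suppression_ratio(rng, N=512, k=37, K=50):
        """Ratio of the averaged-amplitude peak to the mean-trace peak.

        The mean of K randomly phased unit sinusoids has expected amplitude
        ~1/sqrt(K) (a Rayleigh resultant), so a single draw of this ratio
        scatters widely around sqrt(K).
        """
        cfg = osc.SamplingConfig(N, 1.0)
        n = np.arange(N)
        runs = [np.cos(2 * np.pi * k * n / N + rng.uniform(0, 2 * np.pi))
                for _ in range(K)]
        avg_amp = osc.average_spectrum(
            [osc.amplitude_spectrum(osc.SampledSeries(x, cfg)) for x in runs]
        )
        mean_trace_spec = osc.amplitude_spectrum(
            osc.SampledSeries(np.mean(runs, axis=0), cfg)
        )
        return avg_amp.means[1:].max() / mean_trace_spec.amplitudes[1:].max()

    def test_time_domain_average_loses_the_oscillatory_peak(self):
        # a single phase draw fluctuates (Rayleigh), so assert the typical
        # (median) suppression over independent draws
        rng = np.random.default_rng(2024)
        ratios = [self.peak_suppression_ratio(rng) for _ in range(11)]
        assert np.median(ratios) >= 5.0

    def test_ks_distance_between_the_two_summaries_is_large(self):
        # with the DC offset of a molecule-count signal the averaged-amplitude
        # summary keeps a large oscillatory mass fraction while the spectrum of
        # the time-domain mean concentrates at DC: the distributions disagree
        rng = np.random.default_rng(7)
        N, k, K = 512, 37, 50
        cfg = osc.SamplingConfig(N, 1.0)
        n = np.arange(N)
        runs = [1.0 + np.cos(2 * np.pi * k * n / N + rng.uniform(0, 2 * np.pi))
                for _ in range(K)]
        avg_amp = osc.average_spectrum(
            [osc.amplitude_spectrum(osc.SampledSeries(x, cfg)) for x in runs]
        )
        mean_trace_spec = osc.amplitude_spectrum(
            osc.SampledSeries(np.mean(runs, axis=0), cfg)
        )
        assert osc.ks_distance(avg_amp, mean_trace_spec).D > 0.3
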