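"""PSTHs, responsiveness criterion, evoked/volley rates, CV_isi."""

import numpy as np
import pytest

from cerebellopipe import (
    EphysSimConfig,
    SpikeTrain,
    StimProtocol,
    classify_unit,
    compute_psth,
    cv_isi,
    early_late_responses,
    evoked_delta_rate,
    gen_evoked_train,
    gen_protocol,
    is_responsive,
    mean_firing_rate,
    volley_delta_rate,
)
from cerebellopipe.responses import Psth

ALL_REGIONS = ("DN", "VAL", "CL", "M1", "DLS")


def naive_psth_counts(spike_times, onsets, edges):
    """Independent double-loop oracle: count (spike, event) pairs whose
    relative time falls in each half-open bin."""
    counts = np.zeros(len(edges) - 1, dtype=int)
    for onset in onsets:
        for t in spike_times:
            rel = t - onset
            for i in range(len(edges) - 1):
                if edges[i] <= rel < edges[i + 1]:
                    counts[i] += 1
    return counts


def make_psth(baseline_rates, stim_rates, n_events=100, bin_width=0.01):
    rates = np.concatenate([baseline_rates, stim_rates])
    counts = np.round(rates * n_events * bin_width).astype(int)
    n_base = len(baseline_rates)
    edges = np.arange(-n_base, len(stim_rates) + 1) * bin_width
    return Psth(edges, counts, n_events, bin_width, n_base)


class TestComputePsth:
    def test_empty_train_gives_zero_counts(self):
        train = SpikeTrain("u", "VAL", [], 0.0, 100.0)
        proto = gen_protocol("low_freq", 100.0)
        psth = compute_psth(train, proto)
        assert psth.counts.sum() == 0 and np.all(psth.rates == 0)

    def test_single_spike_lands_in_first_stim_bin(self):
        train = SpikeTrain("u", "VAL", [10.005], 0.0, 100.0)
        proto = StimProtocol([10.0], 0.1, "low_freq")
        psth = compute_psth(train, proto)
        assert psth.counts[psth.n_baseline_bins] == 1
        assert psth.counts.sum() == 1

    def test_mass_conservation_against_double_loop_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            n_spk = rng.integers(0, 60)
            times = np.unique(rng.uniform(0, 40, n_spk))
            train = SpikeTrain("u", "M1", times, 0.0, 40.0)
            onsets = np.arange(1.0, 37.0, 4.0)
            proto = StimProtocol(onsets, 0.1, "low_freq")
            psth = compute_psth(train, proto)
            expected = naive_psth_counts(times, onsets, psth.bin_edges)
            np.testing.assert_array_equal(psth.counts, expected)

    def test_poisson_rate_recovered_in_every_bin(self):
        duration = 4000.0
        proto = gen_protocol("low_freq", duration)  # 1000 events
        cfg = EphysSimConfig(baseline_rate={r: 20.0 for r in ALL_REGIONS},
                             evoked_delta={r: 0.0 for r in ALL_REGIONS},
                             seed=5)
        train, _ = gen_evoked_train(cfg, proto, "CL", duration)
        psth = compute_psth(train, proto)
        se = np.sqrt(20.0 / (proto.n_pulses * psth.bin_width))
        assert np.all(np.abs(psth.rates - 20.0) < 3 * se)

    def test_uneven_bin_width_warns(self):
        train = SpikeTrain("u", "VAL", [1.0], 0.0, 100.0)
        proto = StimProtocol([10.0], 0.1, "low_freq")
        with pytest.warns(UserWarning, match="truncated"):
            compute_psth(train, proto, bin_width=0.007)


class TestEvokedDeltaRate:
    def test_flat_psth_gives_zero(self):
        psth = make_psth([10.0] * 30, [10.0] * 10)
        assert evoked_delta_rate(psth) == 0.0

    def test_step_psth_gives_difference(self):
        psth = make_psth([10.0] * 30, [25.0] * 10)
        assert evoked_delta_rate(psth) == pytest.approx(15.0)

    def test_recovery_within_sampling_error(self):
        duration = 2000.0
        proto = gen_protocol("low_freq", duration)  # 500 events
        cfg = EphysSimConfig(
            response_latency={r: 0.0 for r in ALL_REGIONS},
            response_window={r: 0.100 for r in ALL_REGIONS},
            seed=21,
        )
        train, truth = gen_evoked_train(cfg, proto, "VAL", duration)
        est = evoked_delta_rate(compute_psth(train, proto))
        assert est == pytest.approx(truth["true_evoked_delta"], abs=1.5)


class TestIsResponsive:
    def test_all_zero_psth_not_responsive(self):
        psth = make_psth([0.0] * 30, [0.0] * 10)
        assert not is_responsive(psth)

    def test_degenerate_zero_sd_uses_mean_exceedance(self):
        psth = make_psth([10.0] * 30, [10.0] * 9 + [11.0])
        assert is_responsive(psth)
        psth_flat = make_psth([10.0] * 30, [10.0] * 10)
        assert not is_responsive(psth_flat)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(3)
        hits = []
        for k in (1.0, 2.0, 4.0, 8.0):
            n_hit = 0
            for s in range(200):
                counts = rng.poisson(5.0, 40)
                psth = Psth(np.arange(-30, 11) * 0.01, counts, 100, 0.01, 30)
                n_hit += is_responsive(psth, k=k)
            hits.append(n_hit)
        assert hits == sorted(hits, reverse=True)


class TestVolleyDeltaRate:
    def test_single_thalamic_spike_in_window(self):
        train = SpikeTrain("u", "VAL", [10.005], 0.0, 20.0)
        proto = StimProtocol([10.0], 0.1, "low_freq")
        assert volley_delta_rate(train, proto, "VAL") == pytest.approx(100.0)

    def test_spike_before_window_not_counted(self):
        train = SpikeTrain("u", "VAL", [10.002], 0.0, 20.0)
        proto = StimProtocol([10.0], 0.1, "low_freq")
        assert volley_delta_rate(train, proto, "VAL") == pytest.approx(0.0)

    def test_dn_window_recovery_from_simulation(self):
        duration = 2000.0
        proto = gen_protocol("low_freq", duration)
        cfg = EphysSimConfig(
            evoked_delta={r: 30.0 for r in ALL_REGIONS},
            response_latency={r: 0.0 for r in ALL_REGIONS},
            response_window={r: 0.010 for r in ALL_REGIONS},
            seed=8,
        )
        train, truth = gen_evoked_train(cfg, proto, "DN", duration)
        est = volley_delta_rate(train, proto, "DN")
        # SE of the 10 ms window rate at baseline 40 + delta 30 Hz
        se = np.sqrt(70.0 / (proto.n_pulses * 0.010))
        assert est == pytest.approx(truth["true_evoked_delta"], abs=3 * se)


class TestRateAndRegularity:
    def test_mean_rate_simple_count(self):
        times = np.arange(600) * 0.1 + 0.05
        train = SpikeTrain("u", "M1", times, 0.0, 60.0)
        assert mean_firing_rate(train) == pytest.approx(10.0)

    def test_empty_train_rate_zero(self):
        assert mean_firing_rate(SpikeTrain("u", "M1", [], 0.0, 60.0)) == 0.0

    def test_regular_train_cv_zero(self):
        times = np.arange(100) * 0.1 + 0.01
        train = SpikeTrain("u", "DN", times, 0.0, 20.0)
        assert cv_isi(train) == pytest.approx(0.0, abs=1e-12)

    def test_poisson_cv_near_one(self):
        rng = np.random.default_rng(17)
        isis = rng.exponential(0.1, 10_000)
        times = np.cumsum(isis)
        train = SpikeTrain("u", "DN", times, 0.0, times[-1] + 1)
        assert cv_isi(train) == pytest.approx(1.0, abs=0.03)

    def test_cv_scale_invariant(self):
        rng = np.random.default_rng(2)
        times = np.sort(rng.uniform(0, 10, 50))
        a = SpikeTrain("u", "DN", times, 0.0, 11.0)
        b = SpikeTrain("u", "DN", times * 2, 0.0, 22.0)
        assert cv_isi(a) == pytest.approx(cv_isi(b), abs=1e-12)

    def test_too_few_spikes_gives_nan(self):
        train = SpikeTrain("u", "DN", [1.0, 2.0], 0.0, 10.0)
        assert np.isnan(cv_isi(train))


class TestUnitClassification:
    @pytest.mark.parametrize("rate,label", [
        (5.9, "slow_spiking"),
        (6.0, "fast_spiking"),  # tie rule: >= threshold is fast
        (25.0, "fast_spiking"),
    ])
    def test_six_hz_threshold(self, rate, label):
        assert classify_unit(rate).label == label


class TestEarlyLate:
    def test_stationary_response_halves_agree(self):
        duration = 4000.0
        proto = gen_protocol("low_freq", duration)
        cfg = EphysSimConfig(seed=31)
        train, _ = gen_evoked_train(cfg, proto, "VAL", duration)
        early, late = early_late_responses(train, proto)
        # each half has 500 events; SE of the difference ~ 0.9 Hz
        assert early == pytest.approx(late, abs=3.0)

    def test_response_only_in_second_half(self):
        onsets = np.arange(10) * 4.0 + 2.0
        proto = StimProtocol(onsets, 0.1, "low_freq")
        spikes = np.sort(np.concatenate([
            onset + np.linspace(0.005, 0.095, 10)
            for onset in onsets[5:]
        ]))
        train = SpikeTrain("u", "M1", spikes, 0.0, 60.0)
        early, late = early_late_responses(train, proto)
        assert early == pytest.approx(0.0)
        # 50 spikes over 5 events x 0.1 s analysis window -> 100 Hz
        assert late == pytest.approx(100.0)

    def test_single_event_rejected(self):
        proto = StimProtocol([2.0], 0.1, "low_freq")
        train = SpikeTrain("u", "M1", [1.0], 0.0, 10.0)
        with pytest.raises(ValueError, match="2 events"):
            early_late_responses(train, proto)
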