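"""Synapses: kinetic waveforms, binomial release, replenishment, train statistics."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from piriform.morphology import discretize, generate_synthetic_morphology
from piriform.synapses import (
    EXC_TRAIN,
    PresynTrain,
    ReleaseState,
    TrainParams,
    ampa_spec,
    conductance_step,
    gaba_spec,
    generate_background,
    generate_train,
    nmda_spec,
    poisson_train,
    replenish,
    sample_release,
)
from piriform.morphology import DendriticLocation

LOC = DendriticLocation(0, 0.5)


class TestConductance:
    def test_no_events_no_conductance(self):
        assert conductance_step(ampa_spec(LOC), 1.0, []) == 0.0

    def test_ampa_single_exponential_decay(self):
        # one full release read one decay constant (1.5 ms) later
        spec = ampa_spec(LOC, g_unit=1.0)
        g = conductance_step(spec, 1.0, [1.5])
        assert g == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_nmda_waveform_peaks_near_7_6_ms(self):
        spec = nmda_spec(LOC, g_unit=2.0)
        t = np.linspace(0.0, 40.0, 8001)
        g = [conductance_step(spec, 1.0, [ti], Vm=0.0) for ti in t]
        t_peak = t[int(np.argmax(g))]
        # maximize exp(-t/80) - exp(-t/2): peak at (160/78)·ln(40) ≈ 7.57 ms
        assert t_peak == pytest.approx(7.57, abs=0.05)
        # normalized waveform: peak conductance equals g_unit times gating
        assert max(g) == pytest.approx(2.0 * 0.8, rel=1e-3)

    def test_superposition_of_release_events(self):
        spec = gaba_spec(LOC)
        both = conductance_step(spec, [1.0, 0.5], [10.0, 3.0])
        single_a = conductance_step(spec, 1.0, [10.0])
        single_b = conductance_step(spec, 0.5, [3.0])
        assert both == pytest.approx(single_a + single_b, rel=1e-12)

    def test_nmda_gating_multiplies_summed_conductance(self):
        spec = nmda_spec(LOC)
        g_rest = conductance_step(spec, 1.0, [7.57], Vm=-70.0)
        g_depol = conductance_step(spec, 1.0, [7.57], Vm=0.0)
        from piriform.biophysics import nmda_gating

        assert g_depol / g_rest == pytest.approx(
            float(nmda_gating(0.0) / nmda_gating(-70.0)), rel=1e-9
        )

    def test_invalid_kinetics_rejected(self):
        with pytest.raises(ValueError):
            # rise must stay below decay
            type(ampa_spec(LOC))("AMPA", 1.0, 5.0, 1.5, 0.0, LOC)


class TestRelease:
    def test_zero_probability_never_releases(self):
        rng = np.random.default_rng(0)
        state = ReleaseState(Pr=0.0)
        for _ in range(100):
            n, state = sample_release(state, rng)
            assert n == 0

    def test_release_matches_binomial_oracle(self):
        """Released counts from a full pool follow Binomial(5, 0.1)
        (chi-square goodness of fit over 20k draws)."""
        rng = np.random.default_rng(42)
        counts = np.zeros(6, dtype=int)
        for _ in range(20_000):
            n, _ = sample_release(ReleaseState(), rng)
            counts[n] += 1
        expected = sps.binom.pmf(np.arange(6), 5, 0.1) * 20_000
        keep = expected > 5
        chi2 = float(np.sum((counts[keep] - expected[keep]) ** 2 / expected[keep]))
        assert chi2 < sps.chi2.ppf(0.999, keep.sum() - 1)
        assert counts @ np.arange(6) / 20_000 == pytest.approx(0.5, abs=0.02)

    def test_probability_of_any_release(self):
        rng = np.random.default_rng(1)
        hits = sum(
            sample_release(ReleaseState(), rng)[0] > 0 for _ in range(20_000)
        )
        assert hits / 20_000 == pytest.approx(1 - 0.9**5, abs=0.01)

    def test_depletion_decrements_pool(self):
        rng = np.random.default_rng(3)
        state = ReleaseState(Pr=1.0)
        n, state = sample_release(state, rng)
        assert n == 5 and state.available == 0

    def test_full_pool_with_pr_one_releases_everything_each_spike(self):
        rng = np.random.default_rng(4)
        state = ReleaseState(Pr=1.0, replenish_rate=1e6)
        for _ in range(5):
            n, state = sample_release(state, rng)
            assert n == state.n_slots
            state = replenish(state, 1.0, rng)


class TestReplenish:
    def test_full_pool_unchanged(self):
        rng = np.random.default_rng(0)
        state = ReleaseState()
        assert replenish(state, 10.0, rng) == state

    def test_refill_probability_matches_exponential(self):
        # one empty slot, 100 s⁻¹, 10 ms → P(refill) = 1 − e⁻¹
        rng = np.random.default_rng(5)
        refills = 0
        for _ in range(20_000):
            st = ReleaseState(available=4)
            st = replenish(st, 10.0, rng)
            refills += st.available == 5
        assert refills / 20_000 == pytest.approx(1 - math.exp(-1), abs=0.01)

    def test_zero_rate_never_refills(self):
        rng = np.random.default_rng(6)
        st = ReleaseState(available=0, replenish_rate=0.0)
        assert replenish(st, 1e6, rng).available == 0


class TestTrains:
    def test_zero_count_gives_empty_train(self):
        t = generate_train(TrainParams(count_mean=0.0, count_sd=0.0), seed=0)
        assert t.times == ()

    def test_fixed_seed_reproducible(self):
        a = generate_train(EXC_TRAIN, seed=11)
        b = generate_train(EXC_TRAIN, seed=11)
        assert a.times == b.times

    def test_excitatory_statistics_over_many_trains(self):
        """10⁴ excitatory trains: start ≈ 100 ms, count ≈ 5, ISI slightly
        above 8 ms (the 0.1 ms floor biases it upward)."""
        rng = np.random.default_rng(123)
        starts, counts, isis = [], [], []
        for _ in range(10_000):
            t = generate_train(EXC_TRAIN, rng)
            counts.append(len(t.times))
            if t.times:
                starts.append(t.times[0])
            if len(t.times) > 1:
                isis.extend(np.diff(t.times))
        assert np.mean(counts) == pytest.approx(5.0, abs=0.15)
        assert np.mean(starts) == pytest.approx(100.0, abs=0.3)
        assert 8.0 < np.mean(isis) < 9.5

    def test_times_strictly_increasing(self):
        for seed in range(50):
            t = generate_train(EXC_TRAIN, seed=seed)
            assert all(a < b for a, b in zip(t.times, t.times[1:]))

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            generate_train(TrainParams(isi_sd=-1.0), seed=0)


@pytest.fixture(scope="module")
def grid():
    return discretize(generate_synthetic_morphology(seed=1))


class TestBackground:
    def test_population_size_and_kinds(self, grid):
        pairs = generate_background(grid, seed=0)
        assert len(pairs) == 120
        kinds = [spec.kind for spec, _ in pairs]
        assert kinds.count("AMPA") == 100  # excitatory background is AMPA-only
        assert kinds.count("GABA_A") == 20

    def test_poisson_rate(self, grid):
        rng = np.random.default_rng(9)
        n = [len(poisson_train(10.0, 1000.0, rng).times) for _ in range(10_000)]
        assert np.mean(n) == pytest.approx(10.0, abs=0.1)

    def test_zero_rate_empty(self, grid):
        pairs = generate_background(grid, rate_hz=0.0, seed=0)
        assert all(len(t.times) == 0 for _, t in pairs)

    def test_unique_per_seed(self, grid):
        a = generate_background(grid, seed=1)
        b = generate_background(grid, seed=2)
        assert any(
            ta.times != tb.times for (_, ta), (_, tb) in zip(a, b)
        )
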