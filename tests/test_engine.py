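"""Integration engine against analytic cable/RC oracles and a dense solver."""

import math

import numpy as np
import pytest

from piriform.biophysics import ChannelSet, PassiveParams
from piriform.engine import (
    CompartmentalSystem,
    CurrentInjection,
    Synapse,
    VoltageClamp,
    integrate,
    voltage_clamp,
)
from piriform.morphology import (
    DendriticLocation,
    Morphology,
    Section,
    discretize,
    generate_synthetic_morphology,
)
from piriform.synapses import PresynTrain, ampa_spec, nmda_spec

E_REST = -70.0


def passive_system(morph, max_seg=4.6, **kw):
    return CompartmentalSystem(
        grid=discretize(morph, max_seg), channels=ChannelSet.passive(), **kw
    )


def soma_only(area=829.0):
    return Morphology((), soma_area=area)


def cable(length=1000.0, diam=1.0, soma_area=1e-3):
    """Uniform cable with a massless soma node at x = 0 (sealed end)."""
    return Morphology((Section(0, -1, length, diam, diam, 0, 0),), soma_area=soma_area)


class TestEquilibriumAndDeterminism:
    def test_passive_system_stays_at_rest(self):
        sys0 = passive_system(generate_synthetic_morphology(seed=1))
        r = integrate(sys0, 500.0)
        assert np.max(np.abs(r.v("soma") - E_REST)) < 1e-6

    def test_same_seed_bit_reproducible(self):
        m = generate_synthetic_morphology(seed=1)
        loc = DendriticLocation(m.terminal_sections()[0], 0.5)
        syn = Synapse(
            (ampa_spec(loc), nmda_spec(loc)),
            PresynTrain((20.0, 40.0, 60.0)),
        )
        sys0 = passive_system(m, synapses=(syn,))
        a = integrate(sys0, 150.0, seed=9)
        b = integrate(sys0, 150.0, seed=9)
        assert np.array_equal(a.v("soma"), b.v("soma"))
        assert np.array_equal(a.released, b.released)

    def test_invalid_dt_rejected(self):
        sys0 = passive_system(soma_only())
        with pytest.raises(ValueError):
            integrate(sys0, 10.0, dt=0.5)


class TestRCOracle:
    """Isolated soma under a current step follows V = I·R·(1 − e^(−t/τ))."""

    def run_step(self, dt):
        inj = CurrentInjection(None, 0.05, 10.0, 900.0)  # 50 pA
        sys0 = passive_system(soma_only(), injection=inj)
        return integrate(sys0, 400.0, dt=dt)

    def test_steady_state_and_tau_within_1pct(self):
        r = self.run_step(0.025)
        area_cm2 = 829e-8
        R = 25_000.0 / area_cm2  # Ω
        dv_inf = 0.05e-9 * R * 1e3  # mV
        v = r.v("soma")
        t = r.t
        sim_inf = v[-1] - E_REST
        assert sim_inf == pytest.approx(dv_inf, rel=0.01)
        # analytic curve comparison over the charging phase
        mask = (t >= 10.0) & (t <= 150.0)
        pred = dv_inf * (1.0 - np.exp(-(t[mask] - 10.0) / 25.0))
        err = np.max(np.abs((v[mask] - E_REST) - pred))
        assert err < 0.01 * dv_inf

    def test_backward_euler_first_order_convergence(self):
        """Halving dt roughly halves the error against the analytic curve."""
        errs = []
        for dt in (0.1, 0.05):
            r = self.run_step(dt)
            area_cm2 = 829e-8
            dv_inf = 0.05e-9 * (25_000.0 / area_cm2) * 1e3
            mask = (r.t >= 10.0) & (r.t <= 120.0)
            pred = dv_inf * (1.0 - np.exp(-(r.t[mask] - 10.0) / 25.0))
            errs.append(np.max(np.abs((r.v("soma")[mask] - E_REST) - pred)))
        assert 1.6 < errs[0] / errs[1] < 2.5


class TestCableOracle:
    def test_steady_attenuation_matches_cosh(self):
        """Steady distal current into a sealed cable: V(x) ∝ cosh(x/λ), so
        the end-to-end attenuation is 1/cosh(L/λ) (within 1%)."""
        L, d = 1000.0, 1.0
        m = cable(L, d)
        inj = CurrentInjection(DendriticLocation(0, 1.0), 0.01, 5.0, 5000.0)
        sys0 = passive_system(m, max_seg=2.0, injection=inj)
        r = integrate(
            sys0, 1500.0, record={"tip": DendriticLocation(0, 1.0)}
        )
        lam = math.sqrt((d * 1e-4 / 4.0) * (25_000.0 / 100.0)) * 1e4  # µm
        ratio_pred = 1.0 / math.cosh(L / lam)
        v_tip = r.traces["tip"][-1] - E_REST
        v_end = r.v("soma")[-1] - E_REST
        assert v_end / v_tip == pytest.approx(ratio_pred, rel=0.01)


class TestSolverExactness:
    def test_single_step_matches_dense_solve(self):
        """One backward-Euler step on a random passive tree equals the dense
        linear-algebra solution of the same system."""
        secs = [
            Section(0, -1, 60.0, 2.0, 1.5, 0, 0),
            Section(1, 0, 40.0, 1.5, 1.0, 1, 0),
            Section(2, 0, 50.0, 1.5, 0.8, 1, 0),
            Section(3, 1, 30.0, 1.0, 0.7, 2, 0),
        ]
        m = Morphology(tuple(secs), soma_area=829.0)
        inj = CurrentInjection(DendriticLocation(3, 1.0), 0.1, 0.0, 1.0)
        sys0 = passive_system(m, max_seg=10.0, injection=inj)
        dt = 0.025
        r = integrate(sys0, dt, dt=dt, record={
            f"c{i}": DendriticLocation(s.index, 0.99) for i, s in enumerate(secs)
        })

        from piriform.engine import _passive_arrays

        parent, g_ax, cap, g_leak = _passive_arrays(sys0)
        n = len(cap)
        A = np.zeros((n, n))
        rhs = cap / dt * E_REST + g_leak * E_REST
        np.fill_diagonal(A, cap / dt + g_leak)
        for i in range(1, n):
            A[i, i] += g_ax[i]
            A[parent[i], parent[i]] += g_ax[i]
            A[i, parent[i]] -= g_ax[i]
            A[parent[i], i] -= g_ax[i]
        inj_comp = sys0.comp_of(DendriticLocation(3, 1.0))
        rhs[inj_comp] += 0.1
        v_dense = np.linalg.solve(A, rhs)
        for i, s in enumerate(secs):
            comp = sys0.comp_of(DendriticLocation(s.index, 0.99))
            assert r.traces[f"c{i}"][-1] == pytest.approx(v_dense[comp], abs=1e-10)

    def test_charge_conservation_at_steady_state(self):
        """At steady state every compartment's axial inflow plus injection
        balances its leak current (relative residual < 1e-9)."""
        secs = [
            Section(0, -1, 80.0, 2.0, 1.5, 0, 0),
            Section(1, 0, 60.0, 1.5, 1.0, 1, 0),
            Section(2, 0, 60.0, 1.5, 1.0, 1, 0),
        ]
        m = Morphology(tuple(secs), soma_area=829.0)
        inj_loc = DendriticLocation(1, 1.0)
        sys0 = passive_system(
            m, max_seg=10.0,
            injection=CurrentInjection(inj_loc, 0.05, 0.0, 5000.0),
        )
        grid = sys0.grid
        rec = {f"c{i}": None for i in range(grid.n_comp)}
        rec_locs = {}
        for i, c in enumerate(grid.compartments):
            if c.section < 0:
                rec_locs[f"c{i}"] = None
            else:
                rec_locs[f"c{i}"] = DendriticLocation(c.section, c.arc_mid)
        r = integrate(sys0, 1200.0, record=rec_locs)
        v = np.array([r.traces[f"c{i}"][-1] for i in range(grid.n_comp)])

        from piriform.engine import _passive_arrays

        parent, g_ax, cap, g_leak = _passive_arrays(sys0)
        inj_comp = sys0.comp_of(inj_loc)
        residual = -g_leak * (v - E_REST)
        residual[inj_comp] += 0.05
        for i in range(1, len(v)):
            flow = g_ax[i] * (v[parent[i]] - v[i])
            residual[i] += flow
            residual[parent[i]] -= flow
        assert np.max(np.abs(residual)) < 1e-9 * 0.05


class TestVoltageClamp:
    def test_clamp_at_rest_without_synapses_holds_zero_current(self):
        sys0 = passive_system(generate_synthetic_morphology(seed=1))
        r = voltage_clamp(sys0, None, E_REST, 100.0)
        assert np.max(np.abs(r.clamp_current_pA)) < 0.5  # pA

    def test_clamp_at_reversal_nulls_synaptic_current(self):
        """An AMPA synapse at the clamped compartment contributes no current
        when the holding potential equals its reversal potential."""
        m = cable(100.0, 1.0, soma_area=829.0)
        loc = DendriticLocation(0, 0.0)
        syn = Synapse(
            (ampa_spec(loc),), PresynTrain((20.0,)), deterministic=True
        )
        sys0 = passive_system(m, synapses=(syn,))
        r = voltage_clamp(sys0, loc, 0.0, 60.0)
        i = r.clamp_current_pA
        # subtract the large holding current; the synapse adds nothing
        hold = np.median(i[: int(15 / r.dt)])
        assert np.max(np.abs(i[int(19 / r.dt):] - hold)) < 1.0

    def test_distal_synapse_epsc_is_inward(self):
        m = generate_synthetic_morphology(seed=1)
        t = m.terminal_sections()[0]
        loc = DendriticLocation(t, 0.8)
        syn = Synapse(
            (ampa_spec(loc), nmda_spec(loc)), PresynTrain((20.0,)),
            deterministic=True,
        )
        sys0 = passive_system(m, synapses=(syn,))
        r = voltage_clamp(sys0, None, E_REST, 80.0)
        i = r.clamp_current_pA - np.median(r.clamp_current_pA[: int(18 / r.dt)])
        assert i.min() < -3.0  # inward current reported negative


class TestSelfConvergence:
    def test_dt_halving_changes_peak_by_less_than_half_percent(self):
        """Standard stimulus (calibrated burst at a distal site): somatic
        peak at dt = 0.025 and 0.0125 ms agrees within 0.5%."""
        m = generate_synthetic_morphology(seed=1)
        t = m.terminal_sections()[0]
        loc = DendriticLocation(t, 0.7)
        syns = tuple(
            Synapse(
                (ampa_spec(loc), nmda_spec(loc)),
                PresynTrain((50.0, 70.0, 90.0)),
                scale=4.0,
                deterministic=True,
            )
            for _ in range(4)
        )
        peaks = []
        for dt in (0.025, 0.0125):
            sys0 = passive_system(m, synapses=syns)
            r = integrate(sys0, 250.0, dt=dt)
            peaks.append(float(np.max(r.v("soma")) - E_REST))
        assert abs(peaks[0] - peaks[1]) / peaks[1] < 0.005


class TestSpikingAndAdaptation:
    def test_somatic_step_evokes_adapting_spike_train(self):
        """With the full channel set a suprarheobase somatic step produces
        repetitive firing whose inter-spike intervals lengthen (gKs)."""
        m = generate_synthetic_morphology(seed=1)
        sys0 = CompartmentalSystem(
            grid=discretize(m),
            injection=CurrentInjection(None, 0.4, 50.0, 550.0),
        )
        r = integrate(sys0, 600.0)
        v = r.v("soma")
        crossings = np.flatnonzero((v[:-1] < 0.0) & (v[1:] >= 0.0))
        assert len(crossings) >= 5
        isis = np.diff(crossings) * r.dt
        # steady lengthening after the onset transient
        assert isis[-1] > isis[1]
        assert np.all(np.diff(isis[1:]) > -0.5)

    def test_subthreshold_step_does_not_fire(self):
        m = generate_synthetic_morphology(seed=1)
        sys0 = CompartmentalSystem(
            grid=discretize(m),
            injection=CurrentInjection(None, 0.02, 50.0, 550.0),
        )
        r = integrate(sys0, 600.0)
        assert np.max(r.v("soma")) < 0.0


class TestTraceExport:
    def test_hdf5_and_csv_round_trip(self, tmp_path):
        import h5py
        import pandas as pd

        sys0 = passive_system(generate_synthetic_morphology(seed=1))
        r = integrate(sys0, 20.0, seed=4)
        h5 = tmp_path / "run.h5"
        r.to_hdf5(str(h5))
        with h5py.File(h5) as fh:
            assert np.allclose(fh["voltage_mV/soma"][...], r.v("soma"))
            assert fh.attrs["seed"] == 4
        csv = tmp_path / "run.csv"
        r.to_csv(str(csv))
        df = pd.read_csv(csv)
        assert np.allclose(df["v_soma_mV"].to_numpy(), r.v("soma"))
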