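import math

import numpy as np
import pytest

from thetalock.cell_model import (
    E_PAS,
    N_STATE_EQUATIONS,
    SimulationDiverged,
    build_cell,
    detect_spikes,
    effective_conductance,
    integrate,
    ionic_current,
)
from thetalock.morphology import Compartment, Morphology


@pytest.fixture(scope="module")
def tiny_cell(tiny_morph):
    return build_cell(tiny_morph)


def single_compartment():
    return Morphology([Compartment(0, -1, "soma", 20.0, 20.0, 0.0)])


class TestScalarOps:
    @pytest.mark.parametrize("gmax,factor,expected", [
        (0.05, 1.0, 0.05), (1.0, 0.0, 0.0), (0.02, 2.5, 0.05),
    ])
    def test_effective_conductance(self, gmax, factor, expected):
        assert effective_conductance(gmax, factor) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            effective_conductance(-1.0, 1.0)
        with pytest.raises(ValueError):
            ionic_current(-0.1, 0.0, 0.0)

    @pytest.mark.parametrize("g,v,vrev,expected", [
        (0.3, -77.0, -77.0, 0.0),
        (0.0, 30.0, -77.0, 0.0),
        (0.01, -50.0, -77.0, 0.27),
    ])
    def test_ionic_current(self, g, v, vrev, expected):
        assert ionic_current(g, v, vrev) == pytest.approx(expected)

    def test_outward_positive_above_reversal(self):
        assert ionic_current(1.0, -50.0, -90.0) > 0
        assert ionic_current(1.0, -50.0, 0.0) < 0


class TestStructure:
    def test_state_equations_per_compartment(self):
        # membrane potential + calcium pool + 16 gating variables
        assert N_STATE_EQUATIONS == 18

    def test_topological_order(self, tiny_cell):
        assert tiny_cell.parent[0] == -1
        assert all(tiny_cell.parent[1:] < np.arange(1, tiny_cell.n))


class TestPassive:
    def test_relaxes_to_leak_reversal(self, tiny_cell):
        tr = integrate(tiny_cell, duration=3000.0, dt=0.05, passive_only=True,
                       detect=False)
        for label in tr.v:
            assert tr.v[label][-1] == pytest.approx(E_PAS, abs=0.05)

    def test_single_compartment_rc_step_response(self):
        cell = build_cell(single_compartment())
        tau = cell.cm[0] / cell.gpas[0]  # ms
        amp = -0.01  # nA
        tr = integrate(cell, duration=6000.0, dt=0.05, passive_only=True,
                       detect=False, record=("soma",),
                       current_steps=[(0, amp, 1000.0, 6000.0)])
        v = tr.v["soma"]
        dv_inf = amp * 1e-3 / (cell.gpas[0] * 1e-3 * cell.area[0]) * 1e-3  # mV
        v_end = v[-1]
        assert v_end - E_PAS == pytest.approx(dv_inf, rel=0.01)
        # voltage at one time constant after onset: 63.2% of the step
        i_tau = int((1000.0 + tau) / 0.05)
        frac = (v[i_tau] - E_PAS) / dv_inf
        assert frac == pytest.approx(1.0 - math.exp(-1.0), rel=0.01)

    def test_charge_conservation_brief_pulse(self):
        # with leak nearly frozen, injected charge maps to C * dV
        cell = build_cell(single_compartment())
        amp, width = 0.05, 5.0  # nA, ms
        tr = integrate(cell, duration=30.0, dt=0.01, passive_only=True,
                       detect=False, record=("soma",), v_init=E_PAS,
                       current_steps=[(0, amp, 10.0, 10.0 + width)])
        dv = tr.v["soma"][int(15.2 / 0.01)] - tr.v["soma"][0]
        q = amp * 1e-9 * width * 1e-3  # C
        c = cell.cm[0] * 1e-6 * cell.area[0]  # F
        # leak bleeds a little charge during the pulse (tau >> width)
        assert dv == pytest.approx(q / c * 1e3, rel=0.05)


class TestActive:
    def test_spike_at_suprarheobase(self, tiny_cell):
        # brute-force rheobase sweep, then 1.5x must spike
        rheo = None
        for amp in np.arange(0.005, 0.2, 0.005):
            tr = integrate(tiny_cell, duration=600.0, dt=0.05,
                           current_steps=[(tiny_cell.soma_idx, amp, 100.0, 500.0)])
            if tr.spike_times.size > 0:
                rheo = amp
                break
        assert rheo is not None
        tr = integrate(tiny_cell, duration=600.0, dt=0.05,
                       current_steps=[(tiny_cell.soma_idx, 1.5 * rheo, 100.0, 500.0)])
        assert tr.spike_times.size >= 1

    def test_spike_count_monotone_below_block(self, default_morph):
        cell = build_cell(default_morph)
        counts = []
        # sweep below the depolarization-block regime
        for amp in (0.25, 0.3, 0.4, 0.5):
            tr = integrate(cell, duration=600.0, dt=0.05,
                           current_steps=[(cell.soma_idx, amp, 100.0, 500.0)])
            counts.append(tr.spike_times.size)
        assert counts == sorted(counts)
        assert counts[-1] > 0

    def test_dt_convergence(self, tiny_cell):
        v1 = integrate(tiny_cell, duration=200.0, dt=0.05, detect=False).v["soma"][-1]
        v2 = integrate(tiny_cell, duration=200.0, dt=0.025, detect=False).v["soma"][-1]
        assert abs(v1 - v2) < 0.1

    def test_determinism(self, tiny_cell):
        a = integrate(tiny_cell, duration=300.0, dt=0.05,
                      current_steps=[(0, 0.05, 50.0, 250.0)])
        b = integrate(tiny_cell, duration=300.0, dt=0.05,
                      current_steps=[(0, 0.05, 50.0, 250.0)])
        assert np.array_equal(a.v["soma"], b.v["soma"])

    def test_divergence_reported_with_location(self, tiny_cell):
        # strong hyperpolarizing drive pushes V past the -200 mV guard
        with pytest.raises(SimulationDiverged, match="compartment"):
            integrate(tiny_cell, duration=400.0, dt=0.05,
                      current_steps=[(0, -1.0, 10.0, 390.0)])


class TestDetectSpikes:
    fs = 20000.0

    def _template(self):
        t = np.arange(0, 2.0, 1000.0 / self.fs)
        return 90.0 * np.exp(-((t - 0.6) ** 2) / 0.05)

    def test_subthreshold_sine_yields_none(self):
        t = np.arange(int(self.fs)) / self.fs
        v = -65.0 + 5.0 * np.sin(2 * np.pi * 8.0 * t)
        assert detect_spikes(v, self.fs).size == 0

    def test_three_templates_found_at_peaks(self):
        v = np.full(int(self.fs), -65.0)
        tpl = self._template()
        locs = [2000, 8000, 15000]
        for lo in locs:
            v[lo:lo + tpl.size] += tpl
        spikes = detect_spikes(v, self.fs)
        assert spikes.size == 3
        expected = (np.array(locs) + np.argmax(tpl)) * 1000.0 / self.fs
        assert np.allclose(np.sort(spikes), expected, atol=1000.0 / self.fs)

    def test_refractory_merges_close_events(self):
        v = np.full(int(self.fs), -65.0)
        tpl = self._template()
        v[2000:2000 + tpl.size] += tpl
        v[2000 + int(0.001 * self.fs):2000 + int(0.001 * self.fs) + tpl.size] += tpl
        spikes = detect_spikes(v, self.fs, refractory_ms=2.0)
        assert spikes.size == 1

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="warm-up"):
            detect_spikes(np.zeros(50), self.fs)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(np.zeros(1000), 500.0)
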