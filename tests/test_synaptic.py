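import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats as sstats

from thetalock.circstats import circ_dist, circ_mean_deg
from thetalock.synaptic import (
    DEFAULT_PATHWAYS,
    PERISOMATIC_BAND,
    PathwaySpec,
    apply_manipulation,
    build_schedule,
    default_pathways,
    load_pathways,
    place_boutons,
    sample_event_phases,
    save_pathways,
    syn_conductance,
)


class TestPathwaySpec:
    def test_default_table_complete(self):
        assert set(DEFAULT_PATHWAYS) == {
            "CA3", "CA2", "ECIII", "ECII", "Axo", "Bis", "CCK", "Ivy",
            "NGF", "OLM", "PV", "SCA",
        }
        for pw in DEFAULT_PATHWAYS.values():
            if pw.klass == "glutamatergic":
                assert pw.erev == 0.0
            else:
                assert pw.erev < -60.0

    def test_invalid_reversal_rejected(self):
        with pytest.raises(ValueError, match="reversal"):
            PathwaySpec("CA3", "glutamatergic", 10, ("basal",), (0, 100),
                        -70.0, 0.5, 3.0, 1e-3, 1.0, 0.0)

    def test_equal_taus_rejected(self):
        with pytest.raises(ValueError, match="tau1"):
            PathwaySpec("PV", "GABAergic", 10, ("soma",), (0, 100),
                        -75.0, 3.0, 3.0, 1e-3, 1.0, 0.0)

    def test_json_round_trip(self, tmp_path):
        p = tmp_path / "pathways.json"
        save_pathways(default_pathways(), p)
        back = load_pathways(p)
        assert back.keys() == DEFAULT_PATHWAYS.keys()
        assert back["PV"] == DEFAULT_PATHWAYS["PV"]


class TestPlaceBoutons:
    def test_perisomatic_band_respected(self, default_morph):
        ids = place_boutons(default_morph, DEFAULT_PATHWAYS["PV"], seed=4)
        zs = default_morph.signed_z()[ids]
        assert ids.size == DEFAULT_PATHWAYS["PV"].n_boutons
        assert np.all((zs >= PERISOMATIC_BAND[0]) & (zs <= PERISOMATIC_BAND[1]))

    def test_zero_boutons_empty(self, default_morph):
        pw = replace(DEFAULT_PATHWAYS["PV"], n_boutons=0)
        assert place_boutons(default_morph, pw, seed=0).size == 0

    def test_deterministic(self, default_morph):
        a = place_boutons(default_morph, DEFAULT_PATHWAYS["CA3"], seed=9)
        b = place_boutons(default_morph, DEFAULT_PATHWAYS["CA3"], seed=9)
        assert np.array_equal(a, b)

    def test_empty_band_names_pathway(self, default_morph):
        pw = replace(DEFAULT_PATHWAYS["OLM"], band=(5000.0, 6000.0))
        with pytest.raises(ValueError, match="OLM"):
            place_boutons(default_morph, pw, seed=0)


class TestEventPhases:
    theta = 8.0

    def _phases(self, pw, n_cycles, seed=0):
        t = sample_event_phases(pw, n_cycles, self.theta, seed=seed)
        period = 1000.0 / self.theta
        return (t / period * 360.0) % 360.0

    def test_symmetric_beta_centered_on_mu(self):
        pw = replace(DEFAULT_PATHWAYS["CA3"], phase_mu=200.0, beta1=4.0,
                     beta2=4.0, rate=80.0)
        phases = self._phases(pw, 2000)
        assert abs(circ_dist(circ_mean_deg(phases), 200.0)) < 5.0

    def test_degenerate_concentration_collapses_to_mu(self):
        pw = replace(DEFAULT_PATHWAYS["CA3"], phase_mu=90.0, beta1=5000.0,
                     beta2=5000.0, rate=40.0)
        phases = self._phases(pw, 500)
        assert np.all(np.abs(circ_dist(phases, 90.0)) < 10.0)

    def test_poisson_event_count(self):
        pw = replace(DEFAULT_PATHWAYS["CA3"], rate=8.0)
        t = sample_event_phases(pw, 1000, 8.0, seed=3)
        assert abs(t.size - 1000) <= 3 * math.sqrt(1000)

    def test_phase_distribution_matches_beta(self):
        pw = replace(DEFAULT_PATHWAYS["CA3"], phase_mu=180.0, beta1=3.0,
                     beta2=3.0, rate=800.0)
        phases = self._phases(pw, 1000)
        u = ((phases - 180.0 + 180.0) % 360.0) / 360.0  # unwrapped support
        assert u.size > 50_000
        _, p = sstats.kstest(u, sstats.beta(3.0, 3.0).cdf)
        assert p > 0.01

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            replace(DEFAULT_PATHWAYS["CA3"], beta1=0.0)


class TestSynConductance:
    def test_zero_at_onset(self):
        assert syn_conductance(0.0, 0.5, 3.0, 1.0) == pytest.approx(0.0)

    def test_peak_time_and_value(self):
        tau1, tau2, g = 0.5, 3.0, 0.7
        tpk = tau1 * tau2 / (tau2 - tau1) * math.log(tau2 / tau1)
        t = np.linspace(0, 30, 30_001)
        gt = syn_conductance(t, tau1, tau2, g)
        assert t[np.argmax(gt)] == pytest.approx(tpk, abs=1e-2)
        assert gt.max() == pytest.approx(g, rel=1e-6)
        assert syn_conductance(tpk, tau1, tau2, g) == pytest.approx(g, rel=1e-9)

    def test_decays_to_zero(self):
        assert syn_conductance(500.0, 0.5, 3.0, 1.0) < 1e-12

    def test_degenerate_taus_rejected(self):
        with pytest.raises(ValueError):
            syn_conductance(1.0, 2.0, 2.0, 1.0)


class TestManipulation:
    def test_deep_profile_fractions(self):
        out = apply_manipulation(default_pathways(), {"CCK": 0.30, "PV": 1.00})
        assert out["CCK"].n_boutons == round(DEFAULT_PATHWAYS["CCK"].n_boutons * 0.3)
        assert out["PV"].n_boutons == DEFAULT_PATHWAYS["PV"].n_boutons

    def test_identity(self):
        pws = default_pathways()
        out = apply_manipulation(pws, {k: 1.0 for k in pws})
        assert out == pws

    def test_full_removal(self):
        out = apply_manipulation(default_pathways(), {"PV": 0.0})
        assert out["PV"].n_boutons == 0

    def test_rate_mode(self):
        out = apply_manipulation(default_pathways(), {"CA3": 0.5}, mode="rate")
        assert out["CA3"].rate == pytest.approx(DEFAULT_PATHWAYS["CA3"].rate * 0.5)
        assert out["CA3"].n_boutons == DEFAULT_PATHWAYS["CA3"].n_boutons

    def test_unknown_pathway_rejected(self):
        with pytest.raises(KeyError):
            apply_manipulation(default_pathways(), {"foo": 0.5})

    def test_rounding_half_up(self):
        pws = {"PV": replace(DEFAULT_PATHWAYS["PV"], n_boutons=5)}
        assert apply_manipulation(pws, {"PV": 0.5})["PV"].n_boutons == 3


class TestBoutonRateEquivalence:
    def test_total_conductance_flux_matches_between_modes(self, default_morph):
        """Scaling boutons or rates by f delivers the same synaptic charge.

        At the input level the expected total conductance-time integral per
        cycle is n_boutons x rate x integral of the unitary event, so the
        two manipulation modes agree within sampling error.
        """
        base = {"CA3": replace(DEFAULT_PATHWAYS["CA3"], n_boutons=400, rate=6.0)}
        f = 0.5
        tot = {}
        for mode in ("boutons", "rate"):
            man = apply_manipulation(base, {"CA3": f}, mode=mode)
            ev, _ = build_schedule(default_morph, man, n_cycles=300, seed=12)
            # every event has the same kinetics, so flux ~ count x peak g
            tot[mode] = ev[3].sum()
        assert tot["boutons"] == pytest.approx(tot["rate"], rel=0.05)


class TestBuildSchedule:
    def test_events_within_window_and_sorted_kinds(self, default_morph):
        ev, names = build_schedule(default_morph, default_pathways(),
                                   n_cycles=5, seed=2)
        times, comps, kinds = ev[0], ev[1], ev[2]
        assert times.min() >= 0.0
        assert times.max() <= 5 * 125.0 + 125.0
        assert set(np.unique(kinds)) <= set(range(len(names)))
        assert comps.max() < default_morph.n_compartments

    def test_deterministic(self, default_morph):
        a, _ = build_schedule(default_morph, default_pathways(), 5, seed=2)
        b, _ = build_schedule(default_morph, default_pathways(), 5, seed=2)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
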