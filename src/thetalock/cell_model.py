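"""Multicompartment Hodgkin-Huxley dynamics of a CA1 pyramidal cell.

Each compartment carries 18 coupled state equations: the membrane
potential, an intracellular calcium pool, and 16 gating variables spread
over 8 active conductances (Na with fast activation/inactivation and a
slow attenuation gate; delayed-rectifier K with a slow inactivation gate;
A-type K; fast Ca-dependent K (BK-like, voltage gate x Ca gate); slow
Ca-dependent K (AHP); M-type K with two activation time scales; L-type Ca
with two gates; and HCN with fast and slow components), plus the passive
leak. Any current is ohmic, I = g(V,t) (V - Vrev), and every effective
conductance is the product of its maximal value and a dimensionless
scaling factor (the "GA factor" tuned by the genetic-algorithm fit).

Numerics: gating variables advance by exponential Euler; the voltage of
the whole tree is solved implicitly each step with a Hines-style
elimination (children before parents), which keeps the stiff axial
coupling stable at dt = 0.025-0.05 ms. Synaptic inputs are event-driven
double-exponential conductances aggregated per compartment and pathway.

Gating-rate parameters live in :data:`DEFAULT_KINETICS` and can be
replaced wholesale from a JSON config; the shipped values are generic CA1
pyramidal kinetics in the Migliore/Poirazi tradition, tuned here to the
package's passive rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import signal as ssig

from .morphology import Morphology, PassiveRules, leak_conductance, spine_correction

__all__ = [
    "CHANNEL_NAMES",
    "DEFAULT_KINETICS",
    "CellParams",
    "SimTrace",
    "N_STATE_EQUATIONS",
    "build_cell",
    "detect_spikes",
    "effective_conductance",
    "integrate",
    "ionic_current",
]

CHANNEL_NAMES = ("Na", "KDR", "KA", "KC", "KAHP", "KM", "CaL", "HCN")
GATE_NAMES = (
    "Na_m", "Na_h", "Na_s", "KDR_n", "KDR_l", "KA_a", "KA_b",
    "KC_c", "KC_d", "KAHP_q", "KM_m1", "KM_m2", "CaL_e", "CaL_f",
    "HCN_hf", "HCN_hs",
)
N_GATES = len(GATE_NAMES)
#: V + [Ca] + 16 gating variables
N_STATE_EQUATIONS = 2 + N_GATES

# Reversal potentials, mV
E_NA, E_K, E_CA, E_H, E_PAS = 55.0, -90.0, 120.0, -30.0, -70.0

# Voltage gate: xinf = base + amp / (1 + exp((vh - V)/k));
# tau = tau0 + tau_amp / (exp((V - vt)/ka) + exp(-(V - vt)/kb)).
# Calcium gates (KC_d, KAHP_q): xinf = Ca^h / (Ca^h + kd^h), tau constant;
# encoded as [kd, h, 0, 0, tau, 0, 0, 1, 1].
DEFAULT_KINETICS: dict[str, list[float]] = {
    #          vh      k    base  amp   tau0  tau_amp   vt    ka    kb
    "Na_m":  [-35.0,  5.0,  0.0, 1.0,  0.04,  0.30, -35.0, 18.0, 18.0],
    "Na_h":  [-45.0, -4.0,  0.0, 1.0,  0.30,  6.00, -45.0, 15.0, 15.0],
    "Na_s":  [-56.0, -6.0,  0.6, 0.4, 50.0, 1500.0, -50.0, 20.0, 20.0],
    "KDR_n": [-30.0,  6.0,  0.0, 1.0,  0.50,  3.00, -30.0, 20.0, 20.0],
    "KDR_l": [-46.0, -10.0, 0.7, 0.3, 2000.0,  0.0, -46.0,  1.0,  1.0],
    "KA_a":  [-35.0, 10.0,  0.0, 1.0,  0.30,  1.50, -30.0, 20.0, 20.0],
    "KA_b":  [-70.0, -7.0,  0.0, 1.0,  6.00, 20.00, -60.0, 25.0, 25.0],
    "KC_c":  [-15.0,  8.0,  0.0, 1.0,  0.80,  1.00, -15.0, 20.0, 20.0],
    "KC_d":  [  1.0,  2.0,  0.0, 0.0,  4.00,  0.0,    0.0,  1.0,  1.0],
    "KAHP_q":[  0.4,  2.0,  0.0, 0.0, 200.0,  0.0,    0.0,  1.0,  1.0],
    "KM_m1": [-35.0,  9.0,  0.0, 1.0, 30.00,  0.0,  -35.0,  1.0,  1.0],
    "KM_m2": [-35.0,  9.0,  0.0, 1.0, 120.0,  0.0,  -35.0,  1.0,  1.0],
    "CaL_e": [-22.0,  6.0,  0.0, 1.0,  1.50,  0.0,  -22.0,  1.0,  1.0],
    "CaL_f": [-50.0, -6.0,  0.4, 0.6, 80.00,  0.0,  -50.0,  1.0,  1.0],
    "HCN_hf":[-82.0, -8.0,  0.0, 1.0, 30.00,  0.0,  -82.0,  1.0,  1.0],
    "HCN_hs":[-82.0, -8.0,  0.0, 1.0, 250.0,  0.0,  -82.0,  1.0,  1.0],
}

# Calcium pool: d[Ca]/dt = -CA_PHI * ICaL - ([Ca] - CA_REST)/CA_TAU
CA_PHI = 0.05   # uM cm^2 / (uA ms)
CA_TAU = 80.0   # ms
CA_REST = 0.05  # uM

# Somatodendritic distribution of maximal conductances, mS/cm^2:
# g(z) = clip(base + slope * z, lo, hi). Na and the delayed rectifier are
# strongest perisomatically and fall off with distance; HCN and the A-type
# current rise with distance from the soma; the rest are uniform.
DEFAULT_GMAX_PROFILES: dict[str, tuple[float, float, float, float]] = {
    #        base   slope/um    lo     hi
    "Na":   (120.0, -0.40,    80.0,  120.0),
    "KDR":  (40.0,  -0.12,    22.0,   40.0),
    "KA":   ( 3.0,   0.02,     3.0,   12.0),
    "KC":   ( 2.0,   0.0,      2.0,    2.0),
    "KAHP": ( 0.8,   0.0,      0.8,    0.8),
    "KM":   ( 0.6,   0.0,      0.6,    0.6),
    "CaL":  ( 0.25,  0.0,      0.25,   0.25),
    "HCN":  ( 0.02,  0.0005,   0.02,   0.3),
}


def effective_conductance(gmax: float, factor: float) -> float:
    """Effective conductance: maximal conductance times its scaling factor."""
    if gmax < 0 or factor < 0:
        raise ValueError("effective_conductance: inputs must be >= 0")
    return gmax * factor


def ionic_current(g: float, v: float, vrev: float) -> float:
    """Ohmic current density I = g (V - Vrev); outward positive for V > Vrev."""
    if g < 0:
        raise ValueError("ionic_current: conductance must be >= 0")
    return g * (v - vrev)


@dataclass
class SimTrace:
    """Recorded simulation output."""

    dt: float  # ms
    v: dict  # label -> membrane potential array, mV
    spike_times: np.ndarray  # ms
    labels: tuple = ("soma", "proximal", "distal")

    @property
    def t(self) -> np.ndarray:
        n = len(next(iter(self.v.values())))
        return np.arange(n) * self.dt

    @property
    def fs(self) -> float:
        return 1000.0 / self.dt


class SimulationDiverged(RuntimeError):
    pass


@dataclass
class CellParams:
    """Flattened per-compartment arrays ready for the integrator.

    All compartments are in topological order (parents before children).
    """

    morph: Morphology
    order: np.ndarray          # original positions in topological order
    parent: np.ndarray         # parent index in topological order, -1 at root
    area: np.ndarray           # cm^2
    cm: np.ndarray             # uF/cm^2
    gpas: np.ndarray           # mS/cm^2
    gax_self: np.ndarray       # coupling coefficient in own row
    gax_parent: np.ndarray     # coupling coefficient in parent's row
    gmax: np.ndarray           # (8, n) mS/cm^2, already scaled by GA factors
    factors: dict = field(default_factory=dict)
    soma_idx: int = 0
    proximal_idx: int = 0
    distal_idx: int = 0

    @property
    def n(self) -> int:
        return self.parent.size


def _kinetics_array(kin: dict[str, list[float]]) -> np.ndarray:
    arr = np.array([kin[g] for g in GATE_NAMES], dtype=np.float64)
    if arr.shape != (N_GATES, 9):
        raise ValueError("kinetics config must provide 9 parameters per gate")
    return arr


def build_cell(
    morph: Morphology,
    factors: dict[str, float] | None = None,
    passive: PassiveRules | None = None,
    gmax_profiles: dict[str, tuple[float, float, float]] | None = None,
) -> CellParams:
    """Assemble integrator-ready arrays from a morphology and GA factors.

    ``factors`` maps channel names (plus optionally "Ra" and "leak") to
    dimensionless multipliers; missing entries default to 1. The effective
    conductance of every channel is Gmax(z) times its factor.
    """
    factors = dict(factors or {})
    passive = passive or PassiveRules()
    profiles = gmax_profiles or DEFAULT_GMAX_PROFILES
    order = morph.ordered_indices()
    comps = [morph.compartments[i] for i in order]
    pos_in_order = {morph.compartments[i].id: k for k, i in enumerate(order)}
    n = len(comps)
    parent = np.array(
        [pos_in_order[c.parent] if c.parent != -1 else -1 for c in comps], dtype=np.int64
    )
    area = np.array([math.pi * c.diameter * c.length * 1e-8 for c in comps])
    ss = np.array(
        [spine_correction(c.section_type, c.z, c.diameter) for c in comps]
    )
    cm = np.where(
        np.array([c.section_type == "soma" for c in comps]),
        passive.Cm_soma,
        passive.Cm_dend_multiplier * passive.Cm_soma * ss,
    )
    z = np.array([c.z for c in comps])
    gpas = leak_conductance(z, ss) * 1000.0 * factors.get("leak", 1.0)  # -> mS/cm^2

    ra = passive.Ra_base * factors.get("Ra", 1.0)
    gax_self = np.zeros(n)
    gax_parent = np.zeros(n)
    for i in range(1, n):
        p = parent[i]
        ci, cp = comps[i], comps[p]
        across_i = math.pi * (ci.diameter * 1e-4 / 2.0) ** 2  # cm^2
        across_p = math.pi * (cp.diameter * 1e-4 / 2.0) ** 2
        r = ra * (ci.length * 1e-4 / 2.0) / across_i + ra * (cp.length * 1e-4 / 2.0) / across_p
        gax_self[i] = 1000.0 / (r * area[i])
        gax_parent[i] = 1000.0 / (r * area[p])

    gmax = np.zeros((len(CHANNEL_NAMES), n))
    for ci, name in enumerate(CHANNEL_NAMES):
        base, slope, lo, hi = profiles[name]
        prof = np.clip(base + slope * z, lo, hi)
        gmax[ci] = prof * factors.get(name, 1.0)

    # recording sites: soma, proximal trunk (~nearest to 100 um), most
    # distal apical compartment
    apical = [k for k, c in enumerate(comps) if c.section_type.startswith("apical")]
    soma_idx = next(k for k, c in enumerate(comps) if c.section_type == "soma")
    if apical:
        proximal_idx = min(apical, key=lambda k: abs(comps[k].z - 100.0))
        distal_idx = max(apical, key=lambda k: comps[k].z)
    else:
        proximal_idx = distal_idx = soma_idx
    return CellParams(
        morph=morph, order=order, parent=parent, area=area, cm=cm, gpas=gpas,
        gax_self=gax_self, gax_parent=gax_parent, gmax=gmax, factors=factors,
        soma_idx=soma_idx, proximal_idx=proximal_idx, distal_idx=distal_idx,
    )


@njit(cache=True)
def _gate_inf_tau(kin, gi, v, ca):
    if gi == 8 or gi == 9:  # calcium gates
        kd = kin[gi, 0]
        h = kin[gi, 1]
        cah = ca ** h
        xinf = cah / (cah + kd ** h)
        tau = kin[gi, 4]
        return xinf, tau
    vh = kin[gi, 0]
    k = kin[gi, 1]
    xinf = kin[gi, 2] + kin[gi, 3] / (1.0 + math.exp((vh - v) / k))
    tau = kin[gi, 4]
    if kin[gi, 5] > 0.0:
        vt = kin[gi, 6]
        tau += kin[gi, 5] / (math.exp((v - vt) / kin[gi, 7]) + math.exp(-(v - vt) / kin[gi, 8]))
    if tau < 0.01:
        tau = 0.01
    return xinf, tau


@njit(cache=True, fastmath=True)
def _run(
    parent, area, cm, gpas, gax_self, gax_parent, gmax, kin,
    dt, n_steps,
    inj_comp, inj_amp, inj_t0, inj_t1,
    ev_step, ev_comp, ev_kind, ev_g,
    syn_d1, syn_d2, syn_erev, n_kinds,
    rec_idx, v_init, passive_only,
):
    n = parent.size
    v = np.full(n, v_init)
    ca = np.full(n, CA_REST)
    gates = np.empty((N_GATES, n))
    for i in range(n):
        for gi in range(N_GATES):
            xinf, _ = _gate_inf_tau(kin, gi, v[i], ca[i])
            gates[gi, i] = xinf
    syn_a = np.zeros((n_kinds, n))
    syn_b = np.zeros((n_kinds, n))
    # exponential-Euler step factor is constant for gates with fixed tau
    const_step = np.full(N_GATES, -1.0)
    for gi in range(N_GATES):
        if kin[gi, 5] == 0.0:
            const_step[gi] = 1.0 - math.exp(-dt / max(kin[gi, 4], 0.01))
    vrec = np.empty((rec_idx.size, n_steps + 1))
    for r in range(rec_idx.size):
        vrec[r, 0] = v[rec_idx[r]]
    diag = np.empty(n)
    rhs = np.empty(n)
    fail_comp = -1
    fail_t = -1.0
    ptr = 0
    n_ev = ev_step.size
    for step in range(n_steps):
        t = step * dt
        # deliver synaptic events scheduled in (t, t+dt]
        while ptr < n_ev and ev_step[ptr] == step:
            k = ev_kind[ptr]
            c = ev_comp[ptr]
            syn_a[k, c] += ev_g[ptr]
            syn_b[k, c] += ev_g[ptr]
            ptr += 1
        # decay synaptic states
        for k in range(n_kinds):
            da = syn_d1[k]
            db = syn_d2[k]
            for i in range(n):
                syn_a[k, i] *= da
                syn_b[k, i] *= db
        for i in range(n):
            vi = v[i]
            # gating update (exponential Euler) and calcium
            if not passive_only:
                for gi in range(N_GATES):
                    xinf, tau = _gate_inf_tau(kin, gi, vi, ca[i])
                    if const_step[gi] >= 0.0:
                        gates[gi, i] += (xinf - gates[gi, i]) * const_step[gi]
                    else:
                        gates[gi, i] += (xinf - gates[gi, i]) * (1.0 - math.exp(-dt / tau))
                e = gates[12, i]
                f = gates[13, i]
                g_cal = gmax[6, i] * e * e * f
                ica = g_cal * (vi - E_CA)
                ca[i] += dt * (-CA_PHI * ica - (ca[i] - CA_REST) / CA_TAU)
                if ca[i] < 1e-6:
                    ca[i] = 1e-6
            # total membrane conductance and reversal-weighted sum
            gsum = gpas[i]
            gesum = gpas[i] * E_PAS
            if not passive_only:
                m = gates[0, i]; h = gates[1, i]; s = gates[2, i]
                g = gmax[0, i] * m * m * m * h * s
                gsum += g; gesum += g * E_NA
                nn = gates[3, i]; l = gates[4, i]
                g = gmax[1, i] * nn * nn * nn * nn * l
                gsum += g; gesum += g * E_K
                g = gmax[2, i] * gates[5, i] * gates[6, i]
                gsum += g; gesum += g * E_K
                g = gmax[3, i] * gates[7, i] * gates[8, i]
                gsum += g; gesum += g * E_K
                g = gmax[4, i] * gates[9, i]
                gsum += g; gesum += g * E_K
                g = gmax[5, i] * gates[10, i] * gates[11, i]
                gsum += g; gesum += g * E_K
                e = gates[12, i]; f = gates[13, i]
                g = gmax[6, i] * e * e * f
                gsum += g; gesum += g * E_CA
                g = gmax[7, i] * (0.5 * gates[14, i] + 0.5 * gates[15, i])
                gsum += g; gesum += g * E_H
            for k in range(n_kinds):
                gs = syn_b[k, i] - syn_a[k, i]
                if gs > 0.0:
                    gsum += gs
                    gesum += gs * syn_erev[k]
            diag[i] = cm[i] / dt + gsum
            rhs[i] = cm[i] / dt * vi + gesum
        # injected step currents
        for si in range(inj_comp.size):
            if inj_t0[si] <= t < inj_t1[si]:
                rhs[inj_comp[si]] += inj_amp[si] * 1e-3 / area[inj_comp[si]]
        # axial terms and Hines elimination (children have larger index)
        for i in range(1, n):
            diag[i] += gax_self[i]
            diag[parent[i]] += gax_parent[i]
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f2 = gax_parent[i] / diag[i]
            diag[p] -= f2 * gax_self[i]
            rhs[p] += f2 * rhs[i]
        v[0] = rhs[0] / diag[0]
        for i in range(1, n):
            v[i] = (rhs[i] + gax_self[i] * v[parent[i]]) / diag[i]
        for i in range(n):
            if not (-200.0 < v[i] < 200.0) or v[i] != v[i]:
                fail_comp = i
                fail_t = t
                return vrec, fail_comp, fail_t
        for r in range(rec_idx.size):
            vrec[r, step + 1] = v[rec_idx[r]]
    return vrec, fail_comp, fail_t


def integrate(
    cell: CellParams,
    duration: float,
    dt: float = 0.025,
    current_steps: list[tuple[int, float, float, float]] | None = None,
    events: tuple | None = None,
    kinetics: dict[str, list[float]] | None = None,
    v_init: float = -65.0,
    passive_only: bool = False,
    record: tuple[str, ...] = ("soma", "proximal", "distal"),
    detect: bool = True,
    spike_threshold: float = 10.0,
) -> SimTrace:
    """Integrate the cell for ``duration`` ms at fixed step ``dt``.

    current_steps : list of (compartment index in topological order,
        amplitude nA, t_on ms, t_off ms).
    events : synaptic schedule as a tuple of arrays
        (time ms, compartment index, kind index, peak conductance uS,
        tau1 ms per kind, tau2 ms per kind, Erev mV per kind). Produced by
        :func:`thetalock.synaptic.build_schedule`.

    Deterministic given its inputs. Raises :class:`SimulationDiverged` if
    any compartment leaves (-200, 200) mV.
    """
    if dt <= 0 or duration < dt:
        raise ValueError("integrate: need dt > 0 and duration >= dt")
    n_steps = int(round(duration / dt))
    kin = _kinetics_array(kinetics or DEFAULT_KINETICS)
    steps = current_steps or []
    inj_comp = np.array([s[0] for s in steps], dtype=np.int64)
    inj_amp = np.array([s[1] for s in steps], dtype=np.float64)
    inj_t0 = np.array([s[2] for s in steps], dtype=np.float64)
    inj_t1 = np.array([s[3] for s in steps], dtype=np.float64)
    if events is None:
        ev_t = np.zeros(0)
        ev_comp = np.zeros(0, dtype=np.int64)
        ev_kind = np.zeros(0, dtype=np.int64)
        ev_gpeak = np.zeros(0)
        tau1 = np.array([0.5])
        tau2 = np.array([3.0])
        erev = np.array([0.0])
    else:
        ev_t, ev_comp, ev_kind, ev_gpeak, tau1, tau2, erev = events
    n_kinds = tau1.size
    # normalize the double exponential so one event of weight w peaks at w
    tpk = tau1 * tau2 / (tau2 - tau1) * np.log(tau2 / tau1)
    norm = 1.0 / (np.exp(-tpk / tau2) - np.exp(-tpk / tau1))
    # order events by time, convert to step indices and local conductance
    # densities (uS -> mS/cm^2 via membrane area)
    if ev_t.size:
        idx = np.argsort(ev_t, kind="stable")
        ev_t = ev_t[idx]
        ev_comp = ev_comp[idx]
        ev_kind = ev_kind[idx]
        ev_gpeak = ev_gpeak[idx]
        ev_step = np.minimum((ev_t / dt).astype(np.int64), n_steps - 1)
        ev_g = ev_gpeak * norm[ev_kind] * 1e-3 / cell.area[ev_comp]
    else:
        ev_step = np.zeros(0, dtype=np.int64)
        ev_g = np.zeros(0)
    syn_d1 = np.exp(-dt / tau1)
    syn_d2 = np.exp(-dt / tau2)

    rec_map = {"soma": cell.soma_idx, "proximal": cell.proximal_idx, "distal": cell.distal_idx}
    rec_idx = np.array([rec_map[r] for r in record], dtype=np.int64)
    vrec, fail_comp, fail_t = _run(
        cell.parent, cell.area, cell.cm, cell.gpas, cell.gax_self, cell.gax_parent,
        cell.gmax, kin, dt, n_steps,
        inj_comp, inj_amp, inj_t0, inj_t1,
        ev_step, ev_comp.astype(np.int64), ev_kind.astype(np.int64), ev_g,
        syn_d1, syn_d2, erev.astype(np.float64), n_kinds,
        rec_idx, v_init, passive_only,
    )
    if fail_comp >= 0:
        raise SimulationDiverged(
            f"voltage diverged in compartment {fail_comp} at t={fail_t:.2f} ms"
        )
    v = {label: vrec[i] for i, label in enumerate(record)}
    fs = 1000.0 / dt
    if detect and "soma" in record and duration > 50.0 and not passive_only:
        spikes = detect_spikes(v["soma"], fs, threshold=spike_threshold)
    else:
        spikes = np.zeros(0)
    return SimTrace(dt=dt, v=v, spike_times=spikes, labels=tuple(record))


def detect_spikes(
    v: np.ndarray,
    fs: float,
    threshold: float = 10.0,
    refractory_ms: float = 2.0,
    hp_hz: float = 300.0,
) -> np.ndarray:
    """Detect spike times (ms) from a somatic voltage trace.

    The trace is high-pass filtered above 300 Hz (zero-phase Butterworth)
    and suprathreshold excursions are reduced to one event per excursion
    peak, with a minimum inter-event (refractory) interval.
    """
    v = np.asarray(v, dtype=float)
    if fs <= 2 * hp_hz:
        raise ValueError("detect_spikes: sampling rate must exceed twice the filter corner")
    warmup = int(3 * fs / hp_hz) * 3
    if v.size <= max(warmup, 33):
        raise ValueError("detect_spikes: trace shorter than filter warm-up")
    sos = ssig.butter(4, hp_hz, btype="highpass", fs=fs, output="sos")
    hp = ssig.sosfiltfilt(sos, v)
    dist = max(1, int(round(refractory_ms * fs / 1000.0)))
    peaks, _ = ssig.find_peaks(hp, height=threshold, distance=dist)
    return peaks * 1000.0 / fs
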