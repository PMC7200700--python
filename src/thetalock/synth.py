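"""Synthetic data generators for the analysis pipeline.

These generators emulate the structure of hippocampal recordings well
enough to exercise every analysis stage without animal data: an LFP with a
theta carrier, planted theta-nested spectral bursts (tSC classes) and 1/f
background noise; spike trains of units with von Mises phase preference;
and cell-feature tables with planted feature-to-phase effects feeding the
regression analysis. Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_FEATURES",
    "LfpPlan",
    "TscBurst",
    "UnitPlan",
    "default_tsc_bursts",
    "generate_feature_table",
    "generate_lfp",
    "generate_spike_trains",
]

# ---------------------------------------------------------------------------
# canonical feature list for the determinants regression
# ---------------------------------------------------------------------------

_PATHWAY_PREFIXES = (
    "CA3", "CA2", "EC3", "EC2", "Axo", "Bis", "CCK", "Ivy", "NGF", "OL-M",
    "PV", "SCA",
)
_PATHWAY_SUFFIXES = ("F", "G", "F*G", "B", "Freq", "Ph")
_INTRINSIC_PREFIXES = (
    "iNa", "iA", "iAHPs", "iC", "iKDR", "iM", "iCa", "HCN", "L", "Ra",
)

#: Full canonical feature-column list: per input pathway its conductance
#: factor, original and final conductance, bouton count, event frequency
#: and phase; per intrinsic channel (and Ra) its factor and mean maximal
#: conductance; plus apical/basal/total dendritic branch counts.
CANONICAL_FEATURES: tuple[str, ...] = tuple(
    f"{p}_{s}" for p in _PATHWAY_PREFIXES for s in _PATHWAY_SUFFIXES
) + tuple(
    f"{p}_{s}" for p in _INTRINSIC_PREFIXES for s in ("F", "Gmean")
) + ("nBrApic", "nBrBasal", "nBrTotal")


# ---------------------------------------------------------------------------
# LFP with planted theta-nested spectral components
# ---------------------------------------------------------------------------

@dataclass
class TscBurst:
    """One theta-nested spectral component class."""

    name: str
    freq_hz: float        # burst center frequency
    phase_deg: float      # theta phase of the burst center (trough-0)
    amplitude: float      # relative to theta amplitude
    proportion: float     # fraction of cycles carrying this class


def default_tsc_bursts() -> list[TscBurst]:
    """The four canonical tSC classes.

    tSC1: <20 Hz at the theta peak; tSC2: 30-40 Hz on the falling
    (descending) phase; tSC3: 50-60 Hz at the peak; tSC4: 70-90 Hz at the
    peak.
    """
    return [
        TscBurst("tSC1", 16.0, 180.0, 0.45, 0.25),
        TscBurst("tSC2", 35.0, 290.0, 0.40, 0.25),
        TscBurst("tSC3", 55.0, 180.0, 0.40, 0.25),
        TscBurst("tSC4", 80.0, 180.0, 0.35, 0.25),
    ]


@dataclass
class LfpPlan:
    duration_s: float = 60.0
    fs: float = 1250.0
    theta_freq: float = 8.0
    theta_amp: float = 1.0
    bursts: list = field(default_factory=default_tsc_bursts)
    noise_level: float = 0.1   # std of 1/f noise relative to theta amp
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if sum(b.proportion for b in self.bursts) > 1.0 + 1e-9:
            raise ValueError("LfpPlan: burst proportions must sum to <= 1")
        for b in self.bursts:
            if not (4.0 < b.freq_hz < self.fs / 2.0):
                raise ValueError(f"LfpPlan: burst {b.name} frequency out of range")


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_lfp(plan: LfpPlan) -> tuple[np.ndarray, pd.DataFrame]:
    """Generate an LFP trace and its ground-truth cycle table.

    The trace is a theta sinusoid (trough at phase 0) plus per-cycle
    Gaussian-windowed oscillatory bursts for the planted tSC class of each
    cycle, over 1/f background noise. Returns (lfp, cycles) where cycles
    has one row per complete theta cycle: sample indices of the cycle
    start (peak), trough and end (next peak), and the planted class label
    ('none' for cycles without a burst).
    """
    rng = np.random.default_rng(plan.seed)
    n = int(round(plan.duration_s * plan.fs))
    t = np.arange(n) / plan.fs
    period = 1.0 / plan.theta_freq
    lfp = -plan.theta_amp * np.cos(2.0 * np.pi * plan.theta_freq * t)

    # complete cycles: trough k at t = k * period; cycle spans the
    # surrounding peaks at (k -/+ 1/2) * period
    n_cycles = int(np.floor(plan.duration_s / period)) - 1
    labels = []
    probs = [b.proportion for b in plan.bursts]
    p_none = max(0.0, 1.0 - sum(probs))
    choices = [b.name for b in plan.bursts] + ["none"]
    by_name = {b.name: b for b in plan.bursts}
    rows = []
    for k in range(1, n_cycles + 1):
        lab = rng.choice(choices, p=probs + [p_none])
        labels.append(lab)
        trough_t = k * period
        start = int(round((trough_t - period / 2.0) * plan.fs))
        trough = int(round(trough_t * plan.fs))
        end = int(round((trough_t + period / 2.0) * plan.fs))
        rows.append({"cycle": k - 1, "start": start, "trough": trough,
                     "end": end, "label": lab})
        if lab != "none":
            b = by_name[lab]
            # burst centred at its theta phase within this cycle
            t0 = trough_t + ((b.phase_deg - 360.0) if b.phase_deg > 180.0
                             else b.phase_deg) / 360.0 * period
            # a nested burst is confined within its cycle: ~1.5 carrier
            # periods, never wider than a third of the theta period
            sigma = min(1.5 / b.freq_hz, period / 3.5)
            i0 = max(0, int((t0 - 4 * sigma) * plan.fs))
            i1 = min(n, int((t0 + 4 * sigma) * plan.fs))
            tt = t[i0:i1]
            env = np.exp(-0.5 * ((tt - t0) / sigma) ** 2)
            lfp[i0:i1] += plan.theta_amp * b.amplitude * env * np.sin(
                2.0 * np.pi * b.freq_hz * (tt - t0)
            )
    if plan.noise_level > 0:
        lfp = lfp + plan.theta_amp * plan.noise_level * _pink_noise(
            n, plan.noise_exponent, rng
        )
    return lfp, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phase-locked spike trains
# ---------------------------------------------------------------------------

@dataclass
class UnitPlan:
    unit: int
    rate_hz: float
    pref_phase_deg: float
    kappa: float
    sublayer: str = "deep"

    def __post_init__(self):
        if self.rate_hz < 0 or self.kappa < 0:
            raise ValueError("UnitPlan: rate and kappa must be >= 0")


def generate_spike_trains(
    units: list[UnitPlan],
    cycles: pd.DataFrame,
    fs: float,
    theta_freq: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample spikes for phase-locked units over a ground-truth cycle table.

    Per cycle the spike count of a unit is Poisson with mean
    rate/theta frequency; spike phases are von Mises around the unit's
    preferred phase (kappa = 0 gives uniform phases). Returns a tidy table
    (unit, time_s, phase_deg, cycle).
    """
    if cycles.empty:
        raise ValueError("generate_spike_trains: empty cycle table")
    rng = np.random.default_rng(seed)
    period = 1.0 / theta_freq
    rows = []
    for u in units:
        lam = u.rate_hz / theta_freq
        counts = rng.poisson(lam, size=len(cycles))
        for (_, cyc), c in zip(cycles.iterrows(), counts):
            if c == 0:
                continue
            if u.kappa > 0:
                ph = np.rad2deg(
                    rng.vonmises(np.deg2rad(u.pref_phase_deg), u.kappa, size=c)
                ) % 360.0
            else:
                ph = rng.uniform(0.0, 360.0, size=c)
            trough_t = cyc["trough"] / fs
            tt = trough_t + np.where(ph > 180.0, ph - 360.0, ph) / 360.0 * period
            for p, s in zip(ph, tt):
                rows.append({"unit": u.unit, "time_s": s, "phase_deg": p,
                             "cycle": int(cyc["cycle"])})
    df = pd.DataFrame(rows, columns=["unit", "time_s", "phase_deg", "cycle"])
    return df.sort_values(["unit", "time_s"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# feature tables with planted feature -> phase effects
# ---------------------------------------------------------------------------

def generate_feature_table(
    n_cells: int,
    planted: list[tuple[str, float]] | None = None,
    kappa: float = 8.0,
    base_phase: float = 90.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate a synthetic cell-feature table with a phase response.

    Unplanted features are independent noise on loosely realistic scales;
    each planted (feature, shift) pair adds ``shift`` degrees per standard
    deviation of that feature to the cell's preferred phase, which is then
    jittered with von Mises noise of concentration ``kappa``. Returns
    (table, response phases in degrees); the table's columns are exactly
    the canonical feature list.
    """
    planted = planted or []
    for name, _ in planted:
        if name not in CANONICAL_FEATURES:
            raise ValueError(f"generate_feature_table: unknown feature {name!r}")
    rng = np.random.default_rng(seed)
    cols = {}
    for name in CANONICAL_FEATURES:
        if name.endswith("_Ph"):
            cols[name] = rng.uniform(0.0, 360.0, n_cells)
        elif name.endswith("_Freq"):
            cols[name] = rng.gamma(4.0, 2.0, n_cells)
        elif name.endswith("_B") or name.startswith("nBr"):
            cols[name] = rng.poisson(30.0, n_cells).astype(float)
        elif name.endswith("_F"):
            cols[name] = rng.uniform(0.5, 2.0, n_cells)
        else:  # conductances / means
            cols[name] = rng.lognormal(0.0, 0.4, n_cells)
    df = pd.DataFrame(cols)
    shift = np.zeros(n_cells)
    for name, deg_per_sd in planted:
        x = df[name].to_numpy()
        zx = (x - x.mean()) / x.std()
        shift = shift + deg_per_sd * zx
    noise = np.rad2deg(rng.vonmises(0.0, kappa, n_cells)) if kappa > 0 else (
        rng.uniform(-180.0, 180.0, n_cells)
    )
    phases = (base_phase + shift + noise) % 360.0
    return df, phases
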