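"""Theta-modulated synaptic pathway inputs.

Twelve input populations converge on the model cell: four glutamatergic
(CA3, CA2, ECIII, ECII) and eight GABAergic (axo-axonic Axo, bistratified
Bis, CCK and PV basket cells, Ivy, neurogliaform NGF, OLM and
Schaffer-associated SCA interneurons). Each pathway is described by its
bouton count, somatodendritic target band (signed coordinate: apical
positive, basal negative, the perisomatic band being -50 to +150 um around
the soma), double-exponential conductance kinetics, a mean event rate, and
a theta phase tuning: event phases follow a Beta(beta1, beta2)
distribution mapped onto the full cycle centred on the preferred phase
(trough = 0 degrees, peak = 180 degrees).

The default parameter table is a literature-informed approximation of the
input organization of CA1 (entorhinal layer-III drive at the theta peak,
CA3/CA2/ECII toward the falling phase and trough, PV baskets on the
falling phase, CCK baskets near the peak, OLM near the trough), sized for
desk-scale morphologies; every value can be overridden or loaded from
JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from .morphology import Morphology

__all__ = [
    "DEFAULT_PATHWAYS",
    "PATHWAY_NAMES",
    "PathwaySpec",
    "apply_manipulation",
    "build_schedule",
    "default_pathways",
    "load_pathways",
    "place_boutons",
    "sample_event_phases",
    "save_pathways",
    "syn_conductance",
]

PATHWAY_NAMES = (
    "CA3", "CA2", "ECIII", "ECII",
    "Axo", "Bis", "CCK", "Ivy", "NGF", "OLM", "PV", "SCA",
)

PERISOMATIC_BAND = (-50.0, 150.0)


@dataclass
class PathwaySpec:
    """One input population."""

    name: str
    klass: str  # 'glutamatergic' | 'GABAergic'
    n_boutons: int
    target_sections: tuple  # section types eligible for boutons
    band: tuple  # (lo, hi) signed somatodendritic coordinate, um
    erev: float  # mV
    tau1: float  # ms (rise)
    tau2: float  # ms (decay)
    gmax_syn: float  # uS per bouton event
    rate: float  # Hz per bouton
    phase_mu: float  # degrees, trough-0 convention
    beta1: float = 6.0
    beta2: float = 6.0

    def __post_init__(self):
        if self.tau1 == self.tau2:
            raise ValueError(f"{self.name}: tau1 must differ from tau2")
        if self.gmax_syn < 0 or self.rate < 0:
            raise ValueError(f"{self.name}: negative conductance or rate")
        if not (0.0 <= self.phase_mu < 360.0):
            raise ValueError(f"{self.name}: phase_mu must be in [0, 360)")
        if self.beta1 <= 0 or self.beta2 <= 0:
            raise ValueError(f"{self.name}: beta parameters must be > 0")
        if self.klass == "glutamatergic" and self.erev != 0.0:
            raise ValueError(f"{self.name}: glutamatergic reversal must be 0 mV")
        if self.klass == "GABAergic" and self.erev >= -60.0:
            raise ValueError(f"{self.name}: GABAergic reversal must be < -60 mV")


_DEND = ("basal", "apical_trunk", "apical_branch")
_PERI = ("soma", "basal", "apical_trunk", "apical_branch")

# Desk-scale default pathway table (documented approximation; override via
# load_pathways/JSON). Bouton counts are sized for tens-of-compartments
# synthetic cells; phase preferences follow juxtacellular recordings of
# identified interneurons (trough-0 convention: CA3/ECII near the trough,
# ECIII at the peak, CCK baskets on the ascending phase, axo-axonic cells
# just after the peak, PV baskets on the descending phase, OLM and
# bistratified cells near the trough). Conductances were calibrated once so
# that a default synthetic cell fires at realistic rates (0.01-8 Hz) under
# the full input collection.
DEFAULT_PATHWAYS: dict[str, PathwaySpec] = {
    "CA3":   PathwaySpec("CA3", "glutamatergic", 450, _DEND, (-300.0, 300.0), 0.0, 0.5, 3.0, 0.0050, 5.0, 350.0, 2.5, 2.5),
    "CA2":   PathwaySpec("CA2", "glutamatergic", 100, _DEND, (-300.0, 300.0), 0.0, 0.5, 3.0, 0.0016, 4.0, 330.0, 4.0, 4.0),
    "ECIII": PathwaySpec("ECIII", "glutamatergic", 600, _DEND, (100.0, 10000.0), 0.0, 0.5, 3.0, 0.0070, 8.0, 180.0, 5.0, 5.0),
    "ECII":  PathwaySpec("ECII", "glutamatergic", 80, _DEND, (100.0, 10000.0), 0.0, 0.5, 3.0, 0.0016, 4.0, 20.0, 4.0, 4.0),
    "Axo":   PathwaySpec("Axo", "GABAergic", 60, ("soma",), (-30.0, 30.0), -75.0, 0.3, 6.0, 0.0015, 15.0, 210.0, 6.0, 6.0),
    "Bis":   PathwaySpec("Bis", "GABAergic", 150, _DEND, (-300.0, 300.0), -75.0, 0.5, 8.0, 0.0024, 18.0, 40.0, 5.0, 5.0),
    "CCK":   PathwaySpec("CCK", "GABAergic", 150, _PERI, PERISOMATIC_BAND, -75.0, 0.5, 8.0, 0.0035, 14.0, 155.0, 4.0, 4.0),
    "Ivy":   PathwaySpec("Ivy", "GABAergic", 100, _DEND, (-200.0, 200.0), -75.0, 1.0, 12.0, 0.0020, 6.0, 70.0, 4.0, 4.0),
    "NGF":   PathwaySpec("NGF", "GABAergic", 60, _DEND, (250.0, 10000.0), -78.0, 2.0, 20.0, 0.0005, 8.0, 240.0, 4.0, 4.0),
    "OLM":   PathwaySpec("OLM", "GABAergic", 140, _DEND, (250.0, 10000.0), -75.0, 0.5, 10.0, 0.0010, 15.0, 0.0, 4.0, 4.0),
    "PV":    PathwaySpec("PV", "GABAergic", 150, _PERI, PERISOMATIC_BAND, -75.0, 0.3, 6.0, 0.0024, 20.0, 280.0, 6.0, 6.0),
    "SCA":   PathwaySpec("SCA", "GABAergic", 80, _DEND, (50.0, 300.0), -75.0, 0.5, 10.0, 0.0015, 8.0, 90.0, 4.0, 4.0),
}


def default_pathways() -> dict[str, PathwaySpec]:
    """Fresh copy of the default pathway table."""
    return {k: replace(v) for k, v in DEFAULT_PATHWAYS.items()}


def save_pathways(pathways: dict[str, PathwaySpec], path: str | Path) -> None:
    data = {k: asdict(v) for k, v in pathways.items()}
    Path(path).write_text(json.dumps(data, indent=2))


def load_pathways(path: str | Path) -> dict[str, PathwaySpec]:
    data = json.loads(Path(path).read_text())
    out = {}
    for k, v in data.items():
        v["target_sections"] = tuple(v["target_sections"])
        v["band"] = tuple(v["band"])
        out[k] = PathwaySpec(**v)
    return out


def place_boutons(morph: Morphology, pathway: PathwaySpec, seed: int = 0) -> np.ndarray:
    """Sample bouton compartments for one pathway.

    Placements fall inside the pathway's target band and section types,
    with probability proportional to compartment membrane area; the same
    compartment may host several boutons. Deterministic in ``seed``.
    """
    zsigned = morph.signed_z()
    areas = morph.areas_cm2()
    lo, hi = pathway.band
    elig = np.array(
        [
            (c.section_type in pathway.target_sections) and (lo <= zsigned[i] <= hi)
            for i, c in enumerate(morph.compartments)
        ]
    )
    if pathway.n_boutons == 0:
        return np.zeros(0, dtype=np.int64)
    if not elig.any():
        raise ValueError(
            f"place_boutons: no compartment in target band for pathway {pathway.name}"
        )
    w = np.where(elig, areas, 0.0)
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    return rng.choice(morph.n_compartments, size=pathway.n_boutons, p=w)


def sample_event_phases(
    pathway: PathwaySpec,
    n_cycles: int,
    theta_freq: float = 8.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample event times (ms) for one bouton over ``n_cycles`` theta cycles.

    Per cycle the event count is Poisson with mean rate/theta frequency;
    each event phase is Beta(beta1, beta2)-distributed on the full cycle
    centred on the pathway's preferred phase and wrapped circularly.
    """
    if n_cycles < 1 or theta_freq <= 0:
        raise ValueError("sample_event_phases: need n_cycles >= 1 and theta_freq > 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    period = 1000.0 / theta_freq
    lam = pathway.rate / theta_freq
    counts = rng.poisson(lam, size=n_cycles)
    total = int(counts.sum())
    if total == 0:
        return np.zeros(0)
    u = rng.beta(pathway.beta1, pathway.beta2, size=total)
    phases = (pathway.phase_mu + (u - 0.5) * 360.0) % 360.0
    cyc = np.repeat(np.arange(n_cycles), counts)
    return (cyc + phases / 360.0) * period


def syn_conductance(t_ms, tau1: float, tau2: float, gmax_syn: float):
    """Double-exponential synaptic conductance, normalized to peak at gmax.

    g(t) = gmax * N * (exp(-t/tau2) - exp(-t/tau1)), zero at t = 0 and as
    t -> infinity, with N chosen so the maximum equals ``gmax_syn``.
    """
    if tau1 == tau2:
        raise ValueError("syn_conductance: tau1 must differ from tau2")
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0):
        raise ValueError("syn_conductance: t must be >= 0")
    tpk = tau1 * tau2 / (tau2 - tau1) * math.log(tau2 / tau1)
    norm = 1.0 / (math.exp(-tpk / tau2) - math.exp(-tpk / tau1))
    g = gmax_syn * norm * (np.exp(-t / tau2) - np.exp(-t / tau1))
    return float(g) if g.ndim == 0 else g


def apply_manipulation(
    pathways: dict[str, PathwaySpec],
    fractions: dict[str, float],
    mode: str = "boutons",
) -> dict[str, PathwaySpec]:
    """Rescale selected pathways by per-pathway fractions in [0, 1].

    mode='boutons' rescales bouton counts (rounded half-up); mode='rate'
    rescales event rates. Untouched pathways are copied unchanged.
    """
    if mode not in ("boutons", "rate"):
        raise ValueError(f"apply_manipulation: unknown mode {mode!r}")
    out = {k: replace(v) for k, v in pathways.items()}
    for name, frac in fractions.items():
        if name not in out:
            raise KeyError(f"apply_manipulation: unknown pathway {name!r}")
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"apply_manipulation: fraction for {name} outside [0, 1]")
        if mode == "boutons":
            out[name] = replace(out[name], n_boutons=int(math.floor(out[name].n_boutons * frac + 0.5)))
        else:
            out[name] = replace(out[name], rate=out[name].rate * frac)
    return out


def build_schedule(
    morph: Morphology,
    pathways: dict[str, PathwaySpec],
    n_cycles: int,
    theta_freq: float = 8.0,
    seed: int = 0,
    order: np.ndarray | None = None,
):
    """Build the full synaptic event schedule for one simulation.

    Returns the event tuple consumed by :func:`thetalock.cell_model.integrate`:
    (times ms, compartment indices, kind indices, peak conductances uS,
    tau1 per kind, tau2 per kind, Erev per kind), plus the list of pathway
    names in kind order. ``order`` maps original compartment positions to
    topological positions (from CellParams.order); required whenever the
    morphology's natural order is not topological.
    """
    names = [n for n in pathways if pathways[n].n_boutons > 0 and pathways[n].rate > 0]
    times, comps, kinds, gs = [], [], [], []
    tau1 = np.array([pathways[n].tau1 for n in names])
    tau2 = np.array([pathways[n].tau2 for n in names])
    erev = np.array([pathways[n].erev for n in names])
    rng = np.random.default_rng(seed)
    if order is not None:
        remap = np.empty(order.size, dtype=np.int64)
        remap[order] = np.arange(order.size)
    for k, name in enumerate(names):
        pw = pathways[name]
        bout_seed = int(rng.integers(0, 2**31 - 1))
        boutons = place_boutons(morph, pw, seed=bout_seed)
        for b in boutons:
            t = sample_event_phases(pw, n_cycles, theta_freq, rng=rng)
            times.append(t)
            ci = int(b) if order is None else int(remap[b])
            comps.append(np.full(t.size, ci, dtype=np.int64))
            kinds.append(np.full(t.size, k, dtype=np.int64))
            gs.append(np.full(t.size, pw.gmax_syn))
    if times:
        ev = (
            np.concatenate(times),
            np.concatenate(comps),
            np.concatenate(kinds),
            np.concatenate(gs),
            tau1, tau2, erev,
        )
    else:
        ev = (
            np.zeros(0), np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64),
            np.zeros(0), np.array([0.5]), np.array([3.0]), np.array([0.0]),
        )
    return ev, names
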