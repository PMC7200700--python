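"""Genetic-algorithm fitting of conductance scaling factors.

The fit searches over dimensionless factors multiplying each maximal
conductance (and the axial resistivity). An individual is one factor
vector; its error is the integer count of measured response features that
fall outside their experimental acceptance intervals, so error 0 means
every target is matched. Each generation, individuals that hit the target
survive with probability 0.40 and failing ones with probability 0.20 (to
preserve variability); vacated slots are refilled by uniform resampling
within bounds, and 40% of individuals are then mutated at exactly one
randomly chosen factor. The run keeps every error-0 individual it
encounters.

Feature protocols measure resting potential, input resistance, sag,
step-evoked spike count and spike amplitude from somatic current steps;
a synaptic protocol measures the somatic PSP to a synchronous CA3 bouton
volley. Validated individuals can then be propagated to other
morphologies, replacing any that fail until a full cross-validated set is
assembled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cell_model import CellParams, SimulationDiverged, build_cell, integrate
from .morphology import Morphology
from .synaptic import PathwaySpec, place_boutons

__all__ = [
    "FitnessTarget",
    "Individual",
    "cross_morphology_validate",
    "evolve",
    "intrinsic_features",
    "make_recoverable_target",
    "score",
]

INVALID = int(1e9)  # sentinel error for diverged simulations


@dataclass
class Individual:
    factors: np.ndarray
    error: int | None = None

    def key(self) -> tuple:
        return tuple(np.round(self.factors, 10))


@dataclass
class FitnessTarget:
    """Named acceptance intervals for measured features."""

    intervals: dict  # feature name -> (lo, hi)

    def __post_init__(self):
        for name, (lo, hi) in self.intervals.items():
            if lo > hi:
                raise ValueError(f"FitnessTarget: empty interval for {name}")


def intrinsic_features(
    cell: CellParams,
    dt: float = 0.05,
    step_nA: float | None = None,
    sag_nA: float | None = None,
) -> dict[str, float]:
    """Measure intrinsic response features from somatic current steps.

    Protocol: 300 ms settle; a hyperpolarizing step (input resistance and
    sag ratio); a depolarizing step (spike count and spike amplitude).
    When amplitudes are not given they are scaled to the cell's input
    conductance (a 10 mV hyperpolarization and roughly 2.5x that
    depolarizing drive), so the same protocol works from few-compartment
    reductions to full trees.
    """
    settle = 300.0
    tr0 = integrate(cell, duration=settle, dt=dt, detect=False, record=("soma",))
    v_rest = float(np.mean(tr0.v["soma"][-int(50.0 / dt):]))

    if sag_nA is None or step_nA is None:
        # probe input conductance with a small hyperpolarizing current
        # sized from the passive leak of the whole tree
        g_leak_total = float(np.sum(cell.gpas * 1e-3 * cell.area)) * 1e9  # nS
        probe = -max(2.0 * g_leak_total / 1000.0, 1e-4)  # ~2 mV deflection, nA
        pr = integrate(cell, duration=settle + 300.0, dt=dt, detect=False,
                       record=("soma",),
                       current_steps=[(cell.soma_idx, probe, settle, settle + 250.0)])
        vp = pr.v["soma"]
        v_pr = float(np.mean(vp[int((settle + 180.0) / dt):int((settle + 250.0) / dt)]))
        rin_probe = max((v_pr - v_rest) / probe, 1.0)  # MOhm
        if sag_nA is None:
            sag_nA = -10.0 / rin_probe
        if step_nA is None:
            step_nA = 25.0 / rin_probe

    hyp = integrate(
        cell, duration=settle + 400.0, dt=dt, detect=False, record=("soma",),
        current_steps=[(cell.soma_idx, sag_nA, settle, settle + 300.0)],
    )
    vh = hyp.v["soma"]
    i0, i1 = int(settle / dt), int((settle + 300.0) / dt)
    v_min = float(vh[i0:i1].min())
    v_ss = float(np.mean(vh[i1 - int(50.0 / dt):i1]))
    rin = (v_ss - v_rest) / sag_nA  # MOhm
    sag = (v_ss - v_min) / (v_rest - v_min) if v_rest != v_min else 0.0

    dep = integrate(
        cell, duration=settle + 500.0, dt=dt, record=("soma",),
        current_steps=[(cell.soma_idx, step_nA, settle, settle + 400.0)],
    )
    n_spk = int(dep.spike_times.size)
    v_peak = float(dep.v["soma"].max())
    return {
        "v_rest": v_rest,
        "input_resistance": rin,
        "sag_ratio": sag,
        "step_spike_count": float(n_spk),
        "spike_peak": v_peak,
    }


def synaptic_psp_features(
    morph: Morphology,
    factors: dict,
    ca3: PathwaySpec,
    n_syn: int = 40,
    dt: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Somatic PSP amplitude/half-width to a synchronous CA3 volley."""
    cell = build_cell(morph, factors=factors)
    boutons = place_boutons(morph, ca3, seed=seed)[:n_syn]
    remap = np.empty(cell.order.size, dtype=np.int64)
    remap[cell.order] = np.arange(cell.order.size)
    t_on = 300.0
    ev = (
        np.full(boutons.size, t_on),
        remap[boutons],
        np.zeros(boutons.size, dtype=np.int64),
        np.full(boutons.size, ca3.gmax_syn),
        np.array([ca3.tau1]), np.array([ca3.tau2]), np.array([ca3.erev]),
    )
    tr = integrate(cell, duration=t_on + 200.0, dt=dt, events=ev, detect=False,
                   record=("soma",))
    v = tr.v["soma"]
    base = float(np.mean(v[int((t_on - 50.0) / dt):int(t_on / dt)]))
    seg = v[int(t_on / dt):]
    amp = float(seg.max() - base)
    half = base + amp / 2.0
    above = np.nonzero(seg >= half)[0]
    halfwidth = float((above[-1] - above[0]) * dt) if above.size else 0.0
    return {"psp_amp": amp, "psp_halfwidth": halfwidth}


def score(measure, factors: np.ndarray, target: FitnessTarget) -> int:
    """Error = number of features outside their intervals (closed bounds).

    ``measure`` maps a factor vector to a feature dict; a diverged
    simulation yields the INVALID sentinel.
    """
    try:
        feats = measure(factors)
    except SimulationDiverged:
        return INVALID
    err = 0
    for name, (lo, hi) in target.intervals.items():
        v = feats[name]
        if not (lo <= v <= hi) or not math.isfinite(v):
            err += 1
    return err


def evolve(
    measure,
    target: FitnessTarget,
    bounds: dict[str, tuple[float, float]],
    population: int = 64,
    generations: int = 100,
    seed: int = 0,
    p_keep_success: float = 0.40,
    p_keep_failure: float = 0.20,
    mutation_fraction: float = 0.40,
    per_value_survival: bool = False,
    elitism: bool = False,
    early_stop: int | None = None,
    init: np.ndarray | None = None,
):
    """Run the genetic algorithm; returns (valid individuals, history).

    ``measure`` maps a factor vector (ordered as ``bounds``) to a feature
    dict scored against ``target``. Survival is per individual by default
    (the per-value variant redraws failing entries factor-wise). With
    ``elitism`` the best individual is always carried over, making the best
    error non-increasing. ``early_stop`` ends the run once that many valid
    individuals have been collected. Deterministic in ``seed``.
    """
    if population < 1:
        raise ValueError("evolve: empty population")
    if generations < 1:
        raise ValueError("evolve: need at least one generation")
    names = list(bounds)
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    nf = len(names)
    rng = np.random.default_rng(seed)
    cache: dict[tuple, int] = {}

    def eval_err(fac: np.ndarray) -> int:
        key = tuple(np.round(fac, 10))
        if key not in cache:
            cache[key] = score(measure, fac, target)
        return cache[key]

    if init is not None:
        pop = init.copy()
    else:
        pop = lo + rng.random((population, nf)) * (hi - lo)
    valid: dict[tuple, Individual] = {}
    history = []
    for gen in range(generations):
        errs = np.array([eval_err(p) for p in pop])
        for p, e in zip(pop, errs):
            if e == 0:
                ind = Individual(p.copy(), 0)
                valid.setdefault(ind.key(), ind)
        history.append({"generation": gen, "best_error": int(errs.min()),
                        "n_valid": len(valid),
                        "population_hash": hash(np.round(pop, 10).tobytes())})
        if early_stop is not None and len(valid) >= early_stop:
            break
        if gen == generations - 1:
            break
        keep_p = np.where(errs == 0, p_keep_success, p_keep_failure)
        survive = rng.random(population) < keep_p
        new = pop.copy()
        if per_value_survival:
            # factor-wise: non-surviving individuals keep each value with
            # the same probabilities applied per entry
            for i in range(population):
                if not survive[i]:
                    keep_each = rng.random(nf) < keep_p[i]
                    redraw = lo + rng.random(nf) * (hi - lo)
                    new[i] = np.where(keep_each, pop[i], redraw)
        else:
            for i in range(population):
                if not survive[i]:
                    new[i] = lo + rng.random(nf) * (hi - lo)
        n_mut = int(round(mutation_fraction * population))
        mut_idx = rng.choice(population, size=n_mut, replace=False)
        for i in mut_idx:
            j = rng.integers(nf)
            new[i, j] = lo[j] + rng.random() * (hi[j] - lo[j])
        history[-1]["n_mutated"] = n_mut
        if elitism:
            best = int(np.argmin(errs))
            new[0] = pop[best]
        pop = new
    return list(valid.values()), history


def make_recoverable_target(measure, true_factors: np.ndarray,
                            rel_width: float = 0.25,
                            abs_width: dict | None = None) -> FitnessTarget:
    """Build acceptance intervals around the features of a known factor set.

    Used for planted-recovery experiments: a cell simulated with
    ``true_factors`` is measured and each feature receives an interval of
    +/- rel_width (relative, with optional absolute overrides), so the
    planted vector has error 0 by construction.
    """
    feats = measure(true_factors)
    abs_width = abs_width or {}
    intervals = {}
    for name, v in feats.items():
        if name in abs_width:
            w = abs_width[name]
        else:
            w = abs(v) * rel_width if v != 0 else 1.0
        intervals[name] = (v - w, v + w)
    return FitnessTarget(intervals)


def cross_morphology_validate(
    pool: list[Individual],
    measures: dict,
    target: FitnessTarget,
    n_pick: int = 20,
    seed: int = 0,
    max_replacements: int | None = None,
):
    """Validate individuals from a reference pool across morphologies.

    ``measures`` maps morphology name -> measure callable. Randomly picks
    ``n_pick`` individuals and replaces any that fail (error > 0) on any
    morphology with fresh draws from the pool until all validate or the
    pool / replacement budget is exhausted.
    """
    if not pool:
        raise ValueError("cross_morphology_validate: empty pool")
    rng = np.random.default_rng(seed)
    remaining = list(range(len(pool)))
    rng.shuffle(remaining)
    if max_replacements is None:
        max_replacements = 10 * len(pool)

    def valid_everywhere(ind: Individual) -> bool:
        return all(score(mz, ind.factors, target) == 0 for mz in measures.values())

    picked: list[Individual] = []
    replacements = 0
    while len(picked) < n_pick:
        if not remaining or replacements > max_replacements:
            raise RuntimeError(
                f"cross_morphology_validate: pool exhausted with {len(picked)} "
                f"of {n_pick} validated"
            )
        cand = pool[remaining.pop()]
        if valid_everywhere(cand):
            picked.append(cand)
        else:
            replacements += 1
    return picked
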