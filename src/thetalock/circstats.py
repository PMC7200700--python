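"""Circular statistics for theta phase-locking analysis.

All phases are in degrees on the convention used throughout the package:
the theta trough sits at 0 (== 360) degrees and the peak at 180 degrees.
Spike phase locking is quantified with the mean vector length R (0 =
uniform firing over the cycle, 1 = perfect locking), the Rayleigh test of
circular uniformity, and a trough-peak preference index (TP index) that is
positive for trough-preferring ("superficial-like") and negative for
peak-preferring ("deep-like") cells.

Group comparisons use the Watson-Williams circular one-way ANOVA and the
Harrison-Kanji circular two-way ANOVA; both assume reasonably concentrated
(von Mises-like) samples and flag low-concentration inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sstats

__all__ = [
    "CircResult",
    "circ_dist",
    "circ_kappa",
    "circ_mean_deg",
    "circ_r",
    "circ_corr",
    "describe_phases",
    "harrison_kanji",
    "mean_vector",
    "phase_histogram",
    "rayleigh_test",
    "surrogate_modulation_test",
    "tp_index",
    "watson_williams",
    "wrap_deg",
]


def wrap_deg(phi) -> np.ndarray:
    """Wrap angles (degrees) into [0, 360)."""
    return np.asarray(phi, dtype=float) % 360.0


def _to_rad(phi_deg) -> np.ndarray:
    return np.deg2rad(wrap_deg(phi_deg))


def circ_r(phi_deg) -> float:
    """Mean vector length of a sample of phases (degrees)."""
    a = _to_rad(phi_deg)
    if a.size == 0:
        raise ValueError("circ_r: empty phase sample")
    return float(np.abs(np.exp(1j * a).mean()))


def circ_mean_deg(phi_deg) -> float:
    """Circular mean direction in degrees, in [0, 360)."""
    a = _to_rad(phi_deg)
    if a.size == 0:
        raise ValueError("circ_mean_deg: empty phase sample")
    return float(np.angle(np.exp(1j * a).mean(), deg=True) % 360.0)


def mean_vector(phi_deg) -> tuple[float, float]:
    """Return (R, mean direction degrees) of a phase sample."""
    return circ_r(phi_deg), circ_mean_deg(phi_deg)


def circ_dist(a_deg, b_deg) -> np.ndarray:
    """Signed circular distance a - b in degrees, in (-180, 180]."""
    d = (np.asarray(a_deg, float) - np.asarray(b_deg, float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


def circ_kappa(r: float, n: int | None = None) -> float:
    """ML estimate of the von Mises concentration from a resultant length.

    Uses the standard piecewise approximation (Fisher 1993), with the
    small-sample correction when ``n`` is given.
    """
    r = float(r)
    if r < 0.53:
        kappa = 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    elif r < 0.85:
        kappa = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    else:
        kappa = 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)
    if n is not None and n < 15 and n > 1:
        if kappa < 2.0:
            kappa = max(kappa - 2.0 / (n * kappa), 0.0)
        else:
            kappa = (n - 1.0) ** 3 * kappa / (n**3 + n)
    return float(kappa)


def phase_histogram(phi_deg, n_bins: int = 25) -> np.ndarray:
    """Histogram of phases over [0, 360) with ``n_bins`` equal bins.

    Bin 0 starts at 0 degrees. An empty sample yields an all-zero
    histogram.
    """
    if n_bins < 2:
        raise ValueError("phase_histogram: n_bins must be >= 2")
    phi = wrap_deg(np.atleast_1d(np.asarray(phi_deg, float)))
    counts, _ = np.histogram(phi, bins=n_bins, range=(0.0, 360.0))
    return counts


def rayleigh_test(phi_deg) -> float:
    """Rayleigh test of circular uniformity; returns the p-value.

    Requires n >= 4. Uses the standard series approximation
    p = exp(-Z) [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]
    with Z = n R^2.
    """
    phi = np.atleast_1d(np.asarray(phi_deg, float))
    n = phi.size
    if n < 4:
        raise ValueError("rayleigh_test: need at least 4 phases")
    r = circ_r(phi)
    z = n * r * r
    p = math.exp(-z) * (
        1.0
        + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n * n)
    )
    return float(min(max(p, 0.0), 1.0))


# Trough window [270, 360) U [0, 90); peak window [90, 270). With the
# trough-0 convention TP > 0 marks trough-preferring (superficial-like)
# firing and TP < 0 peak-preferring (deep-like) firing.
def tp_index(phi_deg) -> float:
    """Trough-peak preference index in [-1, 1]."""
    phi = wrap_deg(np.atleast_1d(np.asarray(phi_deg, float)))
    if phi.size == 0:
        raise ValueError("tp_index: empty phase sample")
    peak = np.sum((phi >= 90.0) & (phi < 270.0))
    trough = phi.size - peak
    return float((trough - peak) / phi.size)


@dataclass
class CircResult:
    """Summary circular statistics of one unit's spike phases."""

    n: int
    r: float
    pref_phase_deg: float
    rayleigh_p: float
    tp: float

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "R": self.r,
            "pref_phase_deg": self.pref_phase_deg,
            "rayleigh_p": self.rayleigh_p,
            "tp_index": self.tp,
        }


def describe_phases(phi_deg) -> CircResult:
    """Full circular summary (R, preferred phase, Rayleigh p, TP index)."""
    phi = np.atleast_1d(np.asarray(phi_deg, float))
    r, mu = mean_vector(phi)
    p = rayleigh_test(phi) if phi.size >= 4 else float("nan")
    return CircResult(n=int(phi.size), r=r, pref_phase_deg=mu, rayleigh_p=p, tp=tp_index(phi))


def watson_williams(*groups, warn_r: float = 0.45) -> tuple[float, float, bool]:
    """Watson-Williams multi-sample test for equal circular means.

    Parameters
    ----------
    groups : two or more sequences of phases in degrees, each with n >= 5.
    warn_r : weighted mean resultant length below which the concentration
        assumption of the test is considered violated.

    Returns
    -------
    (F, p, assumption_ok)
    """
    if len(groups) < 2:
        raise ValueError("watson_williams: need at least two groups")
    gs = [np.atleast_1d(np.asarray(g, float)) for g in groups]
    for g in gs:
        if g.size < 5:
            raise ValueError("watson_williams: each group needs n >= 5")
    k = len(gs)
    ns = np.array([g.size for g in gs], float)
    n = ns.sum()
    # unnormalized resultant lengths
    ris = np.array([g.size * circ_r(g) for g in gs])
    allphi = np.concatenate(gs)
    rtot = allphi.size * circ_r(allphi)
    rw = ris.sum() / n
    kappa = circ_kappa(rw)
    beta = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    denom = n - ris.sum()
    if denom <= 0:  # all groups perfectly concentrated
        return float("inf"), 0.0, True
    f = beta * ((n - k) * (ris.sum() - rtot)) / ((k - 1) * denom)
    f = max(f, 0.0)
    p = float(sstats.f.sf(f, k - 1, n - k))
    return float(f), p, bool(rw >= warn_r)


def harrison_kanji(phi_deg, factor_a, factor_b, warn_r: float = 0.45):
    """Harrison-Kanji two-way circular ANOVA.

    Tests main effects of two crossed factors and their interaction on the
    mean direction of concentrated circular data (F-approximation of
    Harrison & Kanji 1988, as in CircStat's circ_hktest high-concentration
    branch).

    Returns a dict with keys 'A', 'B', 'AxB', each mapping to
    (F, df1, df2, p), plus 'assumption_ok'.
    """
    phi = np.atleast_1d(np.asarray(phi_deg, float))
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (phi.size == a.size == b.size):
        raise ValueError("harrison_kanji: length mismatch")
    la, ia = np.unique(a, return_inverse=True)
    lb, ib = np.unique(b, return_inverse=True)
    p_lev, q_lev = la.size, lb.size
    if p_lev < 2 and q_lev < 2:
        raise ValueError("harrison_kanji: need >= 2 levels in at least one factor")
    if q_lev < 2 or p_lev < 2:
        # a single-level factor degenerates to the one-way analysis
        labels, idx = (la, ia) if p_lev >= 2 else (lb, ib)
        groups = [phi[idx == i] for i in range(labels.size)]
        f, p, ok = watson_williams(*groups, warn_r=warn_r)
        nan = (float("nan"),) * 4
        one_way = (f, labels.size - 1, phi.size - labels.size, p)
        return {
            "A": one_way if p_lev >= 2 else nan,
            "B": one_way if q_lev >= 2 else nan,
            "AxB": nan,
            "assumption_ok": ok,
        }
    n = phi.size
    z = np.exp(1j * np.deg2rad(phi))

    cell_n = np.zeros((p_lev, q_lev))
    cell_z = np.zeros((p_lev, q_lev), complex)
    for i in range(n):
        cell_n[ia[i], ib[i]] += 1.0
        cell_z[ia[i], ib[i]] += z[i]
    if np.any(cell_n == 0):
        bad = np.argwhere(cell_n == 0)[0]
        raise ValueError(
            f"harrison_kanji: empty cell at A={la[bad[0]]!r}, B={lb[bad[1]]!r}"
        )
    cell_r = np.abs(cell_z)
    row_r = np.abs(cell_z.sum(axis=1))  # resultant per level of A
    col_r = np.abs(cell_z.sum(axis=0))
    tot_r = np.abs(cell_z.sum())
    row_n = cell_n.sum(axis=1)
    col_n = cell_n.sum(axis=0)

    rbar = tot_r / n
    kk = circ_kappa(rbar)
    # sums of squares in resultant form
    ss_a = np.sum(row_r**2 / row_n) - tot_r**2 / n
    ss_b = np.sum(col_r**2 / col_n) - tot_r**2 / n
    ss_cells = np.sum(cell_r**2 / cell_n) - tot_r**2 / n
    ss_i = ss_cells - ss_a - ss_b
    ss_res = n - np.sum(cell_r**2 / cell_n)
    df_a = p_lev - 1
    df_b = q_lev - 1
    df_i = df_a * df_b
    df_res = n - p_lev * q_lev
    if df_res <= 0 or ss_res <= 0:
        raise ValueError("harrison_kanji: not enough residual degrees of freedom")
    beta = 1.0 / (1.0 - 1.0 / (5.0 * kk) - 1.0 / (10.0 * kk**2)) if kk > 1 else 1.0
    ms_res = ss_res / df_res

    def _ftest(ss, df):
        f = beta * (ss / df) / ms_res
        f = max(f, 0.0)
        return float(f), df, df_res, float(sstats.f.sf(f, df, df_res))

    return {
        "A": _ftest(ss_a, df_a),
        "B": _ftest(ss_b, df_b),
        "AxB": _ftest(max(ss_i, 0.0), df_i),
        "assumption_ok": bool(rbar >= warn_r),
    }


def circ_corr(a_deg, b_deg) -> tuple[float, float]:
    """Circular-circular correlation (Jammalamadaka & SenGupta).

    Returns (rho, p) for two paired angle samples in degrees.
    """
    a = _to_rad(a_deg)
    b = _to_rad(b_deg)
    if a.size != b.size or a.size < 3:
        raise ValueError("circ_corr: need paired samples of n >= 3")
    abar = math.atan2(np.sin(a).sum(), np.cos(a).sum())
    bbar = math.atan2(np.sin(b).sum(), np.cos(b).sum())
    sa = np.sin(a - abar)
    sb = np.sin(b - bbar)
    denom = math.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0:
        return 0.0, 1.0
    rho = float((sa * sb).sum() / denom)
    lam22 = np.mean(sa**2 * sb**2)
    lam20 = np.mean(sa**2)
    lam02 = np.mean(sb**2)
    if lam22 <= 0:
        return rho, 1.0
    tstat = math.sqrt(a.size * lam20 * lam02 / lam22) * abs(rho)
    p = float(2.0 * sstats.norm.sf(tstat))
    return rho, p


def surrogate_modulation_test(
    cycle_phases: Sequence[Sequence[float]],
    n_surrogates: int = 1000,
    alpha: float = 0.05,
    statistic: str = "R",
    mode: str = "redraw",
    seed: int | None = None,
):
    """Surrogate test of theta modulation for one unit.

    The unit's firing is summarized per theta cycle (``cycle_phases`` is a
    list with one array of spike phases per cycle). Each surrogate permutes
    the per-cycle spike counts across cycle identities, randomizing the
    cell's firing rate across cycles; in the default ``redraw`` mode the
    spike phases of each surrogate are then drawn uniformly over the cycle,
    giving a null of rate-matched but phase-unlocked firing. ``counts-only``
    keeps the original pooled phases and only permutes the count-to-cycle
    assignment (a weaker null retained for comparison).

    Returns
    -------
    dict with keys 'significant', 'statistic', 'null', 'p'.
    """
    counts = np.array([len(c) for c in cycle_phases], int)
    n_cycles = counts.size
    total = int(counts.sum())
    if n_cycles < 10 or (counts > 0).sum() < 10:
        raise ValueError("surrogate_modulation_test: need >= 10 cycles with spikes")
    if total < 2:
        raise ValueError("surrogate_modulation_test: too few spikes")
    phases = np.concatenate([np.atleast_1d(np.asarray(c, float)) for c in cycle_phases if len(c)])
    stat_fn = {"R": circ_r, "TP": tp_index}[statistic]
    obs = stat_fn(phases)
    rng = np.random.default_rng(seed)
    null = np.empty(n_surrogates)
    for s in range(n_surrogates):
        perm_counts = rng.permutation(counts)
        m = int(perm_counts.sum())
        if mode == "redraw":
            surr = rng.uniform(0.0, 360.0, size=m)
        elif mode == "counts-only":
            # conservative variant: counts permuted, phases bootstrapped
            # from the cell's own marginal phase distribution
            surr = rng.choice(phases, size=m, replace=True)
        else:
            raise ValueError(f"unknown surrogate mode: {mode!r}")
        null[s] = stat_fn(surr)
    if statistic == "R":
        p = float((1 + np.sum(null >= obs)) / (n_surrogates + 1))
    else:  # two-sided for the signed TP index
        p = float((1 + np.sum(np.abs(null) >= abs(obs))) / (n_surrogates + 1))
    return {
        "significant": bool(p <= alpha),
        "statistic": float(obs),
        "null": null,
        "p": p,
    }
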