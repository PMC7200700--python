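"""Rank-order test for repeating multi-unit firing sequences.

Within each theta cycle the first spike of every participating unit is
ranked chronologically and the ranks normalized to [0, 1], removing the
influence of instantaneous theta-frequency variations. Cycles with fewer
than four participating units are excluded. A cycle's sequence is deemed
significant when it has more high-correlation partners (Pearson r above a
threshold, computed over >= 4 shared units) among the other cycles than
expected under within-cycle rank shuffles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "build_rank_matrix",
    "rank_order_test",
    "rank_vector",
]

MIN_UNITS = 4


def rank_vector(cycle_spikes: dict[int, np.ndarray]) -> dict[int, float] | None:
    """Normalized first-spike ranks of one cycle, or None if < 4 units.

    Only each unit's first spike counts; ranks are (position-1)/(k-1) on
    the participating units. Exact ties are broken by unit id
    (deterministic).
    """
    firsts = {
        u: float(np.min(ts)) for u, ts in cycle_spikes.items() if len(ts) > 0
    }
    k = len(firsts)
    if k < MIN_UNITS:
        return None
    order = sorted(firsts, key=lambda u: (firsts[u], u))
    return {u: i / (k - 1) for i, u in enumerate(order)}


def build_rank_matrix(spikes: pd.DataFrame, cycles: pd.DataFrame | None = None,
                      fs: float | None = None) -> pd.DataFrame:
    """Cycles x units matrix of normalized ranks (NaN for silent units).

    ``spikes`` needs columns (unit, time_s, cycle) or (unit, time_s) with
    a cycle table + fs to assign cycles by the [start, end) sample window.
    """
    df = spikes.copy()
    if "cycle" not in df.columns:
        if cycles is None or fs is None:
            raise ValueError("build_rank_matrix: need cycle assignments or a cycle table")
        samp = (df["time_s"] * fs).astype(int)
        cyc = np.full(len(df), -1)
        for ci, row in cycles.iterrows():
            sel = (samp >= row["start"]) & (samp < row["end"])
            cyc[sel.to_numpy()] = ci
        df["cycle"] = cyc
        df = df[df["cycle"] >= 0]
    rows = {}
    for c, grp in df.groupby("cycle"):
        per_unit = {int(u): g["time_s"].to_numpy() for u, g in grp.groupby("unit")}
        rv = rank_vector(per_unit)
        if rv is not None:
            rows[c] = rv
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def _pairwise_counts(mat: np.ndarray, corr_threshold: float, min_shared: int) -> np.ndarray:
    """Per-cycle count of partners with Pearson r > threshold over shared units."""
    n = mat.shape[0]
    counts = np.zeros(n, dtype=int)
    finite = np.isfinite(mat)
    complete = finite.all()
    if complete:
        # fast path: all cycles share all units
        z = mat - mat.mean(axis=1, keepdims=True)
        denom = np.sqrt((z * z).sum(axis=1))
        ok = denom > 0
        zn = np.where(ok[:, None], z / np.where(denom == 0, 1, denom)[:, None], 0.0)
        r = zn @ zn.T
        np.fill_diagonal(r, -np.inf)
        counts = (r > corr_threshold).sum(axis=1)
        return counts
    for i in range(n):
        for j in range(i + 1, n):
            shared = finite[i] & finite[j]
            if shared.sum() < min_shared:
                continue
            a = mat[i, shared]
            b = mat[j, shared]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                continue
            r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
            if r > corr_threshold:
                counts[i] += 1
                counts[j] += 1
    return counts


def rank_order_test(
    rank_matrix: pd.DataFrame,
    n_shuffles: int = 500,
    alpha: float = 0.05,
    corr_threshold: float = 0.8,
    min_shared: int = 4,
    statistic: str = "count",
    seed: int = 0,
) -> pd.DataFrame:
    """Identify cycles whose firing order repeats above chance.

    For each cycle the number of other cycles correlated above
    ``corr_threshold`` (Pearson, >= ``min_shared`` shared units) is
    compared with the same count under ``n_shuffles`` within-cycle rank
    permutations; cycles whose real count exceeds the (1 - alpha) null
    quantile are significant. ``statistic='mean'`` uses the mean pairwise
    correlation instead of the count. Deterministic in ``seed``.

    Returns a DataFrame indexed by cycle with columns (statistic, p,
    significant).
    """
    if statistic not in ("count", "mean"):
        raise ValueError(f"rank_order_test: unknown statistic {statistic!r}")
    mat = rank_matrix.to_numpy(dtype=float)
    n = mat.shape[0]
    if n < 2:
        warnings.warn("rank_order_test: fewer than two included cycles")
        return pd.DataFrame(columns=["statistic", "p", "significant"])
    finite = np.isfinite(mat)
    # at least one cycle pair must share enough units
    share_ok = False
    for i in range(min(n, 200)):
        for j in range(i + 1, min(n, 200)):
            if (finite[i] & finite[j]).sum() >= min_shared:
                share_ok = True
                break
        if share_ok:
            break
    if not share_ok:
        warnings.warn("rank_order_test: no cycle pair shares enough units")
        return pd.DataFrame(columns=["statistic", "p", "significant"])

    if statistic == "count":
        obs = _pairwise_counts(mat, corr_threshold, min_shared).astype(float)
    else:
        obs = _mean_corr(mat, min_shared)
    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, n))
    for s in range(n_shuffles):
        shuf = mat.copy()
        for i in range(n):
            present = finite[i]
            vals = shuf[i, present]
            shuf[i, present] = rng.permutation(vals)
        if statistic == "count":
            null[s] = _pairwise_counts(shuf, corr_threshold, min_shared)
        else:
            null[s] = _mean_corr(shuf, min_shared)
    p = (1 + (null >= obs[None, :]).sum(axis=0)) / (n_shuffles + 1)
    thresh = np.quantile(null, 1.0 - alpha, axis=0)
    sig = obs > thresh
    return pd.DataFrame(
        {"statistic": obs, "p": p, "significant": sig},
        index=rank_matrix.index,
    )


def _mean_corr(mat: np.ndarray, min_shared: int) -> np.ndarray:
    n = mat.shape[0]
    finite = np.isfinite(mat)
    out = np.zeros(n)
    cnt = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            shared = finite[i] & finite[j]
            if shared.sum() < min_shared:
                continue
            a, b = mat[i, shared], mat[j, shared]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                continue
            r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
            out[i] += r
            out[j] += r
            cnt[i] += 1
            cnt[j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnt > 0, out / np.maximum(cnt, 1), 0.0)
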