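"""Theta-cycle detection and unsupervised tSC classification.

Cycles are detected on the 4-12 Hz band of the LFP with a zero-phase
(forward-backward) FIR filter: troughs are kept only when flanked by
peaks of comparable amplitude at lags consistent with the oscillation's
spectral period. Each validated cycle (peak -> trough -> peak) is
resampled to a fixed length, embedded with PCA retaining >90% of the
variance, and organized by a self-organizing map whose units are grouped
into clusters; the cluster count is chosen by the Davies-Bouldin index.
Cluster mean waveforms are then labeled by their dominant theta-nested
spectral component via a Morlet wavelet transform: tSC1 (<20 Hz at the
theta peak), tSC2 (30-40 Hz on the falling phase), tSC3 (50-60 Hz at the
peak) and tSC4 (70-90 Hz at the peak); clusters matching no signature
stay unlabeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as ssig
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA
from sklearn.metrics import davies_bouldin_score

from .circstats import circ_dist

__all__ = [
    "ThetaCycleSet",
    "classify_cycles",
    "cycle_waveforms",
    "detect_theta_cycles",
    "embed_cycles",
    "label_tsc",
    "label_tsc_stack",
    "som_classify",
]

WAVEFORM_LEN = 64  # samples per resampled cycle


@dataclass
class ThetaCycleSet:
    """Detected theta cycles with optional class labels."""

    cycles: pd.DataFrame  # columns: start, trough, end (+ label, cluster)
    fs: float
    waveforms: np.ndarray | None = None  # (n_cycles, WAVEFORM_LEN)

    def __len__(self) -> int:
        return len(self.cycles)


def detect_theta_cycles(
    lfp: np.ndarray,
    fs: float,
    band: tuple[float, float] = (4.0, 12.0),
    peak_fraction: float = 0.5,
    max_lag_fraction: float = 0.6,
    min_band_dominance: float = 0.4,
) -> ThetaCycleSet:
    """Detect theta cycles from a single-channel LFP.

    Troughs of the band-filtered signal are validated when the flanking
    peaks reach at least ``peak_fraction`` of the trough magnitude within
    ``max_lag_fraction`` of the spectral period, the implied cycle
    frequency lies inside the band, and the band-limited RMS of the cycle
    window is at least ``min_band_dominance`` of the raw RMS (continuous
    oscillation rather than broadband noise). Cycles are peak-to-peak
    windows centred on the trough (trough = phase 0 convention) and never
    overlap. Amplitude-scale invariant (up to one-sample extremum ties).
    """
    lfp = np.asarray(lfp, float)
    if fs < 250.0:
        raise ValueError("detect_theta_cycles: fs must be >= 250 Hz")
    if lfp.size < 2 * fs:
        raise ValueError("detect_theta_cycles: need at least 2 s of signal")
    if np.ptp(lfp) == 0:
        return ThetaCycleSet(pd.DataFrame(columns=["start", "trough", "end"]), fs)
    numtaps = int(3 * fs / band[0]) | 1
    fir = ssig.firwin(numtaps, band, pass_zero=False, fs=fs)
    filt = ssig.filtfilt(fir, [1.0], lfp)

    # spectral period of the band-limited oscillation
    freqs, psd = ssig.welch(filt, fs=fs, nperseg=min(filt.size, int(4 * fs)))
    sel = (freqs >= band[0]) & (freqs <= band[1])
    f0 = freqs[sel][np.argmax(psd[sel])] if sel.any() else np.mean(band)
    period = fs / f0  # samples

    min_dist = int(period / 3.0)
    troughs, _ = ssig.find_peaks(-filt, distance=min_dist)
    peaks, _ = ssig.find_peaks(filt, distance=min_dist)
    if troughs.size == 0 or peaks.size < 2:
        return ThetaCycleSet(pd.DataFrame(columns=["start", "trough", "end"]), fs)

    rows = []
    last_end = -1
    for tr in troughs:
        before = peaks[peaks < tr]
        after = peaks[peaks > tr]
        if before.size == 0 or after.size == 0:
            continue
        p0, p1 = before[-1], after[0]
        depth = -filt[tr]
        if depth <= 0:
            continue
        if filt[p0] < peak_fraction * depth or filt[p1] < peak_fraction * depth:
            continue
        if (tr - p0) > max_lag_fraction * period or (p1 - tr) > max_lag_fraction * period:
            continue
        cyc_freq = fs / (p1 - p0)
        if not (band[0] <= cyc_freq <= band[1]):
            continue
        raw_rms = float(np.sqrt(np.mean(lfp[p0:p1 + 1] ** 2)))
        band_rms = float(np.sqrt(np.mean(filt[p0:p1 + 1] ** 2)))
        if raw_rms > 0 and band_rms < min_band_dominance * raw_rms:
            continue
        if p0 < last_end:  # overlap with previous validated cycle
            continue
        rows.append({"start": int(p0), "trough": int(tr), "end": int(p1)})
        last_end = p1
    return ThetaCycleSet(pd.DataFrame(rows, columns=["start", "trough", "end"]), fs)


def cycle_waveforms(lfp: np.ndarray, cycles: pd.DataFrame,
                    length: int = WAVEFORM_LEN) -> np.ndarray:
    """Resample each cycle's raw LFP segment to a fixed length."""
    lfp = np.asarray(lfp, float)
    out = np.empty((len(cycles), length))
    grid = np.linspace(0.0, 1.0, length)
    for i, (_, row) in enumerate(cycles.iterrows()):
        seg = lfp[int(row["start"]):int(row["end"]) + 1]
        out[i] = np.interp(grid, np.linspace(0.0, 1.0, seg.size), seg)
    return out


def embed_cycles(waveforms: np.ndarray, var_target: float = 0.90):
    """PCA embedding retaining > ``var_target`` of the waveform variance.

    Returns (scores, fitted PCA or None). Degenerate input (all cycles
    identical) yields an empty embedding with a warning instead of a
    crash.
    """
    w = np.asarray(waveforms, float)
    if w.shape[0] < 20:
        raise ValueError("embed_cycles: need at least 20 cycles")
    centered = w - w.mean(axis=0)
    total_var = float(np.var(centered))
    if total_var < 1e-30:
        warnings.warn("embed_cycles: degenerate input, all cycles identical")
        return np.zeros((w.shape[0], 0)), None
    pca = PCA()
    scores = pca.fit_transform(w)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, var_target) + 1)
    k = min(k, scores.shape[1])
    return scores[:, :k], pca


class SelfOrganizingMap:
    """Minimal rectangular-grid SOM with Gaussian neighborhood.

    Online training with exponentially decaying learning rate and
    neighborhood radius; deterministic in its seed.
    """

    def __init__(self, grid: tuple[int, int] = (8, 8), n_iter: int | None = None,
                 lr0: float = 0.5, seed: int = 0):
        self.grid = grid
        self.n_iter = n_iter
        self.lr0 = lr0
        self.seed = seed
        self.weights_: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "SelfOrganizingMap":
        gx, gy = self.grid
        n_units = gx * gy
        n, d = x.shape
        if n_units > n:
            raise ValueError("SelfOrganizingMap: grid larger than sample count")
        rng = np.random.default_rng(self.seed)
        # init from random data points
        w = x[rng.choice(n, size=n_units, replace=False)].astype(float).copy()
        coords = np.array([(i, j) for i in range(gx) for j in range(gy)], float)
        n_iter = self.n_iter or 10 * n
        sigma0 = max(gx, gy) / 2.0
        order = rng.integers(0, n, size=n_iter)
        for it, idx in enumerate(order):
            frac = it / n_iter
            lr = self.lr0 * np.exp(-3.0 * frac)
            sigma = max(sigma0 * np.exp(-3.0 * frac), 0.5)
            v = x[idx]
            bmu = int(np.argmin(((w - v) ** 2).sum(axis=1)))
            dist2 = ((coords - coords[bmu]) ** 2).sum(axis=1)
            h = np.exp(-dist2 / (2.0 * sigma * sigma))
            w += lr * h[:, None] * (v - w)
        self.weights_ = w
        return self

    def bmu(self, x: np.ndarray) -> np.ndarray:
        d2 = ((x[:, None, :] - self.weights_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


def som_classify(
    scores: np.ndarray,
    grid: tuple[int, int] = (8, 8),
    k_candidates=range(2, 7),
    seed: int = 0,
    db_max: float = 1.8,
):
    """Cluster cycles via a SOM and Davies-Bouldin model selection.

    The SOM organizes the PCA scores on a topology-preserving grid; its
    unit weight vectors are grouped by similarity (agglomerative/Ward)
    for each candidate cluster count, every cycle inherits the cluster of
    its best-matching unit, and the count minimizing the Davies-Bouldin
    index on the cycle scores wins. If even the best candidate exceeds
    ``db_max`` the data are treated as a single class (k = 1).

    Returns (labels, k, db_scores dict).
    """
    scores = np.asarray(scores, float)
    n = scores.shape[0]
    if scores.ndim != 2 or scores.shape[1] == 0:
        return np.zeros(n, dtype=int), 1, {}
    som = SelfOrganizingMap(grid=grid, seed=seed).fit(scores)
    bmus = som.bmu(scores)
    results = {}
    best_k, best_db, best_labels = 1, np.inf, np.zeros(n, dtype=int)
    for k in k_candidates:
        if k < 2 or k > som.weights_.shape[0]:
            continue
        unit_labels = AgglomerativeClustering(n_clusters=k).fit_predict(som.weights_)
        labels = unit_labels[bmus]
        if np.unique(labels).size < 2:
            continue
        db = davies_bouldin_score(scores, labels)
        results[k] = float(db)
        if db < best_db:
            best_k, best_db, best_labels = k, db, labels
    if best_db > db_max:  # no candidate beats the single-class guard
        return np.zeros(n, dtype=int), 1, results
    return best_labels, best_k, results


# tSC signatures: (name, f_lo, f_hi, phase position). Phase positions are
# theta phases under the trough-0 convention; 'peak' means near 180 and
# 'falling' the descending quadrant after the peak.
_TSC_RULES = (
    ("tSC1", 13.0, 22.0, "peak"),
    ("tSC2", 27.0, 45.0, "falling"),
    ("tSC3", 46.0, 65.0, "peak"),
    ("tSC4", 66.0, 95.0, "peak"),
)


def _phase_matches(pos: str, phase_deg: float) -> bool:
    if pos == "peak":
        return abs(circ_dist(phase_deg, 180.0)) <= 75.0
    if pos == "falling":
        return 215.0 <= phase_deg <= 355.0
    raise ValueError(pos)


def label_tsc(
    mean_waveform: np.ndarray,
    cycle_duration_s: float,
    theta_freq: float | None = None,
) -> str:
    """Label one cluster mean cycle waveform with its tSC class.

    The waveform covers one full theta cycle from peak to peak (trough in
    the middle, i.e. phase 180 -> 360/0 -> 180). Its wavelet (complex
    Morlet) time-frequency map above the theta band is reduced to the
    dominant nested component; the component's frequency band and theta
    phase position select the label, or 'unlabeled' when no signature
    matches.
    """
    power, freqs = _cycle_power_map(np.asarray(mean_waveform, float),
                                    cycle_duration_s)
    return _label_from_power(power, freqs, power.shape[1])


def _cycle_power_map(w: np.ndarray, cycle_duration_s: float):
    """Wavelet power of the nested (supra-theta) content of one cycle.

    The theta component itself (DC + fundamental of the single-cycle
    window) is removed, and the cycle is circularly tiled so bursts at
    the peak (the window edges) are analyzed without boundary loss.
    """
    nlen = w.size
    fs_eff = nlen / cycle_duration_s
    spec = np.fft.rfft(w)
    spec[:2] = 0.0
    resid = np.fft.irfft(spec, nlen)
    tiled = np.concatenate([resid, resid, resid])
    freqs = np.geomspace(12.0, min(100.0, fs_eff / 2.5), 48)
    scales = pywt.frequency2scale("cmor1.5-1.0", freqs / fs_eff)
    coef, _ = pywt.cwt(tiled, scales, "cmor1.5-1.0")
    return np.abs(coef[:, nlen:2 * nlen]) ** 2, freqs  # middle copy


def _label_from_power(power: np.ndarray, freqs: np.ndarray, nlen: int) -> str:
    # compensate the 1/f background so bursts at different frequencies
    # compete on even footing
    prof = power.mean(axis=1) * freqs
    fi = int(np.argmax(prof))
    f_dom = freqs[fi]
    # position of maximal power; the cycle spans 180 -> 360/0 -> 180, so
    # both window edges map circularly to the theta peak
    ti = int(np.argmax(power[fi]))
    phase = (180.0 + 360.0 * ti / nlen) % 360.0
    for name, lo, hi, pos in _TSC_RULES:
        if lo <= f_dom <= hi:
            # sub-22 Hz components ride at twice the theta frequency, so
            # their within-cycle position is not resolvable; the band alone
            # identifies them
            if name == "tSC1" or _phase_matches(pos, phase):
                return name
    return "unlabeled"


def label_tsc_stack(waveforms: np.ndarray, cycle_duration_s: float) -> str:
    """tSC label of a cluster from its members' average wavelet power.

    Averaging the power maps rather than the waveforms keeps high-
    frequency bursts visible even when their carrier phase varies from
    cycle to cycle.
    """
    waveforms = np.atleast_2d(np.asarray(waveforms, float))
    acc = None
    freqs = None
    for w in waveforms:
        p, freqs = _cycle_power_map(w, cycle_duration_s)
        acc = p if acc is None else acc + p
    return _label_from_power(acc / waveforms.shape[0], freqs, waveforms.shape[1])


def classify_cycles(
    lfp: np.ndarray,
    fs: float,
    theta_freq_hint: float | None = None,
    grid: tuple[int, int] = (8, 8),
    k_candidates=range(2, 7),
    seed: int = 0,
) -> ThetaCycleSet:
    """Full pipeline: detect cycles, embed, SOM-cluster, label tSC classes."""
    cs = detect_theta_cycles(lfp, fs)
    if len(cs) < 20:
        cs.cycles["label"] = "unlabeled"
        return cs
    waves = cycle_waveforms(lfp, cs.cycles)
    scores, _ = embed_cycles(waves)
    labels, k, _ = som_classify(scores, grid=grid, k_candidates=k_candidates, seed=seed)
    mean_dur = float((cs.cycles["end"] - cs.cycles["start"]).mean() / fs)
    cluster_names = {}
    for c in np.unique(labels):
        cluster_names[c] = label_tsc_stack(waves[labels == c], mean_dur)
    names = [cluster_names[c] for c in labels]
    out = cs.cycles.copy()
    out["cluster"] = labels
    out["label"] = names
    return ThetaCycleSet(out, fs, waveforms=waves)
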