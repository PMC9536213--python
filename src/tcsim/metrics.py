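"""Population statistics: firing rates, ISI coefficient of variation,
oscillation spectra, synchrony, burst detection and raster export.

The population rate is binned at 5 ms for spectral analysis.  The synchrony
index is the variance of the binned population rate normalized against a
spike-time-shuffled baseline (shuffling preserves per-cell counts while
destroying coordination), clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

RATE_BIN_MS = 5.0


@dataclass
class PopulationStats:
    table: pd.DataFrame   # population, n_cells, n_spikes, rate_hz, cv_mean, cv_sd


@dataclass
class OscillationReport:
    peak_frequency: float
    peak_power: float
    synchrony_index: float


def _window(spikes: pd.DataFrame, t0: float, t1: float) -> pd.DataFrame:
    return spikes[(spikes["time"] >= t0) & (spikes["time"] < t1)]


def population_rates(spikes: pd.DataFrame, populations: dict,
                     window: tuple[float, float]) -> PopulationStats:
    """Mean rate (spikes/cell/s) and ISI CV per population.

    ``populations`` maps name -> iterable of member cell ids.  Cells with
    fewer than 3 spikes are excluded from the CV statistics (and counted).
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty analysis window")
    sub = _window(spikes, t0, t1)
    rows = []
    for pop, ids in populations.items():
        ids = np.asarray(list(ids))
        n = len(ids)
        pop_spikes = sub[sub["cell"].isin(ids)]
        rate = len(pop_spikes) / max(n, 1) / ((t1 - t0) / 1000.0)
        cvs, excluded = isi_cv(pop_spikes)
        rows.append({
            "population": pop, "n_cells": n, "n_spikes": len(pop_spikes),
            "rate_hz": rate if n else 0.0,
            "cv_mean": float(np.mean(cvs)) if len(cvs) else np.nan,
            "cv_sd": float(np.std(cvs)) if len(cvs) else np.nan,
            "cv_excluded": excluded, "empty": n == 0,
        })
    return PopulationStats(pd.DataFrame(rows))


def isi_cv(spikes: pd.DataFrame, min_spikes: int = 3):
    """Per-cell ISI coefficient of variation (sd/mean).

    Returns (array of CVs, number of cells excluded for having fewer than
    ``min_spikes`` spikes)."""
    cvs, excluded = [], 0
    for _, sub in spikes.groupby("cell"):
        t = np.sort(sub["time"].to_numpy())
        if len(t) < min_spikes:
            excluded += 1
            continue
        isi = np.diff(t)
        cvs.append(isi.std() / isi.mean())
    return np.asarray(cvs), excluded


def binned_rate(spikes: pd.DataFrame, window: tuple[float, float],
                n_cells: int, bin_ms: float = RATE_BIN_MS):
    """Population rate (Hz per cell) in fixed bins; returns (t centers, rate)."""
    t0, t1 = window
    edges = np.arange(t0, t1 + bin_ms / 2, bin_ms)
    counts, _ = np.histogram(spikes["time"].to_numpy(), bins=edges)
    rate = counts / max(n_cells, 1) / (bin_ms / 1000.0)
    return 0.5 * (edges[:-1] + edges[1:]), rate


def synchrony_index(spikes: pd.DataFrame, window: tuple[float, float],
                    n_cells: int, bin_ms: float = RATE_BIN_MS,
                    n_shuffles: int = 10, seed: int = 0) -> float:
    """Normalized population-rate variance in [0, 1].

    index = clip(1 - var_shuffled / var_observed, 0, 1): ~0 for independent
    (Poisson-like) firing, ->1 when all cells spike in lockstep.  Invariant
    under cell relabeling (it only uses merged spike times and counts)."""
    sub = _window(spikes, *window)
    if len(sub) < 2:
        return 0.0
    _, rate = binned_rate(sub, window, n_cells, bin_ms)
    v_obs = rate.var()
    if v_obs == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    t0, t1 = window
    v_sh = []
    for _ in range(n_shuffles):
        t_shuf = rng.uniform(t0, t1, size=len(sub))
        counts, _ = np.histogram(t_shuf, bins=np.arange(t0, t1 + bin_ms / 2, bin_ms))
        v_sh.append((counts / max(n_cells, 1) / (bin_ms / 1000.0)).var())
    return float(np.clip(1.0 - np.mean(v_sh) / v_obs, 0.0, 1.0))


def oscillation_peak(spikes: pd.DataFrame, band: tuple[float, float],
                     window: tuple[float, float], n_cells: int,
                     bin_ms: float = RATE_BIN_MS, seed: int = 0) -> OscillationReport:
    """Spectral peak of the population rate within ``band`` (Hz), plus the
    synchrony index.  The recording must span >= 10 cycles of the band's low
    edge."""
    f_lo, f_hi = band
    if f_hi <= f_lo or f_lo < 0:
        raise ValueError("empty frequency band")
    t0, t1 = window
    min_span = 10 * 1000.0 / max(f_lo, 1e-9)
    if (t1 - t0) < min_span:
        raise ValueError(
            f"window of {t1 - t0:.0f} ms is shorter than 10 cycles at {f_lo} Hz")
    _, rate = binned_rate(_window(spikes, t0, t1), (t0, t1), n_cells, bin_ms)
    fs = 1000.0 / bin_ms
    nper = min(len(rate), max(256, int(round(4 * fs / f_lo))))
    freqs, power = _signal.welch(rate - rate.mean(), fs=fs, nperseg=nper)
    ok = (freqs >= f_lo) & (freqs <= f_hi)
    if not ok.any():
        raise ValueError("no spectral estimate inside the requested band")
    k = np.argmax(power[ok])
    return OscillationReport(
        peak_frequency=float(freqs[ok][k]), peak_power=float(power[ok][k]),
        synchrony_index=synchrony_index(spikes, (t0, t1), n_cells,
                                        bin_ms, seed=seed))


def detect_bursts(spikes: pd.DataFrame, window: tuple[float, float],
                  n_cells: int, bin_ms: float = RATE_BIN_MS,
                  threshold_frac: float = 0.3, min_separation_ms: float = 100.0):
    """Population-burst onset times.

    A burst begins when the smoothed population rate crosses
    ``threshold_frac`` of its peak from below, with a refractory
    ``min_separation_ms`` between onsets."""
    t, rate = binned_rate(_window(spikes, *window), window, n_cells, bin_ms)
    if rate.max() == 0:
        return np.empty(0)
    k = max(1, int(round(10.0 / bin_ms)))
    kern = np.ones(k) / k
    sm = np.convolve(rate, kern, mode="same")
    thr = threshold_frac * sm.max()
    above = sm >= thr
    onsets = []
    last = -np.inf
    for i in range(1, len(above)):
        if above[i] and not above[i - 1] and t[i] - last >= min_separation_ms:
            onsets.append(t[i])
            last = t[i]
    return np.asarray(onsets)


def burst_frequency(spikes: pd.DataFrame, window: tuple[float, float],
                    n_cells: int, **kwargs) -> float:
    """Inter-burst frequency (Hz) from the median inter-onset interval."""
    onsets = detect_bursts(spikes, window, n_cells, **kwargs)
    if len(onsets) < 2:
        return 0.0
    return 1000.0 / float(np.median(np.diff(onsets)))


def raster_figure(spikes: pd.DataFrame, path, populations: dict | None = None):
    """Save a raster plot (matplotlib, Agg backend)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 6))
    ax.plot(spikes["time"], spikes["cell"], ".", ms=1.5, color="k")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("cell id")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def export_stats(stats: PopulationStats, path) -> None:
    stats.table.to_csv(path, sep="\t", index=False)
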