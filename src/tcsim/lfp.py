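"""Extracellular potentials by the line-source approximation.

Each neurite segment carries its transmembrane current uniformly along its
axis; in a homogeneous, frequency-independent ohmic medium (sigma, default
0.3 mS/mm = 0.3 S/m) the potential at an electrode is the logarithmic
closed-form integral of the point-source kernel along the segment, and the
total LFP is the superposition over all segments.  Units: currents in nA,
distances in um, potentials in uV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

#: minimum electrode-to-segment distance, um (guards the log singularity)
MIN_DISTANCE = 1.0

#: unit prefactor so that nA / (S/m * um) comes out in uV
_UNIT = 1.0e3


@dataclass(frozen=True)
class Conductivity:
    """Homogeneous, frequency-independent extracellular conductivity (mS/mm)."""

    sigma: float = 0.3

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class Segment:
    """A line segment between two distinct 3D points (um)."""

    a: tuple[float, float, float]
    b: tuple[float, float, float]

    def __post_init__(self):
        if np.allclose(self.a, self.b):
            raise ValueError("segment endpoints must be distinct")


@dataclass
class SegmentCurrentFrame:
    """Per-segment transmembrane currents (nA) at one timestep."""

    segments: list[Segment]
    currents: np.ndarray

    def __post_init__(self):
        self.currents = np.asarray(self.currents, dtype=float)
        if len(self.currents) != len(self.segments):
            raise ValueError("one current per segment required")
        if not np.all(np.isfinite(self.currents)):
            raise ValueError("currents must be finite")


def default_electrodes() -> np.ndarray:
    """The standard 8-electrode array: depths 500/1,000/1,500/2,000 um at
    radial offsets 0 and 297 um from the column axis."""
    depths = [500.0, 1000.0, 1500.0, 2000.0]
    rows = [(0.0, y, 0.0) for y in depths] + [(297.0, y, 0.0) for y in depths]
    return np.array(rows)


def line_source_potential(segment: Segment, current: float,
                          electrode, sigma: float = 0.3) -> float:
    """Potential (uV) of one segment carrying ``current`` nA.

    Closed form: phi = I / (4 pi sigma L) * [asinh((L - s)/r) + asinh(s/r)]
    where s is the electrode's axial coordinate measured from endpoint a and
    r its radial distance from the segment axis, clamped to 1 um.
    """
    a = np.asarray(segment.a, dtype=float)
    b = np.asarray(segment.b, dtype=float)
    e = np.asarray(electrode, dtype=float)
    axis = b - a
    L = float(np.linalg.norm(axis))
    u = axis / L
    s = float(np.dot(e - a, u))                # axial coordinate of electrode
    r = float(np.linalg.norm(e - a - s * u))   # radial distance
    r = max(r, MIN_DISTANCE)
    # integral of 1/sqrt(r^2 + (x - s)^2) dx over x in [0, L]
    val = np.arcsinh((L - s) / r) - np.arcsinh((0.0 - s) / r)
    return _UNIT * current / (4.0 * np.pi * sigma * L) * float(val)


def _geometry_matrix(segments: list[Segment], electrodes: np.ndarray,
                     sigma: float) -> np.ndarray:
    """(n_electrodes, n_segments) map from currents to potentials."""
    out = np.empty((len(electrodes), len(segments)))
    for j, seg in enumerate(segments):
        for i, e in enumerate(electrodes):
            out[i, j] = line_source_potential(seg, 1.0, e, sigma)
    return out


def compute_lfp(frames: list[SegmentCurrentFrame], electrodes,
                sigma: float = 0.3) -> np.ndarray:
    """(n_timesteps, n_electrodes) potential matrix by superposition.

    All frames must share one segment set (the geometry kernel is built once).
    """
    electrodes = np.atleast_2d(np.asarray(electrodes, dtype=float))
    if not frames:
        return np.zeros((0, len(electrodes)))
    segs = frames[0].segments
    for f in frames[1:]:
        if len(f.segments) != len(segs):
            raise ValueError("inconsistent segment sets across frames")
    G = _geometry_matrix(segs, electrodes, sigma)
    I = np.vstack([f.currents for f in frames])      # (T, n_seg)
    return I @ G.T


def lfp_psd(trace: np.ndarray, fs_hz: float, nperseg: int | None = None):
    """Windowed-periodogram (Welch) PSD of an LFP trace.

    Returns (frequencies Hz, power).  The trace must cover at least one
    window.
    """
    trace = np.asarray(trace, dtype=float)
    if nperseg is None:
        nperseg = min(len(trace), 1024)
    if len(trace) < nperseg or len(trace) < 8:
        raise ValueError("trace shorter than the analysis window")
    return _signal.welch(trace, fs=fs_hz, nperseg=nperseg)


def loglog_psd_slope(freqs: np.ndarray, power: np.ndarray,
                     fmin: float = 1.0, fmax: float | None = None) -> float:
    """Least-squares slope of log10(power) vs log10(frequency)."""
    fmax = freqs.max() if fmax is None else fmax
    ok = (freqs >= fmin) & (freqs <= fmax) & (power > 0)
    if ok.sum() < 3:
        raise ValueError("not enough spectral points in the requested band")
    return float(np.polyfit(np.log10(freqs[ok]), np.log10(power[ok]), 1)[0])
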