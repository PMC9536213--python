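"""Reduced single-compartment conductance-based neuron models.

Two families stand in for the morpho-electrical cell types:

- cortical cells: adaptive exponential integrate-and-fire (AdEx) two-variable
  models, one adapting excitatory and one fast-spiking inhibitory set;
- thalamic cells: integrate-and-fire augmented with a low-threshold T-type
  calcium current with instantaneous activation m_inf(V)^2 and slow,
  voltage-dependent inactivation h, giving rebound bursts after release from
  hyperpolarization and tonic firing at depolarized potentials.

Units: mV, ms, pF, nS, pA.  Fixed-step integration (default dt = 0.1 ms) with
exponential-Euler relaxation of the gating/adaptation variables; spike times
are refined by linear interpolation of the threshold crossing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PointNeuronParams:
    """Parameter set for one model cell."""

    C: float = 200.0          # membrane capacitance, pF
    g_L: float = 10.0         # leak conductance, nS
    E_L: float = -70.0        # leak reversal, mV
    V_T: float = -50.0        # spike threshold (AdEx: exponential onset), mV
    Delta_T: float = 2.0      # spike sharpness, mV (0 -> hard-threshold LIF)
    V_spike: float = 0.0      # detection/cut potential, mV
    V_reset: float = -58.0    # reset potential, mV
    t_ref: float = 2.0        # absolute refractory period, ms
    # adaptation (AdEx w)
    a: float = 0.0            # subthreshold adaptation, nS
    b: float = 0.0            # spike-triggered adaptation increment, pA
    tau_w: float = 150.0      # adaptation time constant, ms
    # low-threshold calcium current (thalamic cells; g_T = 0 disables it)
    g_T: float = 0.0          # maximal T conductance, nS
    E_Ca: float = 120.0       # calcium reversal, mV
    m_vhalf: float = -57.0    # activation midpoint, mV
    m_k: float = 6.2          # activation slope, mV
    h_vhalf: float = -81.0    # inactivation midpoint, mV
    h_k: float = 4.0          # inactivation slope, mV
    tau_h_hyper: float = 100.0  # h time constant when hyperpolarized, ms
    tau_h_depol: float = 30.0   # h time constant when depolarized, ms
    tau_h_vhalf: float = -70.0
    tau_h_k: float = 4.0


# ---------------------------------------------------------------------------
# default parameter sets (thalamic kinetics calibrated to the resting-
# potential and rebound-burst targets; see docs/methods.md)

CORTICAL_EXC = PointNeuronParams(
    C=200.0, g_L=10.0, E_L=-70.0, V_T=-50.0, Delta_T=2.0, V_spike=0.0,
    V_reset=-58.0, t_ref=2.0, a=2.0, b=40.0, tau_w=150.0)

CORTICAL_INH = PointNeuronParams(
    C=100.0, g_L=10.0, E_L=-70.0, V_T=-48.0, Delta_T=0.5, V_spike=0.0,
    V_reset=-62.0, t_ref=1.0, a=0.0, b=0.0, tau_w=20.0)

RELAY = PointNeuronParams(
    C=150.0, g_L=10.0, E_L=-63.0, V_T=-50.0, Delta_T=0.0, V_spike=-50.0,
    V_reset=-54.0, t_ref=1.5, a=0.0, b=20.0, tau_w=100.0,
    g_T=80.0, m_vhalf=-62.0, m_k=4.0, h_vhalf=-72.0, h_k=2.5,
    tau_h_hyper=45.0, tau_h_depol=15.0, tau_h_vhalf=-70.0, tau_h_k=4.0)

RTN = PointNeuronParams(
    C=150.0, g_L=10.0, E_L=-80.0, V_T=-58.0, Delta_T=0.0, V_spike=-58.0,
    V_reset=-58.0, t_ref=1.5, a=0.0, b=45.0, tau_w=150.0,
    g_T=200.0, m_vhalf=-66.0, m_k=5.0, h_vhalf=-90.0, h_k=3.0,
    tau_h_hyper=110.0, tau_h_depol=10.0, tau_h_vhalf=-68.0, tau_h_k=4.0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class NeuronGroup:
    """Vectorized state for n cells sharing the model equations (parameters
    may differ per cell)."""

    PARAM_FIELDS = [f for f in PointNeuronParams.__dataclass_fields__]

    def __init__(self, params_per_cell: list[PointNeuronParams], dt: float = 0.1):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.n = len(params_per_cell)
        self.dt = float(dt)
        for f in self.PARAM_FIELDS:
            setattr(self, f, np.array([getattr(p, f) for p in params_per_cell],
                                      dtype=float))
        self.v = self.E_L.copy()
        self.w = np.zeros(self.n)
        self.h = self._h_inf(self.v)
        self.ref = np.zeros(self.n)       # remaining refractory time, ms
        self._v_prev = self.v.copy()

    # gating steady states ---------------------------------------------------
    def _m_inf(self, v):
        return _sigmoid((v - self.m_vhalf) / self.m_k)

    def _h_inf(self, v):
        return _sigmoid(-(v - self.h_vhalf) / self.h_k)

    def _tau_h(self, v):
        frac = _sigmoid(-(v - self.tau_h_vhalf) / self.tau_h_k)
        return self.tau_h_depol + (self.tau_h_hyper - self.tau_h_depol) * frac

    def t_current(self, v=None):
        """Low-threshold calcium current, pA (positive = depolarizing)."""
        v = self.v if v is None else v
        return self.g_T * self._m_inf(v) ** 2 * self.h * (self.E_Ca - v)

    def step(self, i_ext=0.0):
        """One integration step.  ``i_ext`` is the total external + synaptic
        current in pA (scalar or per-cell).  Returns (spike mask, fractional
        spike-time offsets in ms within the step)."""
        dt = self.dt
        v, w, h = self.v, self.w, self.h

        # gating and adaptation relax exponentially toward their targets
        h += (self._h_inf(v) - h) * (1.0 - np.exp(-dt / self._tau_h(v)))
        w += (self.a * (v - self.E_L) - w) * (1.0 - np.exp(-dt / self.tau_w))

        i_ion = -self.g_L * (v - self.E_L) - w + self.t_current(v)
        exp_drive = np.where(
            self.Delta_T > 0,
            self.g_L * np.where(self.Delta_T > 0, self.Delta_T, 1.0)
            * np.exp(np.minimum((v - self.V_T)
                                / np.where(self.Delta_T > 0, self.Delta_T, 1.0), 20.0)),
            0.0,
        )
        dv = (i_ion + exp_drive + i_ext) / self.C
        self._v_prev[:] = v
        v_new = v + dt * dv

        active = self.ref <= 0
        v = np.where(active, v_new, self.V_reset)
        if not np.all(np.isfinite(v)):
            bad = int(np.argmax(~np.isfinite(v)))
            raise FloatingPointError(f"non-finite membrane potential in cell {bad}")

        spikes = active & (v >= self.V_spike)
        # linear interpolation of the crossing inside the step
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = (self.V_spike - self._v_prev) / (v - self._v_prev)
        offsets = np.where(spikes, np.clip(frac, 0.0, 1.0) * dt, 0.0)

        v = np.where(spikes, self.V_reset, v)
        self.w = np.where(spikes, w + self.b, w)
        self.h = h
        self.ref = np.where(spikes, self.t_ref, np.maximum(self.ref - dt, 0.0))
        self.v = v
        return spikes, offsets


def simulate_current_clamp(params: PointNeuronParams, i_inj: np.ndarray,
                           dt: float = 0.1):
    """Single-cell run under an injected-current waveform (pA per step).

    Returns (voltage trace, spike times in ms)."""
    grp = NeuronGroup([params], dt=dt)
    v_trace = np.empty(len(i_inj))
    spike_times = []
    for k, i in enumerate(i_inj):
        spk, off = grp.step(float(i))
        v_trace[k] = grp.v[0]
        if spk[0]:
            spike_times.append(k * dt + off[0])
    return v_trace, np.array(spike_times)


def resting_potential(params: PointNeuronParams, duration: float = 1000.0,
                      dt: float = 0.1) -> float:
    """Steady-state membrane potential after ``duration`` ms of zero input."""
    v, spikes = simulate_current_clamp(params, np.zeros(int(duration / dt)), dt)
    if len(spikes):
        raise RuntimeError("cell is not quiescent at rest")
    if abs(v[-1] - v[len(v) // 2]) > 0.5:
        raise RuntimeError("resting potential did not converge")
    return float(v[-1])


def f_i_curve(params: PointNeuronParams, currents_pA, duration: float = 1000.0,
              dt: float = 0.1) -> np.ndarray:
    """Mean firing rate (Hz) for each constant injected current."""
    rates = []
    for i0 in currents_pA:
        _, spikes = simulate_current_clamp(
            params, np.full(int(duration / dt), float(i0)), dt)
        rates.append(len(spikes) / (duration / 1000.0))
    return np.asarray(rates)


def rebound_burst_test(params: PointNeuronParams, pulse_pA: float = -200.0,
                       pulse_ms: float = 500.0, window_ms: float = 50.0,
                       settle_ms: float = 500.0, dt: float = 0.1) -> int:
    """Spike count within ``window_ms`` of release from a hyperpolarizing
    pulse.  A value >= 2 indicates a rebound burst."""
    n_settle = int(settle_ms / dt)
    n_pulse = int(pulse_ms / dt)
    n_post = int((window_ms + 150.0) / dt)
    i = np.concatenate([np.zeros(n_settle), np.full(n_pulse, pulse_pA),
                        np.zeros(n_post)])
    _, spikes = simulate_current_clamp(params, i, dt)
    t_release = (n_settle + n_pulse) * dt
    return int(np.sum((spikes >= t_release) & (spikes <= t_release + window_ms)))


def burst_vs_holding(params: PointNeuronParams, holding_currents_pA,
                     step_pA: float = 150.0, settle_ms: float = 1000.0,
                     window_ms: float = 40.0, dt: float = 0.1) -> np.ndarray:
    """Early spike count after a fixed depolarizing step, across holding levels.

    The holding current sets the membrane potential (and hence T-current
    de-inactivation) before a common +``step_pA`` step; hyperpolarized holding
    yields a burst (many early spikes), depolarized holding a tonic onset, so
    the count decreases with the holding potential.
    """
    out = []
    n_settle = int(settle_ms / dt)
    for i_hold in holding_currents_pA:
        i = np.concatenate([
            np.full(n_settle, float(i_hold)),
            np.full(int(200.0 / dt), float(step_pA)),
        ])
        _, spikes = simulate_current_clamp(params, i, dt)
        t0 = settle_ms
        out.append(int(np.sum((spikes >= t0) & (spikes <= t0 + window_ms))))
    return np.asarray(out)
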