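"""Deterministic Tsodyks–Markram short-term plasticity and the
dual-exponential conductance kernel.

State per synapse: utilization u and a stored post-release resource level
R+ = R*(1 - u).  On a spike after interval dt:

    u  <- U + u*(1 - U)*exp(-dt/F)          (facilitation, applied first)
    R  <- 1 + (R+ - 1)*exp(-dt/D)           (recovery from depression)
    release = u * R
    R+ <- R * (1 - u)

so the first spike of a train releases exactly U.  The released fraction
scales a dual-exponential conductance with rise time 0.2 ms, peak-normalized
to the synapse's peak conductance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .registry import SynapseClass


@dataclass(frozen=True)
class TMState:
    """Tsodyks–Markram synapse state (between spikes)."""

    u: float = 0.0
    R_plus: float = 1.0
    t_last: float = -np.inf

    def __post_init__(self):
        if not (0.0 <= self.u <= 1.0 and 0.0 <= self.R_plus <= 1.0):
            raise ValueError("u and R must lie in [0, 1]")


@dataclass(frozen=True)
class ConductanceEvent:
    onset: float          # ms
    weight: float         # nS, g_syn * u * R at the spike
    tau_rise: float = 0.2
    tau_decay: float = 1.74


def tm_on_spike(state: TMState, U: float, D: float, F: float,
                t_spike: float) -> tuple[TMState, float]:
    """Advance the TM map through one presynaptic spike.

    Returns the new state and the release fraction u*R.  F -> 0 collapses u
    to the constant U (pure depression); D -> 0 collapses R to 1 (pure
    facilitation).
    """
    dt = t_spike - state.t_last
    if dt < 0:
        raise ValueError(f"spike at {t_spike} precedes last spike {state.t_last}")
    decay_f = np.exp(-dt / F) if F > 0 else 0.0
    decay_d = np.exp(-dt / D) if D > 0 else 0.0
    u = U + state.u * (1.0 - U) * decay_f
    R = 1.0 + (state.R_plus - 1.0) * decay_d
    release = u * R
    return TMState(u=u, R_plus=R * (1.0 - u), t_last=t_spike), release


def tm_train(spike_times, U: float, D: float, F: float) -> np.ndarray:
    """Release fractions for a whole spike train."""
    state = TMState()
    out = []
    for t in spike_times:
        state, rel = tm_on_spike(state, U, D, F, t)
        out.append(rel)
    return np.asarray(out)


def tm_steady_state(isi: float, U: float, D: float, F: float) -> float:
    """Closed-form fixed point of the TM map under periodic stimulation:

        u* = U / (1 - (1 - U) e^(-ISI/F))
        R* = (1 - e^(-ISI/D)) / (1 - (1 - u*) e^(-ISI/D))

    Returns the steady-state release u* R*.
    """
    ef = np.exp(-isi / F) if F > 0 else 0.0
    ed = np.exp(-isi / D) if D > 0 else 0.0
    u_star = U / (1.0 - (1.0 - U) * ef)
    r_star = (1.0 - ed) / (1.0 - (1.0 - u_star) * ed)
    return u_star * r_star


def dual_exp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time-to-peak of the dual-exponential difference kernel."""
    return (tau_rise * tau_decay / (tau_decay - tau_rise)
            * np.log(tau_decay / tau_rise))


def dual_exp_norm(tau_rise: float, tau_decay: float) -> float:
    """Factor normalizing the kernel's peak to 1."""
    tp = dual_exp_peak_time(tau_rise, tau_decay)
    return 1.0 / (np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise))


def conductance_waveform(event: ConductanceEvent, t) -> np.ndarray:
    """g(t) of one conductance event; 0 before onset, peak equals weight."""
    if event.tau_decay <= event.tau_rise:
        raise ValueError("tau_decay must exceed tau_rise")
    t = np.asarray(t, dtype=float)
    dt = t - event.onset
    g = np.where(
        dt >= 0,
        event.weight * dual_exp_norm(event.tau_rise, event.tau_decay)
        * (np.exp(-np.maximum(dt, 0) / event.tau_decay)
           - np.exp(-np.maximum(dt, 0) / event.tau_rise)),
        0.0,
    )
    return g


def run_psp_protocol(cls: SynapseClass, spike_times, n_repeats: int = 20,
                     rng: np.random.Generator | None = None,
                     leak_g: float = 10.0, leak_E: float = -70.0,
                     capacitance: float = 200.0, E_syn: float | None = None,
                     dt: float = 0.025) -> np.ndarray:
    """Per-spike PSP peak amplitudes (mV, relative to rest) on a passive cell.

    Each repeat samples fresh synapse parameters from the class; amplitudes
    are averaged across repeats.  The target is a passive single-compartment
    cell (leak_g nS, capacitance pF), so only the *relative* amplitude
    sequence is physiologically meaningful.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    spike_times = np.asarray(spike_times, dtype=float)
    if E_syn is None:
        E_syn = 0.0 if cls.excitatory else -80.0
    t_end = spike_times.max() + 5.0 * cls.tau_decay[0] + 50.0
    t = np.arange(0.0, t_end, dt)
    amps = np.zeros(len(spike_times))
    for _ in range(n_repeats):
        g_syn = max(rng.normal(*cls.g_syn), 0.01 * cls.g_syn[0])
        tau_d = max(rng.normal(*cls.tau_decay), cls.TAU_RISE * 1.5)
        U = min(max(rng.normal(*cls.U), 0.01 * cls.U[0]), 1.0)
        D = max(rng.normal(*cls.D), 0.01 * cls.D[0])
        F = max(rng.normal(*cls.F), 0.01 * cls.F[0])
        releases = tm_train(spike_times, U, D, F)
        g = np.zeros_like(t)
        for ts, rel in zip(spike_times, releases):
            g += conductance_waveform(
                ConductanceEvent(ts, g_syn * rel, cls.TAU_RISE, tau_d), t)
        # passive membrane: C dV/dt = -gL (V - EL) - g (V - E_syn)
        v = np.full_like(t, leak_E)
        for i in range(1, len(t)):
            dv = (-leak_g * (v[i - 1] - leak_E)
                  - g[i - 1] * (v[i - 1] - E_syn)) / capacitance
            v[i] = v[i - 1] + dt * dv
        dev = np.abs(v - leak_E)
        edges = np.searchsorted(t, np.append(spike_times, t_end))
        for k in range(len(spike_times)):
            amps[k] += dev[edges[k]:edges[k + 1]].max()
    return amps / n_repeats
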