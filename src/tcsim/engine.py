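"""Clock-driven network simulation.

Integrates all cells as one vectorized group, delivers spikes through
Tsodyks–Markram synapses with per-edge delays (a ring buffer binned by dt),
supports replay (spike-source) cells, Poisson background drive, and records
spikes, selected voltages and selected per-cell synaptic currents.

Conductances are dual-exponential, maintained per (receptor, decay-constant)
channel and per cell as a pair of decaying exponentials; synapses are grouped
onto the channel whose decay constant is their class mean (``tau_channel``),
while the per-synapse sampled kinetics remain in the connectome tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .builder import BackgroundStimulus, Connectome
from .geometry import CellInstance
from .neurons import NeuronGroup, PointNeuronParams

RECEPTOR_REVERSAL = {"AMPA": 0.0, "GABA_A": -80.0, "GABA_B": -95.0}

#: background drive kernels (receptor, tau_rise, tau_decay)
BG_EXC_KERNEL = ("AMPA", 0.2, 1.74)
BG_INH_KERNEL = ("GABA_A", 0.2, 8.3)


@dataclass
class SimulationConfig:
    dt: float = 0.1                 # ms
    duration: float = 2000.0        # ms
    transient: float = 1000.0       # ms discarded by analysis helpers
    seed: int = 0
    stp: bool = True                # short-term plasticity on recurrent edges
    record_voltages: tuple = ()     # cell ids
    record_currents: tuple = ()     # cell ids (net synaptic current, pA)

    def __post_init__(self):
        if self.dt <= 0 or self.duration <= self.transient:
            raise ValueError("need dt > 0 and duration > transient")


@dataclass
class SimResult:
    spikes: pd.DataFrame            # columns cell, time (ms), sorted by time
    config: SimulationConfig
    voltages: dict = field(default_factory=dict)
    currents: dict = field(default_factory=dict)
    n_cells: int = 0

    def spikes_after_transient(self) -> pd.DataFrame:
        return self.spikes[self.spikes["time"] >= self.config.transient]


class Simulation:
    """A network ready to run: cells + connectome + background + replay."""

    def __init__(self, cells: list[CellInstance],
                 params_map: dict[str, PointNeuronParams],
                 connectome: Connectome | None = None,
                 background: BackgroundStimulus | None = None,
                 replay: dict | None = None):
        self.cells = cells
        self.n = max(c.id for c in cells) + 1 if cells else 0
        if any(c.id >= self.n or c.id < 0 for c in cells):
            raise ValueError("cell ids must be dense non-negative")
        self.params_map = params_map
        self.connectome = connectome
        self.background = background
        self.replay = {} if replay is None else dict(replay)
        for cid in self.replay:
            if cid >= self.n:
                raise ValueError(f"replay id {cid} is not a placed cell")

    # ------------------------------------------------------------------
    def _build_channels(self, syn: pd.DataFrame):
        keys = [BG_EXC_KERNEL, BG_INH_KERNEL]
        if len(syn):
            for rec, tr, tc in zip(syn["receptor"], syn["tau_rise"],
                                   syn["tau_channel"]):
                k = (rec, round(float(tr), 3), round(float(tc), 3))
                if k not in keys:
                    keys.append(k)
        return keys

    def run(self, config: SimulationConfig) -> SimResult:
        dt = config.dt
        n_steps = int(round(config.duration / dt))
        rng = np.random.default_rng(config.seed)

        replay_ids = np.array(sorted(self.replay), dtype=int)
        is_replay = np.zeros(self.n, dtype=bool)
        is_replay[replay_ids] = True

        params = [self.params_map[c.population] for c in
                  sorted(self.cells, key=lambda c: c.id)]
        group = NeuronGroup(params, dt=dt)

        syn = (self.connectome.synapses if self.connectome is not None
               else pd.DataFrame(columns=Connectome.SYN_COLS))
        channels = self._build_channels(syn)
        nchan = len(channels)
        chan_index = {k: i for i, k in enumerate(channels)}
        tau_r = np.array([k[1] if len(k) == 3 else k[1] for k in channels])
        tau_d = np.array([k[2] for k in channels])
        e_rev = np.array([RECEPTOR_REVERSAL[k[0]] for k in channels])
        fd = np.exp(-dt / tau_d)
        fr = np.exp(-dt / tau_r)
        tp = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
        norm = 1.0 / (np.exp(-tp / tau_d) - np.exp(-tp / tau_r))

        # synapse arrays sorted by presynaptic id
        if len(syn):
            order = np.argsort(syn["pre"].to_numpy(), kind="stable")
            s_pre = syn["pre"].to_numpy()[order].astype(np.int64)
            s_post = syn["post"].to_numpy()[order].astype(np.int64)
            s_w = syn["g_syn"].to_numpy()[order].astype(float)
            s_U = syn["U"].to_numpy()[order].astype(float)
            s_D = syn["D"].to_numpy()[order].astype(float)
            s_F = syn["F"].to_numpy()[order].astype(float)
            s_delay = np.maximum(
                1, np.rint(syn["delay"].to_numpy()[order] / dt)).astype(np.int64)
            s_chan = np.array([
                chan_index[(r, round(float(a), 3), round(float(b), 3))]
                for r, a, b in zip(syn["receptor"].to_numpy()[order],
                                   syn["tau_rise"].to_numpy()[order],
                                   syn["tau_channel"].to_numpy()[order])],
                dtype=np.int64)
            indptr = np.searchsorted(s_pre, np.arange(self.n + 1))
        else:
            s_pre = s_post = s_w = s_U = s_D = s_F = s_delay = s_chan = \
                np.empty(0)
            indptr = np.zeros(self.n + 1, dtype=np.int64)

        n_syn = len(s_pre)
        tm_u = np.zeros(n_syn)
        tm_R = np.ones(n_syn)
        tm_tlast = np.full(n_syn, -1.0e18)
        tm_D_safe = np.maximum(s_D, 1e-9) if n_syn else s_D
        tm_F_safe = np.maximum(s_F, 1e-9) if n_syn else s_F

        buf_len = int(s_delay.max()) + 1 if n_syn else 1
        buf = np.zeros((buf_len, nchan, self.n))
        gd = np.zeros((nchan, self.n))
        gr = np.zeros((nchan, self.n))

        # background
        bg = self.background
        if bg is not None:
            bg_mask = np.zeros(self.n, dtype=bool)
            bg_mask[bg.cell_ids] = True
            lam_e = bg.n_sources * bg.exc_rate * dt / 1000.0
            lam_i = bg.n_sources * bg.inh_rate * dt / 1000.0
            i_bg_e = chan_index[BG_EXC_KERNEL]
            i_bg_i = chan_index[BG_INH_KERNEL]

        # replay schedule: per-step spike lists
        if len(replay_ids):
            rep_cells = np.concatenate([
                np.full(len(self.replay[c]), c, dtype=np.int64)
                for c in replay_ids])
            rep_steps = np.concatenate([
                np.asarray(np.rint(np.asarray(self.replay[c]) / dt), dtype=np.int64)
                for c in replay_ids])
            o = np.argsort(rep_steps, kind="stable")
            rep_cells, rep_steps = rep_cells[o], rep_steps[o]
            rep_ptr_all = np.searchsorted(rep_steps, np.arange(n_steps + 1))
        else:
            rep_cells = rep_steps = np.empty(0, dtype=np.int64)
            rep_ptr_all = np.zeros(n_steps + 1, dtype=np.int64)

        rec_v_ids = np.array(sorted(config.record_voltages), dtype=int)
        rec_i_ids = np.array(sorted(config.record_currents), dtype=int)
        v_out = np.empty((n_steps, len(rec_v_ids))) if len(rec_v_ids) else None
        i_out = np.empty((n_steps, len(rec_i_ids))) if len(rec_i_ids) else None

        spike_cells: list[np.ndarray] = []
        spike_times: list[np.ndarray] = []
        integrated = ~is_replay

        for step in range(n_steps):
            t_now = step * dt
            # conductance decay and delivery of due events
            gd *= fd[:, None]
            gr *= fr[:, None]
            slot = step % buf_len
            gd += buf[slot]
            gr += buf[slot]
            buf[slot] = 0.0

            if bg is not None:
                ne = rng.poisson(lam_e, self.n)
                ni = rng.poisson(lam_i, self.n)
                inc_e = np.where(bg_mask, ne * bg.g_exc, 0.0)
                inc_i = np.where(bg_mask, ni * bg.g_inh, 0.0)
                gd[i_bg_e] += inc_e
                gr[i_bg_e] += inc_e
                gd[i_bg_i] += inc_i
                gr[i_bg_i] += inc_i

            g = norm[:, None] * (gd - gr)
            i_syn = np.einsum("cn,cn->n", g, e_rev[:, None] - group.v)

            spk, offs = group.step(i_syn)
            spk &= integrated
            ids = np.nonzero(spk)[0]
            if len(ids):
                spike_cells.append(ids)
                spike_times.append(t_now + offs[ids])
            if not np.all(np.isfinite(group.v)):
                raise FloatingPointError(
                    f"numerical blow-up at t={t_now:.1f} ms")

            # replay spikes due this step
            a, b = rep_ptr_all[step], rep_ptr_all[step + 1]
            if b > a:
                r_ids = rep_cells[a:b]
                spike_cells.append(r_ids)
                spike_times.append(np.full(len(r_ids), t_now))
                ids = np.concatenate([ids, r_ids])

            if len(ids) and n_syn:
                rows = np.concatenate([
                    np.arange(indptr[i], indptr[i + 1]) for i in ids])
                if len(rows):
                    t_spk = t_now
                    if config.stp:
                        delta = t_spk - tm_tlast[rows]
                        df_ = np.exp(-delta / tm_F_safe[rows])
                        dd_ = np.exp(-delta / tm_D_safe[rows])
                        u = s_U[rows] + tm_u[rows] * (1 - s_U[rows]) * df_
                        R = 1.0 + (tm_R[rows] - 1.0) * dd_
                        release = u * R
                        tm_u[rows] = u
                        tm_R[rows] = R * (1.0 - u)
                        tm_tlast[rows] = t_spk
                    else:
                        release = s_U[rows]
                    w_rel = s_w[rows] * release
                    slots = (step + s_delay[rows]) % buf_len
                    np.add.at(buf, (slots, s_chan[rows], s_post[rows]), w_rel)

            if v_out is not None:
                v_out[step] = group.v[rec_v_ids]
            if i_out is not None:
                i_out[step] = i_syn[rec_i_ids]

        if spike_cells:
            cells_arr = np.concatenate(spike_cells)
            times_arr = np.concatenate(spike_times)
            o = np.argsort(times_arr, kind="stable")
            spikes = pd.DataFrame({"cell": cells_arr[o], "time": times_arr[o]})
        else:
            spikes = pd.DataFrame({"cell": pd.Series(dtype=int),
                                   "time": pd.Series(dtype=float)})
        result = SimResult(spikes=spikes, config=config, n_cells=self.n)
        for k, cid in enumerate(rec_v_ids):
            result.voltages[int(cid)] = v_out[:, k]
        for k, cid in enumerate(rec_i_ids):
            result.currents[int(cid)] = i_out[:, k]
        return result


def run_simulation(cells, params_map, connectome, background,
                   config: SimulationConfig) -> SimResult:
    """Build-and-run convenience wrapper."""
    return Simulation(cells, params_map, connectome, background).run(config)


def replay_from_spikes(spikes: pd.DataFrame, cell_ids) -> dict:
    """Per-cell spike-train dict covering ``cell_ids`` (empty trains included)."""
    trains = {int(c): np.empty(0) for c in cell_ids}
    for c, sub in spikes.groupby("cell"):
        c = int(c)
        if c in trains:
            trains[c] = sub["time"].to_numpy()
    return trains


def run_hybrid(cells, params_map, connectome, background,
               detailed_ids, replay: dict, config: SimulationConfig) -> SimResult:
    """Integrate only ``detailed_ids``; all other cells replay fixed trains.

    Every non-detailed cell must have a train in ``replay`` (possibly empty),
    so the detailed subset sees exactly the presynaptic activity of the source
    run.
    """
    detailed = set(int(i) for i in detailed_ids)
    all_ids = set(c.id for c in cells)
    missing = all_ids - detailed - set(int(k) for k in replay)
    if missing:
        raise ValueError(
            f"missing replay trains for {len(missing)} non-detailed cells "
            f"(e.g. {sorted(missing)[:5]})")
    rep = {int(k): v for k, v in replay.items() if int(k) not in detailed}
    sim = Simulation(cells, params_map, connectome, background, replay=rep)
    return sim.run(config)


def grid_search_background(cells, params_map, connectome, exc_grid, inh_grid,
                           objective, config: SimulationConfig,
                           bg_kwargs: dict | None = None):
    """Evaluate ``objective(SimResult)`` on every (exc, inh) rate pair.

    Returns (best (exc, inh) rates, table DataFrame with the objective per
    grid point; the argmin row is flagged).
    """
    from .builder import attach_background
    if not len(exc_grid) or not len(inh_grid):
        raise ValueError("grids must be non-empty")
    rows = []
    for e in exc_grid:
        for i in inh_grid:
            bg = attach_background(cells, e, i, seed=config.seed,
                                   **(bg_kwargs or {}))
            res = Simulation(cells, params_map, connectome, bg).run(config)
            rows.append({"exc_rate": e, "inh_rate": i,
                         "objective": float(objective(res))})
    table = pd.DataFrame(rows)
    k = int(table["objective"].idxmin())
    table["best"] = False
    table.loc[k, "best"] = True
    return (table.loc[k, "exc_rate"], table.loc[k, "inh_rate"]), table
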