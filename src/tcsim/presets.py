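"""Preset desk-scale study circuits.

Two standard networks are used throughout the tests and the reproduction
script:

- ``scaled_thalamic_network``: the six-population thalamic circuit (outer,
  middle and inner reticular sectors plus VPL, VPM and POm) at a reduced
  scale, wired with the three intrathalamic strategies and driven by Poisson
  background.  Its recurrent relay<->reticular loops generate self-sustained
  rhythmic bursting in the theta range (~6 Hz), carried mainly by the
  divergence-coupled POm/inner-sector loop.

- ``scaled_cortical_column``: a reduced S1 column built end-to-end through
  the probabilistic pipeline — ground-truth distance rules, stochastic
  connectome instances, bin/average/fit/select, then Bernoulli wiring with
  registry synapses.  With short-term plasticity on recurrent connections it
  exhibits slow synchronous bursting near 1 Hz (depression-paced); applying
  the low-calcium U scaling shifts it toward the asynchronous in-vivo-like
  state.

Reduced in-degree at scale s is compensated by scaling synaptic conductances
by 1/s (config-overridable).  Background rates below were tuned by grid
search at the default scales.
"""

from __future__ import annotations

import zlib

import numpy as np

from . import builder, connectivity, geometry, neurons, synth
from .registry import CalciumState, SynapseRegistry, load_synapse_table

# --------------------------------------------------------------------------
# thalamic preset

THALAMIC_SCALE = 0.10
THALAMIC_BG = dict(exc_rate=15.0, inh_rate=0.0, g_exc=2.5, g_inh=1.0)
THALAMIC_WEIGHTS = {"relay_rtn": 20.0, "rtn_relay": 20.0, "rtn_rtn": 2.0}
THALAMIC_DIVERGENCE = 20
THALAMIC_GABA_B_TAU = (5.0, 45.0)   # rise, decay (ms)

THALAMIC_PARAMS = {
    "RTNo": neurons.RTN, "RTNm": neurons.RTN, "RTNi": neurons.RTN,
    "VPL": neurons.RELAY, "VPM": neurons.RELAY, "POm": neurons.RELAY,
}


def scaled_thalamic_network(scale: float = THALAMIC_SCALE, seed: int = 0,
                            weights: dict | None = None,
                            divergence: int = THALAMIC_DIVERGENCE,
                            bg: dict | None = None,
                            gaba_b_tau: tuple = THALAMIC_GABA_B_TAU):
    """Build the scaled thalamic circuit.

    Returns (cells, params_map, connectome, background)."""
    geom = geometry.ThalamicGeometry()
    counts = geometry.default_thalamic_counts().copy()
    counts["count"] = np.maximum(1, np.rint(counts["count"] * scale)).astype(int)
    cells = geometry.place_thalamic_cells(geom, counts, seed=seed)
    conn = builder.build_intrathalamic(
        cells, geom.bounds(), seed=seed + 1,
        divergence=builder.DivergenceRule(divergence),
        weights=dict(THALAMIC_WEIGHTS, **(weights or {})),
        gaba_b_tau=gaba_b_tau)
    bg_cfg = dict(THALAMIC_BG, **(bg or {}))
    background = builder.attach_background(
        cells, bg_cfg["exc_rate"], bg_cfg["inh_rate"], seed=seed + 2,
        g_exc=bg_cfg["g_exc"], g_inh=bg_cfg["g_inh"])
    return cells, dict(THALAMIC_PARAMS), conn, background


# --------------------------------------------------------------------------
# cortical preset

CORTICAL_SCALE = 0.05
CORTICAL_BG = dict(exc_rate=17.0, inh_rate=4.25, g_exc=4.0, g_inh=4.0)

#: ground-truth distance-rule families per pathway kind (amplitude, length
#: constants in um); these define the synthetic connectome the column is
#: fitted from.
GT_EE_SAME = ("exp_linsat", (0.35, 120.0, 0.12))
GT_SAME_LAYER = ("exponential", (0.15, 150.0))
GT_CROSS_LAYER = ("gaussian", (0.08, 0.0, 180.0))
GT_INH = ("exponential", (0.20, 120.0))

MEAN_NSYN_EXC = 3.0
MEAN_NSYN_INH = 6.0


def ground_truth_pathways(populations, registry: SynapseRegistry,
                          layer_of: dict) -> dict:
    """Assign a generating rule to every ordered population pair."""
    out = {}
    for pre in populations:
        for post in populations:
            pre_exc = registry.is_excitatory(pre)
            same_layer = layer_of[pre] == layer_of[post]
            if not pre_exc:
                form, params = GT_INH
            elif pre == post:
                form, params = GT_EE_SAME
            elif same_layer:
                form, params = GT_SAME_LAYER
            else:
                form, params = GT_CROSS_LAYER
            nsyn = MEAN_NSYN_EXC if pre_exc else MEAN_NSYN_INH
            out[(pre, post)] = synth.GroundTruthPathway(form, params, nsyn)
    return out


def fit_pathway_rules(cells, gt: dict, seed: int, n_instances: int = 7) -> list:
    """Run the estimation pipeline: instances -> bins -> average -> best fit."""
    by_pop = {}
    for c in cells:
        by_pop.setdefault(c.population, []).append(c)
    pops = {p: geometry.positions(cs) for p, cs in by_pop.items()}
    rules = []
    for (pre, post), g in gt.items():
        if pre not in pops or post not in pops:
            continue
        same = pre == post
        pathway_tag = zlib.crc32(f"{pre}->{post}".encode()) % 100000
        inst = synth.gen_connectome_instances(
            g, pops[pre], pops[post], n_instances=n_instances,
            seed=seed + pathway_tag, same_population=same)
        profiles = [connectivity.estimate_bin_probabilities(
            e, pops[pre], pops[post], same_population=same)
            for e in inst.instances]
        mean_prof = connectivity.average_across_instances(profiles)
        fit = connectivity.select_best_fit(mean_prof)
        nsyn = np.mean([e["nsyn"].mean() for e in inst.instances
                        if len(e)]) if any(len(e) for e in inst.instances) else 1.0
        rules.append(connectivity.PathwayRule(pre, post, fit,
                                              max(1.0, float(nsyn))))
    return rules


def scaled_cortical_column(scale: float = CORTICAL_SCALE, seed: int = 0,
                           calcium: CalciumState | None = None,
                           registry: SynapseRegistry | None = None,
                           bg: dict | None = None,
                           weight_scale: float | None = None):
    """Build the reduced S1 column through the full probabilistic pipeline.

    Returns (cells, params_map, connectome, background)."""
    registry = load_synapse_table() if registry is None else registry
    geom = geometry.ColumnGeometry()
    counts = synth.gen_cell_counts(scale)
    cells = geometry.place_cortical_cells(geom, counts, seed=seed)
    layer_of = {p: p.split("_")[0] for p in counts["me_type"]}
    gt = ground_truth_pathways(list(counts["me_type"]), registry, layer_of)
    rules = fit_pathway_rules(cells, gt, seed=seed + 1)
    ws = (1.0 / scale) if weight_scale is None else weight_scale
    conn = builder.build_cortical_connectome(
        rules, cells, registry, seed=seed + 2, calcium=calcium,
        weight_scale=ws)
    bg_cfg = dict(CORTICAL_BG, **(bg or {}))
    background = builder.attach_background(
        cells, bg_cfg["exc_rate"], bg_cfg["inh_rate"], seed=seed + 3,
        g_exc=bg_cfg["g_exc"], g_inh=bg_cfg["g_inh"])
    params_map = {}
    for p in counts["me_type"]:
        params_map[p] = (neurons.CORTICAL_EXC if registry.is_excitatory(p)
                         else neurons.CORTICAL_INH)
    return cells, params_map, conn, background


# --------------------------------------------------------------------------
# standard measurements on the preset circuits

def thalamic_oscillation(seed: int, duration: float = 12_000.0,
                         scale: float = THALAMIC_SCALE):
    """Build, run and measure the thalamic circuit's population-rate
    spectral peak (1-15 Hz band) and synchrony index."""
    from . import metrics
    from .engine import Simulation, SimulationConfig
    cells, pm, conn, bg = scaled_thalamic_network(scale=scale, seed=seed)
    cfg = SimulationConfig(duration=duration, transient=1000.0, seed=seed)
    res = Simulation(cells, pm, conn, bg).run(cfg)
    return metrics.oscillation_peak(res.spikes, (1.0, 15.0),
                                    (cfg.transient, duration), len(cells))


def cortical_slow_bursting(seed: int, duration: float = 12_000.0,
                           scale: float = CORTICAL_SCALE,
                           calcium: CalciumState | None = None):
    """Build, run and measure the cortical column's population-burst
    frequency (Hz) and synchrony index."""
    from . import metrics
    from .engine import Simulation, SimulationConfig
    cells, pm, conn, bg = scaled_cortical_column(scale=scale, seed=seed,
                                                 calcium=calcium)
    cfg = SimulationConfig(duration=duration, transient=500.0, seed=seed)
    res = Simulation(cells, pm, conn, bg).run(cfg)
    window = (cfg.transient, duration)
    freq = metrics.burst_frequency(res.spikes, window, len(cells),
                                   min_separation_ms=300.0)
    sync = metrics.synchrony_index(res.spikes, window, len(cells))
    return freq, sync
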