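"""Network assembly.

Builds the full connectome from four ingredients:

- cortical recurrent wiring from fitted distance-probability pathway rules;
- intrathalamic wiring from three strategies: (1) exponential-with-footprint
  truncation between first-order relay nuclei and their reticular (RTN)
  sectors, (2) the same within each RTN sector, (3) fixed-divergence wiring
  without spatial constraint for the higher-order nucleus (POm);
- corticothalamic feedback from L5_TTPC2 and L6_TPC_L4 with fixed convergence
  inside a 50-um horizontal radius (topological to first-order nuclei) and a
  divergence rule to POm;
- thalamocortical input with per-me-type convergence, scaled by ~0.595 for
  inhibitory targets, 9 synapses per connection with depressing (E2)
  parameters.

Footprint *diameters* quoted for thalamic projections are halved to radii for
the truncation rule.  For footprint wiring between stacked populations the
depth coordinate is each cell's offset from the top of its own population box
(topological depth), which reduces to the absolute depth difference within a
single box.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import PathwayRule, xz_distances
from .geometry import CellInstance, THALAMIC_INHIBITORY, positions
from .registry import CalciumState, SynapseRegistry, dependence_class, parse_me_type

log = logging.getLogger(__name__)

#: default synaptic delays, ms (the source data does not constrain them)
DELAY_INTRACORTICAL = 1.0
DELAY_INTERSTRUCTURE = 2.0

#: printed footprint diameters (um) for the first-order projections and the
#: footprint radius for intra-RTN wiring
FOOTPRINT_DIAMETERS = {
    ("RTN", "VPL"): 64.33, ("RTN", "VPM"): 64.33,
    ("VPL", "RTN"): 97.67, ("VPM", "RTN"): 103.57,
}
RTN_RTN_FOOTPRINT_RADIUS = 264.63

#: which RTN sector(s) each nucleus innervates.  First-order nuclei keep a
#: single preferred sector; the higher-order POm projects diffusely across
#: all sectors (weighted toward the inner one), consistent with its less
#: organized reticular innervation.
SECTOR_PREFERENCE = {"VPL": "RTNo", "VPM": "RTNm",
                     "POm": ("RTNi", "RTNm", "RTNo")}

GABA_B_TAU_DECAY = 45.0   # ms, slow kernel of the GABA_A+GABA_B mix
GABA_B_TAU_RISE = 5.0


@dataclass(frozen=True)
class FootprintRule:
    """Strategy 1/2: p(d) = p0 * exp(-d / lam) truncated beyond the footprint
    radius in XZ and beyond y_fraction * radius in (topological) depth."""

    footprint_radius: float
    p0: float = 1.0
    y_fraction: float = 0.10
    lam: float | None = None   # defaults to the footprint radius

    def probability(self, d_xz: np.ndarray, d_y: np.ndarray) -> np.ndarray:
        lam = self.footprint_radius if self.lam is None else self.lam
        p = self.p0 * np.exp(-d_xz / lam)
        p = np.where(d_xz <= self.footprint_radius, p, 0.0)
        p = np.where(np.abs(d_y) <= self.y_fraction * self.footprint_radius, p, 0.0)
        return np.clip(p, 0.0, 1.0)


@dataclass(frozen=True)
class DivergenceRule:
    """Strategy 3: exact out-degree, no spatial constraint."""

    n_targets: int = 20


@dataclass(frozen=True)
class ConvergenceRule:
    """Fixed in-degree, optionally restricted to a maximum XZ distance."""

    n_sources: int = 30
    max_xz: float | None = 50.0


class Connectome:
    """Directed multigraph of connections at synapse granularity.

    ``edges``: one row per connection (pre, post, class_index, nsyn, delay,
    receptor, projection).  ``synapses``: one row per synaptic contact with
    sampled parameters (g_syn, tau_decay, U, D, F) plus ``tau_channel`` —
    the class-mean decay constant used to group conductance channels in the
    simulation engine.
    """

    EDGE_COLS = ["pre", "post", "class_index", "nsyn", "delay", "receptor",
                 "projection"]
    SYN_COLS = ["pre", "post", "class_index", "g_syn", "tau_rise", "tau_decay",
                "tau_channel", "U", "D", "F", "delay", "receptor", "projection"]

    def __init__(self, n_cells: int, edges: pd.DataFrame | None = None,
                 synapses: pd.DataFrame | None = None):
        self.n_cells = int(n_cells)
        self.edges = (edges if edges is not None
                      else pd.DataFrame(columns=self.EDGE_COLS))
        self.synapses = (synapses if synapses is not None
                         else pd.DataFrame(columns=self.SYN_COLS))
        self.validate()

    def validate(self):
        for df in (self.edges, self.synapses):
            if len(df):
                if (df["pre"] == df["post"]).any():
                    raise ValueError("self-edges are not allowed")
                ids = pd.concat([df["pre"], df["post"]])
                if ids.min() < 0 or ids.max() >= self.n_cells:
                    raise ValueError("edge endpoint outside the placed cells")

    @classmethod
    def merge(cls, n_cells: int, parts: list["Connectome"]) -> "Connectome":
        edges = pd.concat([p.edges for p in parts], ignore_index=True)
        syns = pd.concat([p.synapses for p in parts], ignore_index=True)
        return cls(n_cells, edges, syns)

    def export(self, path) -> None:
        self.edges.to_csv(str(path) + ".edges.tsv", sep="\t", index=False)
        self.synapses.to_csv(str(path) + ".synapses.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, path, n_cells: int) -> "Connectome":
        edges = pd.read_csv(str(path) + ".edges.tsv", sep="\t")
        syns = pd.read_csv(str(path) + ".synapses.tsv", sep="\t")
        return cls(n_cells, edges, syns)


def _nsyn_draw(rng, mean_nsyn, size):
    return 1 + rng.poisson(max(mean_nsyn - 1.0, 0.0), size=size)


def _edge_frames(pre_ids, post_ids, nsyn, cls, params, delay, receptor,
                 projection, tau_channel):
    n_edges = len(pre_ids)
    edges = pd.DataFrame({
        "pre": pre_ids, "post": post_ids, "class_index": cls,
        "nsyn": nsyn, "delay": delay, "receptor": receptor,
        "projection": projection,
    })
    rep = np.repeat(np.arange(n_edges), nsyn)
    syns = pd.DataFrame({
        "pre": np.asarray(pre_ids)[rep], "post": np.asarray(post_ids)[rep],
        "class_index": cls,
        "g_syn": params["g_syn"], "tau_rise": params["tau_rise"],
        "tau_decay": params["tau_decay"], "tau_channel": tau_channel,
        "U": params["U"], "D": params["D"], "F": params["F"],
        "delay": delay, "receptor": receptor, "projection": projection,
    })
    return edges, syns


def build_cortical_connectome(
    rules: list[PathwayRule], cells: list[CellInstance],
    registry: SynapseRegistry, seed: int,
    calcium: CalciumState | None = None,
    weight_scale: float = 1.0,
) -> Connectome:
    """Bernoulli wiring per ordered pair with p(d_xz) from the pathway rules.

    ``weight_scale`` multiplies sampled peak conductances (used to compensate
    reduced in-degree in scaled-down columns).
    """
    rng = np.random.default_rng(seed)
    by_pop: dict[str, list[CellInstance]] = {}
    for c in cells:
        by_pop.setdefault(c.population, []).append(c)
    pops = {p: (np.array([c.id for c in cs]), positions(cs))
            for p, cs in by_pop.items()}
    rule_map = {(r.pre_m_type, r.post_m_type): r for r in rules}
    for pre_pop in by_pop:
        for post_pop in by_pop:
            if (pre_pop, post_pop) not in rule_map:
                raise KeyError(f"no pathway rule for ({pre_pop}, {post_pop})")

    edge_parts, syn_parts = [], []
    for (pre_pop, post_pop), rule in rule_map.items():
        if pre_pop not in pops or post_pop not in pops:
            continue
        pre_ids, pre_xyz = pops[pre_pop]
        post_ids, post_xyz = pops[post_pop]
        d = xz_distances(pre_xyz, post_xyz)
        p = rule.probability(d)
        if pre_pop == post_pop:
            np.fill_diagonal(p, 0.0)
        else:
            # distinct populations never share ids; keep all pairs
            pass
        hit = rng.uniform(size=p.shape) < p
        ii, jj = np.nonzero(hit)
        if len(ii) == 0:
            continue
        cls = registry.match_class(pre_pop, post_pop)
        nsyn = _nsyn_draw(rng, rule.mean_nsyn, len(ii))
        total = int(nsyn.sum())
        params = registry.sample_params(cls, rng, size=total)
        params["g_syn"] = params["g_syn"] * weight_scale
        if calcium is not None:
            dep = dependence_class(
                registry.is_excitatory(pre_pop), parse_me_type(post_pop)[1],
                registry.is_excitatory(post_pop))
            params["U"] = params["U"] * calcium.multipliers[dep]
        e, s = _edge_frames(pre_ids[ii], post_ids[jj], nsyn, cls.index, params,
                            DELAY_INTRACORTICAL, cls.receptor, "cortical",
                            cls.tau_decay[0])
        edge_parts.append(e)
        syn_parts.append(s)

    n_cells = max(c.id for c in cells) + 1
    return Connectome(
        n_cells,
        pd.concat(edge_parts, ignore_index=True) if edge_parts else None,
        pd.concat(syn_parts, ignore_index=True) if syn_parts else None,
    )


# ---------------------------------------------------------------------------
# thalamic wiring


def _topological_depth(cells: list[CellInstance], bounds: dict) -> np.ndarray:
    """Depth offset from the top of each cell's own population box."""
    return np.array([c.position[1] - bounds[c.population][0] for c in cells])


@dataclass
class _Pop:
    ids: np.ndarray
    xyz: np.ndarray
    depth: np.ndarray  # topological depth


def _footprint_edges(rng, pre: _Pop, post: _Pop, rule: FootprintRule,
                     same_pop: bool):
    d_xz = xz_distances(pre.xyz, post.xyz)
    d_y = pre.depth[:, None] - post.depth[None, :]
    p = rule.probability(d_xz, d_y)
    if same_pop:
        np.fill_diagonal(p, 0.0)
    hit = rng.uniform(size=p.shape) < p
    return np.nonzero(hit)


def _fixed_params(n, g, tau_rise, tau_decay, receptor, U=1.0, D=670.0, F=17.0):
    return {
        "g_syn": np.full(n, g), "tau_rise": np.full(n, tau_rise),
        "tau_decay": np.full(n, tau_decay), "U": np.full(n, U),
        "D": np.full(n, D), "F": np.full(n, F), "receptor": receptor,
    }


def build_intrathalamic(
    cells: list[CellInstance], bounds: dict, seed: int,
    divergence: DivergenceRule = DivergenceRule(20),
    footprints: dict | None = None,
    sector_preference: dict | None = None,
    weights: dict | None = None,
    stp_relay_rtn: tuple = (0.5, 500.0, 20.0),   # U, D, F for relay->RTN
    stp_rtn: tuple = (0.4, 400.0, 50.0),
    gaba_b_tau: tuple | None = None,             # (tau_rise, tau_decay) ms
) -> Connectome:
    """Wire the six-population thalamic circuit.

    Receptors: RTN->RTN GABA_A; RTN->relay an equal-weight GABA_A + GABA_B
    pair (two synaptic contacts, one per kernel, each carrying half the
    conductance); relay->RTN AMPA.
    """
    rng = np.random.default_rng(seed)
    sector_preference = dict(SECTOR_PREFERENCE, **(sector_preference or {}))
    w = {"relay_rtn": 6.0, "rtn_relay": 6.0, "rtn_rtn": 2.0}
    w.update(weights or {})

    pops: dict[str, _Pop] = {}
    for pop in set(c.population for c in cells):
        sub = [c for c in cells if c.population == pop]
        pops[pop] = _Pop(np.array([c.id for c in sub]), positions(sub),
                         _topological_depth(sub, bounds))

    fp = dict(FOOTPRINT_DIAMETERS)
    fp.update(footprints or {})

    edge_parts, syn_parts = [], []

    def add(pre_ids, post_ids, g, tau_r, tau_d, receptor, projection,
            U, D, F, nsyn=1):
        n = len(pre_ids)
        if n == 0:
            return
        params = _fixed_params(n * nsyn, g, tau_r, tau_d, receptor, U, D, F)
        e, s = _edge_frames(pre_ids, post_ids, np.full(n, nsyn, dtype=int),
                            -1, params, DELAY_INTRACORTICAL,
                            receptor, projection, tau_d)
        edge_parts.append(e)
        syn_parts.append(s)

    gb_rise, gb_decay = (gaba_b_tau if gaba_b_tau is not None
                         else (GABA_B_TAU_RISE, GABA_B_TAU_DECAY))

    def add_inhibitory_mix(pre_ids, post_ids, g, projection):
        # GABA_A and GABA_B kernels with equal total weight
        add(pre_ids, post_ids, g / 2.0, 0.2, 8.3, "GABA_A", projection,
            *stp_rtn)
        add(pre_ids, post_ids, g / 2.0, gb_rise, gb_decay,
            "GABA_B", projection, *stp_rtn)

    # strategy 1: FO relay <-> preferred RTN sector, footprint-truncated
    for relay in ("VPL", "VPM"):
        sector = sector_preference[relay]
        if relay not in pops or sector not in pops:
            continue
        r_to_rtn = FootprintRule(fp[(relay, "RTN")] / 2.0)
        rtn_to_r = FootprintRule(fp[("RTN", relay)] / 2.0)
        ii, jj = _footprint_edges(rng, pops[relay], pops[sector], r_to_rtn, False)
        add(pops[relay].ids[ii], pops[sector].ids[jj], w["relay_rtn"],
            0.2, 1.74, "AMPA", f"{relay}->{sector}", *stp_relay_rtn)
        ii, jj = _footprint_edges(rng, pops[sector], pops[relay], rtn_to_r, False)
        add_inhibitory_mix(pops[sector].ids[ii], pops[relay].ids[jj],
                           w["rtn_relay"], f"{sector}->{relay}")

    # strategy 2: within each RTN sector
    rtn_rule = FootprintRule(RTN_RTN_FOOTPRINT_RADIUS)
    for sector in THALAMIC_INHIBITORY:
        if sector not in pops:
            continue
        ii, jj = _footprint_edges(rng, pops[sector], pops[sector], rtn_rule, True)
        add(pops[sector].ids[ii], pops[sector].ids[jj], w["rtn_rtn"],
            0.2, 8.3, "GABA_A", f"{sector}->{sector}", *stp_rtn)

    # strategy 3: divergence wiring for all POm edges (diffuse across its
    # innervation zones)
    pom_sectors = sector_preference["POm"]
    if isinstance(pom_sectors, str):
        pom_sectors = (pom_sectors,)
    pom_sectors = [s for s in pom_sectors if s in pops]
    if "POm" in pops and pom_sectors:
        pom = pops["POm"]
        rtn_pool = np.concatenate([pops[s].ids for s in pom_sectors])
        nt = min(divergence.n_targets, len(rtn_pool))
        pre_ids = np.repeat(pom.ids, nt)
        post_ids = np.concatenate([
            rng.choice(rtn_pool, size=nt, replace=False) for _ in pom.ids])
        add(pre_ids, post_ids, w["relay_rtn"], 0.2, 1.74, "AMPA",
            "POm->RTN", *stp_relay_rtn)
        nt = min(divergence.n_targets, len(pom.ids))
        pre_ids = np.repeat(rtn_pool, nt)
        post_ids = np.concatenate([
            rng.choice(pom.ids, size=nt, replace=False) for _ in rtn_pool])
        add_inhibitory_mix(pre_ids, post_ids, w["rtn_relay"], "RTN->POm")

    n_cells = max(c.id for c in cells) + 1
    return Connectome(
        n_cells,
        pd.concat(edge_parts, ignore_index=True) if edge_parts else None,
        pd.concat(syn_parts, ignore_index=True) if syn_parts else None,
    )


#: (layer, m-type) pairs of the feedback projection sources
CORTICOTHALAMIC_SOURCES = (("L5", "TTPC2"), ("L6", "TPC_L4"))


def build_corticothalamic(
    cells: list[CellInstance], rule: ConvergenceRule, seed: int,
    targets=("VPL", "VPM"), pom_divergence: DivergenceRule | None = DivergenceRule(20),
    weight: float = 2.0,
) -> Connectome:
    """Feedback wiring from L5_TTPC2 / L6_TPC_L4 onto thalamic cells.

    Topological convergence (``rule.n_sources`` within ``rule.max_xz`` um) to
    first-order targets; a spatially unconstrained divergence rule to POm.
    """
    rng = np.random.default_rng(seed)
    sources = [c for c in cells
               if (c.layer, c.m_type) in CORTICOTHALAMIC_SOURCES]
    if not sources:
        raise ValueError("no corticothalamic source cells "
                         "(need m-types L5_TTPC2 / L6_TPC_L4)")
    src_ids = np.array([c.id for c in sources])
    src_xyz = positions(sources)

    edge_parts, syn_parts = [], []

    def add_edges(pre_ids, post_ids, projection):
        n = len(pre_ids)
        params = _fixed_params(n, weight, 0.2, 1.74, "AMPA",
                               U=0.5, D=671.0, F=17.0)
        e, s = _edge_frames(pre_ids, post_ids, np.ones(n, dtype=int), -1,
                            params, DELAY_INTERSTRUCTURE, "AMPA", projection,
                            1.74)
        edge_parts.append(e)
        syn_parts.append(s)

    for pop in targets:
        tgt = [c for c in cells if c.population == pop]
        if not tgt:
            continue
        tgt_xyz = positions(tgt)
        d = xz_distances(src_xyz, tgt_xyz)
        pre_all, post_all = [], []
        for j, c in enumerate(tgt):
            cand = np.nonzero(d[:, j] <= rule.max_xz)[0] if rule.max_xz \
                else np.arange(len(src_ids))
            if len(cand) == 0:
                warnings.warn(f"no corticothalamic candidates for cell {c.id}")
                continue
            if len(cand) < rule.n_sources:
                log.info("cell %d: only %d corticothalamic candidates "
                         "(wanted %d)", c.id, len(cand), rule.n_sources)
                take = cand
            else:
                take = rng.choice(cand, size=rule.n_sources, replace=False)
            pre_all.append(src_ids[take])
            post_all.append(np.full(len(take), c.id))
        if pre_all:
            add_edges(np.concatenate(pre_all), np.concatenate(post_all),
                      f"CT->{pop}")

    if pom_divergence is not None:
        pom_ids = np.array([c.id for c in cells if c.population == "POm"])
        if len(pom_ids):
            nt = min(pom_divergence.n_targets, len(pom_ids))
            pre_ids = np.repeat(src_ids, nt)
            post_ids = np.concatenate([
                rng.choice(pom_ids, size=nt, replace=False) for _ in src_ids])
            add_edges(pre_ids, post_ids, "CT->POm")

    n_cells = max(c.id for c in cells) + 1
    return Connectome(
        n_cells,
        pd.concat(edge_parts, ignore_index=True) if edge_parts else None,
        pd.concat(syn_parts, ignore_index=True) if syn_parts else None,
    )


def compute_ie_scaling_factor(vpm_inh: int, vpm_exc: int,
                              pop_inh: int, pop_exc: int) -> float:
    """(vpm_inh/vpm_exc) / (pop_inh/pop_exc) — the thalamic convergence factor
    for inhibitory cortical targets (~0.595 with the source counts)."""
    if min(vpm_inh, vpm_exc, pop_inh, pop_exc) <= 0:
        raise ValueError("all counts must be positive")
    return (vpm_inh / vpm_exc) / (pop_inh / pop_exc)


#: source counts behind the default inhibitory scaling factor
IE_COUNTS = dict(vpm_inh=83, vpm_exc=775, pop_inh=4779, pop_exc=26567)
DEFAULT_IE_FACTOR = compute_ie_scaling_factor(**IE_COUNTS)

TC_NSYN = 9          # synapses per thalamocortical connection
TC_CLASS_INDEX = 25  # the depressing (E2) class whose parameters TC edges use


def build_thalamocortical(
    cells: list[CellInstance], convergence: pd.DataFrame,
    registry: SynapseRegistry, seed: int,
    ie_factor: float = DEFAULT_IE_FACTOR,
    convergence_scale: float = 1.0,
    weight_scale: float = 1.0,
    calcium: CalciumState | None = None,
) -> Connectome:
    """Wire thalamic relay populations onto cortical cells.

    Per cortical cell and source population, the in-degree is the (scaled)
    convergence-table value, multiplied by ``ie_factor`` for inhibitory
    targets and rounded half-to-even; each connection carries ``TC_NSYN``
    synapses with class-25 (E2) parameters.
    """
    rng = np.random.default_rng(seed)
    conv = convergence.set_index("me_type")
    cls = registry[TC_CLASS_INDEX]
    src_pops = [p for p in conv.columns]
    sources = {p: np.array([c.id for c in cells if c.population == p])
               for p in src_pops}
    cortical = [c for c in cells if c.me_type in conv.index]

    pre_all, post_all, ndeg_all = [], [], []
    for c in cortical:
        row = conv.loc[c.me_type]
        for pop in src_pops:
            pool = sources[pop]
            if len(pool) == 0:
                continue
            n = float(row[pop]) * convergence_scale
            if not c.excitatory:
                n *= ie_factor
            n = int(np.rint(n))  # round-half-to-even
            n = min(n, len(pool))
            if n <= 0:
                continue
            take = rng.choice(pool, size=n, replace=False)
            pre_all.append(take)
            post_all.append(np.full(n, c.id))
    if not pre_all:
        return Connectome(max(cl.id for cl in cells) + 1)
    pre_ids = np.concatenate(pre_all)
    post_ids = np.concatenate(post_all)
    n_edges = len(pre_ids)
    nsyn = np.full(n_edges, TC_NSYN, dtype=int)
    params = registry.sample_params(cls, rng, size=int(nsyn.sum()))
    params["g_syn"] = params["g_syn"] * weight_scale
    if calcium is not None:
        params["U"] = params["U"] * calcium.multipliers["intermediate"]
    e, s = _edge_frames(pre_ids, post_ids, nsyn, TC_CLASS_INDEX, params,
                        DELAY_INTERSTRUCTURE, "AMPA", "TC", cls.tau_decay[0])
    s["receptor"] = "AMPA"
    e["receptor"] = "AMPA"
    n_cells = max(c.id for c in cells) + 1
    return Connectome(n_cells, e, s)


@dataclass
class BackgroundStimulus:
    """Per-cell Poisson background drive: ``n_sources`` independent generators
    per cell at the population's excitatory/inhibitory rates, delivered as
    quantal conductances."""

    cell_ids: np.ndarray
    exc_rate: float          # Hz per source
    inh_rate: float          # Hz per source
    seed: int
    n_sources: int = 10
    g_exc: float = 1.0       # quantal excitatory conductance, nS
    g_inh: float = 1.0       # quantal inhibitory conductance, nS

    def sample_trains(self, duration_ms: float, kind: str = "exc") -> pd.DataFrame:
        """Realized spike trains of every source (for tests/inspection)."""
        rate = self.exc_rate if kind == "exc" else self.inh_rate
        rng = np.random.default_rng(self.seed + (0 if kind == "exc" else 1))
        rows_cell, rows_src, rows_t = [], [], []
        for cid in self.cell_ids:
            for s in range(self.n_sources):
                n = rng.poisson(rate * duration_ms / 1000.0)
                t = np.sort(rng.uniform(0, duration_ms, n))
                rows_cell.append(np.full(n, cid))
                rows_src.append(np.full(n, s))
                rows_t.append(t)
        return pd.DataFrame({
            "cell": np.concatenate(rows_cell) if rows_cell else [],
            "source": np.concatenate(rows_src) if rows_src else [],
            "time": np.concatenate(rows_t) if rows_t else [],
        })


def attach_background(cells: list[CellInstance], exc_rate: float,
                      inh_rate: float, seed: int, n_sources: int = 10,
                      g_exc: float = 1.0, g_inh: float = 1.0) -> BackgroundStimulus:
    """Attach the standard 10-source Poisson background to every cell."""
    if exc_rate < 0 or inh_rate < 0:
        raise ValueError("rates must be non-negative")
    return BackgroundStimulus(
        cell_ids=np.array([c.id for c in cells]), exc_rate=exc_rate,
        inh_rate=inh_rate, seed=seed, n_sources=n_sources,
        g_exc=g_exc, g_inh=g_inh)
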