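"""Circuit assembly: wiring contracts for the cortical, intrathalamic,
corticothalamic and thalamocortical builders plus background drive."""

import numpy as np
import pandas as pd
import pytest

from tcsim import builder, geometry
from tcsim.builder import (
    ConvergenceRule, DivergenceRule, FootprintRule, attach_background,
    build_corticothalamic, build_cortical_connectome, build_intrathalamic,
    build_thalamocortical, compute_ie_scaling_factor,
)
from tcsim.connectivity import FitModel, PathwayRule


@pytest.fixture(scope="module")
def thalamic_cells():
    geom = geometry.ThalamicGeometry()
    counts = geometry.default_thalamic_counts().copy()
    counts["count"] = (counts["count"] * 0.08).round().astype(int)
    return geometry.place_thalamic_cells(geom, counts, seed=4), geom.bounds()


class TestFootprintRule:
    def test_truncated_beyond_radius(self):
        rule = FootprintRule(footprint_radius=50.0, p0=1.0)
        d = np.array([0.0, 25.0, 49.9, 50.1, 200.0])
        p = rule.probability(d, np.zeros_like(d))
        assert p[3] == 0.0 and p[4] == 0.0
        assert (p[:3] > 0).all()

    def test_truncated_beyond_y_fraction(self):
        rule = FootprintRule(footprint_radius=100.0)
        dy = np.array([0.0, 9.9, 10.1, 50.0])
        p = rule.probability(np.full_like(dy, 10.0), dy)
        assert (p[:2] > 0).all() and (p[2:] == 0.0).all()

    def test_probability_non_increasing_with_distance(self):
        rule = FootprintRule(footprint_radius=264.63)
        d = np.linspace(0, 264.0, 200)
        p = rule.probability(d, np.zeros_like(d))
        assert (np.diff(p) <= 0).all()


def test_ie_scaling_factor_printed_ratios():
    assert 83 / 775 == pytest.approx(0.107, abs=5e-4)
    assert 4779 / 26567 == pytest.approx(0.180, abs=5e-4)
    factor = compute_ie_scaling_factor(83, 775, 4779, 26567)
    assert factor == pytest.approx(0.595, abs=0.005)
    with pytest.raises(ValueError):
        compute_ie_scaling_factor(0, 775, 4779, 26567)


class TestIntrathalamic:
    def test_footprint_truncation_never_violated(self, thalamic_cells):
        """No strategy-1/2 edge spans more than the footprint radius in XZ or
        10% of it in (topological) depth — checked over many seeded builds."""
        cells, bounds = thalamic_cells
        pos = {c.id: np.array(c.position) for c in cells}
        pop = {c.id: c.population for c in cells}
        depth = {c.id: c.position[1] - bounds[c.population][0] for c in cells}
        radii = {
            ("VPL", "RTNo"): 97.67 / 2, ("VPM", "RTNm"): 103.57 / 2,
            ("RTNo", "VPL"): 64.33 / 2, ("RTNm", "VPM"): 64.33 / 2,
            ("RTNo", "RTNo"): 264.63, ("RTNm", "RTNm"): 264.63,
            ("RTNi", "RTNi"): 264.63,
        }
        for seed in range(20):
            conn = build_intrathalamic(cells, bounds, seed=seed)
            for e in conn.edges.itertuples():
                key = (pop[e.pre], pop[e.post])
                if key not in radii:      # divergence-wired POm edges
                    continue
                r = radii[key]
                d_xz = np.hypot(pos[e.pre][0] - pos[e.post][0],
                                pos[e.pre][2] - pos[e.post][2])
                assert d_xz <= r + 1e-9
                assert abs(depth[e.pre] - depth[e.post]) <= 0.1 * r + 1e-9

    def test_pom_out_degree_exactly_divergence(self, thalamic_cells):
        cells, bounds = thalamic_cells
        conn = build_intrathalamic(cells, bounds, seed=1,
                                   divergence=DivergenceRule(20))
        pom_ids = {c.id for c in cells if c.population == "POm"}
        pom_edges = conn.edges[conn.edges["projection"] == "POm->RTN"]
        out_deg = pom_edges.groupby("pre").size()
        assert set(out_deg.index) == pom_ids
        assert (out_deg == 20).all()

    def test_receptor_assignment(self, thalamic_cells):
        cells, bounds = thalamic_cells
        conn = build_intrathalamic(cells, bounds, seed=2)
        by_proj = conn.edges.groupby("projection")["receptor"].unique()
        assert set(by_proj["RTNi->RTNi"]) == {"GABA_A"}
        assert set(by_proj["POm->RTN"]) == {"AMPA"}
        # mixed fast/slow inhibition onto relay cells, equal weight
        rtn_relay = conn.synapses[conn.synapses["projection"] == "RTN->POm"]
        assert set(rtn_relay["receptor"]) == {"GABA_A", "GABA_B"}
        ga = rtn_relay[rtn_relay["receptor"] == "GABA_A"]["g_syn"].sum()
        gb = rtn_relay[rtn_relay["receptor"] == "GABA_B"]["g_syn"].sum()
        assert ga == pytest.approx(gb)

    def test_rtn_sector_segregation(self, thalamic_cells):
        cells, bounds = thalamic_cells
        pop = {c.id: c.population for c in cells}
        conn = build_intrathalamic(cells, bounds, seed=3)
        intra = conn.edges[conn.edges["projection"].str.match(r"RTN\w->RTN\w")]
        for e in intra.itertuples():
            assert pop[e.pre] == pop[e.post]

    def test_determinism(self, thalamic_cells):
        cells, bounds = thalamic_cells
        a = build_intrathalamic(cells, bounds, seed=9)
        b = build_intrathalamic(cells, bounds, seed=9)
        pd.testing.assert_frame_equal(a.edges, b.edges)
        pd.testing.assert_frame_equal(a.synapses, b.synapses)


@pytest.fixture(scope="module")
def mixed_cells(registry):
    """A small cortical+thalamic placement with corticothalamic sources."""
    geom = geometry.ColumnGeometry()
    counts = pd.DataFrame({
        "me_type": ["L5_TTPC2_cADpyr", "L6_TPC_L4_cADpyr", "L4_SS_cADpyr",
                    "L4_LBC_cNAC"],
        "count": [300, 300, 60, 40]})
    cortical = geometry.place_cortical_cells(geom, counts, seed=5)
    tgeom = geometry.ThalamicGeometry()
    tcounts = geometry.default_thalamic_counts().copy()
    tcounts["count"] = (tcounts["count"] * 0.05).round().astype(int)
    thal = geometry.place_thalamic_cells(tgeom, tcounts, seed=6,
                                         id_offset=len(cortical))
    return cortical + thal


class TestCorticothalamic:
    def test_in_degree_thirty_when_candidates_suffice(self, mixed_cells):
        from tcsim.connectivity import xz_distances
        conn = build_corticothalamic(mixed_cells, ConvergenceRule(30, 50.0),
                                     seed=0, pom_divergence=None)
        src = [c for c in mixed_cells
               if (c.layer, c.m_type) in (("L5", "TTPC2"), ("L6", "TPC_L4"))]
        vpl = [c for c in mixed_cells if c.population == "VPL"]
        d = xz_distances(geometry.positions(src), geometry.positions(vpl))
        n_cand = (d <= 50.0).sum(axis=0)
        in_deg = conn.edges.groupby("post").size()
        for c, nc in zip(vpl, n_cand):
            got = int(in_deg.get(c.id, 0))
            assert got == min(30, int(nc))
        assert any(nc >= 30 for nc in n_cand)  # the exact-30 case is exercised

    def test_fewer_candidates_takes_all(self, mixed_cells):
        conn = build_corticothalamic(mixed_cells, ConvergenceRule(3000, 50.0),
                                     seed=0, pom_divergence=None)
        in_deg = conn.edges.groupby("post").size()
        assert (in_deg < 3000).all()        # took every candidate, no repeats
        assert (~conn.edges.duplicated(["pre", "post"])).all()

    def test_sources_restricted_to_feedback_m_types(self, mixed_cells):
        conn = build_corticothalamic(mixed_cells, ConvergenceRule(30, 50.0),
                                     seed=1)
        src = {c.id: (c.layer, c.m_type) for c in mixed_cells}
        for pre in conn.edges["pre"].unique():
            assert src[pre] in (("L5", "TTPC2"), ("L6", "TPC_L4"))

    def test_pom_divergence_edges(self, mixed_cells):
        conn = build_corticothalamic(mixed_cells, ConvergenceRule(30, 50.0),
                                     seed=1, pom_divergence=DivergenceRule(5))
        ct_pom = conn.edges[conn.edges["projection"] == "CT->POm"]
        assert (ct_pom.groupby("pre").size() == 5).all()


@pytest.fixture(scope="module")
def conv_table():
    return pd.DataFrame({
        "me_type": ["L4_SS_cADpyr", "L4_LBC_cNAC"],
        "VPL": [100, 100], "VPM": [40, 40], "POm": [10, 10]})


class TestThalamocortical:

    def test_excitatory_in_degree_matches_table(self, mixed_cells, registry,
                                                conv_table):
        conn = build_thalamocortical(mixed_cells, conv_table, registry, seed=0)
        exc = [c for c in mixed_cells if c.me_type == "L4_SS_cADpyr"]
        vpl = {c.id for c in mixed_cells if c.population == "VPL"}
        pom = {c.id for c in mixed_cells if c.population == "POm"}
        e = conn.edges
        for c in exc[:10]:
            # table value 100 capped by the available VPL pool
            mine = e[(e["post"] == c.id) & (e["pre"].isin(vpl))]
            assert len(mine) == min(100, len(vpl))
            # POm table value 10 is not capped: exact in-degree
            assert len(e[(e["post"] == c.id) & (e["pre"].isin(pom))]) == 10

    def test_inhibitory_scaling_rounds_half_even(self, mixed_cells, registry,
                                                 conv_table):
        conn = build_thalamocortical(mixed_cells, conv_table, registry, seed=0)
        inh = [c for c in mixed_cells if c.me_type == "L4_LBC_cNAC"]
        pom = {c.id for c in mixed_cells if c.population == "POm"}
        e = conn.edges
        for c in inh[:10]:
            mine = e[(e["post"] == c.id) & (e["pre"].isin(pom))]
            assert len(mine) == 6   # rint(10 * 0.595...) = 6

    def test_nine_synapses_per_edge_with_e2_params(self, mixed_cells, registry,
                                                   conv_table):
        conn = build_thalamocortical(mixed_cells, conv_table, registry, seed=1)
        assert (conn.edges["nsyn"] == 9).all()
        assert (conn.edges["class_index"] == 25).all()
        per_edge = conn.synapses.groupby(["pre", "post"]).size()
        assert (per_edge == 9).all()

    def test_missing_me_type_rows_are_skipped(self, mixed_cells, registry,
                                              conv_table):
        conn = build_thalamocortical(mixed_cells, conv_table, registry, seed=2)
        covered = {c.id for c in mixed_cells
                   if c.me_type in set(conv_table["me_type"])}
        assert set(conn.edges["post"]).issubset(covered)


class TestCorticalConnectome:
    def _cells(self, registry, n=40):
        counts = pd.DataFrame({"me_type": ["L23_PC_cADpyr", "L23_MC_cACint"],
                               "count": [n, n // 2]})
        return geometry.place_cortical_cells(
            geometry.ColumnGeometry(), counts, seed=8)

    def _rules(self, p):
        fit = FitModel("exp_linsat", (10.0, 1e5, p), 0.0)
        pops = ["L23_PC_cADpyr", "L23_MC_cACint"]
        return [PathwayRule(a, b, fit, 1.0) for a in pops for b in pops]

    def test_unit_probability_complete_digraph(self, registry):
        cells = self._cells(registry)
        conn = build_cortical_connectome(self._rules(1.0), cells, registry,
                                         seed=0)
        n = len(cells)
        assert len(conn.edges) == n * (n - 1)
        assert not (conn.edges["pre"] == conn.edges["post"]).any()

    def test_missing_rule_rejected(self, registry):
        cells = self._cells(registry)
        with pytest.raises(KeyError):
            build_cortical_connectome(self._rules(1.0)[:2], cells, registry,
                                      seed=0)

    def test_determinism(self, registry):
        cells = self._cells(registry)
        a = build_cortical_connectome(self._rules(0.3), cells, registry, seed=3)
        b = build_cortical_connectome(self._rules(0.3), cells, registry, seed=3)
        pd.testing.assert_frame_equal(a.synapses, b.synapses)

    def test_edge_count_matches_expectation(self, registry):
        from tcsim.connectivity import expected_connection_count, xz_distances
        cells = self._cells(registry, n=60)
        rules = self._rules(0.25)
        pcs = [c for c in cells if c.me_type == "L23_PC_cADpyr"]
        xyz = geometry.positions(pcs)
        rule = rules[0]
        expect = expected_connection_count(rule, xyz, xyz, same_population=True)
        counts = []
        for seed in range(60):
            conn = build_cortical_connectome(rules, cells, registry, seed=seed)
            pc_ids = {c.id for c in pcs}
            e = conn.edges
            counts.append(len(e[e["pre"].isin(pc_ids) & e["post"].isin(pc_ids)]))
        p = rule.probability(xz_distances(xyz, xyz))
        np.fill_diagonal(p, 0.0)
        var = float((p * (1 - p)).sum())
        assert abs(np.mean(counts) - expect) < 3 * np.sqrt(var / len(counts))

    def test_class_assignment_and_receptors(self, registry):
        cells = self._cells(registry)
        conn = build_cortical_connectome(self._rules(1.0), cells, registry,
                                         seed=0)
        pc = {c.id for c in cells if c.me_type == "L23_PC_cADpyr"}
        e = conn.edges
        pcpc = e[e["pre"].isin(pc) & e["post"].isin(pc)]
        assert (pcpc["class_index"] == 18).all()
        mcpc = e[~e["pre"].isin(pc) & e["post"].isin(pc)]
        assert (mcpc["class_index"] == 6).all()
        assert (mcpc["receptor"] == "GABA_A").all()


class TestBackground:
    def test_exactly_ten_sources_per_cell(self, thalamic_cells):
        cells, _ = thalamic_cells
        bg = attach_background(cells[:5], 8.0, 2.0, seed=0)
        trains = bg.sample_trains(1000.0, "exc")
        assert set(trains.groupby("cell")["source"].nunique()) == {10}

    def test_zero_rate_no_spikes(self, thalamic_cells):
        cells, _ = thalamic_cells
        bg = attach_background(cells[:5], 0.0, 0.0, seed=0)
        assert len(bg.sample_trains(1000.0, "exc")) == 0

    def test_total_count_within_3se(self, thalamic_cells):
        cells, _ = thalamic_cells
        n, r, T = 20, 5.0, 10.0  # cells, Hz, seconds
        bg = attach_background(cells[:n], r, 0.0, seed=1)
        total = len(bg.sample_trains(T * 1000.0, "exc"))
        lam = 10 * n * r * T
        assert abs(total - lam) < 3 * np.sqrt(lam)

    def test_negative_rate_rejected(self, thalamic_cells):
        cells, _ = thalamic_cells
        with pytest.raises(ValueError):
            attach_background(cells[:2], -1.0, 0.0, seed=0)


def test_connectome_rejects_self_edges():
    edges = pd.DataFrame({"pre": [0], "post": [0], "class_index": [0],
                          "nsyn": [1], "delay": [1.0], "receptor": ["AMPA"],
                          "projection": ["x"]})
    with pytest.raises(ValueError):
        builder.Connectome(3, edges, None)
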