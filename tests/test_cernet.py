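import numpy as np
import pytest

from circernet.cernet import (
    CeRNANetwork,
    CeRNATriple,
    SignedFeature,
    ThresholdConfig,
    abundance_filter,
    assemble_network,
    de_threshold_filter,
    filter_mirna_mrna_predictions,
    inverse_modulation_filter,
    merge_circ_mirna_predictions,
    network_summary,
    rank_hubs,
)
from circernet.tabio import (
    CircMirEdge,
    Confidence,
    CountMatrix,
    DERecord,
    DETable,
    Layer,
    MirMrnaEdge,
)

from conftest import SPONGE_TABLE, build_tripartite_network, random_small_network
from oracles import cascade_oracle

CFG = ThresholdConfig()


def sf(fid, layer, lfc):
    return SignedFeature(fid, Layer.coerce(layer), lfc, 0.001)


def make_matrix(rows, groups=None):
    rows = np.asarray(rows, dtype=np.int64)
    n = rows.shape[1]
    groups = groups or ["case"] * (n // 2) + ["control"] * (n - n // 2)
    return CountMatrix(feature_ids=tuple(f"j{i}" for i in range(rows.shape[0])),
                      sample_ids=tuple(f"s{j}" for j in range(n)),
                      counts=rows, groups=tuple(groups))


class TestAbundanceFilter:
    def test_ceiling_rule_on_39_samples(self):
        # >= 5 reads in at least 50% of 39 samples means >= 20 samples
        hit20 = [5] * 20 + [0] * 19
        hit19 = [5] * 19 + [0] * 20
        m = make_matrix([hit20, hit19])
        kept, report = abundance_filter(m, CFG)
        assert kept.feature_ids == ("j0",)
        assert (report.n_in, report.n_out) == (2, 1)

    def test_all_zero_matrix_drops_everything(self):
        m = make_matrix(np.zeros((3, 6), dtype=int))
        kept, _ = abundance_filter(m, CFG)
        assert kept.n_features == 0

    def test_zero_read_threshold_is_vacuous(self):
        m = make_matrix(np.zeros((3, 6), dtype=int))
        kept, _ = abundance_filter(m, ThresholdConfig(bsj_min_reads=0))
        assert kept.n_features == 3


class TestDeThresholdFilter:
    def test_mrna_gate_uses_padj_only(self):
        table = DETable(Layer.MRNA, (
            DERecord("keep", Layer.MRNA, 0.3, 0.001, 0.009),
            DERecord("drop", Layer.MRNA, 5.0, 0.001, 0.02),
        ))
        kept = de_threshold_filter(table, CFG)
        assert {f.feature_id for f in kept} == {"keep"}
        assert next(iter(kept)).sign == 1  # no fold-change gate at mRNA layer

    def test_circ_gate_needs_both_p_and_lfc(self):
        table = DETable(Layer.CIRCRNA, (
            DERecord("weak_fc", Layer.CIRCRNA, 0.9, 0.04, None),
            DERecord("weak_p", Layer.CIRCRNA, 2.0, 0.06, None),
            DERecord("good", Layer.CIRCRNA, -1.0, 0.04, None),
        ))
        kept = de_threshold_filter(table, CFG)
        assert {f.feature_id for f in kept} == {"good"}
        assert next(iter(kept)).sign == -1

    def test_mirna_gate_falls_back_to_raw_p(self):
        table = DETable(Layer.MIRNA, (
            DERecord("adj", Layer.MIRNA, 1.0, 0.001, 0.01),
            DERecord("raw", Layer.MIRNA, -1.0, 0.03, None),
            DERecord("ns", Layer.MIRNA, 1.0, 0.2, None),
        ))
        assert {f.feature_id for f in de_threshold_filter(table, CFG)} == \
            {"adj", "raw"}

    def test_zero_lfc_never_retained(self):
        table = DETable(Layer.MRNA,
                        (DERecord("flat", Layer.MRNA, 0.0, 1e-9, 1e-8),))
        assert de_threshold_filter(table, CFG) == frozenset()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_row_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(50):
            p = float(rng.uniform(0, 0.2))
            recs.append(DERecord(f"g{i}", Layer.CIRCRNA,
                                 float(rng.uniform(-3, 3)), p, None))
        table = DETable(Layer.CIRCRNA, tuple(recs))
        kept = {f.feature_id for f in de_threshold_filter(table, CFG)}
        # independent plain-python scan of the stated predicates
        expected = {r.feature_id for r in recs
                    if r.p < 0.05 and abs(r.log2fc) >= 1.0 and r.log2fc != 0}
        assert kept == expected


class TestMergePredictions:
    def test_union_merges_sources(self):
        t1 = [CircMirEdge("c1", "m1", frozenset({"encori"}))]
        t2 = [CircMirEdge("c1", "m1", frozenset({"circatlas"})),
              CircMirEdge("c2", "m2", frozenset({"circatlas"}))]
        res = merge_circ_mirna_predictions([t1, t2])
        by_key = {e.key: e for e in res.edges}
        assert by_key[("c1", "m1")].sources == {"encori", "circatlas"}
        assert len(res.edges) == 2

    def test_unmatched_circs_reported(self):
        # circRNAs absent from every database land in the coverage report
        t1 = [CircMirEdge("circBPTF", "hsa-let-7a-5p", frozenset({"encori"}))]
        res = merge_circ_mirna_predictions(
            [t1], circ_universe=["circBPTF", "circHDAC9", "circALPK2",
                                 "circMLIP"])
        assert res.no_match_circs == ("circALPK2", "circHDAC9", "circMLIP")

    def test_empty_input(self):
        res = merge_circ_mirna_predictions([], circ_universe=["c1"])
        assert res.edges == () and res.no_match_circs == ("c1",)

    def test_case_insensitive_mirna_join(self):
        t1 = [CircMirEdge("c1", "hsa-miR-7-5p", frozenset({"a"}))]
        t2 = [CircMirEdge("c1", "hsa-mir-7-5p", frozenset({"b"}))]
        res = merge_circ_mirna_predictions([t1, t2])
        assert len(res.edges) == 1
        assert res.edges[0].sources == {"a", "b"}


class TestMirMrnaFilter:
    @pytest.mark.parametrize("rc,conf,kept", [
        (5, Confidence.HIGH, True),       # boundary: exactly 5, exactly high
        (4, Confidence.VERY_HIGH, False),  # resources below floor
        (20, Confidence.MEDIUM, False),    # confidence below floor
        (6, Confidence.VERY_HIGH, True),
    ])
    def test_boundaries(self, rc, conf, kept):
        edge = MirMrnaEdge("m1", "g1", rc, conf)
        out = filter_mirna_mrna_predictions([edge], CFG)
        assert (len(out) == 1) is kept

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_predicate_scan(self, seed):
        rng = np.random.default_rng(seed)
        edges = [MirMrnaEdge(f"m{i}", f"g{i}", int(rng.integers(1, 12)),
                             Confidence(int(rng.integers(0, 4))))
                 for i in range(40)]
        kept = {e.key for e in filter_mirna_mrna_predictions(edges, CFG)}
        expected = {e.key for e in edges
                    if e.resource_count >= 5 and int(e.confidence_class) >= 2}
        assert kept == expected


class TestInverseModulation:
    DE_CIRC = [sf("c_up", "circRNA", 2.0), sf("c_dn", "circRNA", -2.0)]
    DE_MIR = [sf("m_up", "miRNA", 1.0), sf("m_dn", "miRNA", -1.0)]

    def test_opposite_signs_retained(self):
        edges = [CircMirEdge("c_up", "m_dn", frozenset({"s"}))]
        res = inverse_modulation_filter(edges, self.DE_CIRC, self.DE_MIR)
        assert len(res.retained) == 1
        assert res.concordant_count == 0

    def test_concordant_counted_separately(self):
        edges = [CircMirEdge("c_up", "m_up", frozenset({"s"}))]
        res = inverse_modulation_filter(edges, self.DE_CIRC, self.DE_MIR)
        assert res.retained == ()
        assert res.concordant_count == 1
        assert res.dropped_non_de_count == 0

    def test_non_de_endpoint_counted_separately(self):
        edges = [CircMirEdge("c_up", "m_other", frozenset({"s"})),
                 CircMirEdge("c_other", "m_dn", frozenset({"s"}))]
        res = inverse_modulation_filter(edges, self.DE_CIRC, self.DE_MIR)
        assert res.retained == ()
        assert res.dropped_non_de_count == 2

    def test_works_on_mirna_mrna_edges(self):
        de_mrna = [sf("g_up", "mRNA", 1.0)]
        edges = [MirMrnaEdge("m_dn", "g_up", 7, Confidence.HIGH)]
        res = inverse_modulation_filter(edges, self.DE_MIR, de_mrna)
        assert len(res.retained) == 1


class TestAssembleNetwork:
    SIGNED = {
        Layer.CIRCRNA: [sf("c1", "circRNA", 2.0), sf("c2", "circRNA", 1.5)],
        Layer.MIRNA: [sf("m1", "miRNA", -1.0)],
        Layer.MRNA: [sf("g1", "mRNA", 1.0), sf("g2", "mRNA", 0.5),
                     sf("g3", "mRNA", 2.0)],
    }

    def test_empty_circ_mir_gives_empty_network(self):
        net = assemble_network([], [MirMrnaEdge("m1", "g1", 7, "high")],
                               self.SIGNED)
        assert len(net) == 0

    def test_product_count(self):
        # two circRNAs sponging one miRNA that targets three mRNAs -> 6
        cm = [CircMirEdge("c1", "m1", frozenset({"s"})),
              CircMirEdge("c2", "m1", frozenset({"s"}))]
        mm = [MirMrnaEdge("m1", g, 7, "high") for g in ("g1", "g2", "g3")]
        net = assemble_network(cm, mm, self.SIGNED)
        assert len(net) == 6
        assert net.nodes(Layer.MIRNA) == {"m1"}

    def test_sign_violation_is_an_error(self):
        bad_signed = {Layer.CIRCRNA: [sf("c1", "circRNA", 2.0)],
                      Layer.MIRNA: [sf("m1", "miRNA", 1.0)],  # concordant!
                      Layer.MRNA: [sf("g1", "mRNA", 1.0)]}
        cm = [CircMirEdge("c1", "m1", frozenset({"s"}))]
        mm = [MirMrnaEdge("m1", "g1", 7, "high")]
        with pytest.raises(ValueError, match="sign-inconsistent"):
            assemble_network(cm, mm, bad_signed)

    def test_targetless_mirna_absent_from_node_table(self):
        signed = dict(self.SIGNED)
        signed[Layer.MIRNA] = [sf("m1", "miRNA", -1.0),
                               sf("m_lonely", "miRNA", -1.0)]
        cm = [CircMirEdge("c1", "m1", frozenset({"s"})),
              CircMirEdge("c1", "m_lonely", frozenset({"s"}))]
        mm = [MirMrnaEdge("m1", "g1", 7, "high")]
        net = assemble_network(cm, mm, signed)
        assert net.nodes(Layer.MIRNA) == {"m1"}


class TestSummaryAndHubs:
    def test_interaction_totals_conserved(self, sponge_table_network):
        s = network_summary(sponge_table_network)
        assert s.total_interactions == 662
        assert s.total_interactions == sum(
            c for _m, c in s.per_circ.values())
        assert s.n_mirnas == 13
        assert s.n_circs == 5

    def test_per_circ_counts(self, sponge_table_network):
        s = network_summary(sponge_table_network)
        assert {c: n for c, (_m, n) in s.per_circ.items()} == \
            {c: n for c, (_m, n) in SPONGE_TABLE.items()}

    def test_empty_network_all_zero(self):
        s = network_summary(CeRNANetwork(triples=frozenset()))
        assert (s.total_interactions, s.n_circs, s.n_mirnas, s.n_mrnas) == \
            (0, 0, 0, 0)

    def test_hub_is_the_most_connected_sponge(self, sponge_table_network):
        hubs = rank_hubs(sponge_table_network)
        assert hubs[0] == ("circBPTF", 5, 220)

    def test_single_circ_network(self):
        net = build_tripartite_network({"circX": (("m1",), 3)})
        assert rank_hubs(net)[0][0] == "circX"

    def test_degree_tie_breaks_lexicographically(self):
        net = build_tripartite_network({"circB": (("m1",), 2),
                                        "circA": (("m2",), 2)})
        assert [h[0] for h in rank_hubs(net)] == ["circA", "circB"]

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_grouped_two_ways(self, seed):
        net = random_small_network(np.random.default_rng(seed))
        by_circ = {}
        by_mirna = {}
        for t in net.triples:
            by_circ[t.circ.feature_id] = by_circ.get(t.circ.feature_id, 0) + 1
            by_mirna[t.mirna.feature_id] = \
                by_mirna.get(t.mirna.feature_id, 0) + 1
        assert sum(by_circ.values()) == len(net) == sum(by_mirna.values())
        s = network_summary(net)
        assert {c: n for c, (_m, n) in s.per_circ.items()} == by_circ


def _random_instance(rng):
    """Random DE rows + prediction edges on <= 10 nodes per layer."""
    circ_rows = {f"c{i}": (float(rng.uniform(-3, 3)),
                           float(rng.uniform(0, 0.15)), None)
                 for i in range(int(rng.integers(2, 11)))}
    def with_padj():
        padj = float(rng.uniform(0, 0.15))
        return padj / 2, padj  # raw p always below its adjusted value

    mirna_rows = {f"m{i}": (float(rng.uniform(-3, 3)), *with_padj())
                  for i in range(int(rng.integers(2, 11)))}
    mrna_rows = {f"g{i}": (float(rng.uniform(-3, 3)), *with_padj())
                 for i in range(int(rng.integers(2, 11)))}
    cm_edges = {(c, m) for c in circ_rows for m in mirna_rows
                if rng.random() < 0.4}
    mm_edges = {(m, g): (int(rng.integers(1, 12)), int(rng.integers(0, 4)))
                for m in mirna_rows for g in mrna_rows if rng.random() < 0.4}
    return circ_rows, mirna_rows, mrna_rows, cm_edges, mm_edges


def _run_cascade(circ_rows, mirna_rows, mrna_rows, cm_edges, mm_edges, cfg):
    from circernet.pipeline import infer_network

    def table(layer, rows):
        return DETable(layer, tuple(
            DERecord(fid, layer, lfc if lfc != 0 else 1e-9, p,
                     padj if padj is not None else None)
            for fid, (lfc, p, padj) in rows.items()))

    cm = [CircMirEdge(c, m, frozenset({"sim"})) for c, m in cm_edges]
    mm = [MirMrnaEdge(m, g, rc, Confidence(conf))
          for (m, g), (rc, conf) in mm_edges.items()]
    net, _counts = infer_network(table(Layer.MRNA, mrna_rows),
                                 table(Layer.MIRNA, mirna_rows),
                                 table(Layer.CIRCRNA, circ_rows),
                                 [cm], mm, cfg)
    return net.triple_keys


@pytest.mark.parametrize("seed", range(30))
def test_cascade_matches_joint_enumeration(seed):
    rng = np.random.default_rng(seed)
    inst = _random_instance(rng)
    assert _run_cascade(*inst, CFG) == cascade_oracle(*inst, CFG)


@pytest.mark.parametrize("field,tighter", [
    ("mrna_padj_max", 0.005), ("circ_p_max", 0.01),
    ("circ_abs_lfc_min", 2.0), ("mirna_padj_max", 0.01),
    ("mm_min_resources", 8), ("mm_min_confidence", Confidence.VERY_HIGH),
])
def test_tightening_any_threshold_never_adds_triples(field, tighter):
    import dataclasses

    rng = np.random.default_rng(99)
    inst = _random_instance(rng)
    base = _run_cascade(*inst, CFG)
    strict = _run_cascade(*inst, dataclasses.replace(CFG, **{field: tighter}))
    assert strict <= base
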