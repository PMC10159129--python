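import numpy as np
import pandas as pd
import pytest

from micronet import PcitEdgeSet, assemble_network, mirna_mrna_edges, mrna_mrna_edges
from micronet.io import write_edges


def _pcit(nodes, r_pairs, all_significant=True, insignificant=()):
    """Small PcitEdgeSet from a dict of pair -> r."""
    r = pd.DataFrame(np.eye(len(nodes)), index=nodes, columns=nodes)
    for (a, b), v in r_pairs.items():
        r.at[a, b] = r.at[b, a] = v
    sig = pd.DataFrame(all_significant, index=nodes, columns=nodes, dtype=bool)
    np.fill_diagonal(sig.to_numpy(), False)
    for a, b in insignificant:
        sig.at[a, b] = sig.at[b, a] = False
    return PcitEdgeSet(r=r, significant=sig)


def _matches(pairs):
    return pd.DataFrame(
        [{"mirna_id": m, "seed7": "NNNNNNN", "gene_id": g, "n_sites": n, "offsets": "0"} for m, g, n in pairs],
        columns=["mirna_id", "seed7", "gene_id", "n_sites", "offsets"],
    )


class TestMirnaMrnaEdges:
    def test_strict_minus_050_boundary(self):
        pcit = _pcit(["m", "g1", "g2"], {("m", "g1"): -0.51, ("m", "g2"): -0.49})
        matches = _matches([("m", "g1", 1), ("m", "g2", 1)])
        edges = mirna_mrna_edges(["m"], ["g1", "g2"], pcit, matches)
        assert edges.target.tolist() == ["g1"]
        assert edges.r.iloc[0] == pytest.approx(-0.51)

    def test_strong_correlation_without_seed_site_excluded(self):
        pcit = _pcit(["m", "g"], {("m", "g"): -0.9})
        assert mirna_mrna_edges(["m"], ["g"], pcit, _matches([])).empty
        assert mirna_mrna_edges(["m"], ["g"], pcit, _matches([("m", "g", 0)])).empty

    def test_pcit_significance_required_unless_disabled(self):
        pcit = _pcit(["m", "g"], {("m", "g"): -0.8}, insignificant=[("m", "g")])
        matches = _matches([("m", "g", 1)])
        assert mirna_mrna_edges(["m"], ["g"], pcit, matches).empty
        relaxed = mirna_mrna_edges(["m"], ["g"], pcit, matches, require_pcit=False)
        assert len(relaxed) == 1

    def test_missing_node_is_a_wiring_error(self):
        pcit = _pcit(["m", "g"], {("m", "g"): -0.8})
        with pytest.raises(KeyError, match="missing from the PCIT edge set"):
            mirna_mrna_edges(["m"], ["gX"], pcit, _matches([("m", "gX", 1)]))


class TestMrnaMrnaEdges:
    def test_strict_07_boundary_and_no_self_loops(self):
        pcit = _pcit(["g1", "g2", "g3"], {("g1", "g2"): 0.70, ("g1", "g3"): 0.71})
        edges = mrna_mrna_edges(["g1"], ["g1", "g2", "g3"], pcit)
        assert [(e.source, e.target) for e in edges.itertuples()] == [("g1", "g3")]

    def test_negative_correlation_counts_by_magnitude(self):
        pcit = _pcit(["g1", "g2"], {("g1", "g2"): -0.95})
        edges = mrna_mrna_edges(["g1"], ["g1", "g2"], pcit)
        assert len(edges) == 1 and edges.r.iloc[0] == pytest.approx(-0.95)

    def test_endpoints_lexicographic_and_unique(self):
        pcit = _pcit(["gB", "gA"], {("gB", "gA"): 0.9})
        edges = mrna_mrna_edges(["gB", "gA"], ["gA", "gB"], pcit)
        assert len(edges) == 1
        assert (edges.source.iloc[0], edges.target.iloc[0]) == ("gA", "gB")

    def test_targeted_genes_must_be_de(self):
        pcit = _pcit(["g1", "g2"], {})
        with pytest.raises(ValueError, match="subset"):
            mrna_mrna_edges(["gX"], ["g1", "g2"], pcit)

    def test_equals_brute_force_pair_filter(self):
        rng = np.random.default_rng(8)
        nodes = [f"g{i}" for i in range(9)]
        data = rng.normal(size=(9, 10))
        r = pd.DataFrame(np.corrcoef(data), index=nodes, columns=nodes)
        sig = pd.DataFrame(True, index=nodes, columns=nodes)
        np.fill_diagonal(sig.to_numpy(), False)
        targeted = nodes[:4]
        edges = mrna_mrna_edges(targeted, nodes, PcitEdgeSet(r=r, significant=sig))
        got = {(e.source, e.target) for e in edges.itertuples()}
        expected = {
            tuple(sorted((a, b)))
            for a in targeted
            for b in nodes
            if a != b and abs(r.at[a, b]) > 0.7
        }
        assert got == expected


class TestAssembly:
    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        nodes = ["m1", "g1", "g2", "g3"]
        r = pd.DataFrame(np.corrcoef(rng.normal(size=(4, 8))), index=nodes, columns=nodes)
        sig = pd.DataFrame(True, index=nodes, columns=nodes)
        np.fill_diagonal(sig.to_numpy(), False)
        pcit = PcitEdgeSet(r=r, significant=sig)
        matches = _matches([("m1", g, 1) for g in ["g1", "g2", "g3"]])

        def edge_set(r_max, r_min_abs):
            net = assemble_network(["m1"], ["g1", "g2", "g3"], pcit, matches, r_max, r_min_abs)
            return {tuple(e) for e in net.edges[["source", "target"]].itertuples(index=False)}

        loose = edge_set(-0.1, 0.3)
        assert edge_set(-0.6, 0.3) <= loose  # more negative r_max never adds edges
        assert edge_set(-0.1, 0.8) <= loose  # higher |r| floor never adds edges

    def test_deterministic_edge_file(self, tmp_path, small_sim):
        _, sim = small_sim
        nodes = list(sim.truth.true_de_mirna) + list(sim.truth.true_de_mrna)
        rng = np.random.default_rng(1)
        r = pd.DataFrame(np.corrcoef(rng.normal(size=(len(nodes), 12))), index=nodes, columns=nodes)
        sig = pd.DataFrame(True, index=nodes, columns=nodes)
        np.fill_diagonal(sig.to_numpy(), False)
        pcit = PcitEdgeSet(r=r, significant=sig)
        matches = _matches(
            [(m, g, 1) for (m, g) in sim.truth.true_target_edges]
        )
        net = assemble_network(
            list(sim.truth.true_de_mirna), list(sim.truth.true_de_mrna), pcit, matches
        )
        p1, p2 = tmp_path / "n1.tsv", tmp_path / "n2.tsv"
        write_edges(net, p1)
        write_edges(net, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_every_reported_edge_satisfies_all_conditions(self, small_sim):
        """Independent re-check of the four-way conjunction on a synthetic run."""
        import micronet as mn

        _, sim = small_sim
        m = mn.filter_expressed(sim.mrna_counts)
        mi = mn.filter_expressed(sim.mirna_counts)
        sf_m, sf_i = mn.size_factors(m), mn.size_factors(mi)
        de_m = mn.nb_wald_de(m, sim.samples, 1.5, factors=sf_m)
        de_i = mn.nb_wald_de(mi, sim.samples, 1.2, factors=sf_i)
        g_ids = de_m.index[de_m.is_de].tolist()
        i_ids = de_i.index[de_i.is_de].tolist()
        expr = pd.concat(
            [
                mn.expression_for_correlation(m, sf_m).loc[g_ids],
                mn.expression_for_correlation(mi, sf_i).loc[i_ids],
            ]
        )
        r = mn.pearson_matrix(expr)
        pcit = PcitEdgeSet(r=r, significant=mn.pcit_significant(r))
        matches = mn.scan_all([x for x in sim.mirnas if x.id in i_ids], sim.utrs)
        net = assemble_network(i_ids, g_ids, pcit, matches)
        matched = set(zip(matches.mirna_id, matches.gene_id))
        for e in net.mirna_edges.itertuples():
            assert e.source in i_ids and e.target in g_ids
            assert (e.source, e.target) in matched
            assert r.at[e.source, e.target] < -0.50
            assert bool(pcit.significant.at[e.source, e.target])
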