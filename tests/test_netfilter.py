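import statistics
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from netpharm.netfilter import (
    CentralityRecord,
    InteractionEdge,
    PharmNetwork,
    build_network,
    centralities,
    classify_candidates,
    read_edge_list,
    refine_major_hubs,
    select_hubs,
    write_node_attributes,
    write_sif,
)
from netpharm.simdata import SimConfig, gen_network_fixture

# ---------------------------------------------------------------------------
# independent exhaustive-enumeration oracle (DFS over all simple paths)


def _all_simple_paths(adj, s, t):
    paths = []
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            paths.append(path)
            continue
        for nb in adj[node]:
            if nb not in path:
                stack.append((nb, path + [nb]))
    return paths


def oracle_centralities(nodes, edge_pairs):
    adj = {n: set() for n in nodes}
    for a, b in edge_pairs:
        adj[a].add(b)
        adj[b].add(a)
    n = len(nodes)
    btw = {v: 0.0 for v in nodes}
    dist = {}
    for s, t in combinations(nodes, 2):
        paths = _all_simple_paths(adj, s, t)
        if not paths:
            continue
        d = min(len(p) for p in paths) - 1
        dist[(s, t)] = d
        shortest = [p for p in paths if len(p) - 1 == d]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            btw[v] += through / len(shortest)
    norm = (n - 1) * (n - 2) / 2 if n > 2 else 1.0
    out = {}
    for v in nodes:
        deg = len(adj[v])
        reach, total = 0, 0
        for u in nodes:
            if u == v:
                continue
            key = (v, u) if (v, u) in dist else (u, v)
            if key in dist:
                reach += 1
                total += dist[key]
        clo = reach / total if total else 0.0
        out[v] = (deg, btw[v] / norm, clo)
    return out


def _net_from_graph(g):
    net = PharmNetwork(nx.Graph())
    for node in g.nodes:
        net.graph.add_node(node, role="putative_target")
    net.graph.add_edges_from(g.edges)
    return net


# ---------------------------------------------------------------------------
# build_network


def _edges(pairs, conf=0.9):
    return [InteractionEdge(a, b, conf) for a, b in pairs]


def test_all_edges_below_cutoff():
    net = build_network({"A", "B"}, {"C"}, _edges([("A", "B"), ("B", "C")], conf=0.2))
    assert net.nodes == {"A", "B", "C"}
    assert net.n_edges == 0


def test_edge_outside_universe_dropped():
    net = build_network({"A"}, {"B"}, _edges([("A", "Z"), ("A", "B")]))
    assert net.n_edges == 1


def test_self_loop_and_duplicate_removed():
    edges = _edges([("A", "A"), ("A", "B"), ("B", "A")])
    net = build_network({"A", "B"}, set(), edges)
    assert net.n_edges == 1


def test_roles():
    net = build_network({"A", "B"}, {"B", "C"}, [])
    assert net.role("A") == "putative_target"
    assert net.role("B") == "both"
    assert net.role("C") == "disease_gene"


def test_empty_universe_raises():
    with pytest.raises(ValueError):
        build_network(set(), set(), [])


def test_confidence_filter_count_matches_brute_force(rng):
    nodes = [f"N{i}" for i in range(50)]
    edges = []
    for _ in range(300):
        a, b = rng.choice(50, size=2, replace=False)
        edges.append(InteractionEdge(nodes[int(a)], nodes[int(b)], float(rng.random())))
    net = build_network(set(nodes), set(), edges, min_conf=0.4)
    kept = {
        tuple(sorted((e.a, e.b))) for e in edges if e.confidence >= 0.4 and e.a != e.b
    }
    assert net.n_edges == len(kept)


# ---------------------------------------------------------------------------
# centralities


def test_star_centralities():
    g = nx.star_graph(4)  # center 0
    recs = {r.node: r for r in centralities(_net_from_graph(g))}
    assert recs[0].degree == 4
    assert all(recs[i].degree == 1 for i in range(1, 5))
    assert recs[0].betweenness == pytest.approx(1.0)
    assert all(recs[i].betweenness == 0.0 for i in range(1, 5))
    assert recs[0].closeness == pytest.approx(1.0)


def test_path_middle_betweenness():
    g = nx.path_graph(3)
    recs = {r.node: r for r in centralities(_net_from_graph(g))}
    assert recs[1].betweenness == pytest.approx(1.0)


def test_isolated_node_closeness_zero():
    g = nx.Graph()
    g.add_nodes_from([0, 1])
    recs = {r.node: r for r in centralities(_net_from_graph(g))}
    assert recs[0].closeness == 0.0 and recs[0].degree == 0


@pytest.mark.parametrize("seed", range(25))
def test_centralities_match_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.7)), seed=int(rng.integers(1 << 30)))
    recs = {r.node: r for r in centralities(_net_from_graph(g))}
    expected = oracle_centralities(list(g.nodes), list(g.edges))
    for v, (deg, btw, clo) in expected.items():
        assert recs[v].degree == deg
        assert recs[v].betweenness == pytest.approx(btw, abs=1e-12)
        assert recs[v].closeness == pytest.approx(clo, abs=1e-12)


# ---------------------------------------------------------------------------
# select_hubs


def _records(degrees):
    return [CentralityRecord(f"n{i}", d, 0.0, 0.0) for i, d in enumerate(degrees)]


def test_all_equal_degrees_no_hubs():
    assert select_hubs(_records([3, 3, 3, 3])) == set()


def test_single_high_degree_hub():
    recs = _records([1, 1, 1, 1, 10])
    assert select_hubs(recs) == {"n4"}


def test_even_count_median_is_mean_of_middle_two():
    # degrees {1,2,4,9}: median 3, threshold 6 -> only the 9
    assert select_hubs(_records([1, 2, 4, 9])) == {"n3"}


def test_empty_records_raise():
    with pytest.raises(ValueError):
        select_hubs([])


def test_hub_count_bound(rng):
    for _ in range(20):
        degrees = rng.integers(0, 50, size=int(rng.integers(2, 30))).tolist()
        hubs = select_hubs(_records(degrees))
        n = len(degrees)
        # strictly above the median leaves at most half the nodes
        assert len(hubs) <= (n + 1) // 2


def test_relabeling_invariance(rng):
    g = nx.gnp_random_graph(12, 0.3, seed=5)
    net = _net_from_graph(g)
    hubs = select_hubs(centralities(net))
    mapping = {n: f"x{n}" for n in g.nodes}
    net2 = _net_from_graph(nx.relabel_nodes(g, mapping))
    hubs2 = select_hubs(centralities(net2))
    assert {mapping[h] for h in hubs} == hubs2


def test_planted_star_centers_selected():
    rng = np.random.default_rng(0)
    g = nx.gnp_random_graph(100, 0.03, seed=1)
    centers = [0, 1, 2, 3, 4]
    for c in centers:
        spokes = rng.choice([n for n in g.nodes if n != c], size=30, replace=False)
        g.add_edges_from((c, int(s)) for s in spokes)
    hubs = select_hubs(centralities(_net_from_graph(g)))
    assert set(centers) <= hubs


# ---------------------------------------------------------------------------
# refine_major_hubs


def test_single_hub_empty():
    g = nx.path_graph(3)
    net = _net_from_graph(g)
    assert refine_major_hubs(net, {1}) == set()


def test_clique_all_ties_empty():
    g = nx.complete_graph(4)
    net = _net_from_graph(g)
    assert refine_major_hubs(net, set(g.nodes)) == set()


def test_vertex_transitive_cycle_empty():
    g = nx.cycle_graph(8)
    net = _net_from_graph(g)
    assert refine_major_hubs(net, set(g.nodes)) == set()


def test_hubs_not_subset_raises():
    net = _net_from_graph(nx.path_graph(3))
    with pytest.raises(ValueError):
        refine_major_hubs(net, {99})


def test_core_periphery_matches_triple_median_oracle():
    rng = np.random.default_rng(3)
    g = nx.Graph()
    core = list(range(6))
    periphery = list(range(6, 20))
    g.add_edges_from(combinations(core, 2))  # dense core
    for p in periphery:
        g.add_edge(p, int(rng.integers(0, 6)))  # sparse attachment
    net = _net_from_graph(g)
    hubs = set(g.nodes)
    got = refine_major_hubs(net, hubs)

    recs = centralities(PharmNetwork(net.graph.subgraph(hubs).copy()))
    med_d = statistics.median(r.degree for r in recs)
    med_b = statistics.median(r.betweenness for r in recs)
    med_c = statistics.median(r.closeness for r in recs)
    expected = {
        r.node
        for r in recs
        if r.degree > med_d and r.betweenness > med_b and r.closeness > med_c
    }
    assert got == expected
    assert got <= set(core)
    assert got  # the dense core must survive


def test_stage2_subset_of_stage1():
    g = nx.gnp_random_graph(60, 0.1, seed=9)
    net = _net_from_graph(g)
    hubs = select_hubs(centralities(net))
    major = refine_major_hubs(net, hubs)
    assert major <= hubs <= net.nodes


# ---------------------------------------------------------------------------
# classify_candidates


def _role_net(roles):
    net = PharmNetwork(nx.Graph())
    for node, role in roles.items():
        net.graph.add_node(node, role=role)
    return net


def test_all_disease_no_candidates():
    net = _role_net({"A": "disease_gene", "B": "disease_gene"})
    sel = classify_candidates({"A", "B"}, net)
    assert sel.candidate_targets == frozenset()
    assert sel.disease_genes == {"A", "B"}


def test_dual_role_counted_twice():
    net = _role_net({"T": "putative_target", "D": "disease_gene", "B": "both"})
    sel = classify_candidates({"T", "D", "B"}, net)
    assert sel.candidate_targets == {"T", "B"}
    assert sel.disease_genes == {"D", "B"}
    assert len(sel.candidate_targets) + len(sel.disease_genes) == 4 > len(sel.major_hubs)


def test_counts_match_membership_oracle(rng):
    roles = {}
    for i in range(40):
        roles[f"n{i}"] = ["putative_target", "disease_gene", "both"][int(rng.integers(3))]
    net = _role_net(roles)
    major = {f"n{i}" for i in range(0, 40, 3)}
    sel = classify_candidates(major, net, hubs=set(roles))
    assert sel.candidate_targets == {
        n for n in major if roles[n] in ("putative_target", "both")
    }
    assert sel.disease_genes == {n for n in major if roles[n] in ("disease_gene", "both")}
    assert sel.major_hubs <= sel.hubs


# ---------------------------------------------------------------------------
# fixtures + IO


def test_planted_hub_recovery_single_seed():
    cfg = SimConfig(seed=11, net_nodes=200, n_planted_hubs=5, hub_degree=30)
    edges, roles, planted = gen_network_fixture(cfg)
    targets = {n for n, r in roles.items() if r in ("putative_target", "both")}
    disease = {n for n, r in roles.items() if r in ("disease_gene", "both")}
    net = build_network(targets, disease, edges, 0.4)
    recs = [
        CentralityRecord(n, net.graph.degree(n), 0.0, 0.0) for n in net.graph.nodes
    ]
    hubs = select_hubs(recs)
    assert sum(1 for h in planted if h in hubs) >= 4


def test_string_scores_autodetected(tmp_path):
    p = tmp_path / "edges.tsv"
    p.write_text("node_a\tnode_b\tcombined_score\nA\tB\t900\nB\tC\t150\n")
    edges = read_edge_list(p)
    assert edges[0].confidence == pytest.approx(0.9)
    assert edges[1].confidence == pytest.approx(0.15)
    p2 = tmp_path / "edges01.tsv"
    p2.write_text("A\tB\t0.9\nB\tC\t0.15\n")
    assert [e.confidence for e in read_edge_list(p2)] == [0.9, 0.15]


def test_sif_and_attributes_export(tmp_path):
    net = build_network({"A", "B"}, {"C", "LONE"}, _edges([("A", "B"), ("B", "C")]))
    recs = centralities(net)
    write_sif(net, tmp_path / "net.sif")
    sif = (tmp_path / "net.sif").read_text().splitlines()
    assert "A\tpp\tB" in sif and "LONE" in sif
    write_node_attributes(net, recs, {"B"}, set(), tmp_path / "attrs.tsv")
    lines = (tmp_path / "attrs.tsv").read_text().splitlines()
    assert lines[0].split("\t")[0] == "node"
    assert len(lines) == 1 + 4
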