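"""Site labels, path collapse, transition networks and clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidsites import (
    LipidPath,
    SiteNetwork,
    assign_leaflets,
    build_network,
    canonical_label,
    cluster_network,
    collapse_path,
    frame_site,
    label_from_bits,
    occupancy_filter,
    paths_from_table,
    scan_contacts,
)


def test_canonical_label_examples():
    assert canonical_label({1, 6, 7}) == "167"
    assert canonical_label([7, 6, 1]) == "167"
    assert canonical_label({5}) == "5"
    # idempotent: re-parsing its own digits reproduces it
    assert canonical_label(int(c) for c in "167") == "167"
    with pytest.raises(ValueError, match="non-empty"):
        canonical_label([])
    with pytest.raises(ValueError, match="outside"):
        canonical_label([0, 9])


@settings(derandomize=True, max_examples=50)
@given(st.sets(st.integers(min_value=1, max_value=8), min_size=1))
def test_canonical_label_is_sorted_and_order_free(helix_set):
    lab = canonical_label(helix_set)
    assert list(lab) == sorted(lab)
    assert canonical_label(reversed(sorted(helix_set))) == lab


def test_label_from_bits():
    assert label_from_bits(0) is None
    assert label_from_bits(0b100001) == "16"
    assert label_from_bits(1 << 7) == "8"


def test_collapse_path_examples():
    assert collapse_path(["1", "1", "16", "16", "16", "6", "1"]) == \
        ("1", "16", "6", "1")
    assert collapse_path(["5", None, "5"]) == ("5",)
    assert collapse_path(["167"] * 500) == ("167",)
    assert collapse_path([None, None]) == ()


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.one_of(st.none(),
                          st.sampled_from(["1", "5", "16", "167"]))))
def test_collapse_is_idempotent_and_run_free(seq):
    out = collapse_path(seq)
    assert collapse_path(out) == out
    assert all(a != b for a, b in zip(out, out[1:]))


def test_occupancy_filter_boundary_is_inclusive():
    events = np.zeros((100, 3), dtype=bool)
    events[:10, 0] = True       # 10%: excluded at 0.20
    events[:20, 1] = True       # exactly 20%: retained ("at least 20%")
    retained = occupancy_filter(events, 0.20)
    assert retained.tolist() == [1]


def test_occupancy_filter_extremes():
    events = np.zeros((50, 4), dtype=bool)
    events[0, 0] = True
    events[:, 1] = True
    assert occupancy_filter(events, 1e-12).tolist() == [0, 1]
    assert occupancy_filter(events, 1.0).tolist() == [1]
    with pytest.raises(ValueError):
        occupancy_filter(np.zeros((0, 3), dtype=bool), 0.2)
    with pytest.raises(ValueError):
        occupancy_filter(events, 0.0)


def test_frame_site_matches_scan_bits(biased_run, helices):
    system, traj, truth = biased_run
    table = scan_contacts(traj, system, 0.5, helices=helices)
    checked = 0
    for f in range(0, 40, 7):
        for lip in range(0, system.n_lipids, 17):
            want = label_from_bits(int(table.site_bits[f, lip]))
            got = frame_site(traj, system, helices, lip, f, 0.5)
            assert got == want
            checked += 1
    assert checked > 10


def test_build_network_single_path_example():
    p = LipidPath(0, "external", ("1", "16", "6", "1"))
    net = build_network([p], "external")
    assert net.node_weights == {"1": 2, "16": 1, "6": 1}
    assert net.edge_counts == {("1", "16"): 1, ("16", "6"): 1, ("1", "6"): 1}


def test_two_identical_paths_double_all_weights():
    p = LipidPath(0, "external", ("1", "16", "6", "1"))
    q = LipidPath(1, "external", ("1", "16", "6", "1"))
    one = build_network([p], "external")
    two = build_network([p, q], "external")
    assert two.node_weights == {k: 2 * v for k, v in one.node_weights.items()}
    assert two.edge_counts == {k: 2 * v for k, v in one.edge_counts.items()}


def test_directed_network_preserves_order():
    p = LipidPath(0, "external", ("1", "6", "1"))
    net = build_network([p], "external", directed=True)
    assert net.edge_counts == {("1", "6"): 1, ("6", "1"): 1}
    undirected = build_network([p], "external")
    assert undirected.edge_counts == {("1", "6"): 2}


def test_leaflet_mismatch_rejected():
    p = LipidPath(0, "internal", ("1",))
    with pytest.raises(ValueError, match="leaflet"):
        build_network([p], "external")


def test_conservation_invariants_on_random_paths():
    rng = np.random.default_rng(0)
    labels = ["1", "2", "16", "67", "167", "8"]
    for trial in range(200):
        paths = []
        for lip in range(rng.integers(1, 8)):
            seq = collapse_path(rng.choice(labels, size=rng.integers(1, 12)))
            if seq:
                paths.append(LipidPath(lip, "external", seq))
        net = build_network(paths, "external")
        assert sum(net.node_weights.values()) == sum(len(p) for p in paths)
        assert sum(net.edge_counts.values()) == sum(
            len(p) - 1 for p in paths)


def test_half_networks_sum_to_whole():
    rng = np.random.default_rng(1)
    labels = ["1", "2", "16", "67"]
    paths_a = [LipidPath(i, "external",
                         collapse_path(rng.choice(labels, size=6)))
               for i in range(5)]
    paths_b = [LipidPath(i, "external",
                         collapse_path(rng.choice(labels, size=6)))
               for i in range(5, 9)]
    whole = build_network(paths_a + paths_b, "external")
    na = build_network(paths_a, "external")
    nb = build_network(paths_b, "external")
    for k in whole.node_weights:
        assert whole.node_weights[k] == (na.node_weights.get(k, 0)
                                         + nb.node_weights.get(k, 0))
    for k in whole.edge_counts:
        assert whole.edge_counts[k] == (na.edge_counts.get(k, 0)
                                        + nb.edge_counts.get(k, 0))


def _two_cliques():
    nodes = ["1", "2", "3", "4", "5", "6", "7", "8"]
    edges = {}
    for grp in (nodes[:4], nodes[4:]):
        for i in range(4):
            for j in range(i + 1, 4):
                edges[(grp[i], grp[j])] = 1
    edges[("1", "5")] = 1
    return SiteNetwork(leaflet="external",
                       node_weights={n: 1 for n in nodes},
                       edge_counts=edges)


def test_louvain_two_cliques_and_determinism():
    net = cluster_network(_two_cliques(), resolution=0.8, seed=0)
    groups = {}
    for n, c in net.clusters.items():
        groups.setdefault(c, set()).add(n)
    assert sorted(map(sorted, groups.values())) == [
        ["1", "2", "3", "4"], ["5", "6", "7", "8"]]
    again = cluster_network(_two_cliques(), resolution=0.8, seed=0)
    assert again.clusters == net.clusters
    assert again.modularity_score == net.modularity_score


def test_single_node_network_one_cluster():
    net = SiteNetwork(leaflet="external", node_weights={"1": 3},
                      edge_counts={})
    net = cluster_network(net)
    assert net.clusters == {"1": 0}
    assert net.modularity_score == 0.0
    with pytest.raises(ValueError, match="empty"):
        cluster_network(SiteNetwork(leaflet="x", node_weights={},
                                    edge_counts={}))


def test_paths_require_site_record(small_run):
    system, traj, truth = small_run
    table = scan_contacts(traj, system, 0.5)      # no helix map given
    leaf = assign_leaflets(system, traj)
    with pytest.raises(ValueError, match="site record"):
        paths_from_table(table, leaf)


def test_gexf_round_trip(tmp_path):
    import networkx as nx
    from lipidsites import write_gexf
    net = cluster_network(_two_cliques(), resolution=0.8, seed=0)
    out = tmp_path / "net.gexf"
    write_gexf(net, str(out))
    g = nx.read_gexf(str(out))
    assert set(g.nodes) == set(net.node_weights)
    assert g.nodes["1"]["weight"] == 1
    assert g.nodes["1"]["cluster"] == net.clusters["1"]
    assert g.edges[("1", "2")]["count"] == 1
    # volatile timestamp pinned for reproducibility
    assert 'lastmodifieddate="1970-01-01"' in out.read_text()
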