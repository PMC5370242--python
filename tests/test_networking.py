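"""Consensus clustering, network building/pruning, blank subtraction,
library search and node statistics."""
import itertools

import numpy as np
import pytest

from plantcarto import networking as nw
from plantcarto.errors import ValidationError
from plantcarto.models import ConsensusSpectrum, SampleMetadata
from plantcarto.spectral_processing import cosine_score

from conftest import make_spectrum, random_ms2


def _spec(mz, inten, prec, sample="s1", scan="x1"):
    return make_spectrum(mz, inten, precursor=prec, sample_id=sample,
                         scan_id=scan)


# ---------------------------------------------------------------------------
# clustering


def test_two_identical_spectra_one_node():
    a = _spec([100.0, 150.0, 200.0, 250.0, 300.0], [1, 5, 3, 2, 4], 400.0,
              scan="a")
    b = _spec([100.0, 150.0, 200.0, 250.0, 300.0], [1, 5, 3, 2, 4], 400.0,
              scan="b")
    nodes = nw.cluster_spectra([a, b])
    assert len(nodes) == 1
    assert nodes[0].n_members == 2
    assert nodes[0].precursor_mz == pytest.approx(400.0)


def test_singleton_discarded():
    a = _spec([100.0, 150.0], [1, 2], 400.0)
    assert nw.cluster_spectra([a]) == []


def test_distant_precursor_not_merged():
    peaks = ([100.0, 150.0, 200.0], [1, 5, 3])
    a = _spec(*peaks, 400.00, scan="a")
    b = _spec(*peaks, 400.00, scan="b")
    c = _spec(*peaks, 400.50, scan="c")
    nodes = nw.cluster_spectra([a, b, c])
    assert len(nodes) == 1
    assert nodes[0].n_members == 2


def test_clustering_input_order_invariant():
    rng = np.random.default_rng(5)
    spectra = []
    for i in range(6):
        base = random_ms2(rng, n_peaks=6, precursor=400.0 + i)
        for rep in range(3):
            spectra.append(base.copy(scan_id=f"m{i}r{rep}",
                                     sample_id=f"s{rep}"))
    forward = nw.cluster_spectra(spectra)
    backward = nw.cluster_spectra(spectra[::-1])
    assert [n.node_id for n in forward] == [n.node_id for n in backward]
    for x, y in zip(forward, backward):
        assert x.member_scan_refs == y.member_scan_refs
        np.testing.assert_allclose(x.mz, y.mz)


# ---------------------------------------------------------------------------
# network building and pruning


def _node(node_id, spec, members=None):
    return ConsensusSpectrum(node_id=node_id, precursor_mz=spec.precursor_mz,
                             mz=spec.mz, intensity=spec.intensity,
                             member_scan_refs=members
                             or [("s1", node_id + "a"),
                                 ("s2", node_id + "b")])


def test_edge_created_above_thresholds():
    s = _spec([100.0, 150.0, 200.0, 250.0, 300.0, 350.0],
              [1, 5, 3, 2, 4, 6], 400.0)
    net = nw.build_network([_node("n0", s), _node("n1", s)])
    assert len(net.edges) == 1
    assert net.edges[0].cosine == pytest.approx(1.0)


def test_edge_requires_min_matched_peaks():
    s = _spec([100.0, 150.0, 200.0], [1, 5, 3], 400.0)
    net = nw.build_network([_node("n0", s), _node("n1", s)])
    assert net.edges == []  # cosine 1.0 but only 3 matched peaks


def test_mutual_topk_pruning_matches_enumeration_oracle():
    """Random similar nodes, low threshold: surviving edges must equal the
    literal both-endpoint top-K rule applied to the raw scored pairs."""
    rng = np.random.default_rng(11)
    base_mz = np.sort(rng.uniform(80.0, 380.0, size=8))
    nodes = []
    for i in range(14):
        inten = rng.uniform(1.0, 10.0, size=8)
        nodes.append(_node(f"n{i:02d}",
                           _spec(base_mz, inten, 400.0)))
    top_k = 3
    net = nw.build_network(nodes, edge_cosine=0.2, min_matched=4,
                           top_k=top_k)
    # oracle: score all pairs, apply mutual top-K by explicit sorting
    raw = {}
    for a, b in itertools.combinations(nodes, 2):
        score, matched = cosine_score(a.as_spectrum(), b.as_spectrum(),
                                      shifted=True)
        if score >= 0.2 and matched >= 4:
            raw[(a.node_id, b.node_id)] = score
    keep = {}
    for nid in [n.node_id for n in nodes]:
        inc = sorted(((s, pair) for pair, s in raw.items() if nid in pair),
                     key=lambda x: (-x[0],
                                    x[1][1] if x[1][0] == nid else x[1][0]))
        keep[nid] = {pair for _, pair in inc[:top_k]}
    expected = {pair for pair in raw
                if pair in keep[pair[0]] and pair in keep[pair[1]]}
    got = {(e.node_a, e.node_b) for e in net.edges}
    assert got == expected
    assert got <= set(raw)  # pruning never adds edges
    counts = {}
    for a, b in got:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    assert all(c <= top_k for c in counts.values())


# ---------------------------------------------------------------------------
# blank subtraction


def _meta():
    return [SampleMetadata("s1", "p", "leaf", False, 0, 0, 0, 1),
            SampleMetadata("s2", "p", "stem", False, 0, 0, 0, 1),
            SampleMetadata("bl", "none", "blank", True)]


def test_blank_subtraction_rules():
    s = _spec([100.0, 150.0, 200.0, 250.0, 300.0], [1, 5, 3, 2, 4], 400.0)
    tissue = _node("n0", s)
    tainted = _node("n1", s, members=[("s1", "a"), ("bl", "b")])
    net = nw.build_network([tissue, tainted])
    sub = nw.subtract_blanks(net, _meta())
    assert [n.node_id for n in sub.nodes] == ["n0"]
    assert sub.edges == []  # the edge was incident to the removed node
    again = nw.subtract_blanks(sub, _meta())
    assert [n.node_id for n in again.nodes] == ["n0"]  # idempotent


def test_blank_subtraction_exclusive_mode():
    s = _spec([100.0, 150.0], [1, 5], 400.0)
    tainted = _node("n0", s, members=[("s1", "a"), ("bl", "b")])
    pure_blank = _node("n1", s, members=[("bl", "c"), ("bl", "d")])
    net = nw.MolecularNetwork(nodes=[tainted, pure_blank], edges=[])
    sub = nw.subtract_blanks(net, _meta(), mode="exclusive")
    assert [n.node_id for n in sub.nodes] == ["n0"]


def test_blank_subtraction_missing_metadata():
    s = _spec([100.0], [1], 400.0)
    net = nw.MolecularNetwork(
        nodes=[_node("n0", s, members=[("ghost", "a")])], edges=[])
    with pytest.raises(ValidationError, match="ghost"):
        nw.subtract_blanks(net, _meta())


# ---------------------------------------------------------------------------
# library search


def test_library_identity_hit():
    s = _spec([100.0, 150.0, 200.0, 250.0, 300.0], [1, 5, 3, 2, 4], 400.0)
    lib = s.copy(compound_name="thing", library_id="L1")
    hits = nw.library_search([_node("n0", s)], [lib])
    assert hits["n0"].cosine == pytest.approx(1.0)
    assert hits["n0"].precursor_ppm_error == pytest.approx(0.0)
    assert hits["n0"].compound_name == "thing"


def test_library_precursor_gate():
    s = _spec([100.0, 150.0, 200.0, 250.0, 300.0], [1, 5, 3, 2, 4], 400.0)
    lib = s.copy(precursor_mz=400.5, compound_name="wrong")
    assert nw.library_search([_node("n0", s)], [lib]) == {}


def test_library_best_cosine_wins():
    s = _spec([100.0, 150.0, 200.0, 250.0, 300.0], [1, 5, 3, 2, 4], 400.0)
    perfect = s.copy(compound_name="exact", library_id="L1")
    worse = s.copy(intensity=s.intensity[::-1].copy(),
                   compound_name="approx", library_id="L2")
    hits = nw.library_search([_node("n0", s)], [worse, perfect])
    assert hits["n0"].compound_name == "exact"


# ---------------------------------------------------------------------------
# node statistics


def test_node_sample_frequency_distinct_count():
    s = _spec([100.0], [1], 400.0)
    node = _node("n0", s, members=[("a", "1"), ("a", "2"), ("b", "3"),
                                   ("c", "4"), ("c", "5")])
    assert nw.node_sample_frequency([node]) == {"n0": 3}


def test_msms_overlap_matches_brute_force():
    rng = np.random.default_rng(9)
    tissues = ["leaf", "stem", "fruit"]
    meta = [SampleMetadata(f"s{i}", "p", tissues[i % 3], False, 0, 0, 0, 1)
            for i in range(9)]
    s = _spec([100.0], [1], 400.0)
    nodes = []
    expected = {}
    for i in range(40):
        k = int(rng.integers(1, 10))
        members = [(f"s{j}", f"{i}.{j}")
                   for j in rng.choice(9, size=k, replace=False)]
        nodes.append(_node(f"n{i:02d}", s, members=members))
        region = frozenset(tissues[int(sid[1:]) % 3] for sid, _ in members)
        expected[region] = expected.get(region, 0) + 1
    got = nw.msms_tissue_overlap(nodes, meta)
    assert got == expected
    assert sum(got.values()) == len(nodes)


def test_components_partition_nodes():
    s = _spec([100.0, 150.0, 200.0, 250.0, 300.0], [1, 5, 3, 2, 4], 400.0)
    nodes = [_node(f"n{i}", s) for i in range(3)]
    iso = _node("n9", _spec([111.0, 222.0, 333.0, 345.0], [1, 2, 3, 4],
                            500.0))
    net = nw.build_network(nodes + [iso])
    comps = nw.connected_components(net)
    all_ids = set().union(*comps)
    assert all_ids == {"n0", "n1", "n2", "n9"}
    assert sum(len(c) for c in comps) == 4
    assert {"n9"} in comps
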