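"""MS/MS consensus clustering, molecular network construction, blank
subtraction, spectral-library search, and node/sample statistics.

Clustering is a deterministic single-pass greedy variant of consensus
clustering: spectra sorted by (precursor m/z, sample, scan) join the first
cluster within 0.02 Da whose consensus they match at cosine >= 0.7;
clusters with fewer than 2 member spectra are discarded. Network edges use
the precursor-shifted (modified) cosine at 0.7 with >= 4 matched fragments,
then mutual top-10 pruning. Nodes with any member scan from a blank sample
are subtracted.
"""
from __future__ import annotations

import itertools
from bisect import bisect_left, bisect_right
from collections import Counter

import numpy as np

from .errors import ValidationError
from .models import (ConsensusSpectrum, LibraryHit, MolecularNetwork,
                     NetworkEdge, SampleMetadata, Spectrum)
from .spectral_processing import cosine_score, filter_window_top_n


def _merge_peaks(peak_sets: list[tuple[np.ndarray, np.ndarray]],
                 frag_tol_da: float) -> tuple[np.ndarray, np.ndarray]:
    """Pool member peaks; greedily chain peaks within ``frag_tol_da`` of the
    running intensity-weighted mean m/z into one consensus peak with summed
    intensity."""
    all_mz = np.concatenate([p[0] for p in peak_sets])
    all_int = np.concatenate([p[1] for p in peak_sets])
    order = np.argsort(all_mz, kind="stable")
    all_mz, all_int = all_mz[order], all_int[order]
    out_mz, out_int = [], []
    group_w = group_wm = 0.0
    for mz, inten in zip(all_mz, all_int):
        if group_w > 0 and abs(mz - group_wm / group_w) <= frag_tol_da:
            group_w += inten
            group_wm += mz * inten
        else:
            if group_w > 0:
                out_mz.append(group_wm / group_w)
                out_int.append(group_w)
            group_w, group_wm = inten, mz * inten
    if group_w > 0:
        out_mz.append(group_wm / group_w)
        out_int.append(group_w)
    return np.array(out_mz), np.array(out_int)


class _Cluster:
    __slots__ = ("members", "peak_sets", "prec_weight", "weight",
                 "consensus")

    def __init__(self, s: Spectrum):
        self.members: list[Spectrum] = [s]
        self.peak_sets = [(s.mz, s.intensity)]
        total = float(s.intensity.sum()) or 1.0
        self.prec_weight = s.precursor_mz * total
        self.weight = total
        self.consensus: Spectrum | None = None

    @property
    def precursor(self) -> float:
        return self.prec_weight / self.weight

    def add(self, s: Spectrum):
        self.members.append(s)
        self.peak_sets.append((s.mz, s.intensity))
        total = float(s.intensity.sum()) or 1.0
        self.prec_weight += s.precursor_mz * total
        self.weight += total
        self.consensus = None

    def consensus_spectrum(self, frag_tol_da: float, top_n: int,
                           window_da: float) -> Spectrum:
        if self.consensus is None:
            mz, inten = _merge_peaks(self.peak_sets, frag_tol_da)
            raw = Spectrum(scan_id="consensus", ms_level=2, rt_seconds=0.0,
                           mz=mz, intensity=inten,
                           precursor_mz=self.precursor)
            # re-apply the window filter so a merged consensus obeys the
            # same density bound as its members
            self.consensus = filter_window_top_n(raw, top_n=top_n,
                                                 window_da=window_da)
        return self.consensus


def cluster_spectra(spectra: list[Spectrum], prec_tol_da: float = 0.02,
                    frag_tol_da: float = 0.02,
                    cluster_cosine: float = 0.7,
                    min_members: int = 2,
                    consensus_top_n: int = 6,
                    consensus_window_da: float = 50.0
                    ) -> list[ConsensusSpectrum]:
    """Greedy incremental consensus clustering of filtered MS2 spectra.

    Input order does not matter: spectra are sorted by (precursor m/z,
    sample_id, scan_id) first. Each spectrum joins the first (oldest)
    cluster whose consensus precursor lies within ``prec_tol_da`` and whose
    consensus spectrum scores >= ``cluster_cosine`` (unshifted cosine);
    otherwise it seeds a new cluster. Clusters with fewer than
    ``min_members`` spectra are discarded.
    """
    todo = sorted(spectra,
                  key=lambda s: (s.precursor_mz, s.sample_id, s.scan_id))
    clusters: list[_Cluster] = []
    precursors: list[float] = []  # sorted view for the precursor gate
    cluster_at: list[int] = []  # creation index, parallel to precursors
    for s in todo:
        lo = bisect_left(precursors, s.precursor_mz - prec_tol_da)
        hi = bisect_right(precursors, s.precursor_mz + prec_tol_da)
        target = None
        for k in sorted(cluster_at[lo:hi]):
            c = clusters[k]
            if abs(c.precursor - s.precursor_mz) > prec_tol_da:
                continue
            cons = c.consensus_spectrum(frag_tol_da, consensus_top_n,
                                        consensus_window_da)
            score, _ = cosine_score(s, cons, frag_tol_da=frag_tol_da,
                                    shifted=False)
            if score >= cluster_cosine:
                target = c
                break
        if target is None:
            c = _Cluster(s)
            idx = len(clusters)
            clusters.append(c)
            pos = bisect_left(precursors, s.precursor_mz)
            precursors.insert(pos, s.precursor_mz)
            cluster_at.insert(pos, idx)
        else:
            target.add(s)
    kept = [c for c in clusters if len(c.members) >= min_members]
    kept.sort(key=lambda c: (c.precursor,
                             c.members[0].sample_id, c.members[0].scan_id))
    out = []
    for i, c in enumerate(kept):
        cons = c.consensus_spectrum(frag_tol_da, consensus_top_n,
                                    consensus_window_da)
        out.append(ConsensusSpectrum(
            node_id=f"n{i:05d}", precursor_mz=c.precursor,
            mz=cons.mz, intensity=cons.intensity,
            member_scan_refs=[(m.sample_id, m.scan_id) for m in c.members]))
    return out


def build_network(nodes: list[ConsensusSpectrum], edge_cosine: float = 0.7,
                  min_matched: int = 4, frag_tol_da: float = 0.02,
                  top_k: int = 10) -> MolecularNetwork:
    """Score all node pairs with the shifted cosine; keep edges with
    cosine >= ``edge_cosine`` and n_matched >= ``min_matched``; then prune
    to mutual top-``top_k``: an edge survives iff it ranks within the top_k
    by cosine at BOTH endpoints (ties break toward the lower partner id)."""
    specs = {n.node_id: n.as_spectrum() for n in nodes}
    raw_edges: list[NetworkEdge] = []
    ids = [n.node_id for n in nodes]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate node ids")
    for a, b in itertools.combinations(nodes, 2):
        score, matched = cosine_score(specs[a.node_id], specs[b.node_id],
                                      frag_tol_da=frag_tol_da, shifted=True)
        if score >= edge_cosine and matched >= min_matched:
            raw_edges.append(NetworkEdge(
                node_a=a.node_id, node_b=b.node_id, cosine=score,
                n_matched=matched,
                delta_mz=a.precursor_mz - b.precursor_mz))
    incident: dict[str, list[NetworkEdge]] = {n.node_id: [] for n in nodes}
    for e in raw_edges:
        incident[e.node_a].append(e)
        incident[e.node_b].append(e)
    rank: dict[tuple[str, int], int] = {}
    for nid, edges in incident.items():
        edges.sort(key=lambda e: (-e.cosine,
                                  e.node_b if e.node_a == nid else e.node_a))
        for r, e in enumerate(edges):
            rank[(nid, id(e))] = r
    kept = [e for e in raw_edges
            if rank[(e.node_a, id(e))] < top_k
            and rank[(e.node_b, id(e))] < top_k]
    return MolecularNetwork(nodes=list(nodes), edges=kept)


def subtract_blanks(network: MolecularNetwork,
                    metadata: list[SampleMetadata],
                    mode: str = "any") -> MolecularNetwork:
    """Remove background nodes attributable to solvent/system blanks.

    ``mode='any'`` (default) removes every node with at least one member
    scan from a blank sample; ``mode='exclusive'`` removes only nodes whose
    members all come from blanks. Incident edges are removed with their
    nodes. Idempotent.
    """
    if mode not in ("any", "exclusive"):
        raise ValidationError(f"unknown blank-subtraction mode '{mode}'")
    blank = {m.sample_id: m.is_blank for m in metadata}
    drop = set()
    for node in network.nodes:
        flags = []
        for sid in node.member_samples:
            if sid not in blank:
                raise ValidationError(
                    f"node {node.node_id}: sample '{sid}' missing from "
                    "metadata")
            flags.append(blank[sid])
        if (any(flags) if mode == "any" else (flags and all(flags))):
            drop.add(node.node_id)
    nodes = [n for n in network.nodes if n.node_id not in drop]
    edges = [e for e in network.edges
             if e.node_a not in drop and e.node_b not in drop]
    annotations = {k: v for k, v in network.annotations.items()
                   if k not in drop}
    return MolecularNetwork(nodes=nodes, edges=edges,
                            annotations=annotations)


def library_search(nodes: list[ConsensusSpectrum],
                   library: list[Spectrum], prec_tol_da: float = 0.02,
                   frag_tol_da: float = 0.02, match_cosine: float = 0.7,
                   min_matched: int = 4,
                   ppm_cap: float = 20.0) -> dict[str, LibraryHit]:
    """Best-cosine library identification per node.

    A record qualifies when its precursor lies within ``prec_tol_da`` of the
    node's, the unshifted cosine is >= ``match_cosine`` with
    >= ``min_matched`` matched fragments, and the precursor error is within
    ``ppm_cap`` ppm. Unmatched nodes are absent from the result.
    """
    if not library:
        raise ValidationError("library_search needs a non-empty library")
    lib = sorted(library, key=lambda s: (s.precursor_mz,
                                         s.library_id or s.scan_id))
    lib_prec = [s.precursor_mz for s in lib]
    hits: dict[str, LibraryHit] = {}
    for node in nodes:
        spec = node.as_spectrum()
        lo = bisect_left(lib_prec, node.precursor_mz - prec_tol_da)
        hi = bisect_right(lib_prec, node.precursor_mz + prec_tol_da)
        best: LibraryHit | None = None
        for rec in lib[lo:hi]:
            ppm = 1e6 * (node.precursor_mz - rec.precursor_mz) / rec.precursor_mz
            if abs(ppm) > ppm_cap:
                continue
            score, matched = cosine_score(spec, rec,
                                          frag_tol_da=frag_tol_da,
                                          shifted=False)
            if score < match_cosine or matched < min_matched:
                continue
            if best is None or score > best.cosine:
                best = LibraryHit(node_id=node.node_id,
                                  library_id=rec.library_id or rec.scan_id,
                                  compound_name=rec.compound_name or "",
                                  cosine=score, n_matched=matched,
                                  precursor_ppm_error=ppm)
        if best is not None:
            hits[node.node_id] = best
    return hits


def node_sample_frequency(nodes: list[ConsensusSpectrum]) -> dict[str, int]:
    """Distinct samples contributing member scans, per node (the x-axis of
    a node-frequency plot)."""
    return {n.node_id: len(n.member_samples) for n in nodes}


def msms_tissue_overlap(nodes: list[ConsensusSpectrum],
                        metadata: list[SampleMetadata]
                        ) -> dict[frozenset, int]:
    """Venn region counts of consensus spectra across tissue types.

    Each node maps to the set of tissues of its non-blank member samples;
    the result counts every non-empty region of the k-set partition and
    sums to the number of nodes with at least one non-blank member.
    """
    tissue = {}
    for m in metadata:
        tissue[m.sample_id] = None if m.is_blank else m.tissue
    regions: Counter = Counter()
    for node in nodes:
        groups = set()
        for sid in node.member_samples:
            if sid not in tissue:
                raise ValidationError(
                    f"node {node.node_id}: sample '{sid}' missing from "
                    "metadata")
            if tissue[sid] is not None:
                groups.add(tissue[sid])
        if groups:
            regions[frozenset(groups)] += 1
    return dict(regions)


def connected_components(network: MolecularNetwork) -> list[set[str]]:
    """Molecular families: connected components of the pruned network
    (singletons included)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(n.node_id for n in network.nodes)
    g.add_edges_from((e.node_a, e.node_b) for e in network.edges)
    return [set(c) for c in nx.connected_components(g)]
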