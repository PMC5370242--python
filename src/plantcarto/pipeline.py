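"""Stage orchestration: features -> network -> match -> stats -> map.

Each stage is a function from files to files so that the CLI subcommands
composed stepwise produce byte-identical artifacts to the single ``run``
entry point, which simply calls them in order and writes a manifest
(config hash, input checksums, per-stage counts).
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import feature_finding, formats_io, networking, stats_mapping
from .config import PipelineConfig
from .errors import CartoError, ValidationError
from .models import FeatureMatrix, MolecularNetwork, Spectrum
from .spectral_processing import filter_spectrum
from .synth_data import library_spectra, make_study, render_runs

logger = logging.getLogger("carto")

NODES_MGF = "nodes.mgf"
FEATURE_MATRIX_CSV = "feature_matrix.csv"
EDGES_TSV = "edges.tsv"
NETWORK_GRAPHML = "network.graphml"
ANNOTATIONS_TSV = "annotations.tsv"
DISTANCES_CSV = "distance_matrix.csv"
ORDINATION_CSV = "ordination.csv"
VENN_JSON = "venn_ms1.json"
MSMS_VENN_JSON = "venn_msms.json"
FREQ_TSV = "node_sample_frequency.tsv"
MANIFEST_JSON = "manifest.json"


def _run_paths(cfg: PipelineConfig) -> list[Path]:
    paths = sorted(Path(cfg.input_dir).glob("*.mzML"))
    paths += sorted(Path(cfg.input_dir).glob("*.mzXML"))
    if not paths:
        raise ValidationError(f"no mzML/mzXML runs under {cfg.input_dir}")
    return paths


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig) -> dict:
    """Write the synthetic study (mzML runs, metadata CSV, per-plant STL
    meshes, reference MGF library, truth JSON) into the input directory."""
    out = Path(cfg.input_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = make_study(cfg.seed, n_tissues=cfg.sim_n_tissues,
                       spots_per_tissue=cfg.sim_spots_per_tissue,
                       n_metabolites=cfg.sim_n_metabolites,
                       shared_fraction=cfg.sim_shared_fraction)
    runs = render_runs(study.truth, snr=cfg.sim_snr)
    for run in runs:
        formats_io.write_run_mzml(run, out / f"{run.run_id}.mzML")
    formats_io.write_metadata_csv(study.samples, out / "metadata.csv")
    for plant, mesh in study.meshes.items():
        formats_io.write_mesh_stl(mesh, out / f"mesh_{plant}.stl",
                                  name=plant)
    formats_io.write_library_mgf(library_spectra(study.truth),
                                 out / "library.mgf")
    study.truth.save_json(out / "truth.json")
    logger.info("simulate: wrote %d runs, %d samples", len(runs),
                len(study.samples))
    return {"runs_written": len(runs), "samples": len(study.samples)}


def stage_features(cfg: PipelineConfig) -> dict:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    metadata = formats_io.read_metadata_csv(cfg.metadata_path)
    known = {m.sample_id for m in metadata}
    per_sample = {}
    n_scans = 0
    n_features = 0
    for path in _run_paths(cfg):
        run = formats_io.read_run(path)
        if run.run_id not in known:
            raise ValidationError(
                f"run '{run.run_id}' has no metadata row")
        n_scans += len(run.scans)
        feats = feature_finding.find_features(
            run, noise_threshold=cfg.noise_threshold,
            mz_tol_ppm=cfg.mz_tol_ppm,
            min_width_seconds=cfg.min_width_seconds, baseline=cfg.baseline,
            max_width_seconds=cfg.max_width_seconds,
            rt_tol_seconds=cfg.rt_tol_seconds, max_charge=cfg.max_charge,
            centroided=cfg.centroided)
        per_sample[run.run_id] = feats
        n_features += len(feats)
        logger.info("features: %s -> %d features", run.run_id, len(feats))
    matrix = feature_finding.align_features(
        per_sample, mz_tol_ppm=cfg.mz_tol_ppm,
        rt_tol_seconds=cfg.rt_tol_seconds)
    if cfg.blank_filter_matrix:
        blanks = [m.sample_id for m in metadata
                  if m.is_blank and m.sample_id in matrix.sample_ids]
        if blanks:
            keep = ~(matrix.areas[blanks] > 0).any(axis=1).to_numpy()
            matrix = FeatureMatrix(mz=matrix.mz[keep], rt=matrix.rt[keep],
                                   areas=matrix.areas.loc[keep])
    matrix.to_frame().to_csv(out / FEATURE_MATRIX_CSV, lineterminator="\n")
    return {"scans_read": n_scans, "features_detected": n_features,
            "rows_aligned": matrix.n_features}


def _filtered_ms2(cfg: PipelineConfig) -> tuple[list[Spectrum], int]:
    spectra = []
    n_ms2 = 0
    for path in _run_paths(cfg):
        run = formats_io.read_run(path)
        for s in run.ms2_scans:
            n_ms2 += 1
            f = filter_spectrum(
                s, precursor_half_window_da=cfg.precursor_half_window_da,
                top_n=cfg.window_top_n, window_da=cfg.window_da)
            if f.n_peaks:
                spectra.append(f)
    return spectra, n_ms2


def stage_network(cfg: PipelineConfig) -> dict:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    metadata = formats_io.read_metadata_csv(cfg.metadata_path)
    spectra, n_ms2 = _filtered_ms2(cfg)
    nodes = networking.cluster_spectra(
        spectra, prec_tol_da=cfg.cluster_prec_tol_da,
        frag_tol_da=cfg.frag_tol_da, cluster_cosine=cfg.cluster_cosine,
        consensus_top_n=cfg.window_top_n,
        consensus_window_da=cfg.window_da)
    network = networking.build_network(
        nodes, edge_cosine=cfg.edge_cosine, min_matched=cfg.min_matched,
        frag_tol_da=cfg.frag_tol_da, top_k=cfg.top_k)
    n_before = len(network.nodes)
    network = networking.subtract_blanks(network, metadata,
                                         mode=cfg.blank_mode)
    logger.info("network: %d MS2 -> %d nodes (%d after blank subtraction), "
                "%d edges", n_ms2, n_before, len(network.nodes),
                len(network.edges))
    _write_nodes_mgf(network, out / NODES_MGF)
    _write_edges_tsv(network, out / EDGES_TSV)
    formats_io.write_network_graphml(network, out / NETWORK_GRAPHML,
                                     metadata=metadata)
    freq = networking.node_sample_frequency(network.nodes)
    with (out / FREQ_TSV).open("w", newline="\n") as fh:
        fh.write("node_id\tn_samples\n")
        for nid in sorted(freq):
            fh.write(f"{nid}\t{freq[nid]}\n")
    overlap = networking.msms_tissue_overlap(network.nodes, metadata)
    (out / MSMS_VENN_JSON).write_text(json.dumps(
        {"regions": {"+".join(sorted(k)): v
                     for k, v in sorted(overlap.items(),
                                        key=lambda kv: sorted(kv[0]))},
         "total": sum(overlap.values())}, indent=1, sort_keys=True),
        encoding="utf-8")
    return {"ms2_scans": n_ms2, "spectra_clustered": len(spectra),
            "nodes_total": n_before, "nodes_after_blank": len(network.nodes),
            "edges_after_pruning": len(network.edges)}


def _write_nodes_mgf(network: MolecularNetwork, path: Path) -> None:
    extra = {}
    specs = []
    for n in network.nodes:
        s = n.as_spectrum()
        specs.append(s)
        members = ";".join(f"{sid}:{scan}" for sid, scan
                           in sorted(n.member_scan_refs))
        extra[n.node_id] = {"MEMBERS": members}
    formats_io.write_library_mgf(specs, path, extra_fields=extra)


def read_nodes_mgf(path) -> list:
    """Rehydrate consensus nodes written by the network stage."""
    from .models import ConsensusSpectrum

    raw = Path(path).read_text().splitlines()
    nodes = []
    fields: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    for line in raw:
        line = line.strip()
        if line == "BEGIN IONS":
            fields, peaks = {}, []
        elif line == "END IONS":
            members = [tuple(tok.split(":", 1))
                       for tok in fields.get("MEMBERS", "").split(";")
                       if tok]
            mz, inten = (zip(*peaks) if peaks else ((), ()))
            nodes.append(ConsensusSpectrum(
                node_id=fields["TITLE"],
                precursor_mz=float(fields["PEPMASS"]),
                mz=np.array(mz), intensity=np.array(inten),
                member_scan_refs=[(a, b) for a, b in members]))
        elif "=" in line:
            k, v = line.split("=", 1)
            fields[k.strip().upper()] = v.strip()
        elif line:
            toks = line.split()
            peaks.append((float(toks[0]), float(toks[1])))
    return nodes


def _write_edges_tsv(network: MolecularNetwork, path: Path) -> None:
    with path.open("w", newline="\n") as fh:
        fh.write("node_a\tnode_b\tcosine\tn_matched\tdelta_mz\n")
        for e in sorted(network.edges, key=lambda e: (e.node_a, e.node_b)):
            fh.write(f"{e.node_a}\t{e.node_b}\t{e.cosine!r}\t"
                     f"{e.n_matched}\t{e.delta_mz!r}\n")


def stage_match(cfg: PipelineConfig) -> dict:
    out = Path(cfg.output_dir)
    nodes = read_nodes_mgf(out / NODES_MGF)
    hits = {}
    if cfg.library_path and nodes:
        library = formats_io.read_spectral_library(cfg.library_path)
        hits = networking.library_search(
            nodes, library, prec_tol_da=cfg.library_prec_tol_da,
            frag_tol_da=cfg.frag_tol_da, match_cosine=cfg.match_cosine,
            min_matched=cfg.library_min_matched, ppm_cap=cfg.ppm_cap)
    with (out / ANNOTATIONS_TSV).open("w", newline="\n") as fh:
        fh.write("node_id\tlibrary_id\tcompound\tcosine\tn_matched\t"
                 "ppm_error\n")
        for nid in sorted(hits):
            h = hits[nid]
            fh.write(f"{nid}\t{h.library_id}\t{h.compound_name}\t"
                     f"{h.cosine!r}\t{h.n_matched}\t"
                     f"{h.precursor_ppm_error!r}\n")
    logger.info("match: %d library hits / %d nodes", len(hits), len(nodes))
    return {"library_hits": len(hits)}


def stage_stats(cfg: PipelineConfig) -> dict:
    out = Path(cfg.output_dir)
    metadata = formats_io.read_metadata_csv(cfg.metadata_path)
    matrix = FeatureMatrix.from_frame(
        pd.read_csv(out / FEATURE_MATRIX_CSV, index_col="row_id"))
    normalized = stats_mapping.tic_normalize(matrix)
    dm = stats_mapping.jaccard_distances(normalized)
    dm.to_frame().to_csv(out / DISTANCES_CSV, lineterminator="\n")
    ord_res = stats_mapping.pcoa(dm, n_axes=cfg.n_axes)
    frame = ord_res.to_frame()
    header = ("# eigenvalues: "
              + ",".join(repr(float(v)) for v in ord_res.eigenvalues) + "\n")
    (out / ORDINATION_CSV).write_text(
        header + frame.to_csv(lineterminator="\n"), encoding="utf-8")
    venn = stats_mapping.venn_counts(matrix, metadata)
    (out / VENN_JSON).write_text(
        json.dumps(venn.to_json_dict(), indent=1, sort_keys=True),
        encoding="utf-8")
    return {"samples_ordinated": len(dm.sample_ids),
            "venn_total": venn.total,
            "venn_all_groups": venn.all_groups_count}


def stage_map(cfg: PipelineConfig) -> dict:
    out = Path(cfg.output_dir)
    metadata = formats_io.read_metadata_csv(cfg.metadata_path)
    matrix = FeatureMatrix.from_frame(
        pd.read_csv(out / FEATURE_MATRIX_CSV, index_col="row_id"))
    meshes = sorted(Path(cfg.input_dir).glob("mesh_*.stl"))
    if not meshes:
        raise ValidationError(f"no mesh_*.stl under {cfg.input_dir}")
    n_rows = 0
    written = []
    for mesh_path in meshes:
        plant = mesh_path.stem[len("mesh_"):]
        mesh = formats_io.read_mesh_stl(mesh_path)
        plant_samples = [m for m in metadata
                         if m.plant == plant and not m.is_blank]
        keep_ids = [m.sample_id for m in plant_samples
                    if m.sample_id in matrix.sample_ids]
        if not keep_ids:
            continue
        sub = FeatureMatrix(mz=matrix.mz, rt=matrix.rt,
                            areas=matrix.areas[keep_ids])
        table = stats_mapping.build_eim_table(
            sub, plant_samples, mesh, normalized=cfg.eim_normalized)
        formats_io.write_ili_table(table, out / f"ili_{plant}.csv")
        written.append(f"ili_{plant}.csv")
        n_rows += len(table.sample_names)
    return {"ili_tables": len(written), "ili_rows": n_rows}


STAGES = ("features", "network", "match", "stats", "map")
_STAGE_FN = {"features": stage_features, "network": stage_network,
             "match": stage_match, "stats": stage_stats, "map": stage_map}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order and write the run manifest.

    Any stage failure aborts with the stage name; files created by the
    failed run are removed so no partial output directory survives.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    before = set(out.iterdir())
    counts: dict[str, dict] = {}
    try:
        for name in STAGES:
            logger.info("stage %s: starting", name)
            counts[name] = _STAGE_FN[name](cfg)
    except CartoError as exc:
        for p in set(out.iterdir()) - before:
            p.unlink()
        raise CartoError(f"stage '{name}' failed: {exc}") from exc
    inputs = {p.name: _checksum(p)
              for p in sorted(Path(cfg.input_dir).iterdir())
              if p.is_file()}
    outputs = sorted(p.name for p in out.iterdir()
                     if p.is_file() and p.name != MANIFEST_JSON)
    manifest = {"config_hash": cfg.content_hash(),
                "inputs": inputs, "counts": counts,
                "outputs": outputs + [MANIFEST_JSON]}
    (out / MANIFEST_JSON).write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    return manifest
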