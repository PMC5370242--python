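"""Readers and writers for every external format the pipeline touches.

All retention times are normalized to seconds on read. Numeric output uses
full ``repr`` precision so that rewriting the same table is byte-identical.

Supported formats: mzML 1.1 and mzXML 3.x (read + minimal write, the write
path existing for the synthetic-data generator), MGF and MSP spectral
libraries (read; MGF write), binary and ASCII STL (read + write), the 'ili
intensity CSV (write/read), GraphML networks (via networkx), and the sample
metadata CSV.
"""
from __future__ import annotations

import base64
import csv
import io
import logging
import re
import struct
import zlib
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import networkx as nx

from .errors import (EmptyLibraryError, EmptyMeshError, EmptyRunError,
                     FormatError, ValidationError)
from .models import (IliTable, Mesh, MolecularNetwork, RawRun,
                     SampleMetadata, Spectrum, metadata_from_frame,
                     metadata_to_frame)

logger = logging.getLogger(__name__)

_MZML_NS = "http://psi.hupo.org/ms/mzml"

# mzML controlled-vocabulary accessions actually consumed
_CV_MS_LEVEL = "MS:1000511"
_CV_SCAN_START = "MS:1000016"
_CV_SELECTED_MZ = "MS:1000744"
_CV_ISOLATION_MZ = "MS:1000827"
_CV_64BIT = "MS:1000523"
_CV_32BIT = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_NOCOMP = "MS:1000576"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INT_ARRAY = "MS:1000515"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(text: str, dtype: str, compressed: bool) -> np.ndarray:
    raw = base64.b64decode(text.encode("ascii")) if text else b""
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _parse_mzml_spectrum(elem, path: str) -> Spectrum:
    scan_id = elem.get("id", "")
    ms_level = None
    rt = None
    precursor = None
    mz_arr = None
    int_arr = None
    for cv in elem.iter():
        tag = _local(cv.tag)
        if tag == "cvParam":
            acc = cv.get("accession", "")
            if acc == _CV_MS_LEVEL:
                ms_level = int(cv.get("value"))
            elif acc == _CV_SCAN_START:
                val = float(cv.get("value"))
                unit = (cv.get("unitName", "") or "").lower()
                unit_acc = cv.get("unitAccession", "")
                if unit.startswith("minute") or unit_acc == "UO:0000031":
                    val *= 60.0
                rt = val
            elif acc in (_CV_SELECTED_MZ, _CV_ISOLATION_MZ):
                if precursor is None:
                    precursor = float(cv.get("value"))
    for bda in elem.iter():
        if _local(bda.tag) != "binaryDataArray":
            continue
        dtype = "<f8"
        compressed = False
        kind = None
        text = ""
        for child in bda:
            t = _local(child.tag)
            if t == "cvParam":
                acc = child.get("accession", "")
                if acc == _CV_32BIT:
                    dtype = "<f4"
                elif acc == _CV_64BIT:
                    dtype = "<f8"
                elif acc == _CV_ZLIB:
                    compressed = True
                elif acc == _CV_MZ_ARRAY:
                    kind = "mz"
                elif acc == _CV_INT_ARRAY:
                    kind = "intensity"
            elif t == "binary":
                text = child.text or ""
        try:
            arr = _decode_binary(text, dtype, compressed)
        except Exception as exc:  # malformed base64/zlib payload
            raise FormatError(
                f"{path}: bad binary data in spectrum '{scan_id}': {exc}")
        if kind == "mz":
            mz_arr = arr
        elif kind == "intensity":
            int_arr = arr
    if ms_level is None:
        raise FormatError(f"{path}: spectrum '{scan_id}' lacks ms level")
    if rt is None:
        raise FormatError(f"{path}: spectrum '{scan_id}' lacks scan start time")
    if mz_arr is None or int_arr is None:
        mz_arr = np.array([]) if mz_arr is None else mz_arr
        int_arr = np.array([]) if int_arr is None else int_arr
    if mz_arr.size != int_arr.size:
        raise FormatError(
            f"{path}: spectrum '{scan_id}' m/z and intensity array lengths "
            f"differ ({mz_arr.size} vs {int_arr.size})")
    if ms_level == 2 and (precursor is None or precursor <= 0):
        raise FormatError(
            f"{path}: MS2 spectrum '{scan_id}' lacks a precursor m/z")
    try:
        return Spectrum(scan_id=scan_id, ms_level=ms_level, rt_seconds=rt,
                        mz=mz_arr, intensity=int_arr,
                        precursor_mz=precursor if ms_level == 2 else None)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}")


def _read_mzml(path: Path) -> list[Spectrum]:
    spectra = []
    try:
        for event, elem in ET.iterparse(str(path), events=("end",)):
            if _local(elem.tag) == "spectrum":
                spectra.append(_parse_mzml_spectrum(elem, str(path)))
                elem.clear()
    except ET.ParseError as exc:
        raise FormatError(f"{path}: not well-formed mzML: {exc}")
    return spectra


_RT_RE = re.compile(r"^PT(?:(\d+(?:\.\d+)?)M)?(?:(\d+(?:\.\d+)?)S)?$")


def _parse_mzxml_rt(value: str, path: str) -> float:
    m = _RT_RE.match(value.strip())
    if not m or (m.group(1) is None and m.group(2) is None):
        raise FormatError(f"{path}: unparseable retentionTime '{value}'")
    minutes = float(m.group(1) or 0.0)
    seconds = float(m.group(2) or 0.0)
    return minutes * 60.0 + seconds


def _read_mzxml(path: Path) -> list[Spectrum]:
    spectra = []
    try:
        for event, elem in ET.iterparse(str(path), events=("end",)):
            if _local(elem.tag) != "scan":
                continue
            scan_id = elem.get("num", "")
            ms_level = int(elem.get("msLevel", "1"))
            rt = _parse_mzxml_rt(elem.get("retentionTime", ""), str(path))
            precursor = None
            mz_arr = np.array([])
            int_arr = np.array([])
            for child in elem:
                tag = _local(child.tag)
                if tag == "precursorMz" and child.text:
                    precursor = float(child.text)
                elif tag == "peaks":
                    precision = child.get("precision", "32")
                    dtype = ">f8" if precision == "64" else ">f4"
                    raw = base64.b64decode((child.text or "").encode("ascii"))
                    if child.get("compressionType") == "zlib":
                        raw = zlib.decompress(raw)
                    pairs = np.frombuffer(raw, dtype=dtype).astype(np.float64)
                    if pairs.size % 2:
                        raise FormatError(
                            f"{path}: scan {scan_id} has odd peak array")
                    mz_arr = pairs[0::2]
                    int_arr = pairs[1::2]
            if ms_level == 2 and (precursor is None or precursor <= 0):
                raise FormatError(
                    f"{path}: MS2 scan {scan_id} lacks a precursor m/z")
            try:
                spectra.append(
                    Spectrum(scan_id=f"scan={scan_id}", ms_level=ms_level,
                             rt_seconds=rt, mz=mz_arr, intensity=int_arr,
                             precursor_mz=precursor if ms_level == 2 else None))
            except ValidationError as exc:
                raise FormatError(f"{path}: {exc}")
            elem.clear()
    except ET.ParseError as exc:
        raise FormatError(f"{path}: not well-formed mzXML: {exc}")
    return spectra


def read_run(path, dialect: Optional[str] = None) -> RawRun:
    """Load an LC-MS/MS run from mzML or mzXML.

    ``dialect`` is 'mzML' or 'mzXML'; inferred from the suffix when omitted.
    RTs are normalized to seconds, peak lists sorted by m/z. A run with zero
    MS1 scans raises :class:`EmptyRunError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = {"mzml": "mzML", "mzxml": "mzXML"}.get(suffix.lstrip("."))
        if dialect is None:
            raise FormatError(f"{path}: cannot infer dialect from suffix")
    if dialect == "mzML":
        spectra = _read_mzml(path)
    elif dialect == "mzXML":
        spectra = _read_mzxml(path)
    else:
        raise FormatError(f"unknown dialect '{dialect}'")
    run_id = path.stem
    for s in spectra:
        s.sample_id = run_id
    if not any(s.ms_level == 1 for s in spectra):
        raise EmptyRunError(f"{path}: run contains no MS1 scans")
    return RawRun(run_id=run_id, scans=spectra, source_path=str(path))


def _fmt(x: float) -> str:
    return repr(float(x))


def write_run_mzml(run: RawRun, path) -> None:
    """Write a minimal (uncompressed, 64-bit) mzML 1.1 document."""
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>\n',
        f'<mzML xmlns="{_MZML_NS}" version="1.1.0">\n',
        f'<run id="{run.run_id}">\n',
        f'<spectrumList count="{len(run.scans)}">\n',
    ]
    for i, s in enumerate(run.scans):
        mz64 = base64.b64encode(
            np.asarray(s.mz, dtype="<f8").tobytes()).decode("ascii")
        in64 = base64.b64encode(
            np.asarray(s.intensity, dtype="<f8").tobytes()).decode("ascii")
        parts.append(
            f'<spectrum index="{i}" id="{s.scan_id}" '
            f'defaultArrayLength="{s.n_peaks}">\n')
        parts.append(f'<cvParam cvRef="MS" accession="{_CV_MS_LEVEL}" '
                     f'name="ms level" value="{s.ms_level}"/>\n')
        parts.append('<scanList count="1"><scan>\n')
        parts.append(
            f'<cvParam cvRef="MS" accession="{_CV_SCAN_START}" '
            f'name="scan start time" value="{_fmt(s.rt_seconds)}" '
            'unitAccession="UO:0000010" unitName="second"/>\n')
        parts.append('</scan></scanList>\n')
        if s.ms_level == 2:
            parts.append(
                '<precursorList count="1"><precursor>'
                '<selectedIonList count="1"><selectedIon>\n'
                f'<cvParam cvRef="MS" accession="{_CV_SELECTED_MZ}" '
                f'name="selected ion m/z" value="{_fmt(s.precursor_mz)}"/>\n'
                '</selectedIon></selectedIonList></precursor>'
                '</precursorList>\n')
        parts.append('<binaryDataArrayList count="2">\n')
        for kind, acc, b64 in (("m/z array", _CV_MZ_ARRAY, mz64),
                               ("intensity array", _CV_INT_ARRAY, in64)):
            parts.append(f'<binaryDataArray encodedLength="{len(b64)}">\n')
            parts.append(f'<cvParam cvRef="MS" accession="{_CV_64BIT}" '
                         'name="64-bit float"/>\n')
            parts.append(f'<cvParam cvRef="MS" accession="{_CV_NOCOMP}" '
                         'name="no compression"/>\n')
            parts.append(f'<cvParam cvRef="MS" accession="{acc}" '
                         f'name="{kind}"/>\n')
            parts.append(f'<binary>{b64}</binary>\n')
            parts.append('</binaryDataArray>\n')
        parts.append('</binaryDataArrayList>\n</spectrum>\n')
    parts.append('</spectrumList>\n</run>\n</mzML>\n')
    Path(path).write_text("".join(parts), encoding="utf-8", newline="\n")


def write_run_mzxml(run: RawRun, path) -> None:
    """Write a minimal mzXML 3.2 document (64-bit, network byte order)."""
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>\n',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/'
        'mzXML_3.2">\n',
        f'<msRun scanCount="{len(run.scans)}">\n',
    ]
    for i, s in enumerate(run.scans, start=1):
        pairs = np.empty(2 * s.n_peaks, dtype=">f8")
        pairs[0::2] = s.mz
        pairs[1::2] = s.intensity
        b64 = base64.b64encode(pairs.tobytes()).decode("ascii")
        parts.append(
            f'<scan num="{i}" msLevel="{s.ms_level}" '
            f'peaksCount="{s.n_peaks}" '
            f'retentionTime="PT{_fmt(s.rt_seconds)}S">\n')
        if s.ms_level == 2:
            parts.append(
                f'<precursorMz>{_fmt(s.precursor_mz)}</precursorMz>\n')
        parts.append(
            '<peaks precision="64" byteOrder="network" '
            f'contentType="m/z-int">{b64}</peaks>\n')
        parts.append('</scan>\n')
    parts.append('</msRun>\n</mzXML>\n')
    Path(path).write_text("".join(parts), encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# spectral libraries


def _read_mgf(path: Path) -> list[Spectrum]:
    records = []
    in_record = False
    fields: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    n_skipped = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            in_record, fields, peaks = True, {}, []
        elif line == "END IONS":
            if not in_record:
                raise FormatError(f"{path}:{lineno}: END IONS without BEGIN")
            pep = fields.get("PEPMASS")
            if pep is None or not peaks:
                n_skipped += 1
                logger.warning("%s: skipping record ending at line %d "
                               "(missing PEPMASS or peaks)", path, lineno)
            else:
                mz, inten = zip(*peaks)
                name = fields.get("NAME") or fields.get("TITLE") or ""
                records.append(Spectrum(
                    scan_id=fields.get("TITLE", f"mgf_record_{len(records)}"),
                    ms_level=2, rt_seconds=float(fields.get("RTINSECONDS",
                                                            0.0)),
                    mz=np.array(mz), intensity=np.array(inten),
                    precursor_mz=float(pep.split()[0]),
                    compound_name=name,
                    library_id=fields.get("SPECTRUMID",
                                          f"lib_{len(records):05d}"),
                    sample_id=fields.get("SAMPLE", ""),
                ))
            in_record = False
        elif in_record:
            if "=" in line:
                key, val = line.split("=", 1)
                fields[key.strip().upper()] = val.strip()
            else:
                toks = line.split()
                try:
                    peaks.append((float(toks[0]), float(toks[1])))
                except (IndexError, ValueError):
                    raise FormatError(
                        f"{path}:{lineno}: unparseable peak line '{line}'")
    return records


def _read_msp(path: Path) -> list[Spectrum]:
    records = []
    name = None
    fields: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    expected = None

    def flush(lineno):
        nonlocal name, fields, peaks, expected
        if name is None:
            return
        if expected is not None and len(peaks) != expected:
            raise FormatError(
                f"{path}: record '{name}' declares {expected} peaks "
                f"but has {len(peaks)}")
        pep = fields.get("PRECURSORMZ") or fields.get("PRECURSOR_M/Z")
        if pep is None or not peaks:
            logger.warning("%s: skipping MSP record '%s' (no precursor)",
                           path, name)
        else:
            mz, inten = zip(*peaks)
            records.append(Spectrum(
                scan_id=name, ms_level=2, rt_seconds=0.0,
                mz=np.array(mz), intensity=np.array(inten),
                precursor_mz=float(pep), compound_name=name,
                library_id=fields.get("DB#", f"lib_{len(records):05d}")))
        name, fields, peaks, expected = None, {}, [], None

    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            flush(lineno)
            continue
        low = line.lower()
        if low.startswith("name:"):
            flush(lineno)
            name = line.split(":", 1)[1].strip()
        elif low.startswith("num peaks:"):
            expected = int(line.split(":", 1)[1])
        elif ":" in line and not line[0].isdigit():
            key, val = line.split(":", 1)
            fields[key.strip().upper().replace(" ", "")] = val.strip()
        else:
            toks = line.replace(";", " ").split()
            try:
                peaks.append((float(toks[0]), float(toks[1])))
            except (IndexError, ValueError):
                raise FormatError(
                    f"{path}:{lineno}: unparseable peak line '{line}'")
    flush(None)
    return records


def read_spectral_library(path, dialect: Optional[str] = None
                          ) -> list[Spectrum]:
    """Read an MGF or MSP library; one annotated MS2 Spectrum per record.

    Records without a precursor m/z are skipped with a warning; an empty
    result raises :class:`EmptyLibraryError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if dialect is None:
        dialect = {"mgf": "MGF", "msp": "MSP"}.get(
            path.suffix.lower().lstrip("."))
        if dialect is None:
            raise FormatError(f"{path}: cannot infer dialect from suffix")
    records = _read_mgf(path) if dialect == "MGF" else _read_msp(path)
    if not records:
        raise EmptyLibraryError(f"{path}: no valid library records")
    return records


def write_library_mgf(spectra: Iterable[Spectrum], path,
                      extra_fields=None) -> None:
    """Write MS2 spectra as MGF. ``extra_fields`` maps scan_id -> dict of
    additional KEY=value record headers."""
    lines = []
    for s in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={s.scan_id}")
        lines.append(f"PEPMASS={_fmt(s.precursor_mz)}")
        if s.compound_name:
            lines.append(f"NAME={s.compound_name}")
        if s.library_id:
            lines.append(f"SPECTRUMID={s.library_id}")
        if s.sample_id:
            lines.append(f"SAMPLE={s.sample_id}")
        if s.rt_seconds:
            lines.append(f"RTINSECONDS={_fmt(s.rt_seconds)}")
        if extra_fields and s.scan_id in extra_fields:
            for k, v in extra_fields[s.scan_id].items():
                lines.append(f"{k}={v}")
        for mz, inten in zip(s.mz, s.intensity):
            lines.append(f"{_fmt(mz)} {_fmt(inten)}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# STL meshes


def _dedup_vertices(tri_vertices: np.ndarray) -> Mesh:
    """tri_vertices: (n_tri, 3, 3). Deduplicate by exact coordinate match."""
    flat = tri_vertices.reshape(-1, 3)
    seen: dict[tuple, int] = {}
    indices = np.empty(len(flat), dtype=np.int64)
    verts = []
    for i, v in enumerate(map(tuple, flat)):
        idx = seen.get(v)
        if idx is None:
            idx = len(verts)
            seen[v] = idx
            verts.append(v)
        indices[i] = idx
    return Mesh(vertices=np.array(verts, dtype=np.float64),
                faces=indices.reshape(-1, 3))


_ASCII_FLOAT = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def _read_stl_ascii(text: str, path: str) -> Mesh:
    tris = []
    current: list[list[float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if line.startswith("vertex"):
            nums = _ASCII_FLOAT.findall(line)
            if len(nums) != 3:
                raise FormatError(f"{path}:{lineno}: bad vertex line")
            current.append([float(x) for x in nums])
        elif line.startswith("endfacet"):
            if len(current) != 3:
                raise FormatError(
                    f"{path}:{lineno}: facet with {len(current)} vertices")
            tris.append(current)
            current = []
    if not tris:
        raise EmptyMeshError(f"{path}: STL contains no facets")
    return _dedup_vertices(np.array(tris, dtype=np.float64))


def _read_stl_binary(data: bytes, path: str) -> Mesh:
    if len(data) < 84:
        raise FormatError(f"{path}: truncated binary STL header")
    (n_tri,) = struct.unpack("<I", data[80:84])
    expected = 84 + 50 * n_tri
    if len(data) < expected:
        raise FormatError(
            f"{path}: truncated binary STL "
            f"({len(data)} bytes, need {expected} for {n_tri} facets)")
    if n_tri == 0:
        raise EmptyMeshError(f"{path}: STL contains no facets")
    arr = np.frombuffer(data[84:expected], dtype=np.uint8).reshape(n_tri, 50)
    floats = arr[:, :48].copy().view("<f4").reshape(n_tri, 4, 3)
    return _dedup_vertices(floats[:, 1:4, :].astype(np.float64))


def read_mesh_stl(path) -> Mesh:
    """Read a binary or ASCII STL; vertices deduplicated by exact match,
    triangle count preserved."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    data = path.read_bytes()
    head = data[:512]
    if head.lstrip().startswith(b"solid") and (b"facet" in data[:4096]
                                               or b"endsolid" in data):
        return _read_stl_ascii(data.decode("utf-8", errors="replace"),
                               str(path))
    return _read_stl_binary(data, str(path))


def write_mesh_stl(mesh: Mesh, path, binary: bool = False,
                   name: str = "mesh") -> None:
    path = Path(path)
    tris = mesh.vertices[mesh.faces]  # (n, 3, 3)
    if binary:
        buf = io.BytesIO()
        buf.write(b"B" + b" " * 79)  # header must not start with 'solid'
        buf.write(struct.pack("<I", len(tris)))
        for tri in tris:
            a, b, c = tri
            n = np.cross(b - a, c - a)
            norm = np.linalg.norm(n)
            n = n / norm if norm > 0 else n
            buf.write(struct.pack("<12fH", *n, *a, *b, *c, 0))
        path.write_bytes(buf.getvalue())
        return
    lines = [f"solid {name}"]
    for tri in tris:
        a, b, c = tri
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n)
        n = n / norm if norm > 0 else n
        lines.append(f"  facet normal {n[0]:e} {n[1]:e} {n[2]:e}")
        lines.append("    outer loop")
        for v in (a, b, c):
            lines.append(f"      vertex {v[0]:e} {v[1]:e} {v[2]:e}")
        lines.append("    endloop")
        lines.append("  endfacet")
    lines.append(f"endsolid {name}")
    lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# 'ili CSV


def write_ili_table(table: IliTable, path) -> None:
    """Write the 'ili spot-intensity CSV.

    Header: ``sample name,X,Y,Z,radius,<feature...>``; RFC-4180 quoting,
    LF line endings, full-precision numbers. Missing cells are written as 0.
    Output is byte-stable for identical input.
    """
    if np.any(~np.isfinite(table.coordinates)) or np.any(
            ~np.isfinite(table.radii)):
        raise ValidationError("every 'ili row needs coordinates and a radius")
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n",
                        quoting=csv.QUOTE_MINIMAL)
    writer.writerow(["sample name", "X", "Y", "Z", "radius",
                     *table.feature_names])
    vals = np.nan_to_num(table.values, nan=0.0)
    for i, name in enumerate(table.sample_names):
        x, y, z = table.coordinates[i]
        writer.writerow([name, _fmt(x), _fmt(y), _fmt(z),
                         _fmt(table.radii[i]),
                         *[_fmt(v) for v in vals[i]]])
    Path(path).write_text(buf.getvalue(), encoding="utf-8", newline="\n")


def read_ili_table(path) -> IliTable:
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty 'ili CSV")
    header = rows[0]
    if len(header) < 5 or header[0] != "sample name":
        raise FormatError(f"{path}: not an 'ili CSV (bad header)")
    names, coords, radii, values = [], [], [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != len(header):
            raise FormatError(f"{path}:{lineno}: column count mismatch")
        names.append(row[0])
        coords.append([float(v) for v in row[1:4]])
        radii.append(float(row[4]))
        values.append([float(v) for v in row[5:]])
    return IliTable(sample_names=names, coordinates=np.array(coords),
                    radii=np.array(radii), feature_names=header[5:],
                    values=np.array(values).reshape(len(names),
                                                    len(header) - 5))


# ---------------------------------------------------------------------------
# GraphML


def network_to_graph(network: MolecularNetwork,
                     metadata: Optional[list[SampleMetadata]] = None
                     ) -> nx.Graph:
    """Build a networkx Graph with 'ili/Cytoscape-friendly scalar attrs."""
    tissue_of = {}
    if metadata:
        tissue_of = {m.sample_id: ("blank" if m.is_blank else m.tissue)
                     for m in metadata}
    ids = [n.node_id for n in network.nodes]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate node ids in network")
    g = nx.Graph()
    for node in network.nodes:
        counts: dict[str, int] = {}
        for sample in sorted({s for s, _ in node.member_scan_refs}):
            group = tissue_of.get(sample, sample)
            counts[group] = counts.get(group, 0) + 1
        hit = network.annotations.get(node.node_id)
        g.add_node(node.node_id,
                   precursor_mz=float(node.precursor_mz),
                   n_members=int(node.n_members),
                   n_samples=len(node.member_samples),
                   group_counts=";".join(f"{k}={v}"
                                         for k, v in sorted(counts.items())),
                   library_hit=hit.compound_name if hit else "")
    for e in network.edges:
        g.add_edge(e.node_a, e.node_b, cosine=float(e.cosine),
                   n_matched=int(e.n_matched),
                   delta_precursor_mz=float(e.delta_mz))
    return g


def write_network_graphml(network: MolecularNetwork, path,
                          metadata: Optional[list[SampleMetadata]] = None
                          ) -> None:
    g = network_to_graph(network, metadata)
    nx.write_graphml(g, str(path), infer_numeric_types=True)


# ---------------------------------------------------------------------------
# metadata CSV


def read_metadata_csv(path) -> list[SampleMetadata]:
    df = pd.read_csv(path)
    return metadata_from_frame(df)


def write_metadata_csv(samples: list[SampleMetadata], path) -> None:
    metadata_to_frame(samples).to_csv(path, index=False,
                                      lineterminator="\n")
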