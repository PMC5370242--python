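"""Round-trip and validation behavior of every file codec."""
import numpy as np
import networkx as nx
import pytest

from plantcarto import formats_io
from plantcarto.errors import (EmptyLibraryError, EmptyMeshError,
                               EmptyRunError, FormatError, ValidationError)
from plantcarto.models import (ConsensusSpectrum, IliTable, Mesh,
                               MolecularNetwork, NetworkEdge, RawRun,
                               SampleMetadata)

from conftest import make_spectrum


def _demo_run():
    ms1 = make_spectrum([200.1, 300.5, 410.0], [3e6, 5e6, 1e6], level=1,
                        rt=12.5, scan_id="scan=0")
    ms2 = make_spectrum([120.0, 150.7, 210.2], [10.0, 40.0, 5.0],
                        precursor=300.5, rt=12.6, scan_id="scan=0.0")
    return RawRun(run_id="demo", scans=[ms1, ms2])


@pytest.mark.parametrize("dialect,writer", [
    ("mzML", formats_io.write_run_mzml),
    ("mzXML", formats_io.write_run_mzxml),
])
def test_run_round_trip(tmp_path, dialect, writer):
    path = tmp_path / f"demo.{dialect}"
    run = _demo_run()
    writer(run, path)
    back = formats_io.read_run(path, dialect=dialect)
    assert len(back.scans) == 2
    for orig, new in zip(run.scans, back.scans):
        np.testing.assert_array_equal(orig.mz, new.mz)
        np.testing.assert_array_equal(orig.intensity, new.intensity)
        assert new.rt_seconds == pytest.approx(orig.rt_seconds)
        assert new.sample_id == "demo"
    assert back.scans[1].precursor_mz == pytest.approx(300.5)


_MINUTE_MZML = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
<run id="r"><spectrumList count="1">
<spectrum index="0" id="scan=1" defaultArrayLength="0">
<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
<scanList count="1"><scan>
<cvParam cvRef="MS" accession="MS:1000016" name="scan start time"
 value="2.0" unitAccession="UO:0000031" unitName="minute"/>
</scan></scanList>
</spectrum></spectrumList></run></mzML>
"""


def test_mzml_minute_rt_converted_to_seconds(tmp_path):
    p = tmp_path / "m.mzML"
    p.write_text(_MINUTE_MZML)
    run = formats_io.read_run(p)
    assert run.scans[0].rt_seconds == pytest.approx(120.0)


def test_ms2_without_precursor_rejected(tmp_path):
    bad = _MINUTE_MZML.replace('name="ms level" value="1"',
                               'name="ms level" value="2"')
    p = tmp_path / "bad.mzML"
    p.write_text(bad)
    with pytest.raises(FormatError, match="precursor"):
        formats_io.read_run(p)


def test_run_without_ms1_is_empty_run(tmp_path):
    path = tmp_path / "ms2only.mzML"
    ms2 = make_spectrum([100.0], [5.0], precursor=400.0, rt=1.0)
    formats_io.write_run_mzml(RawRun(run_id="x", scans=[ms2]), path)
    with pytest.raises(EmptyRunError):
        formats_io.read_run(path)


def test_read_run_sorts_peaks(tmp_path):
    # write unsorted peak arrays by hand-swapping the binary payloads
    run = _demo_run()
    path = tmp_path / "demo.mzML"
    formats_io.write_run_mzml(run, path)
    back = formats_io.read_run(path)
    for s in back.scans:
        assert np.all(np.diff(s.mz) >= 0)


# ---------------------------------------------------------------------------
# spectral libraries

_MGF = """BEGIN IONS
TITLE=rec1
PEPMASS=300.5
NAME=compound one
100.0 10.0
150.0 20.0
END IONS

BEGIN IONS
TITLE=rec2
PEPMASS=410.1
210.0 5.0
END IONS
"""


def test_mgf_two_records(tmp_path):
    p = tmp_path / "lib.mgf"
    p.write_text(_MGF)
    lib = formats_io.read_spectral_library(p)
    assert len(lib) == 2
    assert lib[0].compound_name == "compound one"
    assert lib[0].precursor_mz == pytest.approx(300.5)
    assert lib[1].n_peaks == 1


def test_mgf_missing_pepmass_skipped(tmp_path):
    text = _MGF.replace("PEPMASS=410.1\n", "")
    p = tmp_path / "lib.mgf"
    p.write_text(text)
    lib = formats_io.read_spectral_library(p)
    assert len(lib) == 1


def test_empty_library_raises(tmp_path):
    p = tmp_path / "empty.mgf"
    p.write_text("BEGIN IONS\nTITLE=x\nEND IONS\n")
    with pytest.raises(EmptyLibraryError):
        formats_io.read_spectral_library(p)


_MSP = """Name: demo compound
PrecursorMZ: 300.5
Num Peaks: 2
100.0 10.0
150.0 20.0
"""


def test_msp_record(tmp_path):
    p = tmp_path / "lib.msp"
    p.write_text(_MSP)
    lib = formats_io.read_spectral_library(p)
    assert len(lib) == 1
    assert lib[0].compound_name == "demo compound"


def test_msp_num_peaks_mismatch(tmp_path):
    p = tmp_path / "lib.msp"
    p.write_text(_MSP.replace("Num Peaks: 2", "Num Peaks: 3"))
    with pytest.raises(FormatError, match="declares"):
        formats_io.read_spectral_library(p)


# ---------------------------------------------------------------------------
# STL


def _unit_cube():
    v = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                  for z in (0, 1)], dtype=float)
    f = np.array([[0, 1, 3], [0, 3, 2], [4, 6, 7], [4, 7, 5],
                  [0, 4, 5], [0, 5, 1], [2, 3, 7], [2, 7, 6],
                  [0, 2, 6], [0, 6, 4], [1, 5, 7], [1, 7, 3]])
    return Mesh(vertices=v, faces=f)


@pytest.mark.parametrize("binary", [False, True])
def test_stl_cube_round_trip(tmp_path, binary):
    p = tmp_path / "cube.stl"
    formats_io.write_mesh_stl(_unit_cube(), p, binary=binary)
    mesh = formats_io.read_mesh_stl(p)
    assert len(mesh.vertices) == 8
    assert len(mesh.faces) == 12
    lo, hi = mesh.bounds
    np.testing.assert_allclose(lo, [0, 0, 0])
    np.testing.assert_allclose(hi, [1, 1, 1])


def test_stl_dialect_equivalence(tmp_path):
    pa, pb = tmp_path / "a.stl", tmp_path / "b.stl"
    formats_io.write_mesh_stl(_unit_cube(), pa, binary=False)
    formats_io.write_mesh_stl(_unit_cube(), pb, binary=True)
    ma, mb = formats_io.read_mesh_stl(pa), formats_io.read_mesh_stl(pb)
    assert sorted(map(tuple, ma.vertices)) == sorted(map(tuple, mb.vertices))
    assert len(ma.faces) == len(mb.faces)


def test_stl_truncated_binary_rejected(tmp_path):
    p = tmp_path / "cube.stl"
    formats_io.write_mesh_stl(_unit_cube(), p, binary=True)
    data = p.read_bytes()
    p.write_bytes(data[:-1])
    with pytest.raises(FormatError, match="truncated"):
        formats_io.read_mesh_stl(p)


def test_stl_empty_facets_rejected(tmp_path):
    p = tmp_path / "empty.stl"
    p.write_text("solid empty\nendsolid empty\n")
    with pytest.raises(EmptyMeshError):
        formats_io.read_mesh_stl(p)


# ---------------------------------------------------------------------------
# 'ili CSV


def _demo_table(feature_names=("mz_100.0000_rt_10.0s",)):
    return IliTable(sample_names=["s1", "s2"],
                    coordinates=np.array([[0.0, 1.0, 2.0], [3.0, 4.0, 5.0]]),
                    radii=np.array([0.5, 0.5]),
                    feature_names=list(feature_names),
                    values=np.array([[1.5], [0.0]]))


def test_ili_shape_and_header(tmp_path):
    p = tmp_path / "t.csv"
    formats_io.write_ili_table(_demo_table(), p)
    lines = p.read_text().splitlines()
    assert len(lines) == 3
    assert lines[0].split(",")[:5] == ["sample name", "X", "Y", "Z",
                                       "radius"]
    assert len(lines[1].split(",")) == 6


def test_ili_write_read_write_byte_identical(tmp_path):
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    formats_io.write_ili_table(_demo_table(), p1)
    formats_io.write_ili_table(formats_io.read_ili_table(p1), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_ili_comma_in_feature_name_round_trips(tmp_path):
    p = tmp_path / "t.csv"
    table = _demo_table(feature_names=['weird, name'])
    formats_io.write_ili_table(table, p)
    back = formats_io.read_ili_table(p)
    assert back.feature_names == ['weird, name']
    np.testing.assert_array_equal(back.values, table.values)


def test_ili_duplicate_sample_names_rejected():
    with pytest.raises(ValidationError):
        IliTable(sample_names=["s", "s"], coordinates=np.zeros((2, 3)),
                 radii=np.ones(2), feature_names=["f"],
                 values=np.zeros((2, 1)))


def test_ili_mutated_mandatory_field_rejected(tmp_path):
    p = tmp_path / "t.csv"
    formats_io.write_ili_table(_demo_table(), p)
    lines = p.read_text().splitlines()
    # drop the radius column from one data row
    lines[1] = ",".join(lines[1].split(",")[:-2])
    p.write_text("\n".join(lines) + "\n")
    with pytest.raises(FormatError):
        formats_io.read_ili_table(p)


# ---------------------------------------------------------------------------
# GraphML


def _demo_network():
    a = ConsensusSpectrum(node_id="n0", precursor_mz=300.5,
                          mz=np.array([100.0]), intensity=np.array([1.0]),
                          member_scan_refs=[("s1", "x"), ("s2", "y")])
    b = ConsensusSpectrum(node_id="n1", precursor_mz=314.5,
                          mz=np.array([100.0]), intensity=np.array([1.0]),
                          member_scan_refs=[("s1", "z"), ("s1", "w")])
    edge = NetworkEdge(node_a="n0", node_b="n1", cosine=0.91, n_matched=5,
                       delta_mz=-14.0)
    return MolecularNetwork(nodes=[a, b], edges=[edge])


def test_graphml_round_trip(tmp_path):
    p = tmp_path / "net.graphml"
    meta = [SampleMetadata("s1", "p", "leaf", False, 0, 0, 0, 1),
            SampleMetadata("s2", "p", "stem", False, 0, 0, 0, 1)]
    formats_io.write_network_graphml(_demo_network(), p, metadata=meta)
    g = nx.read_graphml(p)
    assert set(g.nodes) == {"n0", "n1"}
    assert g.nodes["n0"]["precursor_mz"] == pytest.approx(300.5)
    assert g.nodes["n0"]["group_counts"] == "leaf=1;stem=1"
    assert g.edges["n0", "n1"]["cosine"] == pytest.approx(0.91)
    assert g.edges["n0", "n1"]["n_matched"] == 5


def test_graphml_empty_network(tmp_path):
    p = tmp_path / "empty.graphml"
    formats_io.write_network_graphml(MolecularNetwork(nodes=[], edges=[]), p)
    g = nx.read_graphml(p)
    assert g.number_of_nodes() == 0
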