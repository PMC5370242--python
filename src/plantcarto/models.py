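"""Core in-memory containers shared by all pipeline stages.

Spectra carry peak lists as parallel numpy arrays (``mz`` ascending,
``intensity`` non-negative); retention times are always seconds.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

PROTON_NEUTRON_DELTA = 1.003355  # Da, C13-C12 spacing used for isotope chains


@dataclass
class Spectrum:
    """One MS1 or MS2 scan.

    MS2 spectra carry ``precursor_mz``; MS1 spectra must not. Peaks are kept
    sorted ascending by m/z with non-negative finite intensities.
    """

    scan_id: str
    ms_level: int
    rt_seconds: float
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None
    sample_id: str = ""
    # provenance flags set by spectral_processing filters
    precursor_window_applied: bool = False
    window_topn_applied: bool = False
    # optional library annotations
    compound_name: Optional[str] = None
    library_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValidationError(
                f"scan {self.scan_id}: mz/intensity length mismatch")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(~np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValidationError(
                f"scan {self.scan_id}: NaN or negative intensity")
        if self.ms_level == 1 and self.precursor_mz is not None:
            raise ValidationError(
                f"scan {self.scan_id}: MS1 spectrum carries a precursor m/z")
        if self.ms_level == 2:
            if self.precursor_mz is None or self.precursor_mz <= 0:
                raise ValidationError(
                    f"scan {self.scan_id}: MS2 spectrum lacks a positive "
                    "precursor m/z")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def copy(self, **changes) -> "Spectrum":
        d = dataclasses.asdict(self)
        d["mz"] = self.mz.copy()
        d["intensity"] = self.intensity.copy()
        d.update(changes)
        return Spectrum(**d)


@dataclass
class RawRun:
    """All scans of one LC-MS/MS acquisition, ordered by retention time."""

    run_id: str
    scans: list[Spectrum]
    source_path: str = ""

    def __post_init__(self) -> None:
        rts = [s.rt_seconds for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            self.scans = sorted(self.scans, key=lambda s: s.rt_seconds)

    @property
    def ms1_scans(self) -> list[Spectrum]:
        return [s for s in self.scans if s.ms_level == 1]

    @property
    def ms2_scans(self) -> list[Spectrum]:
        return [s for s in self.scans if s.ms_level == 2]


@dataclass
class Mesh:
    """Triangle surface mesh in model units."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int indices into vertices

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValidationError("mesh face indices out of range")

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)


@dataclass
class SampleMetadata:
    """One sampling spot (or blank). Coordinates are in mesh model units;
    blanks may omit them (NaN)."""

    sample_id: str
    plant: str
    tissue: str
    is_blank: bool
    x: float = float("nan")
    y: float = float("nan")
    z: float = float("nan")
    radius: float = float("nan")

    @property
    def has_coordinates(self) -> bool:
        return not (np.isnan(self.x) or np.isnan(self.y) or np.isnan(self.z))


def metadata_to_frame(samples: list[SampleMetadata]) -> pd.DataFrame:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_id in metadata")
    return pd.DataFrame(
        {
            "sample_id": ids,
            "plant": [s.plant for s in samples],
            "tissue": [s.tissue for s in samples],
            "is_blank": [s.is_blank for s in samples],
            "x": [s.x for s in samples],
            "y": [s.y for s in samples],
            "z": [s.z for s in samples],
            "radius": [s.radius for s in samples],
        }
    )


def metadata_from_frame(df: pd.DataFrame) -> list[SampleMetadata]:
    required = {"sample_id", "plant", "tissue", "is_blank", "x", "y", "z",
                "radius"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        blank = row["is_blank"]
        if isinstance(blank, str):
            blank = blank.strip().lower() in ("true", "1", "yes")
        out.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                plant=str(row["plant"]),
                tissue=str(row["tissue"]),
                is_blank=bool(blank),
                x=float(row["x"]) if pd.notna(row["x"]) else float("nan"),
                y=float(row["y"]) if pd.notna(row["y"]) else float("nan"),
                z=float(row["z"]) if pd.notna(row["z"]) else float("nan"),
                radius=float(row["radius"]) if pd.notna(row["radius"])
                else float("nan"),
            )
        )
    ids = [s.sample_id for s in out]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_id in metadata")
    return out


@dataclass
class EIC:
    """Extracted ion chromatogram: one narrow-m/z intensity trace."""

    center_mz: float
    rt: np.ndarray  # strictly increasing, seconds
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)


@dataclass
class Feature:
    """One deconvoluted chromatographic peak in one sample."""

    mz: float
    rt_seconds: float  # apex
    area: float  # trapezoidal, intensity x seconds
    height: float
    sample_id: str = ""


@dataclass
class FeatureMatrix:
    """Aligned features (rows) x samples (columns) with peak areas.

    ``areas`` is a DataFrame indexed by row_id with one column per sample;
    ``mz``/``rt`` hold the row consensus values (intensity-weighted means of
    the member features).
    """

    mz: np.ndarray
    rt: np.ndarray
    areas: pd.DataFrame

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.rt = np.asarray(self.rt, dtype=np.float64)
        if len(self.mz) != len(self.areas) or len(self.rt) != len(self.areas):
            raise ValidationError("FeatureMatrix mz/rt/areas length mismatch")
        if self.areas.columns.duplicated().any():
            raise ValidationError("duplicate sample columns in FeatureMatrix")

    @property
    def n_features(self) -> int:
        return len(self.areas)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.columns)

    def feature_labels(self) -> list[str]:
        """'ili-style column labels: mz_<4dp>_rt_<1dp>s."""
        return [f"mz_{m:.4f}_rt_{r:.1f}s" for m, r in zip(self.mz, self.rt)]

    def to_frame(self) -> pd.DataFrame:
        df = self.areas.copy()
        df.insert(0, "rt_seconds", self.rt)
        df.insert(0, "mz", self.mz)
        df.index.name = "row_id"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        if "mz" not in df.columns or "rt_seconds" not in df.columns:
            raise ValidationError("feature matrix needs mz and rt_seconds")
        areas = df.drop(columns=["mz", "rt_seconds"])
        return cls(mz=df["mz"].to_numpy(), rt=df["rt_seconds"].to_numpy(),
                   areas=areas)


@dataclass
class ConsensusSpectrum:
    """Merged representative of a cluster of near-identical MS/MS spectra;
    one node of the molecular network."""

    node_id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    member_scan_refs: list[tuple[str, str]]  # (sample_id, scan_id)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)

    @property
    def n_members(self) -> int:
        return len(self.member_scan_refs)

    @property
    def member_samples(self) -> set[str]:
        return {s for s, _ in self.member_scan_refs}

    def as_spectrum(self) -> Spectrum:
        return Spectrum(scan_id=self.node_id, ms_level=2, rt_seconds=0.0,
                        mz=self.mz, intensity=self.intensity,
                        precursor_mz=self.precursor_mz)


@dataclass
class NetworkEdge:
    node_a: str
    node_b: str
    cosine: float
    n_matched: int
    delta_mz: float


@dataclass
class LibraryHit:
    node_id: str
    library_id: str
    compound_name: str
    cosine: float
    n_matched: int
    precursor_ppm_error: float


@dataclass
class MolecularNetwork:
    nodes: list[ConsensusSpectrum]
    edges: list[NetworkEdge]
    annotations: dict[str, LibraryHit] = field(default_factory=dict)

    def node_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]


@dataclass
class IliTable:
    """Per-spot per-feature intensity table consumed by 'ili together with
    the STL model."""

    sample_names: list[str]
    coordinates: np.ndarray  # (n, 3)
    radii: np.ndarray  # (n,)
    feature_names: list[str]
    values: np.ndarray  # (n, n_features)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.radii = np.asarray(self.radii, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(set(self.sample_names)) != len(self.sample_names):
            raise ValidationError("duplicate sample names in IliTable")
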