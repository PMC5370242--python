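"""Flat pipeline configuration: every stage parameter with its default,
input paths, output directory and seed. Round-trips through YAML.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class PipelineConfig:
    # inputs / outputs
    input_dir: str = "input"
    output_dir: str = "output"
    metadata_csv: str = ""  # default: <input_dir>/metadata.csv
    library_path: str = ""  # optional MGF/MSP
    seed: int = 0
    # feature finding
    noise_threshold: float = 2.0e6
    min_width_seconds: float = 0.3
    baseline: float = 1.0e4
    max_width_seconds: float = 120.0
    mz_tol_ppm: float = 10.0
    rt_tol_seconds: float = 10.0
    max_charge: int = 2
    centroided: bool = True
    blank_filter_matrix: bool = False  # optional matrix-level blank removal
    # MS/MS filtering
    precursor_half_window_da: float = 17.0
    window_top_n: int = 6
    window_da: float = 50.0
    # clustering / networking
    cluster_prec_tol_da: float = 0.02
    frag_tol_da: float = 0.02
    cluster_cosine: float = 0.7
    edge_cosine: float = 0.7
    min_matched: int = 4
    top_k: int = 10
    blank_mode: str = "any"
    # library search
    library_prec_tol_da: float = 0.02
    match_cosine: float = 0.7
    library_min_matched: int = 4
    ppm_cap: float = 20.0
    # statistics / mapping
    n_axes: int = 3
    eim_normalized: bool = False
    # simulation (synthetic-study subcommand)
    sim_n_tissues: int = 4
    sim_spots_per_tissue: int = 6
    sim_n_metabolites: int = 60
    sim_shared_fraction: float = 0.1
    sim_snr: float = 100.0

    _POSITIVE = ("noise_threshold", "min_width_seconds", "baseline",
                 "max_width_seconds", "mz_tol_ppm", "rt_tol_seconds",
                 "precursor_half_window_da", "window_da",
                 "cluster_prec_tol_da", "frag_tol_da",
                 "library_prec_tol_da", "ppm_cap")

    def __post_init__(self) -> None:
        for name in self._POSITIVE:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.blank_mode not in ("any", "exclusive"):
            raise ParameterError("blank_mode must be 'any' or 'exclusive'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @property
    def metadata_path(self) -> Path:
        return (Path(self.metadata_csv) if self.metadata_csv
                else Path(self.input_dir) / "metadata.csv")
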