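"""Deterministic synthetic plants: mesh, sampling spots, metabolite ground
truth, and simulated DDA LC-MS/MS runs with blanks.

The generator states a small idealized world that mirrors a whole-plant
untargeted metabolomics study: a panel of metabolites partitioned into an
all-tissue core (a stated fraction of the panel), tissue-exclusive and
pairwise-shared sets; Gaussian chromatographic elution on a 10-minute
gradient sampled at 2 Hz; +1 isotope companions; top-5 data-dependent MS2
with dynamic exclusion (3 selections, 20 s release); an internal standard
spiked into every injection including blanks; and solvent/system blank runs
that carry only background ions plus the internal standard. All randomness
flows from one integer seed.
"""
from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .models import Mesh, RawRun, SampleMetadata, Spectrum

SQRT_2PI = math.sqrt(2.0 * math.pi)
DEFAULT_TISSUES = ("stem", "leaf", "flower", "fruit")
DEFAULT_PLANTS = ("tomato_like", "pepper_like")
INTERNAL_STANDARD_ID = "internal_standard"
INTERNAL_STANDARD_MZ = 466.3164  # [M+H]+ of the spiked bile-acid standard
INTERNAL_STANDARD_HEIGHT = 5.0e7
SPOT_RADIUS = 0.25  # mesh model units
RT_MAX_SECONDS = 600.0  # 10-minute gradient
MIN_MZ_SEPARATION = 3.2  # Da; keeps panels clear of isotope spacings


@dataclass
class Metabolite:
    id: str
    mz: float
    rt_seconds: float
    sigma_seconds: float
    base_height: float
    fragments: list[tuple[float, float]]  # (mz, relative intensity <= 1)
    tissue_profile: dict[str, float]  # tissue -> abundance multiplier
    plant: str | None = None  # restrict to one plant (None = all)
    family: str | None = None  # analog-family id
    in_library: bool = False
    is_internal_standard: bool = False
    blank_only: bool = False  # background ions live in blank runs only

    def to_dict(self) -> dict:
        return {
            "id": self.id, "mz": self.mz, "rt_seconds": self.rt_seconds,
            "sigma_seconds": self.sigma_seconds,
            "base_height": self.base_height,
            "fragments": [[a, b] for a, b in self.fragments],
            "tissue_profile": self.tissue_profile, "plant": self.plant,
            "family": self.family, "in_library": self.in_library,
            "is_internal_standard": self.is_internal_standard,
            "blank_only": self.blank_only,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Metabolite":
        d = dict(d)
        d["fragments"] = [(a, b) for a, b in d["fragments"]]
        return cls(**d)


@dataclass
class PlantedFeature:
    """Expected (sample, m/z, rt, area) record for one metabolite in one
    run; area is the analytic Gaussian integral height*sigma*sqrt(2*pi)."""

    sample_id: str
    metabolite_id: str
    mz: float
    rt_seconds: float
    height: float
    sigma_seconds: float

    @property
    def area(self) -> float:
        return self.height * self.sigma_seconds * SQRT_2PI

    def to_dict(self) -> dict:
        return {"sample_id": self.sample_id,
                "metabolite_id": self.metabolite_id, "mz": self.mz,
                "rt_seconds": self.rt_seconds, "height": self.height,
                "sigma_seconds": self.sigma_seconds}


@dataclass
class GroundTruth:
    seed: int
    tissues: list[str]
    plants: list[str]
    metabolites: list[Metabolite]
    samples: list[SampleMetadata]
    planted_features: list[PlantedFeature]
    analog_families: dict[str, list[str]] = field(default_factory=dict)

    @property
    def panel(self) -> list[Metabolite]:
        """The biological metabolite panel (background ions excluded)."""
        return [m for m in self.metabolites if not m.blank_only]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def to_dict(self) -> dict:
        from .models import metadata_to_frame

        return {
            "seed": self.seed, "tissues": self.tissues,
            "plants": self.plants,
            "metabolites": [m.to_dict() for m in self.metabolites],
            "samples": metadata_to_frame(self.samples).replace(
                {float("nan"): None}).to_dict(orient="records"),
            "planted_features": [p.to_dict() for p in self.planted_features],
            "analog_families": self.analog_families,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        samples = [SampleMetadata(
            sample_id=s["sample_id"], plant=s["plant"], tissue=s["tissue"],
            is_blank=bool(s["is_blank"]),
            x=float("nan") if s["x"] is None else float(s["x"]),
            y=float("nan") if s["y"] is None else float(s["y"]),
            z=float("nan") if s["z"] is None else float(s["z"]),
            radius=float("nan") if s["radius"] is None else float(s["radius"]),
        ) for s in d["samples"]]
        return cls(
            seed=d["seed"], tissues=list(d["tissues"]),
            plants=list(d["plants"]),
            metabolites=[Metabolite.from_dict(m) for m in d["metabolites"]],
            samples=samples,
            planted_features=[PlantedFeature(**p)
                              for p in d["planted_features"]],
            analog_families={k: list(v)
                             for k, v in d["analog_families"].items()})

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1),
                              encoding="utf-8")

    @classmethod
    def load_json(cls, path) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# metabolite panel


def _draw_mz(rng, existing: list[float], lo=150.0, hi=900.0) -> float:
    for _ in range(10000):
        mz = float(rng.uniform(lo, hi))
        if all(abs(mz - e) >= MIN_MZ_SEPARATION for e in existing):
            return mz
    raise ParameterError("could not place metabolite m/z with required "
                         "separation; too many metabolites for the range")


def _draw_fragments(rng, precursor_mz: float,
                    n_lo=6, n_hi=12) -> list[tuple[float, float]]:
    n = int(rng.integers(n_lo, n_hi + 1))
    mzs = np.sort(rng.uniform(50.0, precursor_mz - 20.0, size=n))
    # enforce >0.05 Da spacing so consensus merging keeps peaks distinct
    keep = np.concatenate([[True], np.diff(mzs) > 0.05])
    mzs = mzs[keep]
    rel = rng.uniform(0.05, 1.0, size=mzs.size)
    rel[int(rng.integers(0, mzs.size))] = 1.0  # guarantee a base peak
    return [(float(a), float(b)) for a, b in zip(mzs, rel)]


def make_panel(seed: int, tissues: list[str], plants: list[str],
               n_metabolites: int = 60, shared_fraction: float = 0.1,
               pairwise_fraction: float = 0.2,
               n_families: int = 2, family_size: int = 3,
               family_delta_da: float = 14.0157) -> tuple[list[Metabolite],
                                                          dict[str, list[str]]]:
    """Build the metabolite panel: all-tissue core (first member is the
    internal standard), pairwise-shared and tissue-exclusive sets, with
    ``n_families`` analog families (shared fragment template, constant
    precursor shift) inside the exclusive sets, and one plant-exclusive
    metabolite per plant when two or more plants are modeled."""
    if not 0.0 <= shared_fraction <= 1.0:
        raise ParameterError("shared_fraction must lie in [0, 1]")
    rng = np.random.default_rng([seed, 101])
    n_core = int(round(shared_fraction * n_metabolites))
    n_core = max(1, n_core)  # the internal standard is always shared
    n_pair = min(int(round(pairwise_fraction * n_metabolites)),
                 n_metabolites - n_core)
    n_excl = n_metabolites - n_core - n_pair
    mzs: list[float] = [INTERNAL_STANDARD_MZ]
    rts: list[float] = []
    metabolites: list[Metabolite] = []

    def new_met(met_id, tissue_set, mz=None, fragments=None, rt=None,
                **kw) -> Metabolite:
        if mz is None:
            mz = _draw_mz(rng, mzs)
            mzs.append(mz)
        if rt is None:
            rt = float(rng.uniform(30.0, RT_MAX_SECONDS - 30.0))
        rts.append(rt)
        profile = {t: float(rng.uniform(0.5, 2.0)) for t in tissue_set}
        m = Metabolite(
            id=met_id, mz=mz, rt_seconds=rt,
            sigma_seconds=float(rng.uniform(1.0, 4.0)),
            base_height=float(10.0 ** rng.uniform(7.0, 8.0)),
            fragments=fragments if fragments is not None
            else _draw_fragments(rng, mz),
            tissue_profile=profile, **kw)
        metabolites.append(m)
        return m

    # all-tissue core; member 0 is the internal standard with multiplier 1
    is_met = new_met(INTERNAL_STANDARD_ID, tissues,
                     mz=INTERNAL_STANDARD_MZ, is_internal_standard=True)
    is_met.tissue_profile = {t: 1.0 for t in tissues}
    is_met.base_height = INTERNAL_STANDARD_HEIGHT
    for i in range(1, n_core):
        new_met(f"core_{i:02d}", tissues)

    pair_list = [(a, b) for i, a in enumerate(tissues)
                 for b in tissues[i + 1:]]
    for i in range(n_pair):
        pair = pair_list[i % len(pair_list)] if pair_list else tuple(tissues)
        new_met(f"pair_{i:02d}", list(pair))

    # tissue-exclusive metabolites, round-robin over tissues; analog
    # families are carved out of the first slots of the first tissues
    families: dict[str, list[str]] = {}
    excl_specs: list[tuple[str, str]] = []  # (id, tissue)
    idx = 0
    for fam in range(n_families):
        tissue = tissues[fam % len(tissues)]
        fam_id = f"family_{fam}"
        families[fam_id] = []
        for j in range(family_size):
            if idx >= n_excl:
                break
            excl_specs.append((f"fam{fam}_m{j}", tissue))
            families[fam_id].append(f"fam{fam}_m{j}")
            idx += 1
    k = 0
    while idx < n_excl:
        tissue = tissues[k % len(tissues)]
        excl_specs.append((f"excl_{tissue}_{k // len(tissues):02d}", tissue))
        k += 1
        idx += 1

    fam_base: dict[str, Metabolite] = {}
    for met_id, tissue in excl_specs:
        fam_id = next((f for f, members in families.items()
                       if met_id in members), None)
        if fam_id is not None and fam_id in fam_base:
            base = fam_base[fam_id]
            j = families[fam_id].index(met_id)
            mz = base.mz + j * family_delta_da
            if any(abs(mz - e) < MIN_MZ_SEPARATION for e in mzs):
                mz = _draw_mz(rng, mzs)  # fall back if the ladder collides
            mzs.append(mz)
            # half the fragments shared exactly, half precursor-shifted
            frags = []
            for fi, (fmz, rel) in enumerate(base.fragments):
                frags.append((fmz + (j * family_delta_da if fi % 2 else 0.0),
                              rel))
            m = new_met(met_id, [tissue], mz=mz, fragments=frags,
                        family=fam_id,
                        rt=min(base.rt_seconds + 15.0 * j,
                               RT_MAX_SECONDS - 10.0))
        else:
            m = new_met(met_id, [tissue], family=fam_id)
            if fam_id is not None:
                fam_base[fam_id] = m

    # one plant-exclusive metabolite per plant, taken from the last
    # tissue's exclusive set (fruit by default), mirroring a
    # pepper-fruit-only / tomato-only pair of marker compounds
    if len(plants) >= 2:
        fruit = tissues[-1]
        markers = [m for m in metabolites
                   if list(m.tissue_profile) == [fruit] and m.family is None]
        for plant, marker in zip(plants, markers):
            marker.plant = plant

    # library subset: core + families + every third exclusive metabolite
    excl_plain = [m for m in metabolites
                  if m.family is None and len(m.tissue_profile) == 1]
    for m in metabolites[:n_core]:
        m.in_library = True
    for fam_members in families.values():
        for mid in fam_members:
            next(m for m in metabolites if m.id == mid).in_library = True
    for m in excl_plain[::3]:
        m.in_library = True
    return metabolites, families


# ---------------------------------------------------------------------------
# mesh and spots


def _ellipsoid_mesh(center, radii, n_stack: int = 8, n_sector: int = 12
                    ) -> tuple[np.ndarray, np.ndarray]:
    cx, cy, cz = center
    rx, ry, rz = radii
    verts = [(cx, cy, cz + rz)]
    for i in range(1, n_stack):
        theta = math.pi * i / n_stack
        for j in range(n_sector):
            phi = 2.0 * math.pi * j / n_sector
            verts.append((cx + rx * math.sin(theta) * math.cos(phi),
                          cy + ry * math.sin(theta) * math.sin(phi),
                          cz + rz * math.cos(theta)))
    verts.append((cx, cy, cz - rz))
    faces = []
    for j in range(n_sector):
        faces.append((0, 1 + j, 1 + (j + 1) % n_sector))
    for i in range(n_stack - 2):
        row0 = 1 + i * n_sector
        row1 = row0 + n_sector
        for j in range(n_sector):
            a, b = row0 + j, row0 + (j + 1) % n_sector
            c, d = row1 + j, row1 + (j + 1) % n_sector
            faces.append((a, c, b))
            faces.append((b, c, d))
    last = len(verts) - 1
    row = 1 + (n_stack - 2) * n_sector
    for j in range(n_sector):
        faces.append((last, row + (j + 1) % n_sector, row + j))
    return np.array(verts, dtype=np.float64), np.array(faces, dtype=np.int64)


def _tissue_patches(tissues: list[str], scale: float
                    ) -> dict[str, list[tuple[tuple, tuple]]]:
    """(center, radii) ellipsoid patches per tissue, a stylized upright
    plant: stem axis, two leaves, one flower, one fruit."""
    base = {
        "stem": [((0.0, 0.0, 2.0), (0.3, 0.3, 2.0))],
        "leaf": [((-1.2, 0.0, 2.6), (1.0, 0.6, 0.18)),
                 ((1.2, 0.3, 3.1), (1.0, 0.6, 0.18))],
        "flower": [((0.0, 0.9, 3.9), (0.45, 0.45, 0.35))],
        "fruit": [((0.9, -0.6, 1.2), (0.6, 0.6, 0.75))],
    }
    patches = {}
    ring = 0
    for t in tissues:
        if t in base:
            spec = base[t]
        else:  # extra tissues sit on a ring around the stem
            ang = 2.0 * math.pi * ring / max(1, len(tissues))
            ring += 1
            spec = [((1.5 * math.cos(ang), 1.5 * math.sin(ang), 1.0 + ring),
                     (0.5, 0.5, 0.5))]
        patches[t] = [(tuple(scale * c for c in ctr),
                       tuple(scale * r for r in rad)) for ctr, rad in spec]
    return patches


def make_plant_geometry(seed: int, plant: str, tissues: list[str],
                        spots_per_tissue: int
                        ) -> tuple[Mesh, list[SampleMetadata]]:
    """Procedural plant mesh (union of ellipsoid patches, one labelled
    patch set per tissue) plus sampling spots on the patch surfaces."""
    rng = np.random.default_rng([seed, 202, zlib.crc32(plant.encode())])
    scale = float(rng.uniform(0.85, 1.15))
    patches = _tissue_patches(tissues, scale)
    all_verts, all_faces = [], []
    offset = 0
    for t in tissues:
        for center, radii in patches[t]:
            v, f = _ellipsoid_mesh(center, radii)
            all_verts.append(v)
            all_faces.append(f + offset)
            offset += len(v)
    mesh = Mesh(vertices=np.vstack(all_verts), faces=np.vstack(all_faces))
    samples = []
    for t in tissues:
        for i in range(spots_per_tissue):
            center, radii = patches[t][i % len(patches[t])]
            theta = math.acos(1.0 - 2.0 * float(rng.uniform(0.05, 0.95)))
            phi = 2.0 * math.pi * float(rng.uniform())
            p = (center[0] + radii[0] * math.sin(theta) * math.cos(phi),
                 center[1] + radii[1] * math.sin(theta) * math.sin(phi),
                 center[2] + radii[2] * math.cos(theta))
            samples.append(SampleMetadata(
                sample_id=f"{plant}_{t}_{i:02d}", plant=plant, tissue=t,
                is_blank=False, x=round(p[0], 4), y=round(p[1], 4),
                z=round(p[2], 4), radius=SPOT_RADIUS))
    return mesh, samples


# ---------------------------------------------------------------------------
# ground truth assembly


def _make_background(seed: int, existing_mz: list[float],
                     n_background: int = 8) -> list[Metabolite]:
    rng = np.random.default_rng([seed, 303])
    mzs = list(existing_mz)
    out = []
    for i in range(n_background):
        mz = _draw_mz(rng, mzs)
        mzs.append(mz)
        out.append(Metabolite(
            id=f"background_{i:02d}", mz=mz,
            rt_seconds=float(rng.uniform(20.0, RT_MAX_SECONDS - 20.0)),
            sigma_seconds=float(rng.uniform(1.0, 4.0)),
            base_height=float(10.0 ** rng.uniform(6.7, 7.3)),
            fragments=_draw_fragments(rng, mz),
            tissue_profile={}, blank_only=True))
    return out


def _plant_features(seed: int, metabolites: list[Metabolite],
                    samples: list[SampleMetadata],
                    spot_cv: float = 0.2) -> list[PlantedFeature]:
    rng = np.random.default_rng([seed, 404])
    planted = []
    for s in samples:
        for m in metabolites:
            if s.is_blank:
                if not (m.blank_only or m.is_internal_standard):
                    continue
                height = m.base_height
            else:
                if m.blank_only:
                    continue
                mult = m.tissue_profile.get(s.tissue, 0.0)
                if m.plant is not None and m.plant != s.plant:
                    mult = 0.0
                if mult <= 0.0:
                    continue
                if m.is_internal_standard:
                    height = m.base_height  # spiked at constant level
                else:
                    height = (m.base_height * mult
                              * float(rng.lognormal(0.0, spot_cv)))
            planted.append(PlantedFeature(
                sample_id=s.sample_id, metabolite_id=m.id, mz=m.mz,
                rt_seconds=m.rt_seconds, height=height,
                sigma_seconds=m.sigma_seconds))
    return planted


def make_plant(seed: int, n_tissues: int = 4, spots_per_tissue: int = 6,
               n_metabolites: int = 60, shared_fraction: float = 0.1,
               plant_name: str = "plant", n_blanks: int = 1,
               panel=None, families=None, tissues=None
               ) -> tuple[Mesh, list[SampleMetadata], GroundTruth]:
    """One synthetic plant: mesh, sampling spots and ground truth.

    ``panel``/``families`` allow a multi-plant study to share one
    metabolite panel across plants.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ParameterError("shared_fraction must lie in [0, 1]")
    if min(n_tissues, spots_per_tissue, n_metabolites) <= 0:
        raise ParameterError("plant parameters must be positive")
    if tissues is None:
        tissues = list(DEFAULT_TISSUES[:n_tissues]) + [
            f"tissue{k}" for k in range(len(DEFAULT_TISSUES), n_tissues)]
    if panel is None:
        panel, families = make_panel(seed, tissues, [plant_name],
                                     n_metabolites=n_metabolites,
                                     shared_fraction=shared_fraction)
    mesh, samples = make_plant_geometry(seed, plant_name, tissues,
                                        spots_per_tissue)
    samples = list(samples)
    for b in range(n_blanks):
        samples.append(SampleMetadata(
            sample_id=f"blank_{plant_name}_{b:02d}", plant="none",
            tissue="blank", is_blank=True))
    background = _make_background(seed, [m.mz for m in panel])
    metabolites = list(panel) + background
    planted = _plant_features(seed, metabolites, samples)
    truth = GroundTruth(seed=seed, tissues=tissues, plants=[plant_name],
                        metabolites=metabolites, samples=samples,
                        planted_features=planted,
                        analog_families=families or {})
    return mesh, samples, truth


@dataclass
class Study:
    """A two-plant study sharing one metabolite panel, plus blanks."""

    truth: GroundTruth
    meshes: dict[str, Mesh]

    @property
    def samples(self) -> list[SampleMetadata]:
        return self.truth.samples


def make_study(seed: int, n_tissues: int = 4, spots_per_tissue: int = 6,
               n_metabolites: int = 60, shared_fraction: float = 0.1,
               plants=DEFAULT_PLANTS, n_blanks: int = 2) -> Study:
    """The default synthetic world: two plants x 4 tissues x 6 spots over a
    shared 60-metabolite panel (10% all-tissue core), plus solvent and
    system blanks, with one plant-exclusive fruit marker per plant."""
    tissues = list(DEFAULT_TISSUES[:n_tissues]) + [
        f"tissue{k}" for k in range(len(DEFAULT_TISSUES), n_tissues)]
    plants = list(plants)
    panel, families = make_panel(seed, tissues, plants,
                                 n_metabolites=n_metabolites,
                                 shared_fraction=shared_fraction)
    meshes = {}
    samples: list[SampleMetadata] = []
    for plant in plants:
        mesh, plant_samples = make_plant_geometry(seed, plant, tissues,
                                                  spots_per_tissue)
        meshes[plant] = mesh
        samples.extend(plant_samples)
    for b, kind in zip(range(n_blanks),
                       ["solvent", "system"] + [f"extra{k}"
                                                for k in range(n_blanks)]):
        samples.append(SampleMetadata(sample_id=f"blank_{kind}",
                                      plant="none", tissue="blank",
                                      is_blank=True))
    background = _make_background(seed, [m.mz for m in panel])
    metabolites = panel + background
    planted = _plant_features(seed, metabolites, samples)
    truth = GroundTruth(seed=seed, tissues=tissues, plants=plants,
                        metabolites=metabolites, samples=samples,
                        planted_features=planted,
                        analog_families=families)
    return Study(truth=truth, meshes=meshes)


# ---------------------------------------------------------------------------
# run rendering (simulated acquisition)


def render_runs(truth: GroundTruth, scan_rate_hz: float = 2.0,
                noise_floor: float = 1.0e3, snr: float = 100.0,
                dda_top_n: int = 5, exclusion_after: int = 3,
                release_seconds: float = 20.0,
                dda_min_intensity: float = 2.0e5,
                mz_jitter_da: float = 0.005,
                rt_max: float = RT_MAX_SECONDS) -> list[RawRun]:
    """Simulate one DDA LC-MS/MS run per sample (blanks included).

    MS1 survey scans sit on a fixed ``1/scan_rate_hz`` grid; each planted
    metabolite elutes as a Gaussian with its truth sigma and height,
    modulated by multiplicative log-normal noise of relative width
    ``1/snr``, accompanied by a +1 isotope at an m/z-scaled natural ratio.
    After every survey scan the ``dda_top_n`` most intense unexcluded
    precursors above ``dda_min_intensity`` are fragmented with the
    metabolite's template (m/z jitter <= ``mz_jitter_da``); an ion is
    excluded after ``exclusion_after`` selections and released after
    ``release_seconds``.
    """
    by_sample: dict[str, list[PlantedFeature]] = {}
    for p in truth.planted_features:
        by_sample.setdefault(p.sample_id, []).append(p)
    met = {m.id: m for m in truth.metabolites}
    dt = 1.0 / scan_rate_hz
    n_scans = int(round(rt_max * scan_rate_hz))
    scan_times = np.arange(n_scans) * dt
    sigma_ln = 1.0 / snr if np.isfinite(snr) else 0.0
    runs = []
    sample_order = sorted(by_sample)
    for run_idx, sid in enumerate(sample_order):
        rng = np.random.default_rng([truth.seed, 505, run_idx])
        planted = sorted(by_sample[sid], key=lambda p: p.metabolite_id)
        # per-scan peak accumulators
        scan_peaks: list[list[tuple[float, float, int]]] = [
            [] for _ in range(n_scans)]  # (mz, intensity, planted_idx)
        for pi, p in enumerate(planted):
            if p.height <= noise_floor:
                continue
            half = p.sigma_seconds * math.sqrt(
                2.0 * math.log(p.height / noise_floor))
            lo = max(0, int(math.ceil((p.rt_seconds - half) / dt)))
            hi = min(n_scans - 1, int(math.floor((p.rt_seconds + half) / dt)))
            if hi < lo:
                continue
            t = scan_times[lo:hi + 1]
            gauss = p.height * np.exp(-0.5 * ((t - p.rt_seconds)
                                              / p.sigma_seconds) ** 2)
            if sigma_ln > 0:
                gauss = gauss * rng.lognormal(0.0, sigma_ln, size=gauss.size)
            iso_ratio = min(0.4, p.mz * 5.5e-4)
            for k, inten in zip(range(lo, hi + 1), gauss):
                if inten <= noise_floor:
                    continue
                scan_peaks[k].append((p.mz, float(inten), pi))
                iso = float(inten) * iso_ratio
                if iso > noise_floor:
                    scan_peaks[k].append((p.mz + 1.003355, iso, -1))
        # assemble scans + DDA
        scans: list[Spectrum] = []
        sel_count = {pi: 0 for pi in range(len(planted))}
        excluded_until = {pi: -1.0 for pi in range(len(planted))}
        for k in range(n_scans):
            peaks = scan_peaks[k]
            peaks.sort(key=lambda x: x[0])
            mz_arr = np.array([x[0] for x in peaks])
            int_arr = np.array([x[1] for x in peaks])
            t = float(scan_times[k])
            scans.append(Spectrum(scan_id=f"scan={k}", ms_level=1,
                                  rt_seconds=t, mz=mz_arr,
                                  intensity=int_arr, sample_id=sid))
            candidates = [(inten, pi) for mzv, inten, pi in peaks
                          if pi >= 0 and inten >= dda_min_intensity
                          and t >= excluded_until[pi]]
            candidates.sort(key=lambda x: (-x[0], x[1]))
            for j, (inten, pi) in enumerate(candidates[:dda_top_n]):
                p = planted[pi]
                frags = met[p.metabolite_id].fragments
                fmz = np.array([f[0] for f in frags])
                frel = np.array([f[1] for f in frags])
                fmz = fmz + rng.uniform(-mz_jitter_da, mz_jitter_da,
                                        size=fmz.size)
                fint = frel * inten
                if sigma_ln > 0:
                    fint = fint * rng.lognormal(0.0, sigma_ln,
                                                size=fint.size)
                # residual unfragmented precursor
                fmz = np.append(fmz, p.mz)
                fint = np.append(fint, 0.2 * inten)
                scans.append(Spectrum(
                    scan_id=f"scan={k}.{j}", ms_level=2,
                    rt_seconds=t + 0.05 * (j + 1) * dt / max(dda_top_n, 1),
                    mz=fmz, intensity=fint, precursor_mz=p.mz,
                    sample_id=sid))
                sel_count[pi] += 1
                if sel_count[pi] >= exclusion_after:
                    excluded_until[pi] = t + release_seconds
                    sel_count[pi] = 0
        runs.append(RawRun(run_id=sid, scans=scans, source_path=""))
    return runs


def library_spectra(truth: GroundTruth) -> list[Spectrum]:
    """Reference MGF library content: the fragment templates of the
    panel subset flagged ``in_library``, annotated with compound names."""
    out = []
    for i, m in enumerate(m for m in truth.panel if m.in_library):
        fmz = np.array([f[0] for f in m.fragments])
        frel = np.array([f[1] for f in m.fragments])
        out.append(Spectrum(scan_id=f"lib_{m.id}", ms_level=2,
                            rt_seconds=0.0, mz=fmz, intensity=frel * 1e4,
                            precursor_mz=m.mz,
                            compound_name=f"compound {m.id}",
                            library_id=f"LIB{i:05d}"))
    return out


# ---------------------------------------------------------------------------
# truth report (oracle tables for end-to-end tests)


@dataclass
class TruthReport:
    expected_features: list[PlantedFeature]  # non-blank biological features
    expected_venn_regions: dict[frozenset, int]
    expected_center_count: int
    tissue_exclusive: dict[str, list[str]]  # tissue -> metabolite ids
    analog_families: dict[str, list[str]]
    internal_standard_samples: int  # expected node/sample frequency
    n_samples: int
    n_blanks: int


def truth_report(truth: GroundTruth) -> TruthReport:
    """Expected pipeline outcomes derived from the ground truth alone."""
    expected = [p for p in truth.planted_features
                if not truth.metabolite(p.metabolite_id).blank_only
                and not any(s.sample_id == p.sample_id and s.is_blank
                            for s in truth.samples)]
    regions: dict[frozenset, int] = {}
    for m in truth.panel:
        groups = frozenset(m.tissue_profile)
        if groups:
            regions[groups] = regions.get(groups, 0) + 1
    center = regions.get(frozenset(truth.tissues), 0)
    exclusive: dict[str, list[str]] = {t: [] for t in truth.tissues}
    for m in truth.panel:
        if len(m.tissue_profile) == 1:
            exclusive[next(iter(m.tissue_profile))].append(m.id)
    return TruthReport(
        expected_features=expected,
        expected_venn_regions=regions,
        expected_center_count=center,
        tissue_exclusive=exclusive,
        analog_families=dict(truth.analog_families),
        internal_standard_samples=len(truth.samples),
        n_samples=len(truth.samples),
        n_blanks=sum(1 for s in truth.samples if s.is_blank))
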