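"""MS1 feature detection, chromatogram deconvolution, isotope removal and
cross-sample alignment.

The stage mirrors a classic untargeted-metabolomics workflow: per-scan mass
detection above a signal threshold (2.0e6 by default), scan-to-scan
chromatogram building at 10 ppm, baseline-cutoff deconvolution at 1.0e4 with
a 2-minute maximum peak width, removal of +1..+3 isotope partners at
1.003355/z Da spacing, and a greedy join alignment at 10 ppm / 10 s.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import LevelError, ValidationError
from .models import (EIC, Feature, FeatureMatrix, RawRun, Spectrum,
                     PROTON_NEUTRON_DELTA)

# chains/segments narrower than this are chromatographic noise
MIN_PEAK_WIDTH_SECONDS = 0.3


def detect_masses(spectrum: Spectrum, noise_threshold: float = 2.0e6,
                  centroided: bool = True) -> list[tuple[float, float]]:
    """Return (mz, intensity) centroids with intensity >= noise_threshold.

    For profile data (``centroided=False``) local maxima are centroided with
    a 3-point parabolic fit in m/z; for stick data every point is a
    candidate centroid.
    """
    if spectrum.ms_level != 1:
        raise LevelError(f"detect_masses needs an MS1 spectrum, got level "
                         f"{spectrum.ms_level}")
    mz, inten = spectrum.mz, spectrum.intensity
    if mz.size == 0:
        return []
    if centroided:
        keep = inten >= noise_threshold
        return list(zip(mz[keep].tolist(), inten[keep].tolist()))
    out = []
    for i in range(1, mz.size - 1):
        y0, y1, y2 = inten[i - 1], inten[i], inten[i + 1]
        if y1 < noise_threshold or y1 < y0 or y1 < y2:
            continue
        if y1 == y0 and y1 == y2:
            continue
        denom = y0 - 2.0 * y1 + y2
        if denom == 0:
            apex_mz, apex_int = mz[i], y1
        else:
            # vertex of the parabola through the three (mz, intensity) points
            delta = 0.5 * (y0 - y2) / denom
            spacing = 0.5 * (mz[i + 1] - mz[i - 1])
            apex_mz = mz[i] + delta * spacing
            apex_int = y1 - 0.25 * (y0 - y2) * delta
        if apex_int >= noise_threshold:
            out.append((float(apex_mz), float(apex_int)))
    return out


class _Chain:
    __slots__ = ("rts", "ints", "mzs", "weight_mz", "weight")

    def __init__(self, rt, mz, inten):
        self.rts = [rt]
        self.ints = [inten]
        self.mzs = [mz]
        self.weight_mz = mz * inten
        self.weight = inten

    @property
    def center(self) -> float:
        return self.weight_mz / self.weight if self.weight > 0 else self.mzs[-1]

    def add(self, rt, mz, inten):
        self.rts.append(rt)
        self.ints.append(inten)
        self.mzs.append(mz)
        self.weight_mz += mz * inten
        self.weight += inten


def build_eics(run: RawRun, mz_tol_ppm: float = 10.0,
               min_width_seconds: float = MIN_PEAK_WIDTH_SECONDS,
               noise_threshold: float = 2.0e6,
               centroided: bool = True) -> list[EIC]:
    """Chain MS1 centroids scan-to-scan into extracted ion chromatograms.

    A centroid extends the open chain whose running intensity-weighted
    center is nearest within ``mz_tol_ppm``; at most one centroid per chain
    per scan. Chains spanning less than ``min_width_seconds`` are dropped.
    """
    chains: list[_Chain] = []
    for scan in run.ms1_scans:
        centroids = detect_masses(scan, noise_threshold=noise_threshold,
                                  centroided=centroided)
        if not chains:
            for mz, inten in centroids:
                chains.append(_Chain(scan.rt_seconds, mz, inten))
            continue
        centers = np.array([c.center for c in chains])
        candidates = []  # (ppm, chain_idx, centroid_idx)
        for j, (mz, inten) in enumerate(centroids):
            ppm = np.abs(centers - mz) / centers * 1e6
            for i in np.nonzero(ppm <= mz_tol_ppm)[0]:
                candidates.append((float(ppm[i]), int(i), j))
        candidates.sort()
        used_chain: set[int] = set()
        used_centroid: set[int] = set()
        for ppm, i, j in candidates:
            if i in used_chain or j in used_centroid:
                continue
            mz, inten = centroids[j]
            chains[i].add(scan.rt_seconds, mz, inten)
            used_chain.add(i)
            used_centroid.add(j)
        for j, (mz, inten) in enumerate(centroids):
            if j not in used_centroid:
                chains.append(_Chain(scan.rt_seconds, mz, inten))
    out = []
    for c in chains:
        if c.rts[-1] - c.rts[0] < min_width_seconds:
            continue
        out.append(EIC(center_mz=c.center, rt=np.array(c.rts),
                       intensity=np.array(c.ints), sample_id=run.run_id))
    out.sort(key=lambda e: e.center_mz)
    return out


def _segment_bounds(rt: np.ndarray, above: np.ndarray,
                    max_gap: float) -> list[tuple[int, int]]:
    """Contiguous above-baseline index ranges, additionally split where the
    trace has a temporal hole wider than ``max_gap`` (no centroid sampled)."""
    segs = []
    start = None
    n = len(above)
    for i in range(n):
        if not above[i]:
            start = None
            continue
        if start is None:
            start = i
        run_ends = (i == n - 1 or not above[i + 1]
                    or rt[i + 1] - rt[i] > max_gap)
        if run_ends:
            segs.append((start, i))
            start = None
    return segs


def _split_wide(rt, inten, lo, hi, max_width, min_width, out):
    width = rt[hi] - rt[lo]
    if width <= max_width or hi - lo < 2:
        if width >= min_width:
            out.append((lo, hi))
        return
    interior = inten[lo + 1:hi]
    split = lo + 1 + int(np.argmin(interior))
    _split_wide(rt, inten, lo, split, max_width, min_width, out)
    _split_wide(rt, inten, split, hi, max_width, min_width, out)


def deconvolute(eic: EIC, baseline: float = 1.0e4,
                max_width_seconds: float = 120.0,
                min_width_seconds: float = MIN_PEAK_WIDTH_SECONDS,
                gap_seconds: float | None = None) -> list[Feature]:
    """Baseline-cutoff deconvolution of one EIC.

    Contiguous above-baseline segments become candidate peaks; segments
    wider than ``max_width_seconds`` are split recursively at their deepest
    internal minimum; segments narrower than ``min_width_seconds`` are
    dropped. Area is the trapezoidal integral of the segment (intensity x
    seconds); apex is the segment's most intense point.
    """
    rt, inten = eic.rt, eic.intensity
    if rt.size == 0:
        return []
    if gap_seconds is None:
        dts = np.diff(rt)
        gap_seconds = 5.0 * float(np.median(dts)) if dts.size else np.inf
    above = inten > baseline
    segs = _segment_bounds(rt, above, gap_seconds)
    bounds: list[tuple[int, int]] = []
    for lo, hi in segs:
        _split_wide(rt, inten, lo, hi, max_width_seconds, min_width_seconds,
                    bounds)
    features = []
    for lo, hi in bounds:
        seg_rt = rt[lo:hi + 1]
        seg_int = inten[lo:hi + 1]
        apex = int(np.argmax(seg_int))
        area = float(np.trapezoid(seg_int, seg_rt))
        if area <= 0:
            continue
        features.append(Feature(mz=eic.center_mz,
                                rt_seconds=float(seg_rt[apex]),
                                area=area, height=float(seg_int[apex]),
                                sample_id=eic.sample_id))
    return features


def remove_isotopes(features: list[Feature], mz_tol_ppm: float = 10.0,
                    rt_tol_seconds: float = 10.0,
                    max_charge: int = 2) -> list[Feature]:
    """Drop +k isotope partners (k = 1..3, z = 1..max_charge) of each
    feature; the lowest-m/z member of each chain is kept.

    A partner qualifies when it sits at mz + k*1.003355/z within the ppm
    tolerance, co-elutes within ``rt_tol_seconds``, and is not more intense
    (area) than the monoisotopic feature.
    """
    feats = sorted(features, key=lambda f: (f.mz, f.rt_seconds))
    removed = [False] * len(feats)
    mzs = np.array([f.mz for f in feats])
    for i, f in enumerate(feats):
        if removed[i]:
            continue
        for z in range(1, max_charge + 1):
            for k in range(1, 4):
                target = f.mz + k * PROTON_NEUTRON_DELTA / z
                tol = target * mz_tol_ppm * 1e-6
                lo = np.searchsorted(mzs, target - tol)
                hi = np.searchsorted(mzs, target + tol, side="right")
                for j in range(lo, hi):
                    if removed[j] or j == i:
                        continue
                    g = feats[j]
                    if (abs(g.rt_seconds - f.rt_seconds) <= rt_tol_seconds
                            and g.area <= f.area):
                        removed[j] = True
    return [f for f, r in zip(feats, removed) if not r]


class _Row:
    __slots__ = ("mz_weight", "rt_weight", "weight", "cells")

    def __init__(self):
        self.mz_weight = 0.0
        self.rt_weight = 0.0
        self.weight = 0.0
        self.cells: dict[str, Feature] = {}

    @property
    def mz(self):
        return self.mz_weight / self.weight

    @property
    def rt(self):
        return self.rt_weight / self.weight

    def add(self, sample_id, feat: Feature):
        self.cells[sample_id] = feat
        self.mz_weight += feat.mz * feat.area
        self.rt_weight += feat.rt_seconds * feat.area
        self.weight += feat.area


def align_features(per_sample_features: dict[str, list[Feature]],
                   mz_tol_ppm: float = 10.0,
                   rt_tol_seconds: float = 10.0) -> FeatureMatrix:
    """Greedy join alignment across samples.

    Samples are processed in lexicographic sample_id order. Each feature
    joins the open row minimizing (dppm/tol)^2 + (drt/tol)^2 when both
    deltas are within tolerance against the row's running consensus;
    otherwise it starts a new row. One feature per sample per row: when two
    features of one sample prefer the same row the better score wins and
    the loser starts a new row. Ties break toward the lower row index.
    """
    sample_ids = sorted(per_sample_features)
    if len(sample_ids) != len(per_sample_features):
        raise ValidationError("duplicate sample ids")
    if not sample_ids:
        raise ValidationError("align_features needs at least one sample")
    rows: list[_Row] = []
    for sid in sample_ids:
        feats = sorted(per_sample_features[sid],
                       key=lambda f: (f.mz, f.rt_seconds))
        candidates = []  # (score, row_idx, feat_idx)
        for fi, f in enumerate(feats):
            for ri, row in enumerate(rows):
                dppm = abs(f.mz - row.mz) / row.mz * 1e6
                drt = abs(f.rt_seconds - row.rt)
                if dppm <= mz_tol_ppm and drt <= rt_tol_seconds:
                    score = (dppm / mz_tol_ppm) ** 2 + (drt / rt_tol_seconds) ** 2
                    candidates.append((score, ri, fi))
        candidates.sort()
        taken_rows: set[int] = set()
        assigned: dict[int, int] = {}
        for score, ri, fi in candidates:
            if fi in assigned or ri in taken_rows:
                continue
            assigned[fi] = ri
            taken_rows.add(ri)
        for fi, f in enumerate(feats):
            if fi in assigned:
                rows[assigned[fi]].add(sid, f)
            else:
                row = _Row()
                row.add(sid, f)
                rows.append(row)
    order = sorted(range(len(rows)), key=lambda i: (rows[i].mz, rows[i].rt))
    mz = np.array([rows[i].mz for i in order])
    rt = np.array([rows[i].rt for i in order])
    data = np.zeros((len(rows), len(sample_ids)))
    for new_i, i in enumerate(order):
        for j, sid in enumerate(sample_ids):
            feat = rows[i].cells.get(sid)
            if feat is not None:
                data[new_i, j] = feat.area
    areas = pd.DataFrame(data, columns=sample_ids,
                         index=[f"f{i:05d}" for i in range(len(rows))])
    return FeatureMatrix(mz=mz, rt=rt, areas=areas)


def find_features(run: RawRun, noise_threshold: float = 2.0e6,
                  mz_tol_ppm: float = 10.0,
                  min_width_seconds: float = MIN_PEAK_WIDTH_SECONDS,
                  baseline: float = 1.0e4, max_width_seconds: float = 120.0,
                  rt_tol_seconds: float = 10.0, max_charge: int = 2,
                  centroided: bool = True) -> list[Feature]:
    """Full per-run feature finding: EICs, deconvolution, isotope removal."""
    eics = build_eics(run, mz_tol_ppm=mz_tol_ppm,
                      min_width_seconds=min_width_seconds,
                      noise_threshold=noise_threshold, centroided=centroided)
    feats: list[Feature] = []
    for eic in eics:
        feats.extend(deconvolute(eic, baseline=baseline,
                                 max_width_seconds=max_width_seconds,
                                 min_width_seconds=min_width_seconds))
    return remove_isotopes(feats, mz_tol_ppm=mz_tol_ppm,
                           rt_tol_seconds=rt_tol_seconds,
                           max_charge=max_charge)
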