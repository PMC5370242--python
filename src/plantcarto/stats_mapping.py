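"""Feature-matrix statistics and 3D ion-map table construction.

Covers TIC normalization, binary Jaccard dissimilarity, classical PCoA
(Gower double centering + eigendecomposition), k-group Venn/overlap region
counts, and assembly of the per-spot per-feature 'ili intensity table.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateSampleError, ValidationError
from .models import FeatureMatrix, IliTable, Mesh, SampleMetadata


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValidationError("distance matrix diagonal not zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids,
                            columns=self.sample_ids)


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives incl.)
    proportion_explained: np.ndarray  # per retained axis

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids,
                            columns=cols)


@dataclass
class VennCounts:
    """Region counts of a k-group Venn partition.

    ``regions`` maps a frozenset of group names to the number of features
    (or nodes) observed in exactly that set of groups. ``total`` is the
    number of items present in at least one group.
    """

    groups: list[str]
    regions: dict[frozenset, int]
    total: int

    @property
    def all_groups_count(self) -> int:
        return self.regions.get(frozenset(self.groups), 0)

    @property
    def all_groups_percent(self) -> float:
        return 100.0 * self.all_groups_count / self.total if self.total else 0.0

    def to_json_dict(self) -> dict:
        return {
            "groups": sorted(self.groups),
            "regions": {"+".join(sorted(k)): v
                        for k, v in sorted(self.regions.items(),
                                           key=lambda kv: sorted(kv[0]))},
            "total": self.total,
            "all_groups_count": self.all_groups_count,
            "all_groups_percent": self.all_groups_percent,
        }


def tic_normalize(m: FeatureMatrix) -> FeatureMatrix:
    """Divide each sample column by its total summed area; every normalized
    column sums to 1. An all-zero column raises
    :class:`DegenerateSampleError` naming the sample."""
    sums = m.areas.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise DegenerateSampleError(
            f"sample '{zero.index[0]}' has zero total ion current")
    return FeatureMatrix(mz=m.mz.copy(), rt=m.rt.copy(),
                         areas=m.areas / sums)


def jaccard_distances(m: FeatureMatrix) -> DistanceMatrix:
    """Binary Jaccard dissimilarity between sample presence sets
    (presence = area > 0); two empty samples are at distance 0."""
    presence = (m.areas.to_numpy() > 0).astype(np.float64)
    inter = presence.T @ presence
    sizes = presence.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1.0),
                           1.0)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(sample_ids=m.sample_ids, d=d)


def pcoa(dm: DistanceMatrix, n_axes: int = 3) -> OrdinationResult:
    """Classical principal coordinates analysis.

    Gower-centers -d^2/2, eigendecomposes, and scales eigenvectors by the
    square root of their (positive) eigenvalues. Negative eigenvalues are
    reported but yield no axes; no Cailliez/Lingoes correction is applied.
    Each axis's largest-magnitude coordinate is made positive so output is
    stable across eigensolver backends.
    """
    d = dm.d
    n = d.shape[0]
    a = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12 if n else 0.0
    n_pos = int(np.sum(eigvals > tol))
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues;"
            " truncating", stacklevel=2)
        n_axes = n_pos
    coords = eigvecs[:, :n_axes] * np.sqrt(eigvals[:n_axes])
    for k in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, k])))
        if coords[i, k] < 0:
            coords[:, k] *= -1.0
    pos_sum = float(eigvals[:n_pos].sum()) if n_pos else 1.0
    prop = eigvals[:n_axes] / pos_sum if n_pos else np.array([])
    return OrdinationResult(sample_ids=list(dm.sample_ids),
                            coordinates=coords, eigenvalues=eigvals,
                            proportion_explained=np.asarray(prop))


def _group_of_samples(metadata: list[SampleMetadata], sample_ids: list[str],
                      grouping: str = "tissue") -> dict[str, str]:
    meta = {m.sample_id: m for m in metadata}
    out = {}
    for sid in sample_ids:
        m = meta.get(sid)
        if m is None:
            raise ValidationError(f"sample '{sid}' missing from metadata")
        if m.is_blank:
            continue
        out[sid] = getattr(m, grouping)
    return out


def venn_counts(m: FeatureMatrix, metadata: list[SampleMetadata],
                grouping: str = "tissue") -> VennCounts:
    """Venn region counts of MS1 features across sample groups.

    A feature belongs to group g iff its area is positive in at least one
    non-blank sample of g. Regions sum to the number of features present in
    at least one group.
    """
    group_of = _group_of_samples(metadata, m.sample_ids, grouping)
    groups = sorted(set(group_of.values()))
    presence = m.areas.to_numpy() > 0
    col_group = [group_of.get(sid) for sid in m.sample_ids]
    regions: Counter = Counter()
    total = 0
    for row in presence:
        present_groups = frozenset(g for g, p in zip(col_group, row)
                                   if p and g is not None)
        if present_groups:
            regions[present_groups] += 1
            total += 1
    return VennCounts(groups=groups, regions=dict(regions), total=total)


def build_eim_table(m: FeatureMatrix, metadata: list[SampleMetadata],
                    mesh: Mesh, normalized: bool = False) -> IliTable:
    """One 'ili row per non-blank sample: coordinates, spot radius, and the
    full per-feature intensity vector (raw areas by default).

    Sample coordinates must fall inside the mesh bounding box expanded by
    one spot radius; violations raise naming the sample.
    """
    matrix = tic_normalize(m) if normalized else m
    lo, hi = mesh.bounds
    meta = {s.sample_id: s for s in metadata}
    names, coords, radii, cols = [], [], [], []
    for sid in matrix.sample_ids:
        s = meta.get(sid)
        if s is None:
            raise ValidationError(f"sample '{sid}' missing from metadata")
        if s.is_blank:
            continue
        if not s.has_coordinates or np.isnan(s.radius):
            raise ValidationError(
                f"sample '{sid}' lacks coordinates or spot radius")
        p = np.array([s.x, s.y, s.z])
        if np.any(p < lo - s.radius) or np.any(p > hi + s.radius):
            raise ValidationError(
                f"sample '{sid}' coordinates lie outside the mesh bounding "
                "box expanded by one radius")
        names.append(sid)
        coords.append(p)
        radii.append(s.radius)
        cols.append(matrix.areas[sid].to_numpy())
    values = (np.vstack(cols) if cols
              else np.empty((0, matrix.n_features)))
    return IliTable(sample_names=names,
                    coordinates=np.array(coords).reshape(-1, 3),
                    radii=np.array(radii),
                    feature_names=matrix.feature_labels(),
                    values=values)
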