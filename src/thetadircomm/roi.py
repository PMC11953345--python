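"""Peak-voxel selection and density-based activity-cluster (AC) formation.

Voxels within 3% of the highest source power are kept and grouped with
DBSCAN (Euclidean distance on physical voxel positions, eps = 1.5x the grid
spacing, minimum cluster size 3). eps = 1.5g admits face (g) and edge
(sqrt(2)g ~ 1.414g) neighbours but not corner (sqrt(3)g ~ 1.732g)
neighbours. Clusters become ordered ROI definitions for the virtual-channel
averaging stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from .beamforming import SourcePowerMap
from .synthetic import ToyHeadModel


@dataclass
class VoxelSet:
    """Selected voxels: grid indices, physical positions, power values."""

    voxel_ids: np.ndarray      # indices into the head-model grid
    coords: np.ndarray         # (n, 3) integer grid coordinates
    positions: np.ndarray      # (n, 3) physical positions
    power: np.ndarray

    def __post_init__(self) -> None:
        if len({tuple(c) for c in self.coords}) != len(self.coords):
            raise ValueError("voxel coordinates must be unique")
        if np.any(self.power < 0):
            raise ValueError("power values must be nonnegative")

    def __len__(self) -> int:
        return len(self.voxel_ids)


@dataclass
class AcSet:
    """DBSCAN activity clusters over a voxel set."""

    clusters: dict[int, np.ndarray]  # cluster id -> member voxel ids
    noise: np.ndarray                # unclustered voxel ids
    eps: float
    min_pts: int
    labels: np.ndarray = field(default=None)  # per input voxel, -1 = noise

    def sizes(self) -> dict[int, int]:
        return {k: len(v) for k, v in self.clusters.items()}


def threshold_top_voxels(pmap: SourcePowerMap, head: ToyHeadModel,
                         frac: float = 0.03,
                         mode: str = "value") -> VoxelSet:
    """Voxels within ``frac`` of the highest source power.

    ``mode="value"`` (default) keeps voxels with power >= (1-frac) * max —
    the reading of "within 3% of the highest value" as value-relative.
    ``mode="quantile"`` keeps the top ``frac`` fraction of voxels instead.
    """
    if not (0 < frac < 1):
        raise ValueError("frac must be in (0, 1)")
    power = np.asarray(pmap.power, float)
    if power.max() <= 0:
        raise ValueError("all-zero power map; nothing to threshold")
    if mode == "value":
        keep = power >= (1 - frac) * power.max()
    elif mode == "quantile":
        k = max(1, int(np.ceil(frac * len(power))))
        keep = power >= np.sort(power)[-k]
    else:
        raise ValueError("mode must be 'value' or 'quantile'")
    ids = np.flatnonzero(keep)
    return VoxelSet(ids, head.grid_coords[ids], head.grid_positions[ids],
                    power[ids])


def dbscan(points: VoxelSet, eps: float | None = None,
           min_pts: int = 3, spacing: float | None = None) -> AcSet:
    """DBSCAN on voxel positions; default eps = 1.5 x grid spacing.

    A core point has >= ``min_pts`` points (itself included) within eps;
    clusters are density-connected components of core points plus their
    border points. min_pts counts the point itself, so "minimum cluster size
    3" means every returned cluster has >= 3 members. Points are processed
    in lexicographic coordinate order, which makes border-point assignment
    deterministic and independent of input order.
    """
    if eps is None:
        if spacing is None:
            if len(points) < 2:
                raise ValueError("cannot infer grid spacing from < 2 points; "
                                 "pass eps or spacing")
            d = np.linalg.norm(points.positions[:, None]
                               - points.positions[None, :], axis=2)
            spacing = float(d[d > 0].min())  # nearest-neighbour step
        eps = 1.5 * spacing
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    if len(points) == 0:
        return AcSet({}, np.array([], int), eps, min_pts,
                     labels=np.array([], int))
    order = np.lexsort(points.coords.T[::-1])  # canonical processing order
    pos = points.positions[order]
    raw = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(pos)
    labels = np.empty(len(points), int)
    labels[order] = raw
    clusters = {}
    for lab in sorted(set(labels) - {-1}):
        clusters[int(lab)] = points.voxel_ids[labels == lab]
    noise = points.voxel_ids[labels == -1]
    return AcSet(clusters, noise, float(eps), min_pts, labels=labels)


@dataclass(frozen=True)
class Roi:
    """One ordered region of interest (activity cluster)."""

    name: str
    voxel_ids: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.voxel_ids)


def build_rois(acs: AcSet, label_table: dict | None = None) -> list[Roi]:
    """Order activity clusters into ROI definitions.

    Clusters are ordered by size descending, ties broken by the smallest
    member voxel index. Names come from ``label_table`` (cluster rank ->
    name) when given, else "AC1".."ACk".
    """
    if not acs.clusters:
        raise ValueError("no clusters to build ROIs from")
    items = sorted(acs.clusters.items(),
                   key=lambda kv: (-len(kv[1]), int(np.min(kv[1]))))
    rois = []
    for rank, (_, members) in enumerate(items, start=1):
        name = (label_table or {}).get(rank, f"AC{rank}")
        rois.append(Roi(name, tuple(int(v) for v in sorted(members))))
    return rois
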