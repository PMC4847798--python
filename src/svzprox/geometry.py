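"""Image-derived tumor/ventricle features.

Computes, from a tumor mask and a lateral-ventricle mask on a common grid:

* tumor volume (cm³) — foreground voxel count x voxel volume;
* tumor centroid — mean world-mm coordinate of all foreground voxel centers;
* contact — non-empty tumor∩ventricle overlap (operational definition of
  subventricular-zone involvement);
* TS — shortest edge-to-edge distance (mm) between tumor and ventricle,
  0 when the masks overlap;
* CS — shortest distance (mm) from the tumor centroid to the ventricle;
* a four-way rostrocaudal partition of the ventricular margin (frontal horn,
  body, occipital horn, temporal horn) and the *dominant* region, i.e. the
  subregion with the greatest tumor overlap.

All distances are Euclidean distances between voxel centers in world mm,
which is exact and well defined on anisotropic grids. Because the minimum
pairwise distance over two voxel sets is attained on their boundaries,
minimising over the full foreground sets equals minimising over "edges",
so no explicit boundary extraction is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .mask_io import EmptyMaskError, LabelError, MaskVolume, validate_pair

__all__ = [
    "REGION_CODES",
    "REGION_NAMES",
    "PartitionConfig",
    "TumorGeometry",
    "compute_volume",
    "compute_centroid",
    "detect_contact",
    "edge_distance_ts",
    "centroid_distance_cs",
    "partition_svz",
    "dominant_region",
    "measure_geometry",
]

#: Rostrocaudal subregions of the lateral-ventricle margin, anterior→posterior,
#: with the temporal horn as the inferior component. The code order 1<2<3<4 is
#: also the deterministic tie-break order for the dominant region.
REGION_NAMES: dict[int, str] = {
    1: "frontal_horn",
    2: "body",
    3: "occipital_horn",
    4: "temporal_horn",
}
REGION_CODES: dict[str, int] = {v: k for k, v in REGION_NAMES.items()}


@dataclass(frozen=True)
class PartitionConfig:
    """Parameters of the heuristic rostrocaudal ventricle partition.

    The ventricle is cut along the anterior–posterior world axis at two
    fractional planes of its AP extent (measured from the anterior end);
    connected components whose centroid lies below the given axial
    percentile of the ventricular z-coordinates are relabeled temporal horn.
    """

    frontal_fraction: float = 1 / 3
    occipital_fraction: float = 2 / 3
    temporal_percentile: float = 25.0

    def __post_init__(self) -> None:
        if not 0 < self.frontal_fraction < self.occipital_fraction < 1:
            raise ValueError("require 0 < frontal_fraction < occipital_fraction < 1")
        if not 0 <= self.temporal_percentile <= 100:
            raise ValueError("temporal_percentile must be in [0, 100]")


@dataclass(frozen=True)
class TumorGeometry:
    """Per-patient derived geometric features."""

    volume_cm3: float
    centroid_mm: np.ndarray
    contact: bool
    ts_mm: float
    cs_mm: float
    region_overlap_counts: Mapping[str, int] = field(default_factory=dict)
    dominant_region: str | None = None
    #: True when the centroid falls inside a ventricle voxel (then cs_mm == 0).
    centroid_in_ventricle: bool = False

    def to_row(self, patient_id: str | None = None) -> dict:
        row: dict = {} if patient_id is None else {"patient_id": patient_id}
        row.update(
            volume_cm3=self.volume_cm3,
            centroid_x_mm=float(self.centroid_mm[0]),
            centroid_y_mm=float(self.centroid_mm[1]),
            centroid_z_mm=float(self.centroid_mm[2]),
            contact=int(self.contact),
            ts_mm=self.ts_mm,
            cs_mm=self.cs_mm,
            dominant_region=self.dominant_region or "none",
            centroid_in_ventricle=int(self.centroid_in_ventricle),
        )
        for code in sorted(REGION_NAMES):
            name = REGION_NAMES[code]
            row[f"overlap_{name}"] = int(self.region_overlap_counts.get(name, 0))
        return row


def _require_nonempty(mask: MaskVolume, what: str) -> None:
    if mask.foreground_count == 0:
        raise EmptyMaskError(f"{what} mask has no foreground voxels")


def compute_volume(tumor: MaskVolume) -> float:
    """Tumor volume in cm³: foreground voxel count x voxel volume."""
    _require_nonempty(tumor, "tumor")
    return tumor.foreground_count * tumor.voxel_volume_mm3 / 1000.0


def compute_centroid(tumor: MaskVolume) -> np.ndarray:
    """Geometric center: mean world-mm coordinate of foreground voxel centers.

    May lie outside the mask for non-convex tumors.
    """
    _require_nonempty(tumor, "tumor")
    return tumor.world_coordinates().mean(axis=0)


def detect_contact(tumor: MaskVolume, ventricle: MaskVolume) -> tuple[bool, int]:
    """Whether tumor and ventricle masks overlap, plus the overlap voxel count."""
    validate_pair(tumor, ventricle)
    overlap = int(np.count_nonzero((tumor.data > 0) & (ventricle.data > 0)))
    return overlap > 0, overlap


def _min_distance_to(ventricle: MaskVolume, points: np.ndarray) -> float:
    tree = cKDTree(ventricle.world_coordinates())
    dists, _ = tree.query(np.atleast_2d(points), k=1)
    return float(np.min(dists))


def edge_distance_ts(tumor: MaskVolume, ventricle: MaskVolume) -> float:
    """TS: shortest tumor-edge-to-ventricle distance in world mm (0 on contact)."""
    validate_pair(tumor, ventricle)
    _require_nonempty(tumor, "tumor")
    _require_nonempty(ventricle, "ventricle")
    contact, _ = detect_contact(tumor, ventricle)
    if contact:
        return 0.0
    return _min_distance_to(ventricle, tumor.world_coordinates())


def centroid_distance_cs(tumor: MaskVolume, ventricle: MaskVolume) -> float:
    """CS: shortest distance (mm) from the tumor centroid to the ventricle.

    0 when the centroid falls inside a ventricle voxel.
    """
    validate_pair(tumor, ventricle)
    _require_nonempty(tumor, "tumor")
    _require_nonempty(ventricle, "ventricle")
    centroid = compute_centroid(tumor)
    if _centroid_inside(ventricle, centroid):
        return 0.0
    return _min_distance_to(ventricle, centroid)


def _centroid_inside(ventricle: MaskVolume, point: np.ndarray) -> bool:
    ijk = ventricle.world_to_index(point)[0]
    if np.any(ijk < 0) or np.any(ijk >= np.array(ventricle.shape)):
        return False
    return bool(ventricle.data[tuple(ijk)] > 0)


def partition_svz(
    ventricle: MaskVolume,
    mode: str = "heuristic",
    config: PartitionConfig | None = None,
) -> MaskVolume:
    """Assign each ventricle voxel one of the four rostrocaudal region labels.

    ``mode="prelabeled"`` validates and passes through a mask already carrying
    labels 1–4 (the fidelity path when an anatomical labeling exists).
    ``mode="heuristic"`` cuts the ventricle along the anterior–posterior world
    axis (+y = anterior in RAS) at the configured fractional planes and
    relabels inferior connected components as temporal horn.
    """
    _require_nonempty(ventricle, "ventricle")
    if mode == "prelabeled":
        if not ventricle.labels <= set(REGION_NAMES):
            raise LabelError(
                f"prelabeled ventricle carries labels {sorted(ventricle.labels)}; "
                f"expected subset of {sorted(REGION_NAMES)}"
            )
        return ventricle
    if mode != "heuristic":
        raise ValueError(f"unknown partition mode {mode!r}")
    config = config or PartitionConfig()

    fg = ventricle.foreground_indices()
    world = ventricle.world_coordinates(fg)
    y = world[:, 1]
    y_min, y_max = y.min(), y.max()
    extent = max(y_max - y_min, 1e-9)
    # fraction of the AP extent measured from the anterior (+y) end
    t = (y_max - y) / extent
    labels = np.where(t < config.frontal_fraction, 1, np.where(t < config.occipital_fraction, 2, 3))

    # temporal horn: connected components centered below the axial plane
    comp, n_comp = ndimage.label(ventricle.data > 0)
    z_plane = np.percentile(world[:, 2], config.temporal_percentile)
    comp_at_fg = comp[tuple(fg.T)]
    for c in range(1, n_comp + 1):
        in_c = comp_at_fg == c
        if in_c.any() and world[in_c, 2].mean() < z_plane:
            labels[in_c] = 4

    out = np.zeros(ventricle.shape, dtype=np.int16)
    out[tuple(fg.T)] = labels
    return MaskVolume(out, ventricle.affine)


def dominant_region(
    tumor: MaskVolume, labeled_ventricle: MaskVolume
) -> tuple[str | None, dict[str, int]]:
    """Per-region tumor overlap counts and the region with the greatest overlap.

    "Area of involvement" is operationalized as overlap voxel count. Exact
    ties break to the lowest region code (frontal horn < body < occipital
    horn < temporal horn). Returns ``(None, counts)`` when there is no
    overlap at all.
    """
    validate_pair(tumor, labeled_ventricle)
    if not labeled_ventricle.labels <= set(REGION_NAMES):
        raise LabelError(
            f"ventricle labels {sorted(labeled_ventricle.labels)} not in 1..4"
        )
    overlap_labels = labeled_ventricle.data[(tumor.data > 0) & (labeled_ventricle.data > 0)]
    counts = {
        REGION_NAMES[code]: int(np.count_nonzero(overlap_labels == code))
        for code in sorted(REGION_NAMES)
    }
    if overlap_labels.size == 0:
        return None, counts
    best = min(
        (code for code in REGION_NAMES),
        key=lambda code: (-counts[REGION_NAMES[code]], code),
    )
    return REGION_NAMES[best], counts


def measure_geometry(
    tumor: MaskVolume,
    ventricle: MaskVolume,
    labeled_ventricle: MaskVolume | None = None,
    partition_config: PartitionConfig | None = None,
) -> TumorGeometry:
    """Compute the full per-patient feature set.

    When no prelabeled ventricle is supplied the heuristic partition of the
    binary ventricle mask is used to attribute overlap to subregions.
    """
    validate_pair(tumor, ventricle)
    _require_nonempty(tumor, "tumor")
    _require_nonempty(ventricle, "ventricle")
    if labeled_ventricle is None:
        labeled_ventricle = partition_svz(ventricle, "heuristic", partition_config)
    else:
        labeled_ventricle = partition_svz(labeled_ventricle, "prelabeled")
        validate_pair(ventricle, labeled_ventricle)

    volume = compute_volume(tumor)
    centroid = compute_centroid(tumor)
    contact, _ = detect_contact(tumor, ventricle)
    ts = 0.0 if contact else edge_distance_ts(tumor, ventricle)
    inside = _centroid_inside(ventricle, centroid)
    cs = 0.0 if inside else _min_distance_to(ventricle, centroid)
    dom, counts = dominant_region(tumor, labeled_ventricle)
    return TumorGeometry(
        volume_cm3=volume,
        centroid_mm=centroid,
        contact=contact,
        ts_mm=float(ts),
        cs_mm=float(cs),
        region_overlap_counts=counts,
        dominant_region=dom,
        centroid_in_ventricle=inside,
    )
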