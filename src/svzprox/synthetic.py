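"""Synthetic phantoms and cohorts with known geometric and survival truth.

Three generators make every pipeline stage testable without patient data:

* :func:`make_ventricle_phantom` — a bilateral ventricle-like structure on an
  anisotropic grid (default 96x96x28 voxels at 0.6 x 0.6 x 5 mm), carrying
  ground-truth rostrocaudal region labels 1-4 (frontal horn, body, occipital
  horn along the main canals, plus separate inferior temporal-horn
  components).
* :func:`make_tumor` — an ellipsoidal tumor with a noisy boundary, carved to
  an exact voxel count and placed to meet contact / centroid-distance (CS) /
  dominant-region targets, verified by re-measuring with the geometry module.
* :func:`simulate_cohort` — a cohort of binary covariates at configurable
  prevalences, proportional-hazards survival times (exponential baseline,
  planted log-hazard-ratios), staggered-entry administrative censoring, the
  death-censors-progression rule for PFS, and (optionally) one mask pair per
  patient whose measured geometry realizes the planted CS/volume/contact
  covariates.

Identical spec + seed reproduce identical masks and tables.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import geometry as geo
from .mask_io import MaskVolume, write_mask

__all__ = [
    "SyntheticCohortSpec",
    "CohortData",
    "InfeasibleTumorError",
    "PlacementField",
    "build_placement_field",
    "make_ventricle_phantom",
    "make_tumor",
    "simulate_cohort",
    "cohort_analysis_frame",
]

#: Default planted log-hazard-ratios (multivariate-scale effect sizes used as
#: the ground truth the analysis must recover).
DEFAULT_LOG_HR_OS = {
    "age_ge40": float(np.log(2.192)),
    "volume_ge60": float(np.log(2.461)),
    "cs_le30": float(np.log(2.260)),
    "less_than_gtr": float(np.log(5.273)),
}
DEFAULT_LOG_HR_PFS = {
    "age_ge40": float(np.log(2.430)),
    "volume_ge60": float(np.log(1.998)),
    "less_than_gtr": float(np.log(4.526)),
}

#: Default covariate prevalences (fractions of patients positive).
DEFAULT_PREVALENCE = {
    "age_ge40": 0.36,
    "male": 0.68,
    "kps_lt80": 0.12,
    "cs_le30": 0.46,  # conditional on SVZ involvement
    "less_than_gtr": 0.72,
    "radiation": 0.75,
    "chemotherapy": 0.19,
}


class InfeasibleTumorError(RuntimeError):
    """A tumor target could not be realized on the grid within the retry budget."""

    def __init__(self, message: str, retries: int):
        super().__init__(f"{message} (after {retries} placement attempts)")
        self.retries = retries


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Ground-truth parameters of a simulated cohort.

    Survival times are exponential (constant baseline hazard) scaled by
    ``exp(sum of planted log-HR x covariate)``; progression has its own
    baseline and is truncated at death; administrative censoring arises from
    uniform accrual over ``accrual_days`` with close-out at ``study_days``
    (the defaults give roughly 30% OS censoring under the default
    prevalences and effects).
    """

    n: int = 200
    seed: int = 0
    grid_shape: tuple[int, int, int] = (96, 96, 28)
    spacing_mm: tuple[float, float, float] = (0.6, 0.6, 5.0)
    contact_prob: float = 0.80
    prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    region_probs: tuple[float, float, float, float] = (0.29, 0.25, 0.19, 0.27)
    log_hr_os: dict = field(default_factory=lambda: dict(DEFAULT_LOG_HR_OS))
    log_hr_pfs: dict = field(default_factory=lambda: dict(DEFAULT_LOG_HR_PFS))
    baseline_hazard_os: float = 1.05e-4  # per day
    baseline_hazard_pfs: float = 1.6e-4  # per day
    accrual_days: float = 2555.0
    study_days: float = 2920.0
    #: target CS (mm) bands; gaps around the 30 mm cut keep the +/-2 mm
    #: placement tolerance from flipping the planted dichotomy, and the far
    #: band stays inside the distances reachable on the default grid
    cs_near_mm: tuple[float, float] = (8.0, 26.0)
    cs_far_mm: tuple[float, float] = (34.0, 40.0)
    #: target tumor volume (cm³) bands around the 60 cm³ cut
    volume_low_cm3: tuple[float, float] = (4.0, 45.0)
    volume_high_cm3: tuple[float, float] = (62.0, 85.0)
    #: P(volume >= 60 cm³) given (non-involved, involved) — large lesions
    #: co-occur with ventricular contact
    volume_ge60_prevalence: tuple[float, float] = (0.21, 0.53)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 < self.contact_prob < 1:
            raise ValueError("contact_prob must be in (0, 1)")
        for k, v in self.prevalence.items():
            if not 0 < v < 1:
                raise ValueError(f"prevalence[{k!r}] must be in (0, 1)")
        if self.baseline_hazard_os <= 0 or self.baseline_hazard_pfs <= 0:
            raise ValueError("baseline hazards must be positive")
        if not 0 < self.accrual_days < self.study_days:
            raise ValueError("require 0 < accrual_days < study_days")
        if abs(sum(self.region_probs) - 1) > 1e-9:
            raise ValueError("region_probs must sum to 1")

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[0, 0], A[1, 1], A[2, 2] = self.spacing_mm
        return A


@dataclass
class CohortData:
    """Output bundle of :func:`simulate_cohort`."""

    spec: SyntheticCohortSpec
    clinical: pd.DataFrame
    truth: dict
    phantom: MaskVolume | None = None
    masks: dict | None = None  # patient_id -> (tumor MaskVolume, achieved dict)
    manifest: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# ventricle phantom
# ---------------------------------------------------------------------------

def make_ventricle_phantom(spec: SyntheticCohortSpec | None = None) -> MaskVolume:
    """Bilateral ventricle phantom with ground-truth region labels 1-4.

    Two parallel canals run along the anterior-posterior (y) axis at a
    superior axial level, labeled frontal horn / body / occipital horn by
    fractional thirds of the AP extent (anterior -> posterior); two separate
    inferior blobs form the temporal horns (label 4). Deterministic for a
    given spec.
    """
    spec = spec or SyntheticCohortSpec()
    nx, ny, nz = spec.grid_shape
    if nx < 32 or ny < 32 or nz < 12:
        raise ValueError(f"grid {spec.grid_shape} too small for the ventricle phantom")
    data = np.zeros(spec.grid_shape, dtype=np.int16)
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")

    y_lo, y_hi = int(round(0.125 * ny)), int(round(0.875 * ny))
    if (y_hi - y_lo) % 3 == 0:
        y_hi -= 1  # keep the fractional cut planes off voxel rows
    z_c = int(round(0.75 * nz))
    canal = np.zeros(spec.grid_shape, dtype=bool)
    for x_c in (int(round(0.365 * nx)), int(round(0.635 * nx))):
        tube = (
            (((ii - x_c) / (0.042 * nx)) ** 2 + ((kk - z_c) / 1.6) ** 2 <= 1.0)
            & (jj >= y_lo)
            & (jj <= y_hi)
        )
        canal |= tube

    # anterior (+y) third = frontal horn, middle = body, posterior = occipital
    extent = y_hi - y_lo
    frontal_from = y_hi - extent / 3.0
    body_from = y_hi - 2.0 * extent / 3.0
    data[canal & (jj > frontal_from)] = 1
    data[canal & (jj <= frontal_from) & (jj > body_from)] = 2
    data[canal & (jj <= body_from)] = 3

    # separate inferior temporal-horn components
    y_t = int(round(0.31 * ny))
    z_t = int(round(0.21 * nz))
    for x_t in (int(round(0.26 * nx)), int(round(0.74 * nx))):
        horn = (
            ((ii - x_t) / (0.052 * nx)) ** 2
            + ((jj - y_t) / (0.083 * ny)) ** 2
            + ((kk - z_t) / 1.8) ** 2
        ) <= 1.0
        data[horn] = 4

    phantom = MaskVolume(data, spec.affine)
    if phantom.labels != {1, 2, 3, 4}:
        raise ValueError("phantom construction failed to produce all four regions")
    return phantom


# ---------------------------------------------------------------------------
# tumor carving
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else np.array([1.0, 0.0, 0.0])


def _carve(
    shape: tuple[int, int, int],
    world: np.ndarray,
    center: np.ndarray,
    u: np.ndarray,
    semis: tuple[float, float, float],
    n_target: int,
    noise_field: np.ndarray,
    stalk: tuple[float, float] | None = None,
) -> np.ndarray:
    """Boolean mask of the ``n_target`` voxels best inside a noisy shape.

    The shape is an ellipsoid with principal axis ``u`` and semi-axes
    ``semis = (L, sp, sq)`` (``sq`` carried by the perpendicular axis most
    aligned with world z), optionally unioned with a thin cylindrical stalk
    ``stalk = (length, radius)`` running from the center along ``-u`` (by
    convention, toward the ventricle). Selecting the n smallest normalized
    radii makes the foreground count exact, so volume targets are met to one
    voxel; contacting tumors whose bulk sits far from the ventricle reach it
    through the stalk, keeping the centroid near the bulk center.
    """
    L, sp, sq = semis
    cross_z = np.cross(u, [0.0, 0.0, 1.0])
    # p is horizontal, so q = u x p carries whatever z-alignment u allows
    p = _unit(cross_z) if np.linalg.norm(cross_z) > 1e-9 else np.array([1.0, 0.0, 0.0])
    q = _unit(np.cross(u, p))

    d = world - center
    du = d @ u
    r = np.sqrt((du / L) ** 2 + (d @ p / sp) ** 2 + (d @ q / sq) ** 2)
    if stalk is not None:
        length, radius = stalk
        perp = np.sqrt(np.maximum((d * d).sum(axis=1) - du**2, 0.0))
        along = (-du >= -radius) & (-du <= length)
        r_stalk = np.where(along, perp / radius, np.inf)
        r = np.minimum(r, r_stalk)
    r = r + noise_field
    keep = np.argpartition(r, n_target - 1)[:n_target]
    out = np.zeros(len(world), dtype=bool)
    out[keep] = True
    return out.reshape(shape)  # world rows enumerate the grid in C order


def _perp_axes(volume_mm3: float, L: float, z_room: float, xy_room: float) -> tuple[float, float]:
    """Perpendicular semi-axes for an ellipsoid of given volume and main semi L."""
    prod = 3.0 * volume_mm3 / (4.0 * np.pi * max(L, 1.0))  # sp * sq
    sq = min(np.sqrt(1.8 * prod), 0.9 * z_room)
    sp = prod / sq
    if sp > xy_room:
        sp = xy_room
        sq = prod / sp
    return max(sp, 0.8), max(sq, 0.8)


def _room_along(center: np.ndarray, u: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> float:
    """Distance from center to the grid boundary along +u."""
    t = np.inf
    for ax in range(3):
        if u[ax] > 1e-9:
            t = min(t, (hi[ax] - center[ax]) / u[ax])
        elif u[ax] < -1e-9:
            t = min(t, (lo[ax] - center[ax]) / u[ax])
    return max(float(t), 0.0)


@dataclass(frozen=True)
class PlacementField:
    """Distance-to-ventricle field over the whole grid, reusable across tumors."""

    world: np.ndarray  # (n_vox, 3) voxel-center world coordinates
    dist: np.ndarray  # (n_vox,) distance to nearest ventricle voxel center
    nearest: np.ndarray  # (n_vox,) index into vent_world
    vent_world: np.ndarray
    vent_labels: np.ndarray
    tree: cKDTree


def build_placement_field(ventricle: MaskVolume) -> PlacementField:
    """Precompute, for every grid voxel, the nearest ventricle voxel and its
    distance in world mm (exact for any affine, via a KD-tree)."""
    fg = ventricle.foreground_indices()
    vent_world = ventricle.world_coordinates(fg)
    vent_labels = ventricle.data[tuple(fg.T)]
    tree = cKDTree(vent_world)
    idx = np.indices(ventricle.shape).reshape(3, -1).T
    world = ventricle.world_coordinates(idx)
    dist, nearest = tree.query(world)
    return PlacementField(world, dist, nearest, vent_world, vent_labels, tree)


def make_tumor(
    ventricle: MaskVolume,
    *,
    volume_cm3: float,
    contact: bool,
    cs_mm: float | None = None,
    region: str | None = None,
    rng: np.random.Generator | None = None,
    max_retries: int = 30,
    cs_tol_mm: float = 2.0,
    noise: float = 0.05,
    field: PlacementField | None = None,
) -> tuple[MaskVolume, dict]:
    """Generate a tumor mask meeting contact / CS / volume / region targets.

    The tumor is an ellipsoid with a noisy boundary — for contacting tumors
    unioned with a thin stalk toward the ventricle, so the centroid can sit
    at any reachable distance while the lesion still touches. It is carved
    to the exact voxel count implied by ``volume_cm3`` (tolerance +/-1 voxel
    by construction) and iteratively re-positioned until the geometry module
    measures the requested contact state, centroid distance (within
    ``cs_tol_mm``) and, when given, dominant region.

    Returns the mask and the achieved geometry (as re-measured by
    :func:`svzprox.geometry.measure_geometry`) plus the retry count.
    """
    rng = rng or np.random.default_rng()
    labeled = ventricle if ventricle.labels <= {1, 2, 3, 4} and not ventricle.is_binary else None
    binary = ventricle.binarized()
    A = ventricle.affine
    voxvol = ventricle.voxel_volume_mm3
    n_target = max(1, int(round(volume_cm3 * 1000.0 / voxvol)))
    n_total = int(np.prod(ventricle.shape))
    if n_target >= n_total - ventricle.foreground_count:
        raise InfeasibleTumorError(
            f"volume {volume_cm3} cm³ needs {n_target} voxels; grid has {n_total}", 0
        )
    vol_mm3 = n_target * voxvol

    if field is None:
        field = build_placement_field(ventricle)
    tree, vent_world = field.tree, field.vent_world
    lo = np.minimum(field.world.min(axis=0), field.world.max(axis=0))
    hi = np.maximum(field.world.min(axis=0), field.world.max(axis=0))
    z_room = (hi[2] - lo[2]) / 2.0
    xy_room = min(hi[0] - lo[0], hi[1] - lo[1]) / 2.0
    r0 = (3.0 * vol_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    d_max = float(field.dist.max())

    if region is not None and region not in geo.REGION_CODES:
        raise ValueError(f"unknown region {region!r}")
    region_ok = (
        np.ones(len(field.world), dtype=bool)
        if region is None
        else field.vent_labels[field.nearest] == geo.REGION_CODES[region]
    )
    if not region_ok.any():
        raise InfeasibleTumorError(f"ventricle has no {region} voxels", 0)

    # target distance of the tumor center from the ventricle
    cs_t = cs_mm
    if cs_t is not None:
        target_d = cs_t
    elif contact:
        target_d = float(np.clip(0.55 * r0, 1.0, 0.8 * d_max))
    else:
        target_d = float(min(r0 + rng.uniform(4.0, 15.0), 0.9 * d_max))
    band = 1.5
    candidates = np.flatnonzero((np.abs(field.dist - target_d) <= band) & region_ok)
    while len(candidates) == 0 and band <= 6.0:
        band *= 2.0
        candidates = np.flatnonzero((np.abs(field.dist - target_d) <= band) & region_ok)
    if len(candidates) == 0:
        raise InfeasibleTumorError(
            f"no grid location at distance ~{target_d:.1f} mm from "
            f"{region or 'the ventricle'} (max reachable {d_max:.1f} mm)", 0
        )

    retries = 0
    for _ in range(max_retries):
        retries += 1
        pick = candidates[rng.integers(len(candidates))]
        center = field.world[pick].astype(float)
        d_c0 = float(field.dist[pick])
        u = _unit(center - vent_world[field.nearest[pick]])
        L = max(min(r0 * rng.uniform(0.95, 1.25), 0.93 * _room_along(center, u, lo, hi)), 1.5)
        if not contact:
            L = max(min(r0, d_c0 - 3.5), 1.5)
        stalk_len = d_c0 + 2.5
        stalk_r = 3.2
        # one noisy boundary per attempt keeps the correction loop stable
        noise_field = noise * rng.standard_normal(int(np.prod(ventricle.shape)))

        ok = False
        for _ in range(10):
            # re-aim at the currently nearest ventricle point: the center
            # moves during correction and the stalk must keep hitting
            d_now, j_now = tree.query(center)
            u = _unit(center - vent_world[j_now])
            stalk_len = float(d_now) + 2.5
            L = max(min(L, 0.93 * _room_along(center, u, lo, hi)), 1.5)
            sp, sq = _perp_axes(vol_mm3, L, z_room, xy_room)
            stalk = (stalk_len, stalk_r) if contact else None
            tumor_bool = _carve(
                ventricle.shape, field.world, center, u, (L, sp, sq), n_target,
                noise_field, stalk,
            )
            overlap = int(np.count_nonzero(tumor_bool & (ventricle.data > 0)))
            got_contact = overlap > 0
            t_world = field.world[tumor_bool.ravel()]
            centroid = t_world.mean(axis=0)
            d_c, j_c = tree.query(centroid)
            cs_meas = float(d_c)
            if contact and not got_contact:
                stalk_r += 0.8  # stalk too thin for this voxel lattice
                continue
            if not contact and got_contact:
                # push the mass away from the ventricle and slim the main axis
                center = np.clip(center + 3.0 * u, lo + 2.0, hi - 2.0)
                L = max(0.7 * L, 1.5)
                continue
            if cs_t is not None and abs(cs_meas - cs_t) > cs_tol_mm:
                direction = _unit(centroid - vent_world[j_c]) if cs_meas > 1e-9 else u
                center = np.clip(center + (cs_t - cs_meas) * direction, lo + 2.0, hi - 2.0)
                continue
            ok = True
            break
        if not ok:
            continue
        tumor = MaskVolume(tumor_bool.astype(np.uint8), A)
        achieved = geo.measure_geometry(tumor, binary, labeled)
        if contact != achieved.contact:
            continue
        if cs_t is not None and abs(achieved.cs_mm - cs_t) > cs_tol_mm:
            continue
        if region is not None and contact and achieved.dominant_region != region:
            continue
        record = achieved.to_row()
        record["retries"] = retries
        record["n_voxels"] = n_target
        return tumor, record

    raise InfeasibleTumorError(
        f"could not realize target (contact={contact}, cs={cs_t}, "
        f"volume={volume_cm3} cm³, region={region})",
        retries,
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _draw_covariates(spec: SyntheticCohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n
    p = spec.prevalence
    involved = (rng.random(n) < spec.contact_prob).astype(int)
    cov = pd.DataFrame(
        {
            "patient_id": [f"p{i:04d}" for i in range(n)],
            "svz_involved": involved,
            "age_ge40": (rng.random(n) < p["age_ge40"]).astype(int),
            "male": (rng.random(n) < p["male"]).astype(int),
            "kps_lt80": (rng.random(n) < p["kps_lt80"]).astype(int),
            "volume_ge60": (
                rng.random(n) < np.where(involved == 1, *spec.volume_ge60_prevalence[::-1])
            ).astype(int),
            "less_than_gtr": (rng.random(n) < p["less_than_gtr"]).astype(int),
            "radiation": (rng.random(n) < p["radiation"]).astype(int),
            "chemotherapy": (rng.random(n) < p["chemotherapy"]).astype(int),
        }
    )
    cs_le30 = np.where(involved == 1, (rng.random(n) < p["cs_le30"]).astype(float), np.nan)
    cov["cs_le30"] = cs_le30
    names = [geo.REGION_NAMES[c] for c in sorted(geo.REGION_NAMES)]
    regions = rng.choice(names, size=n, p=spec.region_probs)
    # far centroids (CS > 30 mm) are only reachable through the anterior or
    # inferior horns on this anatomy, so condition the dominant region on CS
    p_far = np.array([spec.region_probs[0], 0.0, 0.0, spec.region_probs[3]])
    far_regions = rng.choice(names, size=n, p=p_far / p_far.sum())
    regions = np.where(cs_le30 == 0, far_regions, regions)
    cov["region"] = np.where(involved == 1, regions, "none")
    cov["frontal_horn_vs_others"] = np.where(
        involved == 1, (cov["region"] == "frontal_horn").astype(float), np.nan
    )
    return cov


def _linear_predictor(cov: pd.DataFrame, betas: dict) -> np.ndarray:
    lp = np.zeros(len(cov))
    for name, beta in betas.items():
        x = cov[name].to_numpy(dtype=float)
        lp += beta * np.nan_to_num(x)  # undefined covariates contribute 0
    return lp


def _simulate_survival(
    spec: SyntheticCohortSpec, cov: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(cov)
    rate_os = spec.baseline_hazard_os * np.exp(_linear_predictor(cov, spec.log_hr_os))
    rate_pfs = spec.baseline_hazard_pfs * np.exp(_linear_predictor(cov, spec.log_hr_pfs))
    t_death = rng.exponential(1.0 / rate_os)
    t_prog = rng.exponential(1.0 / rate_pfs)
    entry = rng.uniform(0.0, spec.accrual_days, n)
    censor = spec.study_days - entry

    os_days = np.minimum(t_death, censor)
    os_event = (t_death <= censor).astype(int)
    # PFS: progression event if first; death first censors PFS at death
    pfs_days = np.minimum.reduce([t_prog, t_death, censor])
    pfs_event = (t_prog <= np.minimum(t_death, censor)).astype(int)

    out = cov.copy()
    out["os_days"] = np.maximum(1, np.round(os_days)).astype(int)
    out["os_event"] = os_event
    out["pfs_days"] = np.maximum(1, np.round(pfs_days)).astype(int)
    out["pfs_event"] = pfs_event
    # rounding can not break the ordering, but clip defensively
    out["pfs_days"] = np.minimum(out["pfs_days"], out["os_days"])
    return out


def _clinical_from_truth(truth: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    n = len(truth)
    age = np.where(
        truth["age_ge40"] == 1, rng.integers(40, 71, n), rng.integers(18, 40, n)
    )
    kps = np.where(
        truth["kps_lt80"] == 1,
        rng.choice([50, 60, 70], n),
        rng.choice([80, 90, 100], n),
    )
    return pd.DataFrame(
        {
            "patient_id": truth["patient_id"],
            "age": age,
            "sex": np.where(truth["male"] == 1, "male", "female"),
            "kps": kps,
            "extent_of_resection": np.where(truth["less_than_gtr"] == 1, "<GTR", "GTR"),
            "radiation": truth["radiation"],
            "chemotherapy": truth["chemotherapy"],
            "os_days": truth["os_days"],
            "os_event": truth["os_event"],
            "pfs_days": truth["pfs_days"],
            "pfs_event": truth["pfs_event"],
        }
    )


def _draw_geometry_targets(
    spec: SyntheticCohortSpec, truth: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(truth)
    vol = np.where(
        truth["volume_ge60"] == 1,
        rng.uniform(*spec.volume_high_cm3, n),
        rng.uniform(*spec.volume_low_cm3, n),
    )
    # CS targets drive the planted dichotomy for involved patients only;
    # non-involved tumors are placed wherever a non-contacting fit exists
    cs = np.full(n, np.nan)
    for i in range(n):
        if truth.loc[i, "svz_involved"] == 1:
            band = spec.cs_near_mm if truth.loc[i, "cs_le30"] == 1 else spec.cs_far_mm
            cs[i] = rng.uniform(*band)
            if truth.loc[i, "cs_le30"] == 0:
                if truth.loc[i, "volume_ge60"] == 1:
                    # a contacting bulk this large cannot center far out on
                    # this grid: keep the joint draw in the reachable corner
                    cs[i] = rng.uniform(33.5, 36.5)
                    vol[i] = min(vol[i], 72.0)
                else:
                    # very small far tumors would be all stalk; keep enough
                    # bulk for the centroid to balance at the target
                    vol[i] = max(vol[i], 20.0)
    out = truth.copy()
    out["target_volume_cm3"] = vol
    out["target_cs_mm"] = cs
    return out


def simulate_cohort(
    spec: SyntheticCohortSpec,
    with_masks: bool = False,
    out_dir: str | os.PathLike | None = None,
) -> CohortData:
    """Simulate a cohort under the spec's proportional-hazards ground truth.

    Always produces the clinical table and the ground-truth record; with
    ``with_masks`` (implied by ``out_dir``) also generates one tumor mask per
    patient on a shared ventricle phantom, realizing each patient's planted
    contact/CS/volume covariates, and re-measures them with the geometry
    module. With ``out_dir``, masks (NIfTI), ``clinical.csv``,
    ``manifest.csv`` and ``truth.json`` are written to disk.
    """
    rng = np.random.default_rng(spec.seed)
    cov = _draw_covariates(spec, rng)
    truth_frame = _simulate_survival(spec, cov, rng)
    truth_frame = _draw_geometry_targets(spec, truth_frame, rng)
    clinical = _clinical_from_truth(truth_frame, rng)

    truth = {
        "seed": spec.seed,
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(spec).items()
        },
        "log_hr_os": dict(spec.log_hr_os),
        "log_hr_pfs": dict(spec.log_hr_pfs),
        "patients": truth_frame.to_dict(orient="records"),
    }

    phantom = None
    masks = None
    manifest = None
    if with_masks or out_dir is not None:
        phantom = make_ventricle_phantom(spec)
        placement = build_placement_field(phantom)
        masks = {}
        adjustments = []
        for i in range(spec.n):
            row = truth_frame.iloc[i]
            target_vol = float(row["target_volume_cm3"])
            target_cs = float(row["target_cs_mm"])
            kwargs = dict(
                volume_cm3=target_vol,
                contact=bool(row["svz_involved"]),
                cs_mm=None if np.isnan(target_cs) else target_cs,
                region=row["region"] if row["region"] != "none" else None,
                rng=rng,
                field=placement,
                max_retries=60,
            )
            try:
                tumor, achieved = make_tumor(phantom, **kwargs)
            except InfeasibleTumorError:
                # shrink within the planted volume band and retry once
                if row["volume_ge60"] == 1:
                    floor = spec.volume_high_cm3[0]
                elif row["svz_involved"] == 1 and row["cs_le30"] == 0:
                    floor = 20.0  # far contacts need enough bulk to balance
                else:
                    floor = spec.volume_low_cm3[0]
                kwargs["volume_cm3"] = max(floor, 0.75 * target_vol)
                adjustments.append(
                    {"patient_id": row["patient_id"], "volume_cm3": kwargs["volume_cm3"]}
                )
                tumor, achieved = make_tumor(phantom, **kwargs)
            masks[row["patient_id"]] = (tumor, achieved)
        if adjustments:
            truth["volume_adjustments"] = adjustments

    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        mask_dir = os.path.join(out_dir, "masks")
        os.makedirs(mask_dir, exist_ok=True)
        vent_path = os.path.join(mask_dir, "ventricle_labeled.nii.gz")
        write_mask(phantom, vent_path)
        vent_bin_path = os.path.join(mask_dir, "ventricle.nii.gz")
        write_mask(phantom.binarized(), vent_bin_path)
        rows = []
        for pid, (tumor, _) in masks.items():
            t_path = os.path.join(mask_dir, f"{pid}_tumor.nii.gz")
            write_mask(tumor, t_path)
            rows.append(
                {
                    "patient_id": pid,
                    "tumor_path": t_path,
                    "ventricle_path": vent_bin_path,
                    "labeled_ventricle_path": vent_path,
                }
            )
        manifest = pd.DataFrame(rows)
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
        clinical.to_csv(os.path.join(out_dir, "clinical.csv"), index=False)
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1, default=float)

    return CohortData(
        spec=spec,
        clinical=clinical,
        truth=truth,
        phantom=phantom,
        masks=masks,
        manifest=manifest,
    )


def cohort_analysis_frame(cohort: CohortData) -> pd.DataFrame:
    """Analysis-ready table built directly from the planted covariates.

    This is the tabular fast path for simulation studies of the survival
    workflow (no masks involved); the mask path reaches the same table
    through the measure → dichotomize pipeline.
    """
    frame = pd.DataFrame(cohort.truth["patients"])
    cols = [
        "patient_id",
        "svz_involved",
        "age_ge40",
        "male",
        "kps_lt80",
        "volume_ge60",
        "cs_le30",
        "frontal_horn_vs_others",
        "less_than_gtr",
        "radiation",
        "chemotherapy",
        "os_days",
        "os_event",
        "pfs_days",
        "pfs_event",
    ]
    return frame[cols].copy()
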