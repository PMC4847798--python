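"""Geometric features versus exhaustive brute-force oracles and invariants."""

import numpy as np
import pytest

from svzprox.geometry import (
    PartitionConfig,
    centroid_distance_cs,
    compute_centroid,
    compute_volume,
    detect_contact,
    dominant_region,
    edge_distance_ts,
    measure_geometry,
    partition_svz,
)
from svzprox.mask_io import EmptyMaskError, LabelError, MaskVolume

from conftest import ANISO, voxel_mask
import oracles


# -- trivial fixed cases -------------------------------------------------


def test_volume_arithmetic():
    iso = np.eye(4)
    data = np.zeros((10, 10, 10), dtype=np.uint8)
    data.ravel()[:1000] = 1
    assert compute_volume(MaskVolume(data, iso)) == pytest.approx(1.0)
    assert compute_volume(voxel_mask([(0, 0, 0)])) == pytest.approx(0.0018)
    with pytest.raises(EmptyMaskError):
        compute_volume(MaskVolume(np.zeros((3, 3, 3), dtype=np.uint8), ANISO))


def test_centroid_single_voxel_and_symmetry():
    assert np.allclose(compute_centroid(voxel_mask([(2, 3, 1)])), [1.2, 1.8, 5.0])
    affine = ANISO.copy()
    affine[:3, 3] = [-0.6 * 2, 0, -5.0]  # voxels (1,0,0) and (3,0,2) straddle origin
    sym = voxel_mask([(1, 0, 0), (3, 0, 2)], affine=affine)
    assert np.allclose(compute_centroid(sym), [0, 0, 0], atol=1e-12)


def test_contact_and_two_point_distances():
    a = voxel_mask([(0, 0, 0), (1, 0, 0)])
    same = voxel_mask([(0, 0, 0), (1, 0, 0)])
    contact, overlap = detect_contact(a, same)
    assert contact and overlap == 2
    disjoint = voxel_mask([(5, 5, 5)])
    contact, overlap = detect_contact(a, disjoint)
    assert not contact and overlap == 0
    shared = voxel_mask([(1, 0, 0), (2, 2, 2)])
    assert detect_contact(a, shared) == (True, 1)

    # two single voxels 2 slices apart along z: 10 mm on a 5 mm grid
    t = voxel_mask([(4, 4, 0)])
    v = voxel_mask([(4, 4, 2)])
    assert edge_distance_ts(t, v) == pytest.approx(10.0, abs=1e-9)
    assert edge_distance_ts(a, same) == 0.0
    # CS: single-voxel tumor, ventricle 30 mm away along y (50 rows x 0.6 mm)
    grid = (4, 60, 4)
    t1 = voxel_mask([(0, 0, 0)], shape=grid)
    v1 = voxel_mask([(0, 50, 0)], shape=grid)
    assert centroid_distance_cs(t1, v1) == pytest.approx(30.0, abs=1e-9)
    # centroid coincident with a ventricle voxel center
    assert centroid_distance_cs(t1, voxel_mask([(0, 0, 0)], shape=grid)) == 0.0


# -- brute-force oracle equivalence --------------------------------------


@pytest.mark.parametrize("seed", range(20))
def test_distances_match_bruteforce(seed):
    """Volume, centroid, TS and CS equal exhaustive enumeration within 1e-6 mm
    on random anisotropic mask pairs."""
    rng = np.random.default_rng(seed)
    tumor, ventricle = oracles.random_mask_pair(rng)
    assert compute_volume(tumor) == pytest.approx(oracles.bf_volume_cm3(tumor), abs=1e-12)
    assert np.allclose(compute_centroid(tumor), oracles.bf_centroid(tumor), atol=1e-6)
    assert edge_distance_ts(tumor, ventricle) == pytest.approx(
        oracles.bf_ts(tumor, ventricle), abs=1e-6
    )
    assert centroid_distance_cs(tumor, ventricle) == pytest.approx(
        oracles.bf_cs(tumor, ventricle), abs=1e-6
    )


@pytest.mark.parametrize("seed", range(12))
def test_contact_iff_zero_ts_and_cs_bound(seed):
    """contact ⇔ TS == 0; and CS >= TS whenever the centroid voxel lies inside
    the tumor mask."""
    rng = np.random.default_rng(1000 + seed)
    tumor, ventricle = oracles.random_mask_pair(rng)
    contact, _ = detect_contact(tumor, ventricle)
    ts = edge_distance_ts(tumor, ventricle)
    assert contact == (ts == 0.0)
    c = compute_centroid(tumor)
    ijk = tumor.world_to_index(c)[0]
    inside = np.all(ijk >= 0) and np.all(ijk < np.array(tumor.shape)) and tumor.data[tuple(ijk)] > 0
    if inside:
        assert centroid_distance_cs(tumor, ventricle) >= ts - 1e-9


@pytest.mark.parametrize("shift", [(7.2, 0, 0), (0, -3.0, 10.0), (1.8, 2.4, -5.0)])
def test_translation_invariance(shift, rng):
    """A rigid world translation of both masks leaves volume, TS, CS unchanged
    and moves the centroid by exactly the translation vector."""
    tumor, ventricle = oracles.random_mask_pair(rng)
    moved = ANISO.copy()
    moved[:3, 3] += shift
    t2 = MaskVolume(tumor.data, moved)
    v2 = MaskVolume(ventricle.data, moved)
    assert compute_volume(t2) == pytest.approx(compute_volume(tumor), abs=1e-9)
    assert edge_distance_ts(t2, v2) == pytest.approx(edge_distance_ts(tumor, ventricle), abs=1e-6)
    assert centroid_distance_cs(t2, v2) == pytest.approx(
        centroid_distance_cs(tumor, ventricle), abs=1e-6
    )
    assert np.allclose(compute_centroid(t2) - compute_centroid(tumor), shift, atol=1e-6)


# -- subregion partition and dominant region -----------------------------


def test_partition_prelabeled_passthrough_and_validation(phantom):
    out = partition_svz(phantom, "prelabeled")
    assert out is phantom
    bad = voxel_mask([(0, 0, 0), (1, 1, 1)], labels=[1, 5])
    with pytest.raises(LabelError):
        partition_svz(bad, "prelabeled")
    with pytest.raises(ValueError):
        partition_svz(phantom, "no-such-mode")


def test_heuristic_partition_recovers_phantom_labels(phantom):
    """The fractional anterior-posterior cuts plus the inferior-component rule
    reproduce the generator's ground-truth labels on >=95% of voxels."""
    heur = partition_svz(phantom.binarized(), "heuristic", PartitionConfig())
    fg = phantom.foreground_indices()
    truth = phantom.data[tuple(fg.T)]
    got = heur.data[tuple(fg.T)]
    assert (truth == got).mean() >= 0.95
    assert heur.labels == {1, 2, 3, 4}


def test_dominant_region_counts_and_tiebreak():
    labels = [1, 1, 1, 2, 2, 4, 4, 4]
    idx = [(i, 0, 0) for i in range(8)]
    vent = voxel_mask(idx, labels=labels)
    tumor = voxel_mask(idx[:5] + [(9, 9, 5)])  # overlaps 3x frontal, 2x body
    dom, counts = dominant_region(tumor, vent)
    assert dom == "frontal_horn"
    assert counts == {"frontal_horn": 3, "body": 2, "occipital_horn": 0, "temporal_horn": 0}
    # exact tie between frontal (1) and temporal (4): lowest code wins
    tie = voxel_mask([(0, 0, 0), (5, 0, 0)])
    dom_tie, _ = dominant_region(tie, vent)
    assert dom_tie == "frontal_horn"
    # no overlap at all
    dom_none, counts_none = dominant_region(voxel_mask([(9, 9, 5)]), vent)
    assert dom_none is None and sum(counts_none.values()) == 0


def test_measure_geometry_consistency(phantom, rng):
    """The assembled feature record is internally consistent: overlap counts
    sum to the contact overlap, contact ⇔ TS == 0, dominant region None only
    without contact."""
    from svzprox.synthetic import build_placement_field, make_tumor

    field = build_placement_field(phantom)
    tumor, _ = make_tumor(
        phantom, volume_cm3=12, contact=True, cs_mm=15, rng=rng, field=field
    )
    g = measure_geometry(tumor, phantom.binarized(), phantom)
    _, overlap = detect_contact(tumor, phantom.binarized())
    assert sum(g.region_overlap_counts.values()) == overlap
    assert g.contact and g.ts_mm == 0.0 and g.dominant_region is not None
    row = g.to_row("p1")
    assert row["patient_id"] == "p1" and row["contact"] == 1
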