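"""Phantom, tumor generator, and cohort simulator: targets, truth, determinism."""

import json

import numpy as np
import pandas as pd
import pytest

from svzprox.geometry import detect_contact, edge_distance_ts, measure_geometry, partition_svz
from svzprox.synthetic import (
    InfeasibleTumorError,
    SyntheticCohortSpec,
    build_placement_field,
    cohort_analysis_frame,
    make_tumor,
    make_ventricle_phantom,
    simulate_cohort,
)

import oracles


@pytest.fixture(scope="module")
def field(phantom):
    return build_placement_field(phantom)


def test_phantom_regions_and_determinism(phantom):
    assert phantom.labels == {1, 2, 3, 4}
    again = make_ventricle_phantom(SyntheticCohortSpec())
    assert np.array_equal(phantom.data, again.data)
    with pytest.raises(ValueError):
        make_ventricle_phantom(SyntheticCohortSpec(grid_shape=(16, 16, 4)))


def test_phantom_heuristic_partition_agreement(phantom):
    heur = partition_svz(phantom.binarized(), "heuristic")
    fg = phantom.foreground_indices()
    agree = (phantom.data[tuple(fg.T)] == heur.data[tuple(fg.T)]).mean()
    assert agree >= 0.95


def test_tumor_contact_with_region(phantom, field, rng):
    tumor, ach = make_tumor(
        phantom, volume_cm3=15, contact=True, region="body", rng=rng, field=field
    )
    contact, _ = detect_contact(tumor, phantom.binarized())
    assert contact and ach["dominant_region"] == "body"


def test_tumor_cs_target_without_contact(phantom, field, rng):
    """Requested CS 40 mm, no contact → measured CS in [38, 42] and TS > 0."""
    tumor, ach = make_tumor(
        phantom, volume_cm3=8, contact=False, cs_mm=40, rng=rng, field=field
    )
    assert 38.0 <= ach["cs_mm"] <= 42.0
    assert ach["contact"] == 0
    assert edge_distance_ts(tumor, phantom.binarized()) > 0


def test_tumor_volume_is_exact_in_voxels(phantom, field, rng):
    tumor, ach = make_tumor(
        phantom, volume_cm3=60, contact=True, cs_mm=20, rng=rng, field=field
    )
    expected_voxels = round(60 * 1000 / phantom.voxel_volume_mm3)
    assert abs(tumor.foreground_count - expected_voxels) <= 1
    assert ach["volume_cm3"] == pytest.approx(60.0, abs=phantom.voxel_volume_mm3 / 1000)


def test_tumor_achieved_geometry_matches_bruteforce(phantom, field, rng):
    """The generator's reported CS agrees with exhaustive enumeration (on a
    down-sampled ventricle subset it equals the KD-tree value exactly, so use
    the full measurement path against the brute-force centroid oracle)."""
    tumor, ach = make_tumor(
        phantom, volume_cm3=5, contact=False, cs_mm=25, rng=rng, field=field
    )
    assert np.allclose(oracles.bf_centroid(tumor),
                       measure_geometry(tumor, phantom.binarized()).centroid_mm, atol=1e-6)
    assert ach["cs_mm"] == pytest.approx(oracles.bf_cs(tumor, phantom.binarized()), abs=1e-6)


def test_infeasible_target_raises_with_retry_count(phantom, field, rng):
    with pytest.raises(InfeasibleTumorError):
        make_tumor(phantom, volume_cm3=5, contact=False, cs_mm=200, rng=rng, field=field)
    with pytest.raises(InfeasibleTumorError):
        make_tumor(phantom, volume_cm3=1e4, contact=True, rng=rng, field=field)


def test_cohort_tabular_truth_structure():
    spec = SyntheticCohortSpec(n=1500, seed=4)
    cohort = simulate_cohort(spec)
    clin = cohort.clinical
    assert (clin["pfs_days"] <= clin["os_days"]).all()
    # death without observed progression carries PFS censored at death
    dwp = clin[(clin.os_event == 1) & (clin.pfs_event == 0)]
    assert (dwp["pfs_days"] == dwp["os_days"]).all()
    # administrative censoring lands near its design level
    assert abs((1 - clin["os_event"].mean()) - 0.30) <= 0.05
    frame = cohort_analysis_frame(cohort)
    involved = frame[frame.svz_involved == 1]
    assert involved["cs_le30"].notna().all()
    assert frame.loc[frame.svz_involved == 0, "cs_le30"].isna().all()
    assert abs(len(involved) / len(frame) - spec.contact_prob) < 0.05


def test_cohort_same_seed_is_byte_identical(tmp_path):
    spec = SyntheticCohortSpec(n=12, seed=21)
    a = simulate_cohort(spec, out_dir=tmp_path / "a")
    b = simulate_cohort(spec, out_dir=tmp_path / "b")
    csv_a = (tmp_path / "a" / "clinical.csv").read_bytes()
    csv_b = (tmp_path / "b" / "clinical.csv").read_bytes()
    assert csv_a == csv_b
    for pid in a.masks:
        assert np.array_equal(a.masks[pid][0].data, b.masks[pid][0].data)
    truth = json.loads((tmp_path / "a" / "truth.json").read_text())
    assert truth["seed"] == 21 and len(truth["patients"]) == 12


def test_cohort_masks_realize_planted_covariates(tmp_path):
    """Measured contact, CS dichotomy, volume dichotomy and dominant region
    agree with the planted ground truth for every patient."""
    cohort = simulate_cohort(SyntheticCohortSpec(n=25, seed=33), with_masks=True)
    truth = pd.DataFrame(cohort.truth["patients"]).set_index("patient_id")
    for pid, (tumor, ach) in cohort.masks.items():
        row = truth.loc[pid]
        assert bool(ach["contact"]) == bool(row.svz_involved)
        assert (ach["volume_cm3"] >= 60) == bool(row.volume_ge60)
        if row.svz_involved:
            assert (ach["cs_mm"] <= 30) == (row.cs_le30 == 1)
            assert ach["dominant_region"] == row.region


def test_null_effects_recover_no_signal():
    """With all planted log-HRs zero, fitted univariate CIs contain 1 in the
    vast majority of replicates."""
    from svzprox.survival import cox_univariate

    hits = 0
    total = 0
    for seed in range(10):
        spec = SyntheticCohortSpec(
            n=800, seed=seed, log_hr_os={}, log_hr_pfs={}
        )
        frame = cohort_analysis_frame(simulate_cohort(spec))
        for cov in ("age_ge40", "volume_ge60", "less_than_gtr"):
            est = cox_univariate(frame, "os", cov)
            total += 1
            hits += est.ci_lower <= 1.0 <= est.ci_upper
    assert hits / total >= 0.9
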