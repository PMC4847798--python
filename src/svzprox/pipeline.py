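"""End-to-end orchestration: measure → assemble → analyze → report.

`run_pipeline` reads a manifest of per-patient mask paths plus a clinical
table, measures tumor geometry, builds the dichotomized analysis table,
runs the Kaplan–Meier/log-rank comparisons and the univariate-screen →
multivariate Cox cascade within the SVZ-involved subcohort, and writes a
deterministic CSV report bundle with a JSON run log. Per-patient failures
are logged and skipped; the run aborts only on an empty cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .cohort import (
    COVARIATE_COLUMNS,
    Thresholds,
    build_analysis_table,
    follow_up_summary,
    load_clinical,
    split_cohorts,
)
from .geometry import PartitionConfig, measure_geometry, partition_svz
from .mask_io import read_mask, validate_pair
from .survival import km_logrank, screen_then_multivariate

__all__ = ["RunConfig", "run_pipeline", "describe_cohort", "analyze_table",
           "reproduce_reference_statistics"]

log = logging.getLogger("svzprox")

#: Candidate covariates of the univariate screen (report order).
SCREEN_CANDIDATES = COVARIATE_COLUMNS


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    manifest_path: str
    clinical_path: str
    out_dir: str
    partition_mode: str = "prelabeled_if_available"  # | "heuristic" | "prelabeled"
    partition: PartitionConfig = field(default_factory=PartitionConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "partition" in raw:
            raw["partition"] = PartitionConfig(**raw["partition"])
        if "thresholds" in raw:
            raw["thresholds"] = Thresholds(**raw["thresholds"])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _measure_manifest(config: RunConfig) -> tuple[pd.DataFrame, list[dict]]:
    manifest = pd.read_csv(config.manifest_path)
    required = {"patient_id", "tumor_path", "ventricle_path"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must provide columns {sorted(required)}")
    rows, failures = [], []
    for _, entry in manifest.iterrows():
        pid = str(entry["patient_id"])
        try:
            tumor = read_mask(entry["tumor_path"], expected_labels={1})
            ventricle = read_mask(entry["ventricle_path"], expected_labels={1})
            validate_pair(tumor, ventricle)
            labeled = None
            lab_path = entry.get("labeled_ventricle_path")
            use_labels = config.partition_mode in ("prelabeled", "prelabeled_if_available")
            if use_labels and isinstance(lab_path, str) and lab_path:
                labeled = read_mask(lab_path, expected_labels={1, 2, 3, 4})
            elif config.partition_mode == "prelabeled":
                raise ValueError("partition_mode=prelabeled but no labeled ventricle given")
            if labeled is None:
                labeled = partition_svz(ventricle, "heuristic", config.partition)
            geometry = measure_geometry(tumor, ventricle, labeled)
            rows.append(geometry.to_row(pid))
        except Exception as exc:
            log.warning("patient %s skipped: %s", pid, exc)
            failures.append({"patient_id": pid, "reason": str(exc)})
    frame = pd.DataFrame(rows)
    if len(frame):
        frame = frame.sort_values("patient_id", kind="stable").reset_index(drop=True)
    return frame, failures


def describe_cohort(frame: pd.DataFrame, thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Cohort-characteristics table with chi-square group comparisons.

    For every binary covariate, reports counts and percentages in the
    CS ≤30 vs >30 mm strata of the SVZ-involved subcohort (with the
    chi-square p for that contrast) and in the non-involved group (with the
    involved vs non-involved chi-square p). Tests use no continuity
    correction; a comparison with an empty group or a zero expected cell is
    reported as not applicable.
    """
    split = split_cohorts(frame)
    inv, non = split.involved, split.non_involved
    near = inv[inv["cs_le30"] == 1]
    far = inv[inv["cs_le30"] == 0]

    def chi2_p(groups: list[pd.Series]) -> float:
        table = np.array([[int(g.sum()), int(len(g) - g.sum())] for g in groups])
        if table.sum() == 0 or (table.sum(axis=1) == 0).any():
            return float("nan")
        expected = stats.contingency.expected_freq(table)
        if (expected == 0).any():
            return float("nan")
        return float(stats.chi2_contingency(table, correction=False)[1])

    out = []
    variables = [c for c in COVARIATE_COLUMNS if c not in ("cs_le30",)]
    for var in variables:
        within = var not in ("frontal_horn_vs_others",)
        row = {"variable": var}
        for label, g in (("cs_le30", near), ("cs_gt30", far), ("non_involved", non)):
            col = g[var].dropna()
            row[f"n_{label}"] = int(col.sum())
            row[f"pct_{label}"] = float(100 * col.mean()) if len(col) else float("nan")
        row["p_cs_groups"] = chi2_p([near[var].dropna(), far[var].dropna()])
        row["p_involved_vs_not"] = (
            chi2_p([inv[var].dropna(), non[var].dropna()]) if within else float("nan")
        )
        out.append(row)
    return pd.DataFrame(out)


def _km_comparisons(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All Kaplan–Meier/log-rank contrasts of the study design."""
    split = split_cohorts(frame)
    inv = split.involved
    comparisons = [
        ("svz_involved_vs_not", split.all_patients, "svz_involved"),
        ("cs_le30_vs_gt30", inv, "cs_le30"),
        ("frontal_horn_vs_others", inv, "frontal_horn_vs_others"),
        ("dominant_region", inv, "dominant_region")
        if "dominant_region" in inv.columns
        else None,
    ]
    tests, curves = [], []
    for item in comparisons:
        if item is None:
            continue
        name, data, col = item
        sub = data.dropna(subset=[col])
        for endpoint, (dur, ev) in (("os", ("os_days", "os_event")), ("pfs", ("pfs_days", "pfs_event"))):
            try:
                res = km_logrank(sub[dur], sub[ev], sub[col])
            except ValueError as exc:
                tests.append(
                    {"comparison": name, "endpoint": endpoint.upper(), "chi_square": np.nan,
                     "p": np.nan, "note": str(exc)}
                )
                continue
            tests.append(
                {"comparison": name, "endpoint": endpoint.upper(),
                 "chi_square": res.chi_square, "p": res.p_value, "note": ""}
            )
            curve = res.to_frame()
            curve.insert(0, "endpoint", endpoint.upper())
            curve.insert(0, "comparison", name)
            curves.append(curve)
    return pd.DataFrame(tests), pd.concat(curves, ignore_index=True)


def analyze_table(frame: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Run the full statistical workflow on an assembled analysis table.

    KM/log-rank contrasts on all patients and the SVZ-involved subcohort;
    the Cox screen → multivariate cascade runs within the involved subcohort
    only, for each endpoint.
    """
    split = split_cohorts(frame)
    km_tests, km_curves = _km_comparisons(frame)
    reports = {}
    for endpoint in ("os", "pfs"):
        reports[endpoint] = screen_then_multivariate(
            split.involved, endpoint, SCREEN_CANDIDATES, alpha
        )
    effect_frames = [r.to_frame() for r in reports.values() if len(r.to_frame())]
    effects = (
        pd.concat(effect_frames, ignore_index=True)
        if effect_frames
        else pd.DataFrame(
            columns=["covariate", "endpoint", "model", "hr", "ci_lower", "ci_upper", "p", "n", "events"]
        )
    )
    return {
        "split_counts": split.counts,
        "follow_up": follow_up_summary(frame),
        "km_tests": km_tests,
        "km_curves": km_curves,
        "reports": reports,
        "effects": effects,
        "table1": describe_cohort(frame),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute measure → assemble → analyze → report; returns output paths."""
    logging.basicConfig(level=config.log_level)
    os.makedirs(config.out_dir, exist_ok=True)

    geometry, geo_failures = _measure_manifest(config)
    clinical = load_clinical(config.clinical_path)
    if len(geometry) == 0:
        raise RuntimeError("no patient could be measured; aborting")
    frame, exclusions = build_analysis_table(clinical, geometry, config.thresholds)
    if len(frame) == 0:
        raise RuntimeError("analysis table is empty after exclusions; aborting")
    results = analyze_table(frame, config.alpha)

    paths = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = os.path.join(config.out_dir, name)
        df.to_csv(path, index=False, float_format="%.6g")
        paths[name] = path

    _write("geometry.csv", geometry)
    _write("analysis_table.csv", frame)
    _write("table1_characteristics.csv", results["table1"])
    uni = results["effects"]
    _write("table2_univariate.csv", uni[uni["model"] == "univariate"])
    _write("table3_multivariate.csv", uni[uni["model"] == "multivariate"])
    _write("km_tests.csv", results["km_tests"])
    _write("km_curves.csv", results["km_curves"])

    n_manifest = len(pd.read_csv(config.manifest_path))
    run_log = {
        "version": __version__,
        "config_digest": config.digest(),
        "tie_handling": "efron",
        "n_manifest": n_manifest,
        "n_measured": int(len(geometry)),
        "n_analyzed": int(len(frame)),
        "split_counts": results["split_counts"],
        "follow_up": results["follow_up"],
        "measurement_failures": geo_failures,
        "exclusions": exclusions,
        "selected_covariates": {e: r.selected for e, r in results["reports"].items()},
        "notes": {e: r.notes for e, r in results["reports"].items()},
    }
    assert run_log["n_measured"] + len(geo_failures) == n_manifest
    log_path = os.path.join(config.out_dir, "run_log.json")
    with open(log_path, "w") as fh:
        json.dump(run_log, fh, indent=1, sort_keys=True, default=str)
    paths["run_log.json"] = log_path
    return {"paths": paths, "results": results, "run_log": run_log}


def reproduce_reference_statistics(
    clinical_path: str | os.PathLike,
    geometry: pd.DataFrame,
    thresholds: Thresholds | None = None,
    alpha: float = 0.05,
) -> dict:
    """Summary statistics of a measured cohort, in the report layout of the
    original study: cohort split counts, event counts, median follow-up among
    survivors, and the CS ≤30 mm hazard ratios (univariate and, when
    selected, multivariate) for overall survival.

    Intended for checking a cohort table (e.g. a deposited minimal data set
    with precomputed geometry) against published values.
    """
    clinical = load_clinical(clinical_path)
    frame, exclusions = build_analysis_table(clinical, geometry, thresholds)
    results = analyze_table(frame, alpha)
    split = results["split_counts"]
    inv = split_cohorts(frame).involved
    eff = results["effects"]
    cs_rows = eff[(eff["covariate"] == "cs_le30") & (eff["endpoint"] == "OS")]

    def _hr(model: str) -> float:
        sel = cs_rows[cs_rows["model"] == model]
        return float(sel["hr"].iloc[0]) if len(sel) else float("nan")

    return {
        "n": split["all"],
        "n_involved": split["involved"],
        "n_non_involved": split["non_involved"],
        "n_cs_le30": int((inv["cs_le30"] == 1).sum()),
        "n_cs_gt30": int((inv["cs_le30"] == 0).sum()),
        **results["follow_up"],
        "hr_cs_le30_os_univariate": _hr("univariate"),
        "hr_cs_le30_os_multivariate": _hr("multivariate"),
        "n_excluded": len(exclusions),
    }
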