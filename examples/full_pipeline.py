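"""End-to-end run: NIfTI masks on disk → measurement → survival report.

Writes a synthetic cohort (tumor/ventricle mask pairs plus a clinical CSV)
to a temporary directory, then runs the full pipeline: per-patient geometry,
dichotomized analysis table, cohort-characteristics table, Kaplan–Meier
comparisons, and the univariate/multivariate Cox reports.

Equivalent shell usage:
    svzprox simulate --n 100 --seed 5 --out cohort/
    svzprox run --manifest cohort/manifest.csv --clinical cohort/clinical.csv --out report/
"""

import json
import tempfile
from pathlib import Path

from svzprox import RunConfig, run_pipeline
from svzprox.synthetic import SyntheticCohortSpec, simulate_cohort

with tempfile.TemporaryDirectory() as td:
    td = Path(td)
    simulate_cohort(SyntheticCohortSpec(n=100, seed=5), out_dir=td)
    out = run_pipeline(
        RunConfig(
            manifest_path=str(td / "manifest.csv"),
            clinical_path=str(td / "clinical.csv"),
            out_dir=str(td / "report"),
            log_level="WARNING",
        )
    )
    log = out["run_log"]
    print("cohort split       :", log["split_counts"])
    print("follow-up summary  :", log["follow_up"])
    print("screen selections  :", log["selected_covariates"])
    print("report files       :", sorted(out["paths"]))
    print("\nmultivariate table (OS + PFS):")
    eff = out["results"]["effects"]
    print(eff[eff.model == "multivariate"].to_string(index=False))
    print("\nrun log digest:", json.dumps(log["config_digest"]))
# The involved/non-involved split tracks the 80% contact prevalence, and the
# multivariate hazard ratios estimate the planted effect sizes.
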