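"""The survival workflow on a simulated cohort.

Simulates a cohort with planted hazard ratios, compares overall survival of
SVZ-involved vs non-involved patients by log-rank, then runs the univariate
Cox screen and the p<0.05-gated multivariate model within the involved
subcohort — the same cascade the pipeline writes out as its univariate and
multivariate report tables.
"""

from svzprox import km_logrank, screen_then_multivariate
from svzprox.synthetic import SyntheticCohortSpec, cohort_analysis_frame, simulate_cohort

frame = cohort_analysis_frame(simulate_cohort(SyntheticCohortSpec(n=600, seed=3)))
involved = frame[frame.svz_involved == 1]

km = km_logrank(frame.os_days, frame.os_event, frame.svz_involved,
                {0: "non-involved", 1: "involved"})
print(f"OS, involved (n={km.group_sizes['involved']}) vs "
      f"non-involved (n={km.group_sizes['non-involved']}): "
      f"log-rank chi2={km.chi_square:.2f}, p={km.p_value:.4f}")

report = screen_then_multivariate(
    involved, "os",
    ["age_ge40", "male", "kps_lt80", "volume_ge60", "cs_le30",
     "frontal_horn_vs_others", "less_than_gtr", "radiation", "chemotherapy"],
)
print("\nunivariate screen (OS):")
for e in report.univariate:
    flag = "*" if e.p_value < report.alpha else " "
    print(f" {flag} {e.covariate:<24} HR {e.hr:5.2f}  ({e.ci_lower:.2f}-{e.ci_upper:.2f})  p={e.p_value:.4f}")
print(f"\nselected at p<{report.alpha}: {report.selected}")
print("multivariate model:")
for e in report.multivariate:
    print(f"   {e.covariate:<24} HR {e.hr:5.2f}  ({e.ci_lower:.2f}-{e.ci_upper:.2f})  p={e.p_value:.4f}")
# Starred covariates pass the screen; the joint HRs estimate the planted
# effects (2.19 age, 2.46 volume, 2.26 CS<=30, 5.27 <GTR) up to sampling noise.
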