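"""End-to-end synthetic study: simulate, QC, fit diets, niches, statistics.

Generates a ground-truthed five-beach study (plus two forest reference
populations), runs both diet estimators and the niche metrics, and prints
the site summary table alongside the recovery of the known truth.
"""

from isomix import RunConfig, run_full_pipeline

result = run_full_pipeline(RunConfig(seed=1))

print(result.table1_text)

truth = result.study.truth.groupby("site")["true_p_marine"].mean() * 100
site = result.site_summary.set_index("site")
print("site   estimated%  true%   error")
for s in site.index:
    est = site.loc[s, "pct_marine_bayes_mean"]
    print(f"{s:5s}  {est:8.1f}  {truth[s]:6.1f}  {est - truth[s]:+6.1f}")

reg = result.stats_report.set_index("test").loc["ols_pct_marine_vs_slope_mean"]
print(f"\ndiet ~ slope regression: F={reg['statistic']:.2f} p={reg['p_value']:.3f}")

# Errors of a few percentage points show the mixing model recovering each
# site's true mean marine fraction; the significant regression recovers the
# built-in positive slope-subsidy link.
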