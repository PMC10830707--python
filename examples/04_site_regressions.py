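"""Site-level regressions linking shoreline topography to diet and niche.

Uses the published five-beach summary table: mean percent marine diet
regressed on the mean transition-zone hillslope, and the corrected standard
ellipse area regressed on the hillslope SD (within-beach topographic
variability).
"""

from isomix import puget_sound_site_summary, simple_ols

table = puget_sound_site_summary()
print(table.to_string(index=False))

diet = simple_ols(table["slope_mean"], table["pct_marine_bayes_mean"])
print(f"\npercent marine diet ~ slope mean:  F={diet.f_stat:.1f} "
      f"df={diet.df[0]},{diet.df[1]} P={diet.p_value:.3f} R2={diet.r2:.2f}")

niche = simple_ols(table["slope_sd"], table["sea_c"])
print(f"SEA_C ~ slope SD:                  y = {niche.intercept:.2f} + "
      f"{niche.slope:.2f}x, F={niche.f_stat:.2f} P={niche.p_value:.3f} R2={niche.r2:.2f}")

# Steeper shorelines carry more marine-subsidized diets; more variable
# shorelines host broader isotopic niches.
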