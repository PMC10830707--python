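"""Reference site-level summaries for five South Puget Sound beaches.

Published per-site summary statistics from a field study of marine-subsidized
western fence lizard (*Sceloporus occidentalis*) populations: sample sizes,
mean +/- SD percent marine diet from the Bayesian mixing model and from the
algebraic estimator, the small-sample-corrected standard ellipse area, and
the transition-zone hillslope mean +/- SD from five 75 m transects per beach.
Values carry the precision at which they were reported (percent to integers,
areas and slopes to 2 decimals).  Used by the examples and by validation
code to check the site-level regressions; individual-level raw data are not
included here.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["puget_sound_site_summary", "SOURCE_ENDMEMBERS"]

_ROWS = [
    # site, n, %marine bayes mean, sd, %marine alpha mean, sd, SEA_C, slope mean, slope sd
    ("DM", 10, 51, 9, 40, 6, 3.20, 0.44, 0.09),
    ("JB", 11, 39, 21, 32, 11, 4.80, 0.29, 0.11),
    ("LCB", 9, 25, 14, 23, 9, 2.31, 0.07, 0.01),
    ("MMP", 10, 20, 14, 20, 9, 3.41, 0.17, 0.08),
    ("PR", 7, 21, 9, 21, 5, 2.25, 0.05, 0.02),
]

# plant endmember means anchoring the algebraic estimator (per mil VPDB)
SOURCE_ENDMEMBERS = {"terrestrial_mu_C": -30.6, "marine_mu_C": -11.4, "alpha_delta13C": 3.8}


def puget_sound_site_summary() -> pd.DataFrame:
    """Return the published five-beach summary table as a DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "site", "n", "pct_marine_bayes_mean", "pct_marine_bayes_sd",
            "pct_marine_alpha_mean", "pct_marine_alpha_sd",
            "sea_c", "slope_mean", "slope_sd",
        ],
    )
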