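"""Algebraic marine-diet fraction from a single d13C value.

The alpha estimator linearly interpolates the discrimination-corrected
consumer d13C between the terrestrial plant endmember (-30.6 per mil,
blackberry) and the marine endmember (-11.4 per mil, beach-cast algae),
using a bulk plant-to-consumer offset of 3.8 per mil.
"""

from isomix import alpha_marine_fraction

consumers = {
    "terrestrial forager": -26.8,
    "mixed diet": -17.2,
    "marine specialist": -9.0,
}

for label, d13c in consumers.items():
    pct, out_of_range = alpha_marine_fraction(d13c, 3.8, -30.6, -11.4)
    note = " (clamped: outside the endmember interval)" if out_of_range else ""
    print(f"{label:20s} d13C={d13c:6.1f} -> {pct:5.1f}% marine diet{note}")

# Each percentage is the share of assimilated carbon attributed to the marine
# food web; 0% and 100% correspond to consumers sitting exactly on the
# adjusted terrestrial and marine endmembers.
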