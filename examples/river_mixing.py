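"""How much river water would it take to move coastal pH by 0.2 units?

Penobscot River pH rose from 6.6 to 7.2 between 1980 and 2000.  River water
(alkalinity 230 umol/kg, DIC set by its pH) is mixed conservatively into
Gulf of Maine seawater (ALK 2200, DIC 2050, S 33, pH 8.0) and the coastal
pH shift between the two river-pH scenarios is solved at each fraction.
"""

from boronph.mixing import (
    river_fraction_for_shift,
    river_mix,
    river_scenario_delta,
    river_sensitivity,
)

print(f"unmixed seawater pH          : {river_mix(0.0, 6.6).pH:.2f}")
for f in (0.05, 0.10, 0.20):
    print(f"shift at {f:.0%} river fraction : {river_scenario_delta(f):.3f}")

threshold = river_fraction_for_shift(target=0.2, step=0.01)
print(f"\nsmallest fraction for a 0.2 shift: {threshold:.0%}")
print("(far above the ~5% implied by observed coastal salinities 30-33 psu,")
print(" and salinity at that fraction would drop below what coralline algae")
print(" tolerate)")

print("\nsensitivity to the assumed river alkalinity:")
print(river_sensitivity().to_string(index=False))
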