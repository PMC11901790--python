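"""Canopy-pruning scenario: how far can LAI be reduced while keeping an
erosion-protective interception floor?

Uses published heavy-rain interception regressions for a conifer
woodland and an alfalfa grassland: at the largest moderate-rain depth
(24.9 mm/24 h, the erosion boundary condition), scan LAI downward for
the smallest canopy that still intercepts the target depth.
"""

from greenwater.analysis import lai_pruning_trial, predict_gwi

cases = [
    ("conifer woodland ", (0.057, 1.724, -1.145), 4.0),
    ("alfalfa grassland", (0.034, 1.137, -0.635), 1.3),
]
P_DESIGN = 24.9  # mm: largest moderate rain, the erosion threshold region

for label, coefs, target in cases:
    res = lai_pruning_trial(lambda P, L: predict_gwi(coefs, P, L),
                            P_design=P_DESIGN, GWI_target=target)
    print(f"{label}: keep GW_I >= {target:.1f} mm at P = {P_DESIGN} mm "
          f"-> prune LAI to {res.lai:.1f} m2/m2 "
          f"(predicted GW_I {res.predicted_GWI:.2f} mm)")

print()
print("Leaves removed beyond these LAI values would start sacrificing the")
print("soil-protective interception floor; leaves kept above them only add")
print("ineffective green-water loss.")
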