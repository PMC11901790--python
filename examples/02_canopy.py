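"""Beer-law ET partition and rainfall interception for a closing canopy.

Shows how a growing leaf area shifts atmospheric demand from soil
evaporation to transpiration, and how canopy interception of a 20-mm
rain saturates toward its storage capacity a*LAI.
"""

from greenwater.canopy import CanopyParams, interception, partition_et0

cp = CanopyParams(mu=0.46, a=0.25)
print("LAI    Tp (mm)  Ep (mm)   GW_I of 20 mm rain   capacity a*LAI")
for lai in (0.0, 0.5, 1.0, 2.0, 3.5):
    part = partition_et0(5.0, lai, cp)          # 5 mm/day of demand
    icp = interception(20.0, lai, cp)
    print(f"{lai:4.1f}   {part.Tp:6.2f}   {part.Ep:6.2f}"
          f"   {icp.GW_I:12.2f} mm      {cp.a * lai:6.2f} mm")
print()
print("Tp + Ep always equals ET0; interception never exceeds the rain depth")
print("or the canopy storage capacity, so dense canopies waste more rain as")
print("ineffective green water (GW_I).")
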