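"""Compute daily reference evapotranspiration for one day of weather.

Builds a single day of atmospheric forcing and evaluates the FAO-56
Penman-Monteith combination equation, printing the intermediate terms
(vapour pressures, curve slope, psychrometric constant) alongside ET0.
"""

import datetime as dt

from greenwater.meteo import DailyMeteo, penman_monteith_et0

met = DailyMeteo(date=dt.date(2019, 6, 15), P=0.0, T_air=22.0, U2=2.1,
                 Rn=14.2, G=0.0, RH=0.55)
terms = penman_monteith_et0(met)

print(f"saturation vapour pressure e_a = {terms.e_a:.3f} kPa")
print(f"actual vapour pressure     e_d = {terms.e_d:.3f} kPa")
print(f"svp curve slope          delta = {terms.delta:.4f} kPa/K")
print(f"psychrometric constant   gamma = {terms.gamma:.4f} kPa/K")
print(f"reference ET0                  = {terms.ET0:.2f} mm/day")
print()
print("ET0 is the atmospheric demand an unstressed reference surface would")
print("evaporate; the canopy module splits it between plants and soil.")
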