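"""Parameter recovery: calibrate the pore-size parameter from synthetic
soil-moisture observations.

A truth run with known parameters emits noise-free TDR-style moisture
observations at 20/70/160 cm; calibration starts from a deliberately
wrong pore-size-distribution value n1 and recovers the truth by
maximising the mean Nash-Sutcliffe efficiency.
"""

from greenwater.calibrate import calibrate
from greenwater.forward import CalibrationRunner
from greenwater.synth import WeatherGenSpec, gen_weather, make_truth_run, species_templates
from greenwater.templates import PARAM_RANGES

template = species_templates()["R. pseudoacacia"]
weather = gen_weather(WeatherGenSpec(seed=3, year=2019)).iloc[:60]  # 60-day window
truth = make_truth_run(template, weather, sigma_theta=0.0, seed=0)

start = template.with_params(n1=1.35)
runner = CalibrationRunner(start, weather, truth.forward.lai)
result = calibrate(runner, truth.observations, {"n1": PARAM_RANGES["n1"]},
                   nominal={"n1": 1.35}, n_screen=12, seed=5, maxiter=60)

print(f"true n1        = {template.n1:.4f}")
print(f"starting guess = 1.3500")
print(f"calibrated n1  = {result.params['n1']:.4f}")
print(f"mean theta NSE = {result.objective:.5f}  (1 = perfect)")
print(f"bands: {result.bands}")
print()
print("With noise-free observations the optimiser recovers the generating")
print("parameter almost exactly and the skill bands are all 'very good'.")
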