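"""Run the daily soil-water bucket and the tensiometer irrigation trigger.

A 184 mm bucket (the platform's mean plant-available water at the end of
winter) is drawn down by constant evapotranspiration; the stress factor
falls once less than 40% of the capacity remains.  A 60 cm tension series
then shows when the irrigation thresholds fire.
"""

import pandas as pd

from canopytraits import water

weather = pd.DataFrame(
    {"rain_mm": [0.0] * 30, "irrigation_mm": [0.0] * 30, "et_mm": [4.0] * 30}
)
ledger = water.run_budget(whc_mm=184.0, initial_storage_mm=184.0, weather=weather)
frame = ledger.to_frame()
for day in (9, 19, 29):
    row = frame.iloc[day]
    frac = row["storage_mm"] / 184.0
    sf = water.sinclair_stress_factor(frac)
    print(f"day {day + 1:2d}: storage {row['storage_mm']:6.1f} mm "
          f"(fraction {frac:.2f}) stress factor {sf:.2f}")

tension = water.TensionSeries(60, list(range(10, 70, 10)), [40, 60, 75, 85, 110, 130])
triggers = water.irrigation_triggers(tension, lambda d: "pre-Z39" if d < 40 else "post-Z39")
print("irrigation triggers:")
print(triggers[["date", "tension_cbar", "threshold_cbar", "water_stress"]].to_string(index=False))
# A stress factor of 1 means unconstrained growth; tensions above the
# threshold call for irrigation, and above 120 cbar the crop is considered
# water stressed.
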