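"""Relate call counts to the temperature-humidity index (THI).

Draws a 200-window THI series spanning all four comfort zones with the
default call-count couplings (alarm decreases with THI, squawk increases),
normalises counts onto levels 1-10 per class, and reports the Pearson
correlations with their two-tailed p-values.
"""

from henvox import compute_thi, thi_zone
from henvox.synth import synth_thermal
from henvox.thermal import CALL_TYPES, add_levels, correlate_windows

print("THI examples: 25 degC / 50% RH ->", round(compute_thi(25.0, 50.0), 1),
      f"({thi_zone(compute_thi(25.0, 50.0))});",
      "35 degC / 70% RH ->", round(compute_thi(35.0, 70.0), 1),
      f"({thi_zone(compute_thi(35.0, 70.0))})")

records, windows = synth_thermal(n_windows=200, seed=7)
windows = add_levels(windows)
print("\nwindows per zone:", windows["zone"].value_counts().to_dict())

corr = correlate_windows(windows)
print("\nPearson correlation of 5-min call counts with THI (n = 200):")
for c in CALL_TYPES:
    v = corr[c]
    flag = "**" if v["significant_01"] else "  "
    print(f"  {c:8s} r = {v['r']:+.3f}   p = {v['p']:.2e} {flag}")
print("\n** significant at the 0.01 level (2-tailed).  A negative alarm and"
      "\npositive squawk correlation mirror the coupling built into the"
      "\ngenerator: heat-stressed hens squawk more and give fewer alarm calls.")
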