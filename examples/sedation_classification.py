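"""Sedation-level classification from infusion records.

Applies the published dose thresholds per drug, including the
propofol/dexmedetomidine synergy rule (the propofol deep threshold drops
from 50 to 35 ug/kg/min when dexmedetomidine runs at >= 0.5 ug/kg/h).
"""

from seeme.clinical import SedationRecord, classify_sedation

rec = lambda drug, rate, unit: SedationRecord("patient", "t0", drug, rate, unit)

cases = {
    "propofol 40 ug/kg/min alone": [rec("propofol", 40.0, "ug/kg/min")],
    "propofol 40 + dexmedetomidine 0.6": [
        rec("propofol", 40.0, "ug/kg/min"),
        rec("dexmedetomidine", 0.6, "ug/kg/h"),
    ],
    "fentanyl 1.0 mcg/kg/h (analgesia)": [rec("fentanyl", 1.0, "mcg/kg/h")],
    "no infusions": [],
}
for name, records in cases.items():
    print(f"{name:>36}: {classify_sedation(records)}")
# 40 ug/kg/min propofol is light on its own, but deep once dexmedetomidine
# reaches 0.5 ug/kg/h; sub-1.5 fentanyl is analgesic (light).
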