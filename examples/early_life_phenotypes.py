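"""Construct the early-life environment phenotypes from raw birth records.

Shows the eight constructors on a tiny record table: preterm birth, birth
month, the continuous seasonal birth-date score, young/lone parent flags and
the urban indicator.
"""

import pandas as pd

from stressmwas import phenotypes as ph

records = pd.DataFrame({
    "gestation_weeks": [36, 40, 28],
    "birth_month": [12, 6, 4],
    "birth_doy": [355.0, 172.0, 100.0],
    "mother_age": [20, 34, 27],
    "father_age": [24, 36, 29],
    "birth_region": ["Glasgow", "Highland", "Dundee"],
    "mother_region": ["Glasgow", "Highland", "Dundee"],
    "father_region": ["Glasgow", "Moray", "Dundee"],
})

print("preterm (<37 weeks):     ", ph.preterm_flag(records["gestation_weeks"]).tolist())
print("born Apr-Oct:            ", ph.birth_month_flag(records["birth_month"]).tolist())
print("birth-date score:        ",
      [round(v, 3) for v in ph.birth_date_score(records["birth_doy"])])
print("young parent (<21):      ", ph.young_parent_flag(records).tolist())
print("lone parent (by region): ", ph.lone_parent_flag(records).tolist())
print("urban (4 cities):        ", ph.urban_flag(records["birth_region"]).tolist())
# The birth-date score is -1 at the winter solstice (day 355) and +1 at the
# summer solstice (day 172); exposures are coded 1, boundaries are strict.
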