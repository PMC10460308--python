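"""Score WHO-ASSIST responses and derive use/harm indicators and groups.

Builds a tiny hand-written cohort of three participants, computes each
substance's involvement (risk) score — the weighted sum of the frequency
item Q2 and the harm items Q3-Q7 — then dichotomises items to past-3-month
use/harm flags and assigns the four-group classification driven by the two
high-centrality substances (ATS, cannabis).
"""

import pandas as pd

from assistnet import assign_group, classify_polysubstance, dichotomize_items, score_involvement
from assistnet.instrument import SUBSTANCES, substance_items

rows = [
    # a daily cannabis user who also smokes, with several harms
    {
        "cannabis_q2": "daily_or_almost_daily", "cannabis_q3": "weekly",
        "cannabis_q4": "monthly", "cannabis_q6": "yes_past_3_months",
        "tobacco_q2": "daily_or_almost_daily", "tobacco_q3": "daily_or_almost_daily",
    },
    # occasional drinker, no harms
    {"alcohol_q2": "once_or_twice"},
    # ATS plus cannabis use
    {"ats_q2": "monthly", "ats_q3": "monthly", "cannabis_q2": "weekly"},
]
columns = [f"{s}_{it}" for s in SUBSTANCES for it in substance_items(s)]
cohort = pd.DataFrame([{c: row.get(c, "never") for c in columns} for row in rows])

scores = score_involvement(cohort)
indicators = dichotomize_items(cohort)

print("involvement scores (raw):")
print(scores[["tobacco_score", "alcohol_score", "cannabis_score", "ats_score"]])
print()
print("past-3-month use flags:")
print(indicators[["tobacco_used", "alcohol_used", "cannabis_used", "ats_used"]])
print()
print("polysubstance class (incl. tobacco/alcohol):",
      classify_polysubstance(indicators, True).tolist())
print("substance group:", assign_group(indicators).tolist())
# Row 1 scores 6+5+5+6 = 22 for cannabis (a heavy pattern); row 2's single
# "once_or_twice" drink scores 2; groups follow the ATS > cannabis > other
# precedence, so participant 3 lands in "ats" despite also using cannabis.
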