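"""Derive budburst metrics and clean a height series from raw records.

Shows the stage-timing rules (midpoint for skipped stages, site-relative
timing) and the height-reversal cleaning with adjacent-year increments.
"""

import pandas as pd

from markertrait import clean_height_series, derive_budburst_metrics

obs = pd.DataFrame({
    "individual_id": ["t1"] * 3 + ["t2"] * 2 + ["t3"] * 2,
    "day":   [10, 17, 24,   12, 26,   15, 22],
    "stage": [4, 5, 6,       4, 6,     4, 5],
})
bb = derive_budburst_metrics(obs)
print("Budburst timing (days after the first tree per stage) and duration:")
print(bb.round(1))
# t2 skipped stage 5: its stage-5 date is the midpoint of days 12 and 26.
# t3 never reached stage 6, so its duration is missing.

heights = pd.DataFrame([[100.0, 150.0, 140.0, 200.0],
                        [90.0, 130.0, 170.0, 210.0]],
                       index=["t1", "t2"], columns=[2010, 2011, 2012, 2013])
cleaned, increments = clean_height_series(heights)
print("\nCleaned heights (t1's 2012 reversal removed):")
print(cleaned)
print("\nAnnual increments (only between adjacent surviving years):")
print(increments)
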