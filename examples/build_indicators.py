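"""Build the six migration indicators from a census-style count table.

A toy table with two wards and two census years; the age/tenure counts are
absent in the earlier year, so those indicator cells come out missing —
exactly how the model later skips them in the likelihood.
"""

import pandas as pd

import migtraj as m

counts = pd.DataFrame(
    [
        # 1991: only residents and in-mover counts were published
        {"area_id": "W1", "year": 1991, "usual_residents": 5000,
         "internal_inmovers": 400, "international_inmovers": 50},
        {"area_id": "W2", "year": 1991, "usual_residents": 8000,
         "internal_inmovers": 240, "international_inmovers": 20},
        # 2001: full detail
        {"area_id": "W1", "year": 2001, "usual_residents": 5200,
         "internal_inmovers": 520, "international_inmovers": 80,
         "inmovers_18_24": 420, "inmovers_65plus": 30,
         "inmover_households_total": 300, "inmover_households_owner": 90,
         "inmover_households_social": 60},
        {"area_id": "W2", "year": 2001, "usual_residents": 7900,
         "internal_inmovers": 250, "international_inmovers": 15,
         "inmovers_18_24": 40, "inmovers_65plus": 70,
         "inmover_households_total": 160, "inmover_households_owner": 120,
         "inmover_households_social": 10},
    ]
)

panel = m.build_panel(counts)
long = panel.to_long()
print(long.to_string(index=False))
print()
obs = long[long.missing_flag == 0]
print(f"observed cells: {len(obs)} of {len(long)} (age/tenure missing in 1991)")
# W1 in 2001 looks like a studentifying ward: 70% of its in-movers are 18-24.
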