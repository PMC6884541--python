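"""Bog growth in the saturated (fully anoxic) limit.

A single permanently waterlogged peat column receiving constant litter p
with anoxic decay rate alpha approaches the classic bog-growth asymptote
p/alpha; at any time t the accumulated mass is (p/alpha)(1 - exp(-alpha t)).
This is the model's most basic sanity check: the near-surface artefact in
real cores is the early, steep part of exactly this saturation curve.
"""

import math

import bogsim as bs

alpha = 0.01   # yr-1 anoxic decay
p = 400.0      # g m-2 yr-1 litter input
params = bs.ModelParams(anoxic_decay_rate=alpha)

col = bs.Column(0.0, 2.0, params)
print(" year    simulated (g m-2)   closed form (g m-2)")
for year in range(1, 501):
    bs.decompose_cohorts(col, 0.0, 7.1, 1.0, params)  # 0 = fully anoxic
    bs.add_annual_cohort(col, p, year)
    if year % 100 == 0:
        closed = (p / alpha) * (1.0 - math.exp(-alpha * year))
        print(f"{year:5d} {col.total_mass:18.1f} {closed:18.1f}")

final = col.total_mass
closed = (p / alpha) * (1.0 - math.exp(-0.01 * 500))
print(f"\nrelative difference at t = 5/alpha: "
      f"{abs(final - closed) / closed * 100:.2f}% "
      f"(asymptote p/alpha = {p / alpha:.0f} g m-2)")
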