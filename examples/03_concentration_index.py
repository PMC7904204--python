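"""Measure socioeconomic inequality in an outcome with the concentration index.

Individuals are ranked poorest to richest by their continuous wealth score;
the index C = 2 cov(y, R) / mu is negative when the outcome is concentrated
among the poor.  The concentration curve plots the cumulative outcome share
against the cumulative population share — above the diagonal means pro-poor
concentration of the burden.
"""

import numpy as np

from healthineq import SimulationConfig, concentration, generate_population

population = generate_population(SimulationConfig(n=20_594, seed=1))

for sex in ("boy", "girl"):
    sub = population[population["sex"] == sex]
    for outcome in ("thinness", "stunting", "both"):
        res = concentration(
            sub[outcome].to_numpy(dtype=float), sub["wealth_score"].to_numpy()
        )
        print(
            f"{sex:5s} {outcome:9s}  C = {res.index:+.3f}  ({res.orientation}; "
            f"mean {res.mean_outcome:.3f}, n {res.n_effective})"
        )

# Curve coordinates for plotting: the poorest 40% of boys carry well over
# 40% of the thinness burden when C < 0.
boys = population[population["sex"] == "boy"]
res = concentration(boys["thinness"].to_numpy(float), boys["wealth_score"].to_numpy())
pts = res.curve_points
share_at_40 = np.interp(0.4, pts["pop_share"], pts["outcome_share"])
print(f"\npoorest 40% of boys carry {100 * share_at_40:.1f}% of the thinness burden")
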