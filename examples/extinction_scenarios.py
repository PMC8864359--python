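"""Extinction risk under constant additional mortality (e.g. turbine strikes).

Runs 1000 Monte-Carlo population trajectories of 100 years per scenario,
drawing parameters from the published posterior approximation, and prints
the probability that the population reaches zero when 0/1/3/5 adults are
removed every year.
"""

import numpy as np

from harrierpva import pva
from harrierpva.published import POSTERIOR_SUMMARY

print("removals/yr   P(extinct <=25y)  P(<=50y)  P(<=75y)  P(<=100y)")
for removals in (0, 1, 3, 5):
    scenario = pva.ScenarioConfig(
        removals_per_year=removals, removed_stage="adult",
        horizon_years=100, n_trajectories=1000, seed=42,
    )
    ensemble = pva.run_scenario(POSTERIOR_SUMMARY, scenario)
    curve = pva.extinction_curve(ensemble)
    print(f"{removals:>10d}   " + "  ".join(f"{curve[y]:>8.3f}" for y in (25, 50, 75, 100)))

print("\nTrajectories share seeds across scenarios, so differences are purely")
print("the effect of the removals. Removing sub-adults instead of adults gives")
print("bit-for-bit identical results (the matrix columns are identical);")
print("removing fledglings is less harmful.")
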