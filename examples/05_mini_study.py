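"""A small end-to-end simulation study comparing all seven methods.

Two scenarios (MCAR and MAR at 50% missingness), 100 repetitions each.
Prints per-method bias and coverage: under MCAR everything except worst case
is nearly unbiased; under MAR only MICE stays close to the truth and keeps
its nominal coverage.
"""

import pandas as pd

import diagmiss as dm
import diagmiss.runner as rn

config = dm.StudyConfig(
    grid={
        "true_sens": [0.8],
        "true_spec": [0.8],
        "mechanism": ["MCAR", "MAR"],
        "miss_prop": [0.5],
        "prevalence": [0.2],
        "n": [800],
    },
    n_sim=100,
    seed=1,
)
frames = [
    rn.run_scenario(sc, i, config) for i, sc in enumerate(dm.build_grid(config))
]
summary = dm.summarize(pd.concat(frames, ignore_index=True))

for mech, grp in summary.groupby("mechanism"):
    print(f"\n=== {mech}, 50% missing, sens=spec=0.8, n=800 ===")
    table = grp.pivot(index="method", columns="estimand",
                      values=["bias", "coverage"]).round(3)
    print(table)

print(
    "\nWC trades bias for a guaranteed lower bound; CCA/RHD are biased under\n"
    "MAR; the allocation methods fix the point estimate but undercover; MICE\n"
    "is nearly unbiased with coverage close to the nominal 95%."
)
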