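#!/usr/bin/env python
"""Simulate the four clone cohorts (P1, P2, O1, O2), 3 mice each.

P1/P2/O1 carry the experimentally estimated (Fc, Td); O2 carries
representative oligometastatic values. Fixtures (colonies.csv, mice.csv,
params.json per clone) go under results/cohorts/ for the later steps.
"""

from pathlib import Path

from livermet import scenario_params, simulate_cohort, write_fixtures
from livermet.simulate import SCENARIOS

OUT = Path(__file__).resolve().parents[1] / "results" / "cohorts"
SEED = 20260919

for name in SCENARIOS:
    params = scenario_params(name, seed=SEED)
    cohort = simulate_cohort(params, n_mice=3)
    write_fixtures(cohort, OUT / name)
    counts = [b.n_tumors for b in cohort.burdens]
    print(
        f"{name}: Fc={params.fc:.2g} Td={params.td_mean:.1f} h "
        f"harvest={params.harvest_time:.0f} h -> colony counts {counts}"
    )

print(f"\nFixtures written under {OUT}/<clone>/")
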