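"""Tally why candidate qualifying fills fail cohort eligibility.

Generates a synthetic population with a high ineligible fraction, builds
the new-user cohort, and prints how many candidate fills each criterion
rejected. Each deliberately ineligible person violates exactly one
criterion by construction (a washout violator's earlier fill can also
fail enrollment/utilization checks, so those tallies can exceed the
violator count).
"""

from dkaval.cohort_builder import build_cohort
from dkaval.synthetic_data import SimulationConfig, generate_population

config = SimulationConfig(n_persons=600, seed=3, ineligible_fraction=0.3)
db, truth = generate_population(config)
members, tally = build_cohort(db, return_exclusions=True)

print(f"persons generated:        {len(db.persons)}")
print(f"designated ineligible:    {len(truth.ineligible)}")
print(f"cohort members:           {len(members)}")
print("rejected qualifying fills by criterion:")
for criterion, count in sorted(tally.items()):
    print(f"  {criterion:24s} {count}")
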