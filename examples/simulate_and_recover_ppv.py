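"""Generate synthetic claims with a known PPV and recover it end-to-end.

The generator plants a DKA-coded hospitalization for a fraction of
eligible new users and decides, with probability ``true_ppv``, whether
each flagged admission is genuinely DKA; false positives present with
severe hyperglycemia but no acidosis. The pipeline never sees the truth
labels — it re-derives the cohort, re-flags the cases, and adjudicates
the generated chart abstractions — so the printed estimate is a genuine
recovery of the planted 0.85, and its Wilson interval should cover 0.85.
"""

from dkaval.pipeline import run_validation
from dkaval.synthetic_data import (
    SimulationConfig,
    generate_abstractions,
    generate_population,
)

config = SimulationConfig(n_persons=2000, seed=11, true_ppv=0.85)
db, truth = generate_population(config)
records = generate_abstractions(truth, config)

result = run_validation(db, records, with_strata=False)
o = result.overall
print(f"flagged cases found by the pipeline: {result.n_potential}")
print(f"adjudicable (abstraction complete):  {o.n}")
print(f"confirmed:                           {o.x}")
print(f"estimated PPV: {o.ppv:.3f}  (planted true_ppv = 0.85)")
print(f"Wilson 95% CI: {o.ci_lo:.3f} to {o.ci_hi:.3f}")
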