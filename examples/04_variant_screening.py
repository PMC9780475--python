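"""Screen somatic variant records and assign TP53 mutation groups.

Thresholds (all strict): total depth > 30, variant allele fraction > 1%,
Q = -10*log10(P) > 10.  A sample with at least one passing TP53 record is
called mutant.
"""

import pandas as pd

from tp53tme import SimulationConfig, assign_mutation_group, screen_table
from tp53tme.simulate import simulate_expression, simulate_variants

cfg = SimulationConfig(n_samples=80, seed=13)
_, states = simulate_expression(cfg)
variants = simulate_variants(states, cfg)

screened = screen_table(variants)
print(screened[~screened["passed"]][["sample_id", "gene", "total_depth", "vaf",
                                     "quality_q", "fail_reason"]].head())

samples = [f"S{j:04d}" for j in range(cfg.n_samples)]
status = assign_mutation_group(screened, samples)
table = pd.crosstab(status.to_numpy(), states, rownames=["mutation"], colnames=["tp53_active"])
print("\n", table)
# Inactive samples (column 0) carry TP53 mutations more often — the synthetic
# analogue of the positive association between a low score and TP53 mutation.
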