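"""Kaplan-Meier / log-rank comparison of the high and low score groups.

Simulates survival whose hazard is 3x larger for TP53-inactive samples,
scores and stratifies the cohort, and tests whether the low-score group
does worse — the synthetic analogue of the prognostic claim.
"""

from tp53tme import SimulationConfig, classify_groups, compare_groups, load_signature, tp53_score
from tp53tme.simulate import simulate_expression, simulate_survival

cfg = SimulationConfig(n_samples=200, effect_delta=2.0, hazard_ratio=3.0, seed=7)
expr, states = simulate_expression(cfg)
clinical = simulate_survival(states, cfg)

scores = classify_groups(tp53_score(expr, load_signature()))
res = compare_groups(clinical, scores)

for label, curve in res["curves"].items():
    last = curve.iloc[-1]
    print(f"{label:>4} group: {len(curve)} event times, "
          f"S({last['time']:.1f}) = {last['survival']:.3f}")
print(f"log-rank chi-square = {res['statistic']:.2f}, p = {res['p_value']:.2e}")
# p < 0.05 with lower survival in the low group reproduces the expected
# direction: low TP53 activity marks the poor-prognosis stratum.
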