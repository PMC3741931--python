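"""Check that mining recovers a planted association at realistic effect size.

Draws 271-patient strata in which the four-item combination (moderate
differentiation, early stage, tongue site, surgery) is planted at 1.9 times
its independence frequency — the effect size of the reference benchmark —
mines each draw and asks whether the planted association occupies the two
top lift-ranked rules.  Fifty seeds keep this demo quick; the acceptance
suite runs 200.
"""

import clinrules as cr

result = cr.recovery_experiment(n=271, boost=1.9, n_seeds=50, seed=7)
print(f"seeds: {result.n_seeds}, recoveries: {result.successes}")
print(f"recovery rate: {result.rate:.2f}")
print(f"mean empirical lift of the planted split rules: {result.planted_lift:.2f}")

null = cr.recovery_experiment(n=271, boost=1.0, n_seeds=50, seed=7)
print(f"\nwith no planted signal (boost 1.0) the rate drops to {null.rate:.2f} "
      "(chance level: any rule pair may top the ranking)")
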