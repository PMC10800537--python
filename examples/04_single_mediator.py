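"""Single-mediator mediation with closed-form effects and delta-method CIs.

Decomposes the Black-White gap in gestational age into the natural direct
effect and the part mediated by the index, and evaluates controlled direct
effects with the mediator fixed at its quartiles (scenario S1b adds an
exposure-mediator interaction, so the CDE varies with the level).
"""

from mixmediate import builtin_scenarios, generate_cohort, mediate

cohort = generate_cohort(builtin_scenarios()["S1b"], n=50_000, seed=5)
fit = mediate(cohort, "m", "ga_weeks", ["cov_confounder"], interaction=True)
eff = fit.effects["black"]

print("Black vs White, gestational age (weeks):")
print(f"  TE  = {eff.te}")
print(f"  NDE = {eff.nde}")
print(f"  NIE = {eff.nie}")
for label, cde in eff.cdes.items():
    print(f"  CDE({label}) = {cde}")
print(
    "\nWith the interaction, fixing everyone's mediator at a lower percentile "
    "moves the controlled direct effect toward the null (planted: -0.18 at p25, "
    "-0.23 at the median)."
)
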