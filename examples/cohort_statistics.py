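"""Group comparison on a simulated two-group cohort.

Simulates a cohort with the published group sizes (20 controls, 18
diabetic-neuropathy patients) from the printed per-group summaries of
the morphometric parameters, then runs the normality-driven test
dispatcher on every variable.  Most variables separate the groups
decisively, mirroring the published contrasts.
"""

from sbpquant import compare_groups, simulate_cohort
from sbpquant import reference as ref

table = simulate_cohort(
    ref.GROUP_SUMMARIES,
    {"control": ref.N_HEALTHY, "diabetic": ref.N_DIABETIC},
    seed=7,
)
print(f"simulated cohort: {len(table)} subjects, "
      f"{table.columns.size - 1} variables\n")

print(f"{'variable':32s} {'test':13s} {'stat':>8s} {'p':>10s}")
for r in compare_groups(table):
    print(f"{r.variable:32s} {r.test_used:13s} {r.statistic:8.2f} {r.p_value:10.2e}")

print("\nA p-value below 0.05 marks a parameter that distinguishes the"
      "\nrarefied neuropathic plexus from the healthy one in this draw.")
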