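"""Simulate and analyse a nine-concentration UV melting experiment.

Generates synthetic absorbance-vs-temperature curves for a duplex with
known ΔH°/ΔS° (nine strand concentrations, 10⁻⁶–10⁻³ M, Gaussian noise),
then recovers the thermodynamics by both standard routes — averaging
individual two-state curve fits and the Tm⁻¹ vs ln(CT/4) van't Hoff plot —
and applies the 15% two-state consistency criterion.
"""

from psimelt import SyntheticSpec, TwoStateParams, analyze_dataset, generate_dataset

true = TwoStateParams(dh=-77.6, ds=-217.1)  # the unmodified core duplex
spec = SyntheticSpec(params=true, noise_sd=0.002, seed=1)
result = analyze_dataset(generate_dataset(spec))

print(f"true parameters:     ΔH° = {true.dh:.1f} kcal/mol, ΔS° = {true.ds:.1f} eu")
for fit in (result.curve_average, result.tm_plot):
    print(
        f"{fit.method:14s}  ΔH° = {fit.dh.value:7.1f} ± {fit.dh.sd:4.1f}   "
        f"ΔS° = {fit.ds.value:7.1f} ± {fit.ds.sd:4.1f}   "
        f"ΔG°37 = {fit.dg37.value:6.2f} ± {fit.dg37.sd:4.2f}   "
        f"Tm(1e-4 M) = {fit.tm_1e4_c:5.2f} °C"
    )
print(
    f"relative ΔH° difference between routes: {100 * result.rel_dh_difference:.1f}% "
    f"-> {'two-state' if result.two_state else 'NOT two-state'} (bound: 15%)"
)
print("\nThe small ΔG°37 uncertainty relative to ΔH°/ΔS° reflects their")
print("near-perfect compensation along the van't Hoff line.")
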