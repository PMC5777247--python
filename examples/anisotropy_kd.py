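"""Equilibrium dissociation constants from fluorescence anisotropy.

Simulates titrations of a protein against three labeled DNA probes, fits
the law-of-mass-action isotherm P = (P_bound - P_free)[protein]/(Kd +
[protein]) + P_free to each, and ranks the substrates by affinity.
"""

from tightrope import compare_affinities, fit_binding, simulate_titration

conc = [0, 5, 10, 25, 50, 100, 200, 400, 700, 1000]  # nM
substrates = {"overhang": 56.4, "flap": 103.8, "dsDNA_66bp": 175.3}

fits = []
for i, (name, kd) in enumerate(substrates.items()):
    titration = simulate_titration(Kd_nM=kd, P_free_mP=100.0, P_bound_mP=300.0,
                                   concentrations_nM=conc, noise_sd_mP=4.0,
                                   seed=100 + i, substrate_id=name)
    fit = fit_binding(titration)
    fits.append(fit)
    print(f"{name:>11}: Kd = {fit.Kd_nM:6.1f} +/- {fit.se_Kd_nM:4.1f} nM "
          f"(true {kd})")

table, ratios = compare_affinities(fits)
print("\naffinity ranking (strongest first):",
      ", ".join(table["substrate_id"]))
best = ratios.iloc[0]
print(f"Kd ratio {best['substrate_a']}/{best['substrate_b']} = "
      f"{best['Kd_ratio']:.2f} +/- {best['se_ratio']:.2f}")
print()
print("A lower Kd means tighter binding: the ssDNA-containing overhang is")
print("bound ~3x more tightly than blunt duplex DNA of the same length.")
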