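"""Binding specificity for a ssDNA gap from an AFM position distribution.

Deposits complexes on a 2030-bp linear substrate carrying a gap at 470 bp
(23% from one end), histograms positions folded to the closest end (0-50%),
and estimates the specificity S = K_SP/K_NSP from fractional occupancies.
Also converts AFM volumes to protein copy numbers via V = 1.45*M_r - 21.59.
"""

from tightrope import (SubstrateGeometry, build_position_histogram,
                       estimate_copy_number, estimate_specificity,
                       simulate_afm_positions, specific_regions_from_geometry,
                       substrate_fraction)

geometry = SubstrateGeometry(length_bp=2030, specific_sites=(("gap", 470),),
                             rise_nm_per_bp=0.32)
gap = substrate_fraction(470, 2030)
print(f"gap position: {gap.pct:.1f}% of the substrate "
      f"({gap.folded_pct:.1f}% from the closest end)")
print(f"substrate contour length: {geometry.contour_length_nm:.0f} nm")

records = simulate_afm_positions(geometry, S=2000.0, n_complexes=5000, seed=6)
regions = specific_regions_from_geometry(geometry, site_halfwidth_bp=5)
hist = build_position_histogram(records, bin_width_pct=0.5,
                                specific_regions=regions)
result = estimate_specificity(hist, N_sites=geometry.length_bp, seed=0)
print(f"estimated specificity S = {result.S:.0f} +/- {result.se_S:.0f} "
      f"(generator used S = 2000)")
print(f"occupancies: {result.A_SP} complexes in the gap region, "
      f"{result.A_NSP} elsewhere over {result.N_sites} sites")

cn = estimate_copy_number(volume_nm3=1025.0, monomer_kDa=141.0)
print(f"a 1025-nm^3 complex of a 141-kDa protein holds {cn.copies} copies "
      f"(ratio {cn.ratio:.2f})")
print()
print("S in the thousands means a complex is thousands of times more likely")
print("to occupy the gap than any single nonspecific base-pair site.")
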