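"""Mass-density-normalized HU on the commercial calibration phantom.

HU depends on how densely a material is packed; dividing it out,
HU_rho = (HU+1000)/rho - 1000, leaves an intrinsic property of the
material's chemistry and the beam. Here we recompute HU_rho for every
phantom insert from its measured HU and manufacturer density.
"""

from humol import fixtures, hu_rho_from_hu, round_half_away

table1 = fixtures.load_fixture("table1")
print(f"{'material':<20} {'HU(kV)':>7} {'rho':>6} {'HU_rho(kV)':>11}")
for _, row in table1.iterrows():
    hu_rho = hu_rho_from_hu(row["hu_kv"], row["rho"])
    print(f"{row['name']:<20} {row['hu_kv']:>7.0f} {row['rho']:>6.3f} "
          f"{hu_rho:>8.1f} ({round_half_away(hu_rho):d})")

# Note how Muscle (HU=49) and Solid Water (HU=2) collapse to nearly the
# same HU_rho (~-17 vs ~-14): their very different HU is almost entirely a
# density effect, not a chemistry effect.
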