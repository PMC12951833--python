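"""Design a diagonal-sampling crystallization plate.

Four corner conditions (protein mg/ml, precipitant mM) are interpolated
bilinearly over an 8x12 grid; each well gets four channel volumes that the
dispensing robot can execute.  The printed totals are what the plate costs
in protein and reagents.
"""

from phaseplan import CornerSpec, GridDesign, Mixture, StockSet, plan_plate

stocks = StockSet(
    protein_stock=Mixture.of(xylanase=(36, "mg_per_ml")),
    protein_name="xylanase",
    cocktail_stock=Mixture.of(sodium_formate=(8000, "mM")),
    primary_precipitant="sodium_formate",
)

grid = GridDesign(
    rows=8, cols=12, drop_volume=2.0,
    # corners chosen so gradients run roughly parallel to the expected
    # solubility boundary: high-protein/low-salt down to low-protein/high-salt
    corners=CornerSpec((16, 2600), (16, 4400), (6, 3800), (6, 5600)),
)

plate = plan_plate(grid, stocks)

print(f"wells: {len(plate.wells)} "
      f"({sum(1 for w in plate.wells if w.feasible)} feasible)")
for w in plate.wells[:3]:
    print(f"  {w.well_label}: {w.protein_mg_ml:.2f} mg/ml, "
          f"{w.precipitant_conc:.0f} mM -> protein {w.v_protein:.2f} ul, "
          f"cocktail {w.v_cocktail:.2f} ul, water {w.v_diluent:.2f} ul")
t = plate.totals
print(f"consumption: protein {t.v_protein:.1f} ul = {t.protein_mass_mg:.2f} mg, "
      f"cocktail {t.v_cocktail:.1f} ul, water {t.v_diluent:.1f} ul")
# The protein total is the full cost of mapping this phase diagram —
# tens of microlitres, not the millilitres a classical grid screen needs.
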