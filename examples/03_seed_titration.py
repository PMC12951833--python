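"""Cross-matrix seed-stock titration.

Rows carry a decade serial dilution of the seed stock (neat down to 1e-7);
columns carry crystallization conditions.  Reading the plate row by row
shows which seed concentration gives dense microcrystal showers and which
gives a few large single crystals, per condition.
"""

from phaseplan import Mixture, StockSet, cross_matrix, serial_dilution

stocks = StockSet(
    protein_stock=Mixture.of(xylanase=(36, "mg_per_ml")),
    protein_name="xylanase",
    cocktail_stock=Mixture.of(sodium_formate=(8000, "mM")),
    primary_precipitant="sodium_formate",
)

factors = serial_dilution(levels=8, step=10)
print("dilution series:", ", ".join(f"{f:g}" for f in factors))

# twelve conditions along the hit region around 20.1 mg/ml, 3.54 M formate
conditions = [(20.1 - 0.8 * i, 3540.0 + 60 * i) for i in range(12)]
plate = cross_matrix(factors, conditions, stocks, drop_volume=2.0, seed_fraction=0.1)

print(f"{len(plate.wells)} wells; seed channel fixed at "
      f"{plate.wells[0].v_seed:.2f} ul/well")
first_col = [w for w in plate.wells if w.col == 0]
for w in first_col[:4]:
    print(f"  row {w.row}: seed at {w.seed_dilution:g} of neat")
# Adjacent rows differ by exactly one 10x step, so crystal counts can be
# read against seed concentration directly.
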