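"""Scale a chosen well condition to a seeded batch, then retune the seed load.

A 1:1:1 protein:precipitant:seed recipe at 500 ul puts 167 ul in each part;
doubling the seed weight to 1:1:2 moves the seed part to 250 ul without
changing the total.  More seed means more growth templates, a depleted
protein pool per crystal, and hence smaller, more numerous crystals.
"""

from phaseplan import Mixture, make_recipe, retune_seed

parts = [
    ("protein", 1, Mixture.of(AtPdx1_3=(12, "mg_per_ml"))),
    ("cocktail", 1, Mixture.of(sodium_citrate=600, HEPES=100.2, pH=7.0)),
    ("seed", 1, Mixture.of(seed=(0.01, "fraction"))),  # 1:100 diluted stock
]

recipe = make_recipe(parts, total_volume=500)
print("1:1:1 batch:")
print(recipe.report())

retuned = retune_seed(recipe, new_seed_weight=2)
print("\nretuned to 1:1:2:")
print(retuned.report())
# The final composition changes only through the seed part's share; the
# protein and precipitant concentrations scale down accordingly.
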