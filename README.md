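# phaseplan

Toolkit for mapping protein crystallization phase diagrams with automated
microbatch-under-oil experiments, and for turning those diagrams into
microcrystal production recipes for serial crystallography (SX).

## The problem

SX beamlines consume dense, uniform suspensions of microcrystals, but most
crystallization optimization is still trial and error. The phase diagram —
protein concentration *P* versus precipitant concentration *c*, partitioned
into **undersaturated**, **metastable**, **nucleation (labile)** and
**precipitation** zones — is the rational map: crystals nucleate
spontaneously only in the labile zone, while the metastable zone (where
growth is favorable but nucleation is kinetically hindered) is reachable
only by adding seed stock. Microbatch-under-oil drops do not evaporate, so
the composition at nucleation is exactly the composition dispensed, which
makes zone boundaries measurable well by well.

`phaseplan` covers the desk side of that workflow:

- **design** — interpolate four user-chosen corner conditions bilinearly
  over a well grid (diagonal sampling: gradients roughly parallel to the
  expected solubility boundary) and compute per-well four-channel volumes
  (protein / cocktail / seed / diluent) for a dispensing robot, with
  feasibility flags, robot-precision rounding and reagent-consumption totals;
- **phase_analysis** — classify paired seeded/unseeded outcomes
  (clear / crystals / shower / precipitate) into zones and estimate phase
  boundaries as minimum-misclassification monotone staircases;
- **titration** — seed-stock serial dilutions and cross-matrix titration
  plates (dilution rows × condition columns);
- **scaleup** — batch recipes at arbitrary volume and component ratio, with
  seed-ratio retuning;
- **simulate** — a parametric solubility model that generates outcomes, so
  the whole loop is testable without a laboratory;
- **config / cli** — JSON experiment configs, CSV plate maps, and a
  `phaseplan` command-line surface over all of it.

## The model behind the simulator

Solubility follows a log-quadratic (Cohn-style) law

```
ln S(c) = ln S0 + beta·c − K·c²
```

with salting-out coefficient `K > 0` and an optional salting-in term
`beta ≥ 0` that makes `S(c)` rise before it falls — the mechanism that
produces *two* disjoint metastable lobes on one diagram. Outcomes are driven
by the supersaturation ratio `σ = P / S(c)` against thresholds
`1 < σ_nuc ≤ σ_shower ≤ σ_prec`: below 1 drops stay clear (seeds dissolve);
between 1 and `σ_nuc` only seeded drops crystallize (metastable); above
`σ_nuc` crystals appear spontaneously, becoming dense showers and finally
amorphous precipitate.

## Worked example

`examples/04_scaleup_batch.py` scales a phase-diagram hit to a seeded batch:

```
1:1:1 batch:
batch 500 ul, ratio 1:1:1
  protein: 167 ul
  cocktail: 167 ul
  seed: 167 ul
  final AtPdx1_3: 4 mg_per_ml
  final HEPES: 33.4 mM
  final sodium_citrate: 200 mM

retuned to 1:1:2:
  protein: 125 ul
  cocktail: 125 ul
  seed: 250 ul
```

A 500 µl batch at a 1:1:1 protein:precipitant:seed ratio puts 167 µl in each
part; retuning to 1:1:2 moves the seed part to 250 µl at the same total.
Doubling the seed load doubles the growth templates, so the protein pool is
shared among more crystals — the standard lever to push a batch from few
large crystals toward a dense population of small ones.

The other examples design a 96-well diagonal plate
(`01_design_plate.py` — 58.6 µl ≈ 2.1 mg of protein maps a full diagram),
simulate and classify paired plates (`02_simulate_and_classify.py` — prints
zone fractions and the solubility staircase), and build an 8-decade
cross-matrix seed titration (`03_seed_titration.py`).

The same capabilities are available from the shell:

```
phaseplan fixture classic --config-out cfg.json --model-out model.json
phaseplan design   --config cfg.json --out plate.csv --worklist wl.csv
phaseplan simulate --plate plate.csv --model model.json --out obs.csv
phaseplan classify --plate plate.csv --obs obs.csv --out zones.csv --frontier frontier.json
phaseplan titrate  --config cfg.json --levels 8 --step 10 --out titration.csv
phaseplan scaleup  --recipe recipe.json --total 500 --seed-weight 2 --out batch.json
```

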