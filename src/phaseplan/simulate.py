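"""Synthetic phase-diagram ground truth.

The simulator generates plate outcomes from a parametric solubility model so
the whole design → observe → classify → frontier-estimate loop can be
exercised and validated without laboratory data.

Solubility follows a log-quadratic (Cohn-style) law

    ln S(c) = ln S0 + beta * c - K * c**2

where c is the precipitant concentration.  K > 0 is the salting-out
coefficient; beta >= 0 adds an optional salting-in term that makes S(c) rise
before it falls (peak at c* = beta / 2K), which is the mechanism proposed for
landscapes with two disjoint metastable lobes.  Outcomes are driven by the
supersaturation ratio sigma = P / S(c) against fixed thresholds:

    sigma < 1                 undersaturated     -> clear (seeds dissolve)
    1 <= sigma < sigma_nuc    metastable         -> clear unseeded, crystals seeded
    sigma_nuc <= sigma        labile             -> spontaneous crystals,
    ... < sigma_shower                              dense showers above
    sigma >= sigma_prec       precipitation      -> amorphous precipitate

``p_nuc`` > 0 adds the only stochastic element: a linear ramp of spontaneous
nucleation probability across the metastable band.  With p_nuc = 0 the model
is fully deterministic and classification must recover it exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .phase_analysis import Outcome, ObservationPair, Zone


@dataclass
class PhaseModel:
    S0: float                     # solubility at zero precipitant, mg/ml
    K: float                      # salting-out coefficient, per conc^2
    beta: float = 0.0             # salting-in coefficient, per conc
    sigma_nuc: float = 2.0        # metastable ceiling
    sigma_shower: float = 4.0     # crystals -> dense shower
    sigma_prec: float = 6.0       # precipitation floor
    p_nuc: float = 0.0            # spontaneous-nucleation ramp amplitude
    rng_seed: int = 0

    def __post_init__(self):
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")
        if self.K <= 0:
            raise ValueError("K (salting-out) must be positive")
        if self.beta < 0:
            raise ValueError("beta (salting-in) must be >= 0")
        if not (1 < self.sigma_nuc <= self.sigma_shower <= self.sigma_prec):
            raise ValueError("need 1 < sigma_nuc <= sigma_shower <= sigma_prec")
        if not (0 <= self.p_nuc <= 1):
            raise ValueError("p_nuc must be in [0, 1]")

    @classmethod
    def from_json(cls, path) -> "PhaseModel":
        with open(path) as fh:
            raw = json.load(fh)
        raw.setdefault("rng_seed", raw.pop("seed", 0))
        return cls(**raw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "S0": self.S0, "beta": self.beta, "K": self.K,
                "sigma_nuc": self.sigma_nuc, "sigma_shower": self.sigma_shower,
                "sigma_prec": self.sigma_prec, "p_nuc": self.p_nuc,
                "seed": self.rng_seed,
            }, fh, indent=2)
            fh.write("\n")


def solubility(model: PhaseModel, c: float) -> float:
    """S(c) = exp(ln S0 + beta*c - K*c^2); strictly decreasing when beta = 0."""
    return model.S0 * math.exp(model.beta * c - model.K * c * c)


def supersaturation(model: PhaseModel, protein: float, c: float) -> float:
    """sigma = P / S(c)."""
    return protein / solubility(model, c)


def analytic_zone(model: PhaseModel, protein: float, c: float) -> Zone:
    """Closed-form zone membership from the sigma thresholds (p_nuc ignored)."""
    sigma = supersaturation(model, protein, c)
    if sigma < 1:
        return Zone.UNDERSATURATED
    if sigma < model.sigma_nuc:
        return Zone.METASTABLE
    if sigma < model.sigma_prec:
        return Zone.NUCLEATION
    return Zone.PRECIPITATION


def _ramp(model: PhaseModel, sigma: float) -> float:
    """Spontaneous-nucleation probability inside the metastable band."""
    if model.p_nuc <= 0 or model.sigma_nuc <= 1:
        return 0.0
    frac = (sigma - 1.0) / (model.sigma_nuc - 1.0)
    return model.p_nuc * min(max(frac, 0.0), 1.0)


def simulate_outcome(model: PhaseModel, target: tuple[float, float],
                     seeded: bool, rng: np.random.Generator) -> Outcome:
    """Outcome of one drop.  Exactly one uniform draw is consumed per call so
    the observation stream is reproducible regardless of where thresholds fall.
    """
    protein, c = target
    sigma = supersaturation(model, protein, c)
    u = rng.uniform()
    if sigma < 1:
        return Outcome.CLEAR
    if sigma >= model.sigma_prec:
        return Outcome.PRECIPITATE
    if sigma >= model.sigma_shower:
        return Outcome.SHOWER
    if seeded:
        return Outcome.CRYSTALS
    if sigma >= model.sigma_nuc:
        return Outcome.CRYSTALS
    # metastable band, unseeded: spontaneous nucleation only via the ramp
    return Outcome.CRYSTALS if u < _ramp(model, sigma) else Outcome.CLEAR


def simulate_plate(model: PhaseModel, plate,
                   arms: Sequence[str] = ("unseeded", "seeded"),
                   ) -> list[ObservationPair]:
    """Simulated observations for every feasible well of a plate.

    ``plate`` is a PlateDesign or any object with a ``wells`` list (or a bare
    list of wells).  Deterministic given ``model.rng_seed``: wells are visited
    in stored (row-major) order, unseeded arm drawn before seeded.
    """
    wells = plate.wells if hasattr(plate, "wells") else plate
    rng = np.random.default_rng(model.rng_seed)
    pairs = []
    for w in wells:
        if not w.feasible:
            continue
        target = (w.protein_mg_ml, w.precipitant_conc)
        pair = ObservationPair(w.well_label, target=target)
        if "unseeded" in arms:
            pair.unseeded = simulate_outcome(model, target, seeded=False, rng=rng)
        if "seeded" in arms:
            pair.seeded = simulate_outcome(model, target, seeded=True, rng=rng)
        pairs.append(pair)
    return pairs
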