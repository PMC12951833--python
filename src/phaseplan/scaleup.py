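"""Batch scale-up recipes.

Once a well condition is chosen from the phase diagram, production for serial
crystallography runs in batch: the same final composition at hundreds of
microlitres, mixed from stocks at a stated volume ratio (e.g. a 1:1:1
protein:precipitant:seed batch, retuned to 1:1:2 to double the seed load and
outrun macrocrystal growth).  Everything here is ratio arithmetic plus the
mixture algebra — no kinetic model links seed load to final crystal size;
that relationship is read off the bench and fed back as a new ratio.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .chem_core import Mixture, VolumetricPart, mix

log = logging.getLogger(__name__)


def scale_by_ratio(weights: list[float], total_volume: float) -> list[float]:
    """v_i = total * w_i / sum(w); exact floats, no rounding.

    (1,1,2) at 500 ul gives (125, 125, 250); (1,1,1) gives thirds that report
    as 167 ul each under the integer convention of :func:`format_volume`.
    """
    if not weights:
        raise ValueError("weights must be non-empty")
    if any(w <= 0 for w in weights):
        raise ValueError(f"weights must be positive, got {weights}")
    if total_volume < 0:
        raise ValueError("total volume must be >= 0")
    s = sum(weights)
    vols = [total_volume * w / s for w in weights]
    # force exact conservation: the largest part absorbs the float residue
    if vols:
        i = max(range(len(vols)), key=vols.__getitem__)
        vols[i] = total_volume - (sum(vols) - vols[i])
    return vols


def format_volume(v: float) -> str:
    """Reporting convention: >= 100 ul to the nearest integer, else 0.1 ul."""
    return f"{v:.0f}" if v >= 100 else f"{v:.1f}"


@dataclass
class BatchPart:
    name: str            # protein | cocktail/precipitant | seed | diluent | free-form
    weight: float
    mixture: Mixture
    volume: float = 0.0


@dataclass
class BatchRecipe:
    total_volume: float
    parts: list[BatchPart]
    final_composition: Mixture
    protein_mass_mg: float

    def part(self, name: str) -> BatchPart | None:
        for p in self.parts:
            if p.name == name:
                return p
        return None

    def report(self) -> str:
        lines = [f"batch {format_volume(self.total_volume)} ul, "
                 f"ratio {':'.join(f'{p.weight:g}' for p in self.parts)}"]
        for p in self.parts:
            lines.append(f"  {p.name}: {format_volume(p.volume)} ul")
        for comp in self.final_composition.components.values():
            lines.append(f"  final {comp.name}: {comp.concentration:g} {comp.unit.value}")
        if self.protein_mass_mg:
            lines.append(f"  protein: {self.protein_mass_mg:g} mg")
        return "\n".join(lines)


def make_recipe(parts: list[tuple[str, float, Mixture]], total_volume: float,
                protein_name: str | None = None) -> BatchRecipe:
    """Build a batch recipe from (name, ratio weight, source mixture) parts.

    Final composition comes from volume-weighted mixing, so it depends only on
    the weights, never on the total volume.  Protein mass is read from the
    part named "protein" (its first mg/ml component, or ``protein_name``).
    """
    vols = scale_by_ratio([w for _, w, _ in parts], total_volume)
    batch_parts = [BatchPart(name, w, mixture, v)
                   for (name, w, mixture), v in zip(parts, vols)]
    if total_volume > 0:
        final = mix([VolumetricPart(p.mixture, p.volume) for p in batch_parts])
    else:
        final = Mixture()

    protein_mass = 0.0
    prot = next((p for p in batch_parts if p.name == "protein"), None)
    if prot is not None:
        if protein_name is None:
            from .chem_core import Unit
            protein_name = next((c.name for c in prot.mixture.components.values()
                                 if c.unit == Unit.MG_PER_ML), None)
        if protein_name is not None:
            protein_mass = prot.volume * prot.mixture.concentration_of(protein_name) / 1000.0

    return BatchRecipe(total_volume=total_volume, parts=batch_parts,
                       final_composition=final, protein_mass_mg=protein_mass)


def retune_seed(recipe: BatchRecipe, new_seed_weight: float) -> BatchRecipe:
    """Same recipe, same total, new seed ratio weight; all volumes recomputed.

    Logs the old -> new seed volume so the provenance of a size change is on
    record (e.g. 1:1:1 -> 1:1:2 moves the seed part from 167 to 250 ul of a
    500 ul batch).
    """
    if new_seed_weight <= 0:
        raise ValueError("seed weight must be positive")
    old = recipe.part("seed")
    if old is None:
        raise ValueError("recipe has no seed part to retune")
    new = make_recipe(
        [(p.name, new_seed_weight if p.name == "seed" else p.weight, p.mixture)
         for p in recipe.parts],
        recipe.total_volume,
    )
    log.info("seed retuned: %s -> %s ul (weight %g -> %g)",
             format_volume(old.volume), format_volume(new.part("seed").volume),
             old.weight, new_seed_weight)
    return new


# ---------------------------------------------------------------------------
# JSON I/O (CLI surface)
# ---------------------------------------------------------------------------

def recipe_from_json(path) -> tuple[list[tuple[str, float, Mixture]], float | None]:
    """Read parts (and optional total) from a recipe JSON:

    {"total_volume_ul": 500,
     "parts": [{"name": "protein", "weight": 1,
                "mixture": {"components": {"AtPdx1_3": {"conc": 12, "unit": "mg_per_ml"}}}}, ...]}
    """
    from .config import mixture_from_dict
    with open(path) as fh:
        raw = json.load(fh)
    parts = [(p["name"], float(p["weight"]), mixture_from_dict(p.get("mixture", {})))
             for p in raw["parts"]]
    return parts, raw.get("total_volume_ul")


def recipe_to_json(recipe: BatchRecipe, path) -> None:
    from .config import mixture_to_dict
    payload = {
        "total_volume_ul": recipe.total_volume,
        "parts": [{"name": p.name, "weight": p.weight, "volume_ul": p.volume,
                   "mixture": mixture_to_dict(p.mixture)} for p in recipe.parts],
        "final_composition": mixture_to_dict(recipe.final_composition),
        "protein_mass_mg": recipe.protein_mass_mg,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
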