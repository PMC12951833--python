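"""Units-aware mixture algebra.

Concentrations, dilution and volume-weighted mixing are the currency of every
plate-design and scale-up calculation in this package.  The model is
deliberately linear: volumes are additive (ideal mixing, no excess-volume
correction) and each component's concentration in a blend is the
volume-weighted mean of its concentrations in the parts.  Units are declared
per component and are never converted implicitly; ``normalize_molar`` is the
single explicit place where M becomes mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence


class Unit(str, Enum):
    """Concentration units recognised in configs and plate maps."""

    MG_PER_ML = "mg_per_ml"
    M = "M"
    MM = "mM"
    PERCENT_W_V = "percent_w_v"
    FRACTION = "fraction"


class MixingError(ValueError):
    """Invalid input to a mixing operation (empty parts, zero volume...)."""


class UnitClashError(MixingError):
    """The same component name appears with two different units."""


class InfeasibleTargetError(ValueError):
    """A target concentration exceeds what the stock can deliver."""

    def __init__(self, component: str, target: float, stock: float):
        self.component = component
        self.target = target
        self.stock = stock
        super().__init__(
            f"target {target:g} for {component!r} exceeds stock concentration {stock:g}"
        )


@dataclass(frozen=True)
class Component:
    """One chemical species at a concentration.

    Protein concentrations are carried in mg/ml; salts and buffers in mM or M;
    polymers such as PEG in %(w/v).  ``fraction`` is a unitless share of neat,
    used for seed stocks whose particle density is never quantified.
    """

    name: str
    concentration: float
    unit: Unit = Unit.MM

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError(f"negative concentration for {self.name!r}")
        object.__setattr__(self, "unit", Unit(self.unit))

    def scaled(self, factor: float) -> "Component":
        return Component(self.name, self.concentration * factor, self.unit)


@dataclass
class Mixture:
    """A named set of components plus optional pH.

    pH is metadata: it is never interpolated between parts.  When mixing, the
    pH is kept only if every part that declares one agrees (buffered parts set
    the drop pH; unbuffered diluent is silent).
    """

    components: dict[str, Component] = field(default_factory=dict)
    pH: float | None = None

    def __post_init__(self):
        for name, comp in self.components.items():
            if comp.name != name:
                raise ValueError(f"component keyed {name!r} is named {comp.name!r}")

    @classmethod
    def of(cls, pH: float | None = None, **conc: tuple[float, Unit | str] | float) -> "Mixture":
        """Convenience literal: ``Mixture.of(sodium_citrate=(1000, "mM"))``.

        A bare number defaults to mM.
        """
        comps = {}
        for name, val in conc.items():
            if isinstance(val, tuple):
                c, u = val
            else:
                c, u = val, Unit.MM
            comps[name] = Component(name, float(c), Unit(u))
        return cls(comps, pH)

    def concentration_of(self, name: str) -> float:
        comp = self.components.get(name)
        return comp.concentration if comp is not None else 0.0

    def unit_of(self, name: str) -> Unit | None:
        comp = self.components.get(name)
        return comp.unit if comp is not None else None

    def scaled(self, factor: float) -> "Mixture":
        return Mixture({n: c.scaled(factor) for n, c in self.components.items()}, self.pH)

    def is_water(self) -> bool:
        return not self.components

    def __eq__(self, other) -> bool:
        if not isinstance(other, Mixture):
            return NotImplemented
        return self.components == other.components and self.pH == other.pH

    def isclose(self, other: "Mixture", rel: float = 1e-9, abs_tol: float = 1e-12) -> bool:
        names = set(self.components) | set(other.components)
        for n in names:
            a, b = self.concentration_of(n), other.concentration_of(n)
            ua, ub = self.unit_of(n), other.unit_of(n)
            if ua is not None and ub is not None and ua != ub:
                return False
            if not math.isclose(a, b, rel_tol=rel, abs_tol=abs_tol):
                return False
        return True


#: Pure water — the default diluent.
WATER = Mixture()


@dataclass(frozen=True)
class VolumetricPart:
    """A mixture together with the volume (µl) of it entering a blend."""

    mixture: Mixture
    volume: float

    def __post_init__(self):
        if self.volume < 0:
            raise MixingError(f"negative part volume {self.volume}")


def mix(parts: Sequence[VolumetricPart]) -> Mixture:
    """Volume-weighted blend of the given parts.

    Each component ends at sum(c_i * v_i) / sum(v_i); mass is conserved
    exactly.  Raises :class:`MixingError` on empty input or zero total volume
    and :class:`UnitClashError` if one component name carries two units.
    """
    if not parts:
        raise MixingError("mix() needs at least one part")
    total = sum(p.volume for p in parts)
    if total <= 0:
        raise MixingError("total volume must be positive")

    units: dict[str, Unit] = {}
    mass: dict[str, float] = {}
    for part in parts:
        for name, comp in part.mixture.components.items():
            if name in units and units[name] != comp.unit:
                raise UnitClashError(
                    f"component {name!r} mixed with units {units[name].value} and {comp.unit.value}"
                )
            units.setdefault(name, comp.unit)
            mass[name] = mass.get(name, 0.0) + comp.concentration * part.volume

    components = {
        name: Component(name, mass[name] / total, units[name]) for name in sorted(mass)
    }

    declared = {p.mixture.pH for p in parts if p.volume > 0 and p.mixture.pH is not None}
    pH = declared.pop() if len(declared) == 1 else None
    return Mixture(components, pH)


def dilute(mixture: Mixture, factor: float) -> Mixture:
    """Scale every concentration by ``factor`` in (0, 1].

    factor 1 is the identity (neat); 1e-7 is the deepest seed-stock dilution
    used in titration series.
    """
    if not (0 < factor <= 1):
        raise ValueError(f"dilution factor must be in (0, 1], got {factor}")
    if factor == 1:
        return Mixture(dict(mixture.components), mixture.pH)
    return mixture.scaled(factor)


def volume_for_target(target_conc: float, stock_conc: float, total_volume: float,
                      component: str = "component") -> float:
    """Volume of stock needed so the final ``total_volume`` hits ``target_conc``.

    Pure C1·V1 = C2·V2 arithmetic; raises :class:`InfeasibleTargetError` when
    the stock is not concentrated enough.
    """
    if stock_conc <= 0:
        raise ValueError(f"stock concentration must be positive, got {stock_conc}")
    if target_conc < 0:
        raise ValueError(f"negative target concentration {target_conc}")
    if target_conc > stock_conc:
        raise InfeasibleTargetError(component, target_conc, stock_conc)
    return total_volume * target_conc / stock_conc


def normalize_molar(mixture: Mixture) -> Mixture:
    """Convert any M-denominated component to mM (the canonical molar unit).

    The one sanctioned unit conversion; run once at config load so downstream
    arithmetic never compares M with mM.
    """
    comps = {}
    for name, comp in mixture.components.items():
        if comp.unit == Unit.M:
            comps[name] = Component(name, comp.concentration * 1000.0, Unit.MM)
        else:
            comps[name] = comp
    return Mixture(comps, mixture.pH)
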