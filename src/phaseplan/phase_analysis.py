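"""Phase-diagram construction from paired seeded/unseeded observations.

A crystallization phase diagram partitions (precipitant, protein) space into
four zones.  With microbatch-under-oil drops the composition at nucleation is
fixed, so a pair of plates — one without seed stock, one with — identifies
the zones well by well:

* spontaneous crystals without seeds  → nucleation (labile) zone
* crystals only after seeding        → metastable zone
* clear in both arms                 → undersaturated
* precipitate                        → precipitation zone

The solubility boundary (undersaturated vs everything supersaturated) and the
metastable-zone ceiling (metastable vs nucleation) are estimated as monotone
staircases: protein as a non-increasing step function of precipitant chosen
to minimise misclassified wells, with mid-gap thresholds for maximal margin.
Landscapes with two metastable lobes (competing salting-in/salting-out) break
global monotonicity, so fitting runs per connected metastable component and
may emit several monotone segments.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd


class Outcome(str, Enum):
    CLEAR = "clear"
    CRYSTALS = "crystals"
    SHOWER = "shower"          # dense microcrystal shower; same zone logic as crystals
    PRECIPITATE = "precipitate"


#: Outcomes that count as crystal growth for zone logic.
CRYSTAL_LIKE = frozenset({Outcome.CRYSTALS, Outcome.SHOWER})


class Zone(str, Enum):
    UNDERSATURATED = "undersaturated"
    METASTABLE = "metastable"
    NUCLEATION = "nucleation"
    PRECIPITATION = "precipitation"
    INCONSISTENT = "inconsistent"
    UNKNOWN = "unknown"


@dataclass
class ObservationPair:
    """One well's outcome in the unseeded and/or seeded arm."""

    well_label: str
    unseeded: Outcome | None = None
    seeded: Outcome | None = None
    target: tuple[float, float] | None = None  # (protein, precipitant) if known

    def __post_init__(self):
        self.unseeded = Outcome(self.unseeded) if self.unseeded is not None else None
        self.seeded = Outcome(self.seeded) if self.seeded is not None else None


def classify_pair(p: ObservationPair) -> Zone:
    """Zone call for one well from its (unseeded, seeded) outcome pair.

    The unseeded arm dominates: spontaneous crystals mean nucleation zone and
    precipitate means precipitation zone regardless of the seeded arm — except
    the contradictory case of spontaneous crystals vanishing under seeding,
    which is flagged inconsistent rather than guessed.  A clear unseeded drop
    that crystallises only with seeds is the defining metastable signature.
    Wells missing the unseeded arm cannot be placed (a clear seeded drop says
    only "at or below solubility") and degrade to unknown.
    """
    u, s = p.unseeded, p.seeded
    if u is None:
        return Zone.UNKNOWN
    if u in CRYSTAL_LIKE:
        return Zone.INCONSISTENT if s == Outcome.CLEAR else Zone.NUCLEATION
    if u == Outcome.PRECIPITATE:
        return Zone.PRECIPITATION
    # unseeded clear
    if s in CRYSTAL_LIKE:
        return Zone.METASTABLE
    if s == Outcome.CLEAR:
        return Zone.UNDERSATURATED
    if s == Outcome.PRECIPITATE:
        return Zone.PRECIPITATION
    return Zone.UNKNOWN  # seeded arm missing: undersaturated or metastable


# ---------------------------------------------------------------------------
# Monotone staircase frontier estimation
# ---------------------------------------------------------------------------

Side = Literal["below", "above"]


@dataclass
class FrontierSegment:
    """A monotone staircase: protein threshold as a step function of precipitant.

    ``steps`` is a list of (precipitant_level, protein_threshold); the
    boundary at precipitant x is the threshold of the last step with level
    <= x.  ``direction`` records the monotone sense of the thresholds.
    """

    steps: list[tuple[float, float]]
    direction: Literal["non_increasing", "non_decreasing"] = "non_increasing"
    misclassified: int = 0

    def value_at(self, precipitant: float) -> float:
        t = math.inf if self.direction == "non_increasing" else -math.inf
        for level, thr in self.steps:
            if level <= precipitant:
                t = thr
            else:
                break
        return t


def _candidate_thresholds(proteins: Sequence[float]) -> list[float]:
    """Mid-gap thresholds between adjacent distinct protein levels, plus sentinels."""
    levels = sorted(set(proteins))
    if not levels:
        return [0.0]
    span = max(levels[-1] - levels[0], 1.0)
    cands = [levels[0] - 0.5 * span]
    cands += [(a + b) / 2 for a, b in zip(levels, levels[1:])]
    cands.append(levels[-1] + 0.5 * span)
    return cands


def estimate_frontier(points: Sequence[tuple[float, float, Side]],
                      direction: Literal["non_increasing", "non_decreasing"] = "non_increasing",
                      ) -> FrontierSegment:
    """Minimum-misclassification monotone staircase separating below from above.

    ``points`` are (precipitant, protein, side) with side "below" meaning the
    point should fall under the boundary and "above" over it.  Thresholds are
    restricted to mid-gaps between observed protein levels (maximal margin);
    the staircase is found by dynamic programming over (precipitant level,
    threshold index) and is exactly optimal — equal to exhaustive search over
    all monotone staircases.  With points on only one side the boundary
    degenerates to ±infinity with a warning.
    """
    pts = list(points)
    if not pts:
        warnings.warn("estimate_frontier called with no points")
        return FrontierSegment([], direction)
    sides = {s for _, _, s in pts}
    if sides == {"below"}:
        warnings.warn("only 'below' points: frontier degenerates to +inf")
        return FrontierSegment([(min(c for c, _, _ in pts), math.inf)], direction)
    if sides == {"above"}:
        warnings.warn("only 'above' points: frontier degenerates to -inf")
        return FrontierSegment([(min(c for c, _, _ in pts), -math.inf)], direction)

    cs = sorted({c for c, _, _ in pts})
    thr = _candidate_thresholds([p for _, p, _ in pts])
    # order thresholds so that "later columns pick an index >= current" encodes monotonicity
    thr_ordered = sorted(thr, reverse=(direction == "non_increasing"))
    nt, nc = len(thr_ordered), len(cs)

    # cost[j][k]: misclassified points in column j under threshold k
    cost = np.zeros((nc, nt), dtype=int)
    col_pts: dict[float, list[tuple[float, Side]]] = {c: [] for c in cs}
    for c, p, s in pts:
        col_pts[c].append((p, s))
    for j, c in enumerate(cs):
        for k, t in enumerate(thr_ordered):
            bad = 0
            for p, s in col_pts[c]:
                if s == "below" and p > t:
                    bad += 1
                elif s == "above" and p < t:
                    bad += 1
            cost[j, k] = bad

    # DP: dp[j][k] = best cost for columns j.. with threshold index >= k at column j
    dp = np.zeros((nc, nt), dtype=int)
    choice = np.zeros((nc, nt), dtype=int)
    # suffix handling: work backwards with running minimum over k' >= k
    dp[nc - 1] = cost[nc - 1]

    def suffix_min(row: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        bs = np.empty(nt, dtype=int)
        bi = np.empty(nt, dtype=int)
        best, bidx = None, -1
        for k in range(nt - 1, -1, -1):
            if best is None or row[k] <= best:  # prefer smaller k on ties -> higher threshold first in order
                best, bidx = row[k], k
            bs[k], bi[k] = best, bidx
        return bs, bi

    for j in range(nc - 2, -1, -1):
        best_suffix, best_idx = suffix_min(dp[j + 1])
        for k in range(nt):
            dp[j, k] = cost[j, k] + best_suffix[k]
            choice[j, k] = best_idx[k]

    first_suffix, first_idx = suffix_min(dp[0])
    k = int(first_idx[0])
    total = int(first_suffix[0])
    ks = [k]
    for j in range(nc - 1):
        k = int(choice[j, k])
        ks.append(k)

    steps = [(cs[j], thr_ordered[ks[j]]) for j in range(nc)]
    # collapse repeated thresholds
    collapsed: list[tuple[float, float]] = []
    for level, t in steps:
        if not collapsed or collapsed[-1][1] != t:
            collapsed.append((level, t))
    return FrontierSegment(collapsed, direction, misclassified=total)


# ---------------------------------------------------------------------------
# Diagram assembly
# ---------------------------------------------------------------------------

@dataclass
class PhaseDiagram:
    zones: dict[str, Zone]
    wells: dict[str, tuple[float, float]]           # well -> (protein, precipitant)
    zone_fractions: dict[Zone, float]
    solubility_frontier: list[FrontierSegment] = field(default_factory=list)
    nucleation_frontier: list[FrontierSegment] = field(default_factory=list)

    def zone_count(self, zone: Zone) -> int:
        return sum(1 for z in self.zones.values() if z == zone)


class ReconciliationError(ValueError):
    """Observations reference wells absent from the plate map."""


def _zone_fractions(zones: dict[str, Zone]) -> dict[Zone, float]:
    classified = [z for z in zones.values() if z != Zone.UNKNOWN]
    n = len(classified)
    if n == 0:
        return {}
    return {z: classified.count(z) / n for z in Zone if z in classified}


def _connected_components(cells: set[tuple[int, int]]) -> list[set[tuple[int, int]]]:
    """8-connected components on the well grid.

    Diagonal adjacency counts: a metastable band tracking a sloped boundary
    steps diagonally through the grid and must not be split into fragments.
    """
    remaining = set(cells)
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            r, c = frontier.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nb = (r + dr, c + dc)
                    if nb in remaining:
                        remaining.remove(nb)
                        comp.add(nb)
                        frontier.append(nb)
        comps.append(comp)
    return comps


def _best_direction_fit(points: list[tuple[float, float, Side]]) -> FrontierSegment:
    """Fit both monotone senses, keep the lower-cost one (tie: non-increasing)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dec = estimate_frontier(points, "non_increasing")
        inc = estimate_frontier(points, "non_decreasing")
    return inc if inc.misclassified < dec.misclassified else dec


def build_phase_diagram(wells, observations: Sequence[ObservationPair],
                        ) -> PhaseDiagram:
    """Classify every observed well and estimate both frontiers.

    ``wells`` is any sequence of objects with well_label, row, col,
    protein_mg_ml and precipitant_conc attributes (a PlateDesign's wells or a
    plate map read from CSV).  The solubility frontier separates
    undersaturated wells from all supersaturated ones; the nucleation frontier
    separates {undersaturated, metastable} from {nucleation, precipitation}.
    If the metastable wells split into several grid-connected components the
    frontiers are fitted per component (each in its better monotone sense) and
    reported as multiple segments.
    """
    by_label = {w.well_label: w for w in wells}
    missing = [o.well_label for o in observations if o.well_label not in by_label]
    if missing:
        raise ReconciliationError(f"observations reference unknown wells: {missing}")

    zones: dict[str, Zone] = {}
    coords: dict[str, tuple[float, float]] = {}
    cells: dict[str, tuple[int, int]] = {}
    for obs in observations:
        w = by_label[obs.well_label]
        zones[obs.well_label] = classify_pair(obs)
        coords[obs.well_label] = (w.protein_mg_ml, w.precipitant_conc)
        cells[obs.well_label] = (w.row, w.col)

    fractions = _zone_fractions(zones)

    sol_pts: list[tuple[float, float, Side]] = []
    nuc_pts: list[tuple[float, float, Side]] = []
    for label, z in zones.items():
        protein, precip = coords[label]
        if z == Zone.UNDERSATURATED:
            sol_pts.append((precip, protein, "below"))
            nuc_pts.append((precip, protein, "below"))
        elif z == Zone.METASTABLE:
            sol_pts.append((precip, protein, "above"))
            nuc_pts.append((precip, protein, "below"))
        elif z in (Zone.NUCLEATION, Zone.PRECIPITATION):
            sol_pts.append((precip, protein, "above"))
            nuc_pts.append((precip, protein, "above"))

    meta_cells = {cells[l] for l, z in zones.items() if z == Zone.METASTABLE}
    comps = _connected_components(meta_cells)

    def side_for(z: Zone, nucleation_boundary: bool) -> Side | None:
        if nucleation_boundary:
            if z in (Zone.UNDERSATURATED, Zone.METASTABLE):
                return "below"
            if z in (Zone.NUCLEATION, Zone.PRECIPITATION):
                return "above"
        else:
            if z == Zone.UNDERSATURATED:
                return "below"
            if z in (Zone.METASTABLE, Zone.NUCLEATION, Zone.PRECIPITATION):
                return "above"
        return None

    def fit(points: list[tuple[float, float, Side]],
            nucleation_boundary: bool) -> list[FrontierSegment]:
        if not points:
            return []
        if len({s for _, _, s in points}) < 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return [estimate_frontier(points)]
        if len(comps) <= 1:
            return [_best_direction_fit(points)]
        # dual-metastable landscape: fit one segment per metastable component,
        # using the wells within that component's column span (±1 column margin)
        label_cols = {l: cells[l][1] for l in zones}
        segments = []
        for comp in sorted(comps, key=lambda c: min(col for _, col in c)):
            cols = {col for _, col in comp}
            lo, hi = min(cols), max(cols)
            seg_pts = []
            for l, z in zones.items():
                if lo - 1 <= label_cols[l] <= hi + 1:
                    side = side_for(z, nucleation_boundary)
                    if side is not None:
                        protein, precip = coords[l]
                        seg_pts.append((precip, protein, side))
            if seg_pts and len({s for _, _, s in seg_pts}) == 2:
                segments.append(_best_direction_fit(seg_pts))
        return segments or [_best_direction_fit(points)]

    solubility = fit(sol_pts, nucleation_boundary=False)
    nucleation = fit(nuc_pts, nucleation_boundary=True)
    return PhaseDiagram(zones=zones, wells=coords, zone_fractions=fractions,
                        solubility_frontier=solubility,
                        nucleation_frontier=nucleation)


# ---------------------------------------------------------------------------
# CSV / JSON I/O
# ---------------------------------------------------------------------------

def read_observations_csv(path) -> list[ObservationPair]:
    """Read observations from columns well,arm,outcome (arm: seeded|unseeded)."""
    df = pd.read_csv(path)
    pairs: dict[str, ObservationPair] = {}
    for rec in df.to_dict("records"):
        label = str(rec["well"])
        pair = pairs.setdefault(label, ObservationPair(label))
        arm = str(rec["arm"]).strip().lower()
        outcome = Outcome(str(rec["outcome"]).strip().lower())
        if arm == "seeded":
            pair.seeded = outcome
        elif arm == "unseeded":
            pair.unseeded = outcome
        else:
            raise ValueError(f"unknown arm {rec['arm']!r} for well {label}")
    return list(pairs.values())


def write_observations_csv(pairs: Sequence[ObservationPair], path) -> None:
    rows = []
    for p in pairs:
        if p.unseeded is not None:
            rows.append({"well": p.well_label, "arm": "unseeded", "outcome": p.unseeded.value})
        if p.seeded is not None:
            rows.append({"well": p.well_label, "arm": "seeded", "outcome": p.seeded.value})
    pd.DataFrame(rows, columns=["well", "arm", "outcome"]).to_csv(path, index=False)


def write_zones_csv(diagram: PhaseDiagram, path) -> None:
    rows = [{"well": label, "zone": zone.value,
             "protein_mg_ml": diagram.wells[label][0],
             "precipitant_conc": diagram.wells[label][1]}
            for label, zone in diagram.zones.items()]
    pd.DataFrame(rows, columns=["well", "zone", "protein_mg_ml",
                                "precipitant_conc"]).to_csv(path, index=False)


def frontier_to_json(diagram: PhaseDiagram) -> dict:
    def seg(s: FrontierSegment) -> dict:
        return {"direction": s.direction, "misclassified": s.misclassified,
                "steps": [[lvl, (None if math.isinf(t) else t)] for lvl, t in s.steps]}
    return {
        "solubility_frontier": [seg(s) for s in diagram.solubility_frontier],
        "nucleation_frontier": [seg(s) for s in diagram.nucleation_frontier],
        "zone_fractions": {z.value: f for z, f in diagram.zone_fractions.items()},
    }


def write_frontier_json(diagram: PhaseDiagram, path) -> None:
    with open(path, "w") as fh:
        json.dump(frontier_to_json(diagram), fh, indent=2)
        fh.write("\n")
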