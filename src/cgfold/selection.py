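"""Combination and selection of predicted contacts.

Contact predictors are grouped into four reliability tiers.  Selection
walks the tiers from most to least reliable, granting each tier a
contacts-per-residue quota (summing to 2.4 contacts per residue overall)
and admitting only predictions whose confidence clears an Nf-dependent
cutoff anchored at roughly 50% expected precision.  Unused quota cascades
to the next tier down, so the budget degrades gracefully when a tier is
absent or too unconfident.  Each selected contact becomes a restraint
whose well depth is proportional to the confidence of the record that
selected it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .formats import ContactMap

logger = logging.getLogger(__name__)

TIER_ORDER = ("very_high", "high", "medium", "low")

#: default routing of predictor names to tiers (case-insensitive)
DEFAULT_TIER_TABLE = {
    "nebcon": "very_high", "respre": "very_high", "deepplm": "very_high",
    "deepcov": "high", "deepcontact": "high", "dncon2": "high",
    "metapsicov2": "medium",
    "gremlin": "low", "ccmpred": "low", "freecontact": "low",
}

#: contacts-per-residue quota by tier; sums to 2.4
DEFAULT_QUOTAS = {"very_high": 1.0, "high": 0.8, "medium": 0.4, "low": 0.2}

#: consensus weights by tier
DEFAULT_TIER_WEIGHTS = {"very_high": 1.0, "high": 0.8, "medium": 0.6, "low": 0.4}

#: base confidence cutoffs by tier; the Nf factor roughly doubles them for
#: shallow alignments (Nf ≈ 0) and relaxes toward the base for deep ones
DEFAULT_BASE_CUTOFFS = {"very_high": 0.15, "high": 0.20, "medium": 0.25, "low": 0.30}

NF_SCALE = 15.0  # alignment depth below which contact prediction degrades


def min_confidence(tier: str, nf: float,
                   base_cutoffs: dict[str, float] | None = None) -> float:
    """Nf-dependent confidence cutoff for a tier (non-increasing in Nf)."""
    base = (base_cutoffs or DEFAULT_BASE_CUTOFFS)[tier]
    return base * (1.0 + 1.0 / (1.0 + nf / NF_SCALE))


def assign_tiers(predictor_ids, tier_table: dict[str, str] | None = None,
                 default: str = "medium") -> dict[str, str]:
    """Map predictor identifiers to reliability tiers.

    Unknown predictors fall back to ``default`` (logged)."""
    table = {k.lower(): v for k, v in (tier_table or DEFAULT_TIER_TABLE).items()}
    out = {}
    for pid in predictor_ids:
        tier = table.get(pid.lower())
        if tier is None:
            logger.info("predictor %r not in tier table; defaulting to %s",
                        pid, default)
            tier = default
        if tier not in TIER_ORDER:
            raise ValueError(f"unknown tier {tier!r} for predictor {pid!r}")
        out[pid] = tier
    return out


def consensus_rank(maps: list[ContactMap],
                   tier_of: dict[str, str] | None = None,
                   tier_weights: dict[str, float] | None = None,
                   ) -> list[tuple[int, int, float]]:
    """Rank contact pairs by tier-weighted consensus score.

    Each pair is scored by Σ over maps of tier_weight · confidence; ties
    break toward larger sequence separation, then lexicographically.
    Returns (i, j, score) triples in descending score order.
    """
    if not maps:
        return []
    L = maps[0].L
    if any(m.L != L for m in maps):
        raise ValueError("contact maps disagree on sequence length")
    if tier_of is None:
        tier_of = assign_tiers([m.predictor_id for m in maps])
    weights = tier_weights or DEFAULT_TIER_WEIGHTS
    score: dict[tuple[int, int], float] = {}
    for m in maps:
        w = weights[tier_of[m.predictor_id]]
        for p in m.predictions:
            score[(p.i, p.j)] = score.get((p.i, p.j), 0.0) + w * p.confidence
    ranked = sorted(score.items(), key=lambda kv: (-kv[1], -(kv[0][1] - kv[0][0]),
                                                   kv[0][0], kv[0][1]))
    return [(i, j, s) for (i, j), s in ranked]


@dataclass(frozen=True)
class Restraint:
    """One selected contact restraint."""

    i: int
    j: int
    depth: float       # well depth U_ij > 0
    confidence: float
    predictor_id: str
    tier: str


@dataclass
class RestraintSet:
    """Contacts selected for the simulation, with well depths."""

    L: int
    restraints: list[Restraint] = field(default_factory=list)

    def __post_init__(self):
        pairs = [(r.i, r.j) for r in self.restraints]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate restraint pairs")
        if any(r.depth <= 0 for r in self.restraints):
            raise ValueError("restraint depths must be positive")
        if len(self.restraints) > int(np.ceil(2.4 * self.L)) + 4:
            raise ValueError("restraint count exceeds the 2.4·L budget")

    def __len__(self) -> int:
        return len(self.restraints)

    def pairs(self) -> np.ndarray:
        """(n, 2) array of 1-based (i, j)."""
        if not self.restraints:
            return np.empty((0, 2), dtype=int)
        return np.array([(r.i, r.j) for r in self.restraints], dtype=int)

    def depths(self) -> np.ndarray:
        return np.array([r.depth for r in self.restraints], dtype=float)

    def to_contact_map(self) -> ContactMap:
        from .formats import ContactPrediction
        preds = [ContactPrediction(r.i, r.j, r.confidence, r.predictor_id)
                 for r in sorted(self.restraints, key=lambda r: (r.i, r.j))]
        return ContactMap(self.L, preds, "selected")


def select_restraints(maps: list[ContactMap], nf: float, L: int | None = None,
                      tier_of: dict[str, str] | None = None,
                      quotas: dict[str, float] | None = None,
                      base_cutoffs: dict[str, float] | None = None,
                      w_con: float = 1.0) -> RestraintSet:
    """Select ~2.4·L contact restraints from a multi-predictor ensemble.

    Tiers are visited from most to least reliable.  Within a tier,
    candidates are the union of that tier's maps (duplicate pairs keep the
    maximum confidence), ordered by descending confidence; a candidate is
    admitted if its confidence clears the tier's Nf-dependent cutoff and
    the pair was not already selected by a higher tier.  Quota unused by a
    tier passes to the next one down.
    """
    if not maps:
        raise ValueError("at least one contact map is required")
    if nf <= 0:
        raise ValueError("nf must be positive")
    if L is None:
        L = maps[0].L
    if any(m.L != L for m in maps):
        raise ValueError("contact maps disagree on sequence length")
    if tier_of is None:
        tier_of = assign_tiers([m.predictor_id for m in maps])
    quotas = quotas or DEFAULT_QUOTAS

    selected: dict[tuple[int, int], Restraint] = {}
    available = 0.0
    for tier in TIER_ORDER:
        available += quotas.get(tier, 0.0) * L
        tier_maps = [m for m in maps if tier_of[m.predictor_id] == tier]
        if not tier_maps:
            continue
        cutoff = min_confidence(tier, nf, base_cutoffs)
        best: dict[tuple[int, int], tuple[float, str]] = {}
        for m in tier_maps:
            for p in m.predictions:
                key = (p.i, p.j)
                if key not in best or p.confidence > best[key][0]:
                    best[key] = (p.confidence, m.predictor_id)
        candidates = sorted(
            ((conf, pid, i, j) for (i, j), (conf, pid) in best.items()),
            key=lambda t: (-t[0], -(t[3] - t[2]), t[2], t[3]),
        )
        budget = int(np.floor(available + 1e-9))
        taken = 0
        for conf, pid, i, j in candidates:
            if taken >= budget:
                break
            if conf < cutoff or (i, j) in selected:
                continue
            selected[(i, j)] = Restraint(i, j, w_con * conf, conf, pid, tier)
            taken += 1
        available -= taken
    return RestraintSet(L, list(selected.values()))
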