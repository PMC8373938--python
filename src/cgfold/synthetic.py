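"""Synthetic inputs: toy folds, noisy contact ensembles, MSAs, libraries.

Everything the pipeline consumes can be generated here at desk scale,
bit-reproducibly from (spec, seed): ideal-geometry α/β/αβ toy folds with
their native contact maps, contact predictions corrupted to an exact
target precision with confidences calibrated to correctness, synthetic
predictor ensembles spanning the four reliability tiers, alignments with
a tunable effective depth, and a mini fragment source library.

Corruption uses exact-count composition (not Bernoulli sampling): a map
requested at precision p with n predictions contains round(p·n) native
pairs, so measured precision equals the request without statistical
slack.  Decoy (false) pairs reuse the separation distribution of the
true contacts, so selection cannot succeed through sequence separation
alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .evaluate import native_contacts
from .formats import ContactMap, ContactPrediction, compute_nf
from .formats import write_structure
from .geometry import (CA_BOND, CoarseStructure, HELIX_RADIUS, HELIX_RISE,
                       HELIX_TURN, STRAND_OFFSET, STRAND_RISE)

HELIX_SPACING = 9.8   # Å between packed helix axes
STRAND_SPACING = 4.9  # Å between paired strand axes
SHEET_SPACING = 8.4   # Å between sheet layers (close enough for Cβ contacts)

AA_BIAS = {"H": "ALEK", "E": "VITY", "C": "GSND", "L": "GSND"}


@dataclass(frozen=True)
class TopologySpec:
    """Blueprint of a toy fold: SSE blocks, loops and a packing plan.

    ``blocks`` is a sequence of (type, length) with type H (helix),
    E (strand) or L (loop); ``plan`` is one of bundle, hairpin, sandwich.
    """

    blocks: tuple
    plan: str = "bundle"

    def __post_init__(self):
        for t, n in self.blocks:
            if t not in "HEL" or n < 1:
                raise ValueError(f"bad block ({t},{n})")
        if self.plan not in ("bundle", "hairpin", "sandwich"):
            raise ValueError(f"unknown packing plan {self.plan!r}")
        if not (6 <= self.length <= 300):
            raise ValueError(f"total length {self.length} out of range")

    @property
    def length(self) -> int:
        return sum(n for _, n in self.blocks)

    @property
    def ss_string(self) -> str:
        return "".join(("C" if t == "L" else t) * n for t, n in self.blocks)


def three_helix_bundle(helix_len: int = 14, loop_len: int = 5) -> TopologySpec:
    return TopologySpec((("H", helix_len), ("L", loop_len), ("H", helix_len),
                         ("L", loop_len), ("H", helix_len)), "bundle")


@dataclass(frozen=True)
class CorruptionSpec:
    """How to corrupt a native contact map into a noisy prediction."""

    precision: float          # fraction of emitted pairs that are native
    coverage: float           # emitted contacts per residue
    slope: float = 6.0        # confidence-calibration steepness
    conf_range: tuple = (0.10, 0.98)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.precision <= 1.0):
            raise ValueError("precision outside [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


def _arc_bridge(a: np.ndarray, b: np.ndarray, n: int, normal_hint: np.ndarray,
                bond: float = CA_BOND) -> np.ndarray:
    """n interior points between fixed endpoints, all n+1 chords = bond.

    Points lie on a circular arc in the plane spanned by (b − a) and a
    perpendicular derived from ``normal_hint``; infeasible spans raise.
    """
    g = float(np.linalg.norm(b - a))
    m = n + 1
    if g > bond * m + 1e-9:
        raise ValueError(f"loop of {n} residues cannot span {g:.1f} Å")
    if abs(g - bond * m) < 1e-9:
        ts = np.linspace(0, 1, m + 1)[1:-1]
        return a + np.outer(ts, b - a)

    def gap(phi):
        return bond * np.sin(m * phi / 2) / np.sin(phi / 2) - g

    phi = brentq(gap, 1e-9, 2 * np.pi / m * 0.9999, xtol=1e-13)
    R = bond / (2 * np.sin(phi / 2))
    e1 = (b - a) / g
    u = normal_hint - np.dot(normal_hint, e1) * e1
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(e1, [0.0, 0.0, 1.0])
        if np.linalg.norm(u) < 1e-6:
            u = np.cross(e1, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    mid = 0.5 * (a + b)
    centre = mid - R * np.cos(m * phi / 2) * u
    # walk from a to b about the centre in the (e1, u) plane
    t0 = np.arctan2(np.dot(a - centre, u), np.dot(a - centre, e1))
    t1 = np.arctan2(np.dot(b - centre, u), np.dot(b - centre, e1))
    sign = 1.0 if np.isclose((t1 - t0) % (2 * np.pi), m * phi, atol=1e-6) else -1.0
    ts = t0 + sign * phi * np.arange(1, m)
    return centre + R * (np.cos(ts)[:, None] * e1 + np.sin(ts)[:, None] * u)


def _best_bridge(a: np.ndarray, b: np.ndarray, n: int,
                 placed: np.ndarray | None) -> np.ndarray:
    """Bridge two anchors with the arc plane that stays clearest of the
    already-placed atoms (loops should bulge outward, not through the
    fold).  Deterministic given the anchors and obstacles, so structures
    sharing a topology share their loop geometry — local geometry is then
    recurrent across the synthetic library, as it is in real folds."""
    centre = placed.mean(axis=0) if placed is not None else np.zeros(3)
    outward = 0.5 * (a + b) - centre
    hints = [outward, outward + [0, 0, 3.0], outward - [0, 0, 3.0],
             np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0]),
             np.array([1.0, 0.5, 0.0]), np.array([-0.5, 1.0, 0.0])]
    best, best_clear = None, -np.inf
    for hint in hints:
        if np.linalg.norm(hint) < 1e-6:
            continue
        loop = _arc_bridge(a, b, n, hint)
        if placed is None or len(placed) == 0:
            return loop
        d = np.sqrt(((loop[:, None, :] - placed[None, :, :]) ** 2).sum(-1))
        clear = float(d.min())
        if clear > best_clear + 1e-9:
            best, best_clear = loop, clear
        if clear > 4.5:
            break
    return best


def _element_coords(kind: str, n: int, origin: np.ndarray, direction: int,
                    phase: float = 0.0) -> np.ndarray:
    """Ideal-geometry SSE along ±z through ``origin`` (axis at x/y of
    origin, first residue near z = origin_z)."""
    idx = np.arange(n)
    if kind == "H":
        z = origin[2] + direction * HELIX_RISE * idx
        ang = phase + direction * HELIX_TURN * idx
        x = origin[0] + HELIX_RADIUS * np.cos(ang)
        y = origin[1] + HELIX_RADIUS * np.sin(ang)
    else:  # strand
        z = origin[2] + direction * STRAND_RISE * idx
        # zigzag phase tied to absolute height so paired strands pleat in
        # sync and keep their full axis spacing
        x = origin[0] + STRAND_OFFSET * ((-1.0) ** np.rint(z / STRAND_RISE))
        y = np.full(n, origin[1])
    return np.column_stack([x, y, z])


def _axis_positions(plan: str, kinds: list[str],
                    spacing_scale: float = 1.0) -> list[np.ndarray]:
    n = len(kinds)
    hs = HELIX_SPACING * spacing_scale
    es = STRAND_SPACING * spacing_scale
    pos = []
    if plan == "bundle":
        d = hs if "H" in kinds else es
        if n == 1:
            return [np.zeros(3)]
        if n == 2:
            return [np.zeros(3), np.array([d, 0.0, 0.0])]
        R = d / (2 * np.sin(np.pi / n))
        for k in range(n):
            ang = 2 * np.pi * k / n
            pos.append(np.array([R * np.cos(ang), R * np.sin(ang), 0.0]))
    elif plan == "hairpin":
        x = 0.0
        for k in range(n):
            pos.append(np.array([x, 0.0, 0.0]))
            if k < n - 1:
                pair = {kinds[k], kinds[k + 1]}
                x += es if pair == {"E"} else hs
        return pos
    elif plan == "sandwich":
        half = (n + 1) // 2
        for k in range(n):
            row = 0 if k < half else 1
            col = k if row == 0 else k - half
            pos.append(np.array([col * es + (0.5 * es if row else 0.0),
                                 row * SHEET_SPACING * spacing_scale, 0.0]))
    return pos


def make_toy_structure(spec: TopologySpec, seed: int = 0,
                       spacing_scale: float = 1.0
                       ) -> tuple[CoarseStructure, ContactMap]:
    """Build an ideal-geometry toy fold and its native contact map.

    SSEs are placed per the packing plan with alternating axis
    directions; loops are circular arcs with exact 3.8 Å virtual bonds.
    The native map collects all virtual-Cβ pairs under 8 Å with sequence
    separation >= 6.
    """
    rng = np.random.default_rng(seed)
    sses = [(t, n) for t, n in spec.blocks if t in "HE"]
    axis_pos = _axis_positions(spec.plan, [t for t, _ in sses], spacing_scale)

    # place every SSE first (alternating axis direction), so loop bridges
    # can be steered clear of the whole scaffold
    sse_coords: list[np.ndarray] = []
    for k, (t, n) in enumerate(sses):
        direction = 1 if k % 2 == 0 else -1
        rise = HELIX_RISE if t == "H" else STRAND_RISE
        origin = axis_pos[k].copy()
        if direction < 0:
            origin[2] += rise * (n - 1)
        sse_coords.append(_element_coords(t, n, origin, direction,
                                          phase=float(k) * 1.7))
    scaffold = np.vstack(sse_coords)

    pieces: list[np.ndarray] = []
    sse_idx = 0
    prev_end = None
    pending_loop = 0
    for t, n in spec.blocks:
        if t == "L":
            pending_loop += n
            continue
        coords = sse_coords[sse_idx]
        if prev_end is not None:
            if pending_loop == 0:
                raise ValueError("consecutive SSE blocks need a loop between")
            obstacles = [scaffold] + [p for p in pieces]
            loop = _best_bridge(prev_end, coords[0], pending_loop,
                                np.vstack(obstacles))
            pieces.append(loop)
        pending_loop = 0
        pieces.append(coords)
        prev_end = coords[-1]
        sse_idx += 1
    if pending_loop:  # trailing loop: extend from the last SSE end
        tail_dir = pieces[-1][-1] - pieces[-1][-2]
        tail_dir /= np.linalg.norm(tail_dir)
        far = prev_end + tail_dir * CA_BOND * (pending_loop + 1) * 0.8
        loop = _arc_bridge(prev_end, far, pending_loop - 1,
                           np.array([1.0, 0.0, 0.0]))
        pieces.append(np.vstack([loop, far]))

    coords = np.vstack(pieces)
    ss = spec.ss_string
    if len(coords) != len(ss):
        raise RuntimeError("assembled length mismatch")
    sequence = "".join(rng.choice(list(AA_BIAS[s])) for s in ss)
    structure = CoarseStructure(sequence, coords, ss=ss, name=f"toy{seed}")

    pairs = sorted(native_contacts(structure, min_sep=6))
    cmap = ContactMap(len(ss),
                      [ContactPrediction(i, j, 1.0, "native") for i, j in pairs],
                      "native")
    return structure, cmap


def _all_noncontact_pairs(L: int, native: set, min_sep: int = 6):
    out = []
    for i in range(1, L + 1):
        for j in range(i + min_sep, L + 1):
            if (i, j) not in native:
                out.append((i, j))
    return out


def corrupt_contacts(native: ContactMap, spec: CorruptionSpec,
                     predictor_id: str = "synthetic") -> ContactMap:
    """Corrupt a native map to an exact target precision and coverage.

    Emits n = round(coverage·L) predictions of which round(precision·n)
    are native contacts; false pairs are drawn with the native separation
    distribution.  Confidences descend over the emitted list and the
    correct/incorrect labels are laid out so that P(correct | confidence)
    follows a logistic curve of the requested slope — higher-confidence
    deciles are never less accurate than lower ones.
    """
    rng = np.random.default_rng(spec.seed)
    L = native.L
    nat_pairs = sorted(native.pairs())
    n = int(round(spec.coverage * L))
    n_true = int(round(spec.precision * n))
    if n_true > len(nat_pairs):
        raise ValueError(
            f"requested {n_true} true contacts but only {len(nat_pairs)} exist")
    non = _all_noncontact_pairs(L, set(nat_pairs))
    if n - n_true > len(non):
        raise ValueError("not enough non-contact pairs for the requested noise")

    true_sel = [nat_pairs[k] for k in
                rng.choice(len(nat_pairs), size=n_true, replace=False)]
    # separation-matched decoys
    seps = np.array([j - i for i, j in nat_pairs]) if nat_pairs else np.array([6])
    non_by_sep: dict[int, list] = {}
    for i, j in non:
        non_by_sep.setdefault(j - i, []).append((i, j))
    false_sel: list[tuple[int, int]] = []
    used = set(true_sel)
    avail_seps = sorted(non_by_sep)
    while len(false_sel) < n - n_true:
        s = int(seps[rng.integers(len(seps))])
        if s not in non_by_sep or not non_by_sep[s]:
            s = avail_seps[int(np.argmin([abs(x - s) for x in avail_seps]))]
        bucket = non_by_sep[s]
        k = int(rng.integers(len(bucket)))
        pair = bucket.pop(k)
        if not bucket:
            del non_by_sep[s]
            avail_seps = sorted(non_by_sep)
            if not avail_seps and len(false_sel) + 1 < n - n_true:
                raise ValueError("exhausted decoy pairs")
        if pair not in used:
            used.add(pair)
            false_sel.append(pair)

    # descending confidences with a logistic truth layout: slot k gets
    # truth probability ∝ exp(slope·conf_k) (water-filled to the exact
    # true count), realised decile-by-decile so that the fraction of true
    # contacts is non-increasing from the top decile down by construction
    c_lo, c_hi = spec.conf_range
    ranks = np.linspace(1.0, 0.0, n) if n > 1 else np.array([1.0])
    conf = c_lo + (c_hi - c_lo) * ranks ** 0.8
    w = np.exp(spec.slope * conf)
    lo, hi = 0.0, 2.0 * n_true / max(w.sum(), 1e-12) + 1.0
    for _ in range(80):
        lam = 0.5 * (lo + hi)
        if np.minimum(1.0, lam * w).sum() < n_true:
            lo = lam
        else:
            hi = lam
    p = np.minimum(1.0, 0.5 * (lo + hi) * w)

    ndec = min(10, n)
    base, extra = divmod(n, ndec)
    sizes = [base] * (ndec - extra) + [base + 1] * extra  # small chunks first
    bounds = np.cumsum([0] + sizes)
    sums = np.array([p[bounds[g]:bounds[g + 1]].sum() for g in range(ndec)])
    share = sums / max(sums.sum(), 1e-12) * n_true
    counts = np.floor(share).astype(int)
    for g in np.argsort(-(share - counts)):
        if counts.sum() >= n_true:
            break
        counts[g] += 1
    counts = np.sort(counts)[::-1]          # monotone down the deciles
    overflow = 0
    for g in range(ndec):                   # respect decile capacities
        counts[g] += overflow
        overflow = max(counts[g] - sizes[g], 0)
        counts[g] = min(counts[g], sizes[g])
    truth = np.zeros(n, dtype=bool)
    for g in range(ndec):
        slots = np.arange(bounds[g], bounds[g + 1])
        pick = rng.choice(slots, size=counts[g], replace=False)
        truth[pick] = True

    rng.shuffle(true_sel)
    rng.shuffle(false_sel)
    it_t, it_f = iter(true_sel), iter(false_sel)
    preds = []
    for k in range(n):
        i, j = next(it_t) if truth[k] else next(it_f)
        preds.append(ContactPrediction(i, j, float(conf[k]), predictor_id))
    preds.sort(key=lambda p: (p.i, p.j))
    return ContactMap(L, preds, predictor_id)


#: default per-tier (precision, coverage) of the synthetic predictor pool
DEFAULT_TIER_PROFILE = {
    "very_high": (0.70, 1.2),
    "high": (0.55, 1.2),
    "medium": (0.45, 1.0),
    "low": (0.30, 1.0),
}

#: synthetic predictor names routed to each tier by the default tier table
TIER_PREDICTOR_NAMES = {
    "very_high": "ResPRE", "high": "DeepCov",
    "medium": "MetaPSICOV2", "low": "CCMpred",
}


def make_predictor_ensemble(native: ContactMap,
                            tier_profile: dict | None = None,
                            seed: int = 0,
                            conf_range: tuple = (0.10, 0.98),
                            ) -> list[ContactMap]:
    """One corrupted map per synthetic predictor tier.

    Predictor ids are chosen so the default tier table routes each map to
    the intended tier."""
    profile = tier_profile or DEFAULT_TIER_PROFILE
    maps = []
    for k, (tier, (prec, cov)) in enumerate(profile.items()):
        pid = TIER_PREDICTOR_NAMES.get(tier, tier)
        spec = CorruptionSpec(precision=prec, coverage=cov,
                              conf_range=conf_range, seed=seed * 1009 + k)
        maps.append(corrupt_contacts(native, spec, predictor_id=pid))
    return maps


ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def make_synthetic_msa(L: int, target_nf: float, seed: int = 0,
                       query: str | None = None, tolerance: float = 0.10,
                       max_sequences: int = 2000) -> list[str]:
    """Alignment whose effective depth lands within 10% of ``target_nf``.

    Rows are organised into 80%-identity clusters: each cluster of
    mutually similar rows contributes ~1 to Σ 1/(1+m), so the effective
    depth is ≈ n_clusters/√L and is verified by recomputation.
    """
    if target_nf <= 0:
        raise ValueError("target_nf must be positive")
    rng = np.random.default_rng(seed)
    if query is None:
        query = "".join(rng.choice(list(ALPHABET), size=L))
    if len(query) != L:
        raise ValueError("query length mismatch")

    def mutant(base: str, frac: float) -> str:
        k = int(round(frac * L))
        pos = rng.choice(L, size=k, replace=False)
        chars = list(base)
        for p in pos:
            chars[p] = ALPHABET[int(rng.integers(20))]
        return "".join(chars)

    rows = [query]
    n_clusters = max(int(round(target_nf * np.sqrt(L))), 1)
    for _ in range(min(n_clusters, max_sequences) - 1):
        rows.append(mutant(query, 0.45))
    nf = compute_nf(rows).nf
    guard = 0
    while abs(nf - target_nf) > tolerance * target_nf and guard < 500:
        if nf < target_nf:
            if len(rows) >= max_sequences:
                raise ValueError(
                    f"cannot reach Nf={target_nf}; achieved {nf:.2f} "
                    f"with {len(rows)} sequences")
            rows.append(mutant(query, 0.45))
        else:
            if len(rows) == 1:
                break
            rows.pop()
        nf = compute_nf(rows).nf
        guard += 1
    return rows


LIBRARY_TEMPLATES = [
    three_helix_bundle(),
    TopologySpec((("H", 12), ("L", 4), ("H", 16), ("L", 4), ("H", 12),
                  ("L", 3), ("H", 10)), "bundle"),
    TopologySpec((("E", 7), ("L", 4), ("E", 7), ("L", 4), ("E", 7),
                  ("L", 4), ("E", 7)), "sandwich"),
    TopologySpec((("E", 6), ("L", 3), ("E", 6)), "hairpin"),
    TopologySpec((("H", 12), ("L", 4), ("E", 6), ("L", 3), ("E", 6),
                  ("L", 4), ("H", 12)), "hairpin"),
    TopologySpec((("H", 18), ("L", 5), ("H", 18)), "hairpin"),
    TopologySpec((("E", 8), ("L", 3), ("E", 8), ("L", 3), ("E", 8)),
                 "bundle"),
]


def _random_spec(rng: np.random.Generator) -> TopologySpec:
    """A random small topology: varied SSE counts, lengths and loops."""
    plan = ("bundle", "hairpin", "sandwich")[int(rng.integers(3))]
    n_sse = int(rng.integers(2, 5))
    mostly = "H" if rng.random() < 0.5 else "E"
    blocks = []
    for k in range(n_sse):
        kind = mostly if rng.random() < 0.8 else ("E" if mostly == "H" else "H")
        length = (int(rng.integers(8, 19)) if kind == "H"
                  else int(rng.integers(5, 10)))
        blocks.append((kind, length))
        if k < n_sse - 1:
            blocks.append(("L", int(rng.integers(3, 7))))
    return TopologySpec(tuple(blocks), plan)


def make_mini_library(n_structures: int = 50, seed: int = 0,
                      out_dir=None) -> list[CoarseStructure]:
    """Desk-scale fragment source library of toy structures.

    Mixes fixed α/β/αβ templates with randomly drawn topologies, varying
    SSE lengths, loop lengths and packing spacing, so the library's local
    geometry is diverse the way a non-redundant structure set is.  When
    ``out_dir`` is given the structures are also written as PDB files
    with a FASTA index.
    """
    if n_structures < 1:
        raise ValueError("need at least one structure")
    structures = []
    rng = np.random.default_rng(seed)
    k = 0
    while len(structures) < n_structures:
        if k < len(LIBRARY_TEMPLATES):
            spec = LIBRARY_TEMPLATES[k]
        else:
            spec = _random_spec(rng)
        scale = float(rng.uniform(0.92, 1.12))
        try:
            s, _ = make_toy_structure(spec, seed=seed * 7919 + k,
                                      spacing_scale=scale)
        except ValueError:
            k += 1
            continue  # infeasible random packing; draw another
        s.name = f"lib{len(structures):03d}"
        structures.append(s)
        k += 1
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "index.fasta", "w") as fh:
            for s in structures:
                write_structure(s, out / f"{s.name}.pdb")
                fh.write(f">{s.name}\n{s.sequence}\n")
    return structures


def benchmark_specs(n: int = 10):
    """Varied small α/β/αβ topologies for multi-target comparisons.

    All are compact folds whose native contact maps carry medium- and
    long-range information, so contact guidance can in principle pin the
    topology."""
    base = [
        three_helix_bundle(),
        three_helix_bundle(helix_len=12, loop_len=4),
        TopologySpec((("H", 16), ("L", 5), ("H", 16), ("L", 5), ("H", 12)),
                     "bundle"),
        TopologySpec((("E", 7), ("L", 4), ("E", 7), ("L", 4), ("E", 7),
                      ("L", 4), ("E", 7)), "sandwich"),
        TopologySpec((("E", 6), ("L", 3), ("E", 6), ("L", 3), ("E", 6),
                      ("L", 3), ("E", 6)), "sandwich"),
        TopologySpec((("H", 12), ("L", 4), ("H", 12), ("L", 4), ("H", 12),
                      ("L", 4), ("H", 12)), "bundle"),
        TopologySpec((("H", 14), ("L", 4), ("H", 14), ("L", 4), ("H", 14),
                      ("L", 4), ("H", 10)), "bundle"),
        TopologySpec((("E", 8), ("L", 3), ("E", 8), ("L", 3), ("E", 8)),
                     "bundle"),
        TopologySpec((("H", 18), ("L", 5), ("H", 18)), "hairpin"),
        TopologySpec((("H", 12), ("L", 3), ("H", 12), ("L", 3), ("E", 6),
                      ("L", 3), ("E", 6)), "bundle"),
    ]
    return [base[k % len(base)] for k in range(n)]


def sse_prediction_from_plan(spec: TopologySpec, confidence: float = 0.9):
    """Perfect-knowledge SS2-style prediction from the topology plan."""
    from .formats import SsePrediction
    ss = spec.ss_string
    conf = np.full((len(ss), 3), (1.0 - confidence) / 2)
    for k, s in enumerate(ss):
        conf[k, "CHE".index(s)] = confidence
    return SsePrediction(ss, conf)
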