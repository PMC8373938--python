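"""Position-specific fragment libraries and distance profiles.

The query is scanned by gapless threading against a library of
coarse-grained structures: every contiguous window of every library
structure is scored against every query position for fragment lengths 1
to 20, by average BLOSUM62 substitution score plus a secondary-structure
match bonus, and the best 200 windows per (position, length) slot are
kept.  Pairs of top fragments that come from the same source structure
with a consistent register vote for the source's residue-pair distance;
the resulting histograms become distance-profile restraints whenever
they peak below 9 Å.

Library structures with more than 30% sequence identity to the query are
removed first, so profiles never lean on homologs of the target.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .geometry import CoarseStructure, pseudo_angles

FRAGMENT_LENGTHS = tuple(range(1, 21))
TOP_FRAGMENTS = 200
PROFILE_BIN = 0.5      # Å
PROFILE_MAX = 40.0     # Å
PROFILE_PEAK_CUT = 9.0  # Å: usable iff the modal bin centre is below this

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {aa: k for k, aa in enumerate(_ALPHABET)}
_BLOSUM_ARR = np.array(
    [[_BLOSUM[a][b] for b in _ALPHABET] for a in _ALPHABET], dtype=float
)


def _seq_to_idx(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(a, _AA_INDEX["X"]) for a in seq.upper()])


def assign_ss_geometric(coords: np.ndarray) -> str:
    """3-state secondary structure from Cα pseudo-angles.

    Helix and strand are recognised by their characteristic virtual bond
    angle / torsion ranges; everything else is coil.  A stand-in for
    hydrogen-bond-based assignment on Cα-only models.
    """
    L = len(coords)
    if L < 4:
        return "C" * L
    theta, tau = pseudo_angles(coords)
    ss = ["C"] * L
    for i in range(1, L - 2):
        th = np.rad2deg(theta[i - 1])
        ta = np.rad2deg(tau[i - 1]) if i - 1 < len(tau) else 0.0
        if 75.0 <= th <= 105.0 and 30.0 <= ta <= 70.0:
            ss[i] = "H"
        elif 105.0 < th <= 145.0 and abs(ta) >= 140.0:
            ss[i] = "E"
    return "".join(ss)


@dataclass(frozen=True)
class Fragment:
    """A gaplessly threaded structural fragment.

    ``position`` is the 1-based query start; ``source_start`` the 1-based
    start within the source structure."""

    position: int
    length: int
    source_id: str
    source_start: int
    score: float


@dataclass
class FragmentLibrary:
    """Ranked fragments per (query position, length) slot.

    ``slots[(p, l)]`` is a score-descending list of :class:`Fragment`;
    ``sources`` maps source ids to their structures so fragment
    coordinates can be materialised."""

    L: int
    slots: dict = field(default_factory=dict)
    sources: dict = field(default_factory=dict)
    cap: int = TOP_FRAGMENTS

    def fragments(self, position: int, length: int) -> list[Fragment]:
        return self.slots.get((position, length), [])

    def coords(self, frag: Fragment) -> np.ndarray:
        src = self.sources[frag.source_id]
        a = frag.source_start - 1
        return src.coords[a:a + frag.length]

    def n_fragments(self) -> int:
        return sum(len(v) for v in self.slots.values())


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity, normalised by the shorter
    sequence."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.2
    aligner.end_open_gap_score = 0.0
    aligner.end_extend_gap_score = 0.0
    aln = aligner.align(a, b)[0]
    matches = sum(
        x == y
        for sa, sb in zip(aln.aligned[0], aln.aligned[1])
        for x, y in zip(a[sa[0]:sa[1]], b[sb[0]:sb[1]])
    )
    return matches / min(len(a), len(b))


def homolog_filter(library: list[CoarseStructure], query_seq: str,
                   max_identity: float = 0.30) -> list[CoarseStructure]:
    """Drop library structures whose global sequence identity to the query
    exceeds ``max_identity`` (strictly greater)."""
    return [s for s in library
            if sequence_identity(query_seq, s.sequence) <= max_identity]


def gapless_thread(query_seq: str, query_ss: str,
                   library: list[CoarseStructure],
                   lengths=FRAGMENT_LENGTHS, top: int = TOP_FRAGMENTS,
                   w_ssm: float = 1.0) -> FragmentLibrary:
    """Thread the query through the library without gaps.

    The score of placing a library window at a query position is the mean
    BLOSUM62 substitution score over the window plus ``w_ssm`` times the
    fraction of matching secondary-structure states.
    """
    if not library:
        raise ValueError("empty fragment source library")
    L = len(query_seq)
    qidx = _seq_to_idx(query_seq)
    qss = np.frombuffer(query_ss.encode(), dtype=np.uint8)

    per_struct = []
    for s in library:
        sidx = _seq_to_idx(s.sequence)
        ss = s.ss or assign_ss_geometric(s.coords)
        sss = np.frombuffer(ss.encode(), dtype=np.uint8)
        M = _BLOSUM_ARR[qidx[:, None], sidx[None, :]]
        M = M + w_ssm * (qss[:, None] == sss[None, :])
        per_struct.append((s, M))

    lib = FragmentLibrary(L=L, cap=top)
    for s in library:
        lib.sources[s.name] = s

    for ell in lengths:
        rows = []      # window scores per structure
        meta = []      # (source index, window start array)
        for si, (s, M) in enumerate(per_struct):
            T = M.shape[1]
            if T < ell or L < ell:
                continue
            # windowed diagonal sums via cumulative diagonal trick
            W = np.zeros((L - ell + 1, T - ell + 1))
            acc = M[:L - ell + 1, :T - ell + 1].copy()
            W += acc
            for k in range(1, ell):
                W += M[k:k + L - ell + 1, k:k + T - ell + 1]
            rows.append(W / ell)
            meta.append(si)
        if not rows:
            continue
        widths = [w.shape[1] for w in rows]
        allw = np.concatenate(rows, axis=1)     # (positions, total windows)
        src_of = np.concatenate(
            [np.full(w, meta[k]) for k, w in enumerate(widths)])
        start_of = np.concatenate([np.arange(w) for w in widths])
        n = allw.shape[1]
        keep = min(top, n)
        for p in range(L - ell + 1):
            scores = allw[p]
            if keep < n:
                part = np.argpartition(-scores, keep - 1)[:keep]
            else:
                part = np.arange(n)
            order = part[np.lexsort((src_of[part], start_of[part],
                                     -scores[part]))]
            lib.slots[(p + 1, ell)] = [
                Fragment(p + 1, ell, per_struct[src_of[t]][0].name,
                         int(start_of[t]) + 1, float(scores[t]))
                for t in order
            ]
    return lib


@dataclass
class DistanceProfile:
    """Histogram of Cα distances for one residue pair (1-based i < j)."""

    i: int
    j: int
    counts: np.ndarray   # bins of PROFILE_BIN Å on [0, PROFILE_MAX)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("negative histogram counts")

    @property
    def usable(self) -> bool:
        if self.counts.sum() == 0:
            return False
        mode_centre = (np.argmax(self.counts) + 0.5) * PROFILE_BIN
        return bool(mode_centre < PROFILE_PEAK_CUT)

    @property
    def peak(self) -> float:
        return (np.argmax(self.counts) + 0.5) * PROFILE_BIN


def build_distance_profiles(flib: FragmentLibrary, min_separation: int = 3,
                            max_separation: int = 8,
                            score_beta: float = 2.0,
                            ) -> dict[tuple[int, int], DistanceProfile]:
    """Distance profiles from co-sourced top fragments.

    For a pair (i, j), every pair of kept fragments — one whose window
    starts at i, one starting at j — drawn from the same source structure
    with the same register offset (source start minus query start) votes
    for the source distance between the residues the pair maps onto.
    Votes are weighted by exp(score_beta · (score − slot best)), so
    well-threaded placements dominate the histogram even when the library
    is small enough that the top-200 cut is not selective by itself.
    Pairs are restricted to sequence separations in
    [min_separation, max_separation]: fragment co-occurrence determines
    local geometry well, but at larger separations the evidence is
    register-degenerate and the histograms stop being informative.
    """
    L = flib.L
    nbins = int(PROFILE_MAX / PROFILE_BIN)
    # per query position: weighted multiset of (source, offset) placements
    placements: list[Counter] = [Counter() for _ in range(L + 1)]
    for (p, _ell), frags in flib.slots.items():
        if not frags:
            continue
        best = frags[0].score
        for f in frags:
            placements[p][(f.source_id, f.source_start - f.position)] += (
                float(np.exp(score_beta * (f.score - best))))

    # cache source coordinate arrays
    src_coords = {name: s.coords for name, s in flib.sources.items()}
    src_len = {name: len(s.coords) for name, s in flib.sources.items()}

    profiles: dict[tuple[int, int], DistanceProfile] = {}
    for i in range(1, L + 1):
        ci = placements[i]
        if not ci:
            continue
        for j in range(i + min_separation,
                       min(i + max_separation, L) + 1):
            cj = placements[j]
            if not cj:
                continue
            common = ci.keys() & cj.keys()
            if not common:
                continue
            counts = np.zeros(nbins)
            # sorted: accumulation order must not depend on hash seeds,
            # or downstream simulations lose cross-process reproducibility
            for key in sorted(common):
                src, off = key
                a, b = i + off - 1, j + off - 1
                if a < 0 or b >= src_len[src]:
                    continue
                d = float(np.linalg.norm(src_coords[src][a]
                                         - src_coords[src][b]))
                if d < PROFILE_MAX:
                    counts[int(d / PROFILE_BIN)] += ci[key] * cj[key]
            if counts.sum() > 0:
                profiles[(i, j)] = DistanceProfile(i, j, counts)
    return profiles


def write_profiles_tsv(profiles: dict, path) -> None:
    """Serialise profiles as TSV (i, j, bin_centre, count, usable)."""
    with open(path, "w") as fh:
        fh.write("i\tj\tbin_center\tcount\tusable\n")
        for (i, j), prof in sorted(profiles.items()):
            usable = int(prof.usable)
            for b, c in enumerate(prof.counts):
                if c > 0:
                    centre = (b + 0.5) * PROFILE_BIN
                    fh.write(f"{i}\t{j}\t{centre:.2f}\t{c:.1f}\t{usable}\n")
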