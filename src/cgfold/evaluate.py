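"""Decoy clustering, model selection and evaluation metrics.

Clustering follows the largest-cluster-first philosophy: the decoy with
the most neighbours within an RMSD cutoff seeds a cluster, its members
are removed, and the process repeats — the biggest cluster is taken as
the lowest-free-energy basin and ranked first.  Metrics cover contact
precision by sequence-separation range, restraint satisfaction rate,
least-squares Cα RMSD and TM-score with the standard length-dependent
normalisation d0 = 1.24·(L−15)^(1/3) − 1.8 (floored at 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CoarseStructure

#: sequence-separation ranges (CASP convention)
RANGE_BOUNDS = {"short": (6, 11), "medium": (12, 23), "long": (24, 10 ** 9),
                "all": (6, 10 ** 9)}
CONTACT_CUT = 8.0


def kabsch_rmsd(a, b) -> float:
    """Least-squares superposition RMSD over Cα coordinates."""
    pa = a.coords if isinstance(a, CoarseStructure) else np.asarray(a, float)
    pb = b.coords if isinstance(b, CoarseStructure) else np.asarray(b, float)
    if pa.shape != pb.shape:
        raise ValueError("structures have different lengths")
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    H = pa.T @ pb
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    S[-1] *= d
    msd = (np.sum(pa ** 2) + np.sum(pb ** 2) - 2.0 * np.sum(S)) / len(pa)
    return float(np.sqrt(max(msd, 0.0)))


def tm_d0(L: int) -> float:
    """TM-score distance scale for target length L (floored at 0.5)."""
    if L <= 15:
        return 0.5
    return max(1.24 * (L - 15) ** (1.0 / 3.0) - 1.8, 0.5)


def _superpose_on(mobile: np.ndarray, target: np.ndarray,
                  idx: np.ndarray) -> np.ndarray:
    mc = mobile[idx].mean(axis=0)
    tc = target[idx].mean(axis=0)
    H = (mobile[idx] - mc).T @ (target[idx] - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return (mobile - mc) @ R.T + tc


def _tm_from_seeds(model: np.ndarray, native: np.ndarray, d0: float,
                   seeds, max_iter: int = 20) -> float:
    L = len(model)
    best = 0.0
    d0_search = max(d0, 4.5)
    for idx in seeds:
        idx = np.asarray(idx)
        if len(idx) < 3:
            continue
        prev = None
        for _ in range(max_iter):
            sup = _superpose_on(model, native, idx)
            d = np.linalg.norm(sup - native, axis=1)
            score = float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))
            best = max(best, score)
            new_idx = np.flatnonzero(d < d0_search)
            if len(new_idx) < 3:
                break
            if prev is not None and np.array_equal(new_idx, prev):
                break
            prev = idx = new_idx
    return best


def tm_score(model, native, seed_stride: int | None = None) -> float:
    """TM-score of a model against a native structure of equal length.

    The score is maximised over iteratively refined superpositions grown
    from seed windows of several lengths (the standard heuristic); the
    normalising length is the common length.
    """
    ma = model.coords if isinstance(model, CoarseStructure) else np.asarray(model)
    na = native.coords if isinstance(native, CoarseStructure) else np.asarray(native)
    if ma.shape != na.shape:
        raise ValueError("structures have different lengths")
    L = len(ma)
    d0 = tm_d0(L)
    stride = seed_stride or 1
    seeds = [np.arange(L)]
    for w in {L, max(L // 2, 4), max(L // 4, 4), min(8, L), min(5, L)}:
        for start in range(0, L - w + 1, stride):
            seeds.append(np.arange(start, start + w))
    return _tm_from_seeds(ma, na, d0, seeds)


def satisfaction_rate(restraints, s: CoarseStructure) -> float:
    """Fraction of selected restraints realised (Cβ distance < 8 Å)."""
    pairs = restraints.pairs() if hasattr(restraints, "pairs") else np.asarray(restraints)
    if isinstance(pairs, set):
        pairs = np.array(sorted(pairs))
    if len(pairs) == 0:
        raise ValueError("satisfaction rate undefined for empty restraints")
    cb = s.cbeta()
    d = np.linalg.norm(cb[pairs[:, 0] - 1] - cb[pairs[:, 1] - 1], axis=1)
    return float(np.mean(d < CONTACT_CUT))


def native_contacts(native: CoarseStructure, min_sep: int = 6) -> set[tuple[int, int]]:
    """Native contact set: Cβ distance < 8 Å, separation >= min_sep."""
    cb = native.cbeta()
    L = len(native)
    out = set()
    for i in range(L):
        d = np.linalg.norm(cb[i + min_sep:] - cb[i], axis=1)
        for off in np.flatnonzero(d < CONTACT_CUT):
            out.add((i + 1, i + min_sep + off + 1))
    return out


def contact_precision(predicted, native: CoarseStructure,
                      top_k: int | None = None,
                      range_class: str = "all") -> tuple[float, int]:
    """Precision of the top-k most confident predictions in a range class.

    ``predicted`` may be a ContactMap or a RestraintSet.  Returns
    (precision, effective k); when fewer than ``top_k`` predictions exist
    in the class, all of them are used.
    """
    if range_class not in RANGE_BOUNDS:
        raise ValueError(f"unknown range class {range_class!r}")
    lo, hi = RANGE_BOUNDS[range_class]
    if hasattr(predicted, "predictions"):
        recs = [(p.confidence, p.i, p.j) for p in predicted.predictions]
    else:
        recs = [(r.confidence, r.i, r.j) for r in predicted.restraints]
    recs = [(c, i, j) for c, i, j in recs if lo <= j - i <= hi]
    recs.sort(key=lambda t: (-t[0], t[1], t[2]))
    if top_k is not None:
        recs = recs[:top_k]
    if not recs:
        return 0.0, 0
    nat = native_contacts(native, min_sep=min(6, lo))
    hits = sum((i, j) in nat for _, i, j in recs)
    return hits / len(recs), len(recs)


@dataclass
class Cluster:
    members: np.ndarray      # snapshot indices
    centroid: int            # snapshot index of the centroid member
    mean_energy: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    cutoff: float

    def __len__(self) -> int:
        return len(self.clusters)


def _pairwise_rmsd(coords: np.ndarray) -> np.ndarray:
    n = len(coords)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = kabsch_rmsd(coords[i], coords[j])
    return D


def cluster_decoys(coords: np.ndarray, energies: np.ndarray | None = None,
                   rmsd_cutoff_init: float = 3.5, max_clusters: int = 5,
                   target_frac: tuple[float, float] = (0.10, 0.70),
                   ) -> ClusterResult:
    """Iterative densest-ball clustering of decoys by pairwise Cα RMSD.

    The cutoff is auto-scaled within [2.5, 8] Å so the largest cluster
    holds between 10% and 70% of the decoys (when attainable).  Clusters
    are ranked by size, ties by lower mean energy; each centroid is the
    member minimising the summed RMSD to its co-members.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n == 0:
        raise ValueError("no decoys to cluster")
    if energies is None:
        energies = np.zeros(n)
    if n == 1:
        return ClusterResult(
            [Cluster(np.array([0]), 0, float(energies[0]))], rmsd_cutoff_init)

    D = _pairwise_rmsd(coords)
    cutoff = float(np.clip(rmsd_cutoff_init, 2.5, 8.0))
    lo_f, hi_f = target_frac
    for _ in range(30):
        largest = int((D < cutoff).sum(axis=1).max())  # includes self
        frac = largest / n
        if frac < lo_f and cutoff < 8.0:
            cutoff = min(cutoff + 0.25, 8.0)
        elif frac > hi_f and cutoff > 2.5:
            cutoff = max(cutoff - 0.25, 2.5)
        else:
            break

    remaining = np.arange(n)
    clusters: list[Cluster] = []
    while len(remaining) and len(clusters) < max_clusters:
        sub = D[np.ix_(remaining, remaining)]
        neigh = sub < cutoff
        counts = neigh.sum(axis=1)
        seed = int(np.argmax(counts))
        members = remaining[neigh[seed]]
        subm = D[np.ix_(members, members)]
        centroid = int(members[np.argmin(subm.sum(axis=1))])
        clusters.append(Cluster(members, centroid,
                                float(np.mean(energies[members]))))
        mask = ~np.isin(remaining, members)
        remaining = remaining[mask]
    clusters.sort(key=lambda c: (-c.size, c.mean_energy))
    return ClusterResult(clusters, cutoff)


@dataclass
class EvalReport:
    """Evaluation of one model against a native structure."""

    tm: float
    rmsd: float
    precision: dict = field(default_factory=dict)   # range -> (rate, k)
    satisfaction: float | None = None

    def to_dict(self) -> dict:
        out = {"tm_score": self.tm, "ca_rmsd": self.rmsd}
        for rng, (rate, k) in self.precision.items():
            out[f"precision_{rng}"] = rate
            out[f"precision_{rng}_k"] = k
        if self.satisfaction is not None:
            out["satisfaction_rate"] = self.satisfaction
        return out


def evaluate_model(model: CoarseStructure, native: CoarseStructure,
                   restraints=None, predicted=None,
                   top_k: int | None = None) -> EvalReport:
    """TM-score, RMSD and (when inputs are given) contact statistics."""
    rep = EvalReport(tm=tm_score(model, native),
                     rmsd=kabsch_rmsd(model, native))
    if predicted is not None:
        for rng in ("short", "medium", "long", "all"):
            rep.precision[rng] = contact_precision(predicted, native,
                                                   top_k=top_k,
                                                   range_class=rng)
    if restraints is not None and len(restraints) > 0:
        rep.satisfaction = satisfaction_rate(restraints, model)
    return rep
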