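"""Replica-exchange Monte Carlo fragment assembly.

Replicas run at a geometric temperature ladder; each cycle every replica
attempts round(30·√L) local moves under the Metropolis criterion, then
conformations in adjacent replicas are swapped (alternating odd/even
pairing).  The move set has eleven local moves in three levels —
residue-level (M1–M4), segmental (M5–M8, including fragment
substitution) and topology-level (M9–M11) — with level frequencies
annealed toward residue-level moves at low temperature.  Snapshots from
the low-temperature half of the ladder form the decoy set for
clustering.

Every accepted move keeps adjacent Cα distances inside [3.4, 4.2] Å:
rotation-based moves preserve bond lengths exactly, displacement-based
moves are rejected outright when they would break the chain.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .forcefield import EnergyModel
from .fragments import FragmentLibrary
from .geometry import (CA_BOND_MAX, CA_BOND_MIN, CoarseStructure, IDEAL_TAU,
                       IDEAL_THETA, extended_chain, pseudo_angles,
                       rotate_about_axis, superpose, virtual_cbeta)

RESIDUE_MOVES = ("M1", "M2", "M3", "M4")
SEGMENTAL_MOVES = ("M5", "M6", "M7", "M8")
TOPOLOGY_MOVES = ("M9", "M10", "M11")
MOVE_LEVELS = {**{m: "residue" for m in RESIDUE_MOVES},
               **{m: "segmental" for m in SEGMENTAL_MOVES},
               **{m: "topology" for m in TOPOLOGY_MOVES}}


@dataclass(frozen=True)
class MoveSpec:
    """Identity and level of one move type."""

    move_id: str

    @property
    def level(self) -> str:
        return MOVE_LEVELS[self.move_id]


@dataclass
class ReplicaLadder:
    """Strictly increasing replica temperatures."""

    temperatures: np.ndarray

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if len(self.temperatures) < 2:
            raise ValueError("need at least two replicas")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")

    def __len__(self) -> int:
        return len(self.temperatures)


def temperature_ladder(n: int, t_min: float, t_max: float) -> ReplicaLadder:
    """Geometric temperature ladder T_k = T_min·(T_max/T_min)^((k−1)/(n−1))."""
    if n < 2:
        raise ValueError("need at least two replicas")
    if not (0 < t_min < t_max):
        raise ValueError("require 0 < t_min < t_max")
    k = np.arange(n)
    return ReplicaLadder(t_min * (t_max / t_min) ** (k / (n - 1)))


def metropolis_accept(dE: float, T: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(−dE/T))."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if dE <= 0:
        return True
    return bool(rng.random() < np.exp(-dE / T))


def replica_swap(energies: np.ndarray, ladder: ReplicaLadder, parity: int,
                 rng: np.random.Generator) -> list[tuple[int, int]]:
    """Metropolis swaps between adjacent replicas of the given parity.

    Returns the list of accepted swap index pairs; the caller exchanges
    the conformations.  Swap probability is
    min(1, exp((1/T_k − 1/T_{k+1})(E_k − E_{k+1}))).
    """
    T = ladder.temperatures
    accepted = []
    for k in range(parity % 2, len(T) - 1, 2):
        arg = (1.0 / T[k] - 1.0 / T[k + 1]) * (energies[k] - energies[k + 1])
        if arg >= 0 or rng.random() < np.exp(arg):
            accepted.append((k, k + 1))
    return accepted


def _bonds_ok(coords: np.ndarray, idx: np.ndarray) -> bool:
    """Check virtual bonds touching the given residues."""
    L = len(coords)
    lo = max(int(idx.min()) - 1, 0)
    hi = min(int(idx.max()) + 1, L - 1)
    d = np.linalg.norm(coords[lo + 1:hi + 1] - coords[lo:hi], axis=1)
    return bool(np.all((d >= CA_BOND_MIN) & (d <= CA_BOND_MAX)))


def _ss_runs(ss: str) -> list[tuple[int, int]]:
    """Contiguous H/E runs of length >= 3 as 0-based [a, b] inclusive."""
    runs, a = [], None
    for k, s in enumerate(ss + "$"):
        if s in "HE":
            if a is None:
                a = k
        else:
            if a is not None and k - a >= 3:
                runs.append((a, k - 1))
            a = None
    return runs


class MoveEngine:
    """Proposes the eleven local moves on a Cα trace."""

    def __init__(self, sequence: str, ss: str | None = None,
                 flib: FragmentLibrary | None = None):
        self.L = len(sequence)
        self.sequence = sequence
        self.ss = ss or "C" * self.L
        self.flib = flib
        self._runs = _ss_runs(self.ss)
        self._frag_slots = ([k for k in flib.slots if k[1] >= 3 and flib.slots[k]]
                            if flib is not None else [])

    def propose(self, coords: np.ndarray, spec: MoveSpec,
                rng: np.random.Generator, scale: float = 1.0):
        """Return (new_coords, moved_indices) or None on proposal failure.

        ``scale`` multiplies the proposal step size (hot replicas take
        larger steps than cold ones)."""
        fn = getattr(self, "_" + spec.move_id.lower())
        return fn(coords, rng, scale)

    # -- residue level -----------------------------------------------------

    def _m1(self, coords, rng, scale=1.0):
        """Torsion pivot: rotate everything downstream of a virtual bond."""
        L = self.L
        if L < 3:
            return None
        i = int(rng.integers(1, L - 1))
        axis = coords[i] - coords[i - 1]
        angle = rng.normal(0.0, 0.35 * scale)
        new = coords.copy()
        new[i + 1:] = rotate_about_axis(coords[i + 1:], coords[i], axis, angle)
        return new, np.arange(i + 1, L)

    def _m2(self, coords, rng, scale=1.0):
        """Single-residue Cα displacement with chain-closure by rejection."""
        i = int(rng.integers(0, self.L))
        new = coords.copy()
        new[i] = coords[i] + rng.normal(0.0, 0.25 * scale, size=3)
        moved = np.array([i])
        if not _bonds_ok(new, moved):
            return None
        return new, moved

    def _m3(self, coords, rng, scale=1.0):
        """Bond-angle bend: rotate downstream about a random axis through
        one Cα."""
        L = self.L
        if L < 3:
            return None
        i = int(rng.integers(1, L - 1))
        axis = rng.normal(size=3)
        angle = rng.normal(0.0, 0.15 * scale)
        new = coords.copy()
        new[i + 1:] = rotate_about_axis(coords[i + 1:], coords[i], axis, angle)
        return new, np.arange(i + 1, L)

    def _m4(self, coords, rng, scale=1.0):
        """Reset one residue's pseudo-torsion/angle to the ideal value for
        its predicted secondary structure."""
        L = self.L
        if L < 4:
            return None
        i = int(rng.integers(1, L - 3))
        state = self.ss[i] if self.ss[i] in "HE" else "C"
        theta, tau = pseudo_angles(coords)
        new = coords.copy()
        # torsion at i (dihedral over i-1..i+2): rotate about bond i->i+1
        dtau = IDEAL_TAU[state] - tau[i - 1]
        axis = new[i + 1] - new[i]
        new[i + 2:] = rotate_about_axis(new[i + 2:], new[i + 1], axis, dtau)
        # bond angle at i: rotate downstream about the plane normal at i
        theta2, _ = pseudo_angles(new)
        dth = IDEAL_THETA[state] - theta2[i - 1]
        normal = np.cross(new[i - 1] - new[i], new[i + 1] - new[i])
        nrm = np.linalg.norm(normal)
        if nrm < 1e-9:
            return None
        new[i + 1:] = rotate_about_axis(new[i + 1:], new[i], normal / nrm, dth)
        return new, np.arange(i + 1, L)

    # -- segmental level ---------------------------------------------------

    def _m5(self, coords, rng, scale=1.0):
        """Fragment substitution: superpose a library fragment onto the
        current window and swap the window coordinates."""
        if not self._frag_slots:
            return None
        p, ell = self._frag_slots[int(rng.integers(len(self._frag_slots)))]
        frags = self.flib.slots[(p, ell)]
        f = frags[int(rng.integers(min(len(frags), 25)))]
        fc = self.flib.coords(f)
        if len(fc) != ell:
            return None
        a = p - 1
        window = coords[a:a + ell]
        fitted = superpose(fc, window)
        new = coords.copy()
        new[a:a + ell] = fitted
        moved = np.arange(a, a + ell)
        if not _bonds_ok(new, moved):
            return None
        return new, moved

    def _m6(self, coords, rng, scale=1.0):
        """Crankshaft: rotate an interior segment about its anchor axis."""
        L = self.L
        if L < 4:
            return None
        span = int(rng.integers(2, min(15, L - 1)))
        i = int(rng.integers(0, L - span))
        j = i + span
        axis = coords[j] - coords[i]
        if np.linalg.norm(axis) < 1e-9:
            return None
        angle = rng.normal(0.0, 0.6 * scale)
        new = coords.copy()
        new[i + 1:j] = rotate_about_axis(coords[i + 1:j], coords[i], axis, angle)
        return new, np.arange(i + 1, j)

    def _m7(self, coords, rng, scale=1.0):
        """Rigid shift of a short segment, closure by rejection."""
        L = self.L
        span = int(rng.integers(3, min(11, L + 1)))
        i = int(rng.integers(0, L - span + 1))
        new = coords.copy()
        new[i:i + span] += rng.normal(0.0, 0.25 * scale, size=3)
        moved = np.arange(i, i + span)
        if not _bonds_ok(new, moved):
            return None
        return new, moved

    def _m8(self, coords, rng, scale=1.0):
        """Loop wiggle: compose small torsion pivots at three consecutive
        bonds (downstream propagation)."""
        L = self.L
        if L < 5:
            return None
        i = int(rng.integers(1, L - 3))
        new = coords.copy()
        for k in range(i, min(i + 3, L - 1)):
            axis = new[k] - new[k - 1]
            new[k + 1:] = rotate_about_axis(new[k + 1:], new[k], axis,
                                            rng.normal(0.0, 0.2 * scale))
        return new, np.arange(i + 1, L)

    # -- topology level ----------------------------------------------------

    def _m9(self, coords, rng, scale=1.0):
        """Terminal-tail hinge rotation (rigid, large angle)."""
        L = self.L
        if L < 4:
            return None
        if rng.random() < 0.5:  # C-terminal tail
            h = int(rng.integers(L // 2, L - 1))
            tail = np.arange(h + 1, L)
        else:
            h = int(rng.integers(1, max(L // 2, 2)))
            tail = np.arange(0, h)
        if len(tail) == 0:
            return None
        axis = rng.normal(size=3)
        angle = rng.normal(0.0, 0.9 * scale)
        new = coords.copy()
        new[tail] = rotate_about_axis(coords[tail], coords[h], axis, angle)
        return new, tail

    def _m10(self, coords, rng, scale=1.0):
        """Rigid translation of one secondary-structure element."""
        if not self._runs:
            return None
        a, b = self._runs[int(rng.integers(len(self._runs)))]
        new = coords.copy()
        new[a:b + 1] += rng.normal(0.0, 0.5 * scale, size=3)
        moved = np.arange(a, b + 1)
        if not _bonds_ok(new, moved):
            return None
        return new, moved

    def _m11(self, coords, rng, scale=1.0):
        """Rigid rotation of one secondary-structure element about its own
        axis."""
        if not self._runs:
            return None
        a, b = self._runs[int(rng.integers(len(self._runs)))]
        axis = coords[b] - coords[a]
        if np.linalg.norm(axis) < 1e-9:
            return None
        centre = coords[a:b + 1].mean(axis=0)
        angle = rng.normal(0.0, 0.7 * scale)
        new = coords.copy()
        new[a:b + 1] = rotate_about_axis(coords[a:b + 1], centre, axis, angle)
        moved = np.arange(a, b + 1)
        if not _bonds_ok(new, moved):
            return None
        return new, moved


def propose_move(s: CoarseStructure, spec: MoveSpec,
                 rng: np.random.Generator,
                 flib: FragmentLibrary | None = None):
    """Propose one move on a structure.

    Returns (candidate CoarseStructure, moved index array) or None when
    the proposal fails (e.g. closure impossible); the input is never
    modified.
    """
    engine = MoveEngine(s.sequence, s.ss, flib)
    out = engine.propose(s.coords, spec, rng)
    if out is None:
        return None
    new_coords, moved = out
    cand = CoarseStructure(s.sequence, new_coords, ss=s.ss)
    return cand, moved


@dataclass
class Snapshot:
    coords: np.ndarray
    energy: float
    replica: int
    cycle: int


@dataclass
class DecoySet:
    """Simulation snapshots with provenance."""

    sequence: str
    snapshots: list[Snapshot] = field(default_factory=list)
    trajectory: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.snapshots)

    def coords_array(self) -> np.ndarray:
        return np.array([s.coords for s in self.snapshots])

    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.snapshots])


@dataclass
class SamplerConfig:
    """REMC run parameters (desk-scale defaults)."""

    n_replicas: int = 8
    n_cycles: int = 100
    t_min: float = 0.1
    t_max: float = 2.5
    moves_per_cycle: int | None = None    # default round(30·√L)
    snapshot_stride: int = 5
    level_probs_cold: tuple = (0.55, 0.30, 0.15)
    level_probs_hot: tuple = (0.40, 0.35, 0.25)
    wall_clock_seconds: float | None = None
    fragment_move_boost: float = 3.0   # relative weight of M5 within its level

    def validate(self):
        if self.n_replicas < 2:
            raise ValueError("need at least 2 replicas")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        for p in (*self.level_probs_cold, *self.level_probs_hot):
            if p < 0:
                raise ValueError("negative move-level probability")


def production_preset() -> SamplerConfig:
    """Production-scale settings: 40 replicas, 500 cycles."""
    return SamplerConfig(n_replicas=40, n_cycles=500)


def _move_table(cfg: SamplerConfig, frac: float):
    """Move ids and probabilities for a replica at ladder fraction
    ``frac`` (0 = coldest)."""
    pc = np.array(cfg.level_probs_cold, dtype=float)
    ph = np.array(cfg.level_probs_hot, dtype=float)
    lv = pc + (ph - pc) * frac
    lv /= lv.sum()
    ids, probs = [], []
    for level, moves, p in zip(("residue", "segmental", "topology"),
                               (RESIDUE_MOVES, SEGMENTAL_MOVES, TOPOLOGY_MOVES),
                               lv):
        w = np.ones(len(moves))
        if level == "segmental":
            w[0] = cfg.fragment_move_boost   # favour fragment substitution
        w = w / w.sum() * p
        ids.extend(moves)
        probs.extend(w)
    return ids, np.array(probs)


def run_remc(sequence: str, ss, model: EnergyModel,
             flib: FragmentLibrary | None = None,
             config: SamplerConfig | None = None,
             seed: int = 0, monitor_restraints=None) -> DecoySet:
    """Run one replica-exchange Monte Carlo folding simulation.

    ``ss`` may be an SsePrediction or a plain H/E/C string.  Snapshots
    are taken from the cold half of the ladder every
    ``config.snapshot_stride`` cycles; the trajectory log records energy
    and restraint satisfaction of the coldest replica each cycle.
    ``monitor_restraints`` supplies a restraint set to track in the log
    when the model itself carries none (unguided runs).  Deterministic
    for a fixed (config, seed).
    """
    cfg = config or SamplerConfig()
    cfg.validate()
    L = len(sequence)

    ss_states = getattr(ss, "states", ss)
    ss_conf = ss.state_confidence() if hasattr(ss, "state_confidence") else None
    start = extended_chain(sequence, ss_states, ss_conf)

    ladder = temperature_ladder(cfg.n_replicas, cfg.t_min, cfg.t_max)
    n_moves = (cfg.moves_per_cycle if cfg.moves_per_cycle is not None
               else int(round(30.0 * np.sqrt(L))))

    master = np.random.SeedSequence(seed)
    streams = master.spawn(cfg.n_replicas + 1)
    rngs = [np.random.default_rng(s) for s in streams[:-1]]
    swap_rng = np.random.default_rng(streams[-1])

    engine = MoveEngine(sequence, ss_states, flib)
    coords = [start.coords.copy() for _ in range(cfg.n_replicas)]
    energies = np.array([model.energy(c) for c in coords])
    move_tables = [
        _move_table(cfg, k / max(cfg.n_replicas - 1, 1))
        for k in range(cfg.n_replicas)
    ]

    rpairs = model.restraint_pairs
    if len(rpairs) == 0 and monitor_restraints is not None:
        rpairs = monitor_restraints.pairs() - 1
    decoys = DecoySet(sequence=sequence,
                      provenance={"seed": seed, "n_replicas": cfg.n_replicas,
                                  "n_cycles": cfg.n_cycles,
                                  "moves_per_cycle": n_moves})
    cold_half = max(cfg.n_replicas // 2, 1)
    t0 = time.monotonic()

    if cfg.n_cycles == 0:
        for k in range(cold_half):
            decoys.snapshots.append(
                Snapshot(coords[k].copy(), float(energies[k]), k, 0))
        return decoys

    # step sizes scale with temperature: cold replicas refine, hot ones roam
    t_mid = np.sqrt(ladder.temperatures[0] * ladder.temperatures[-1])
    step_scales = np.clip(np.sqrt(ladder.temperatures / t_mid), 0.4, 2.5)

    for cycle in range(1, cfg.n_cycles + 1):
        for k in range(cfg.n_replicas):
            rng = rngs[k]
            T = ladder.temperatures[k]
            scale = step_scales[k]
            ids, probs = move_tables[k]
            ck = coords[k]
            picks = rng.choice(len(ids), size=n_moves, p=probs)
            for pick in picks:
                out = engine.propose(ck, MoveSpec(ids[pick]), rng, scale)
                if out is None:
                    continue
                new_coords, moved = out
                dE = model.delta(ck, new_coords, moved)
                if metropolis_accept(dE, T, rng):
                    ck = new_coords
                    energies[k] += dE
            coords[k] = ck

        for a, b in replica_swap(energies, ladder, cycle % 2, swap_rng):
            coords[a], coords[b] = coords[b], coords[a]
            energies[a], energies[b] = energies[b], energies[a]

        # trajectory log for the coldest replica
        entry = {"cycle": cycle, "energy": float(energies[0])}
        if len(rpairs):
            cb = virtual_cbeta(coords[0], sequence)
            d = np.linalg.norm(cb[rpairs[:, 0]] - cb[rpairs[:, 1]], axis=1)
            entry["satisfaction"] = float(np.mean(d < 8.0))
        decoys.trajectory.append(entry)

        if cycle % cfg.snapshot_stride == 0 or cycle == cfg.n_cycles:
            for k in range(cold_half):
                e_full = model.energy(coords[k])
                energies[k] = e_full   # absorb incremental drift
                decoys.snapshots.append(
                    Snapshot(coords[k].copy(), e_full, k, cycle))

        if (cfg.wall_clock_seconds is not None
                and time.monotonic() - t0 > cfg.wall_clock_seconds):
            break

    return decoys
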