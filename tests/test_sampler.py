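"""Replica-exchange machinery: ladder, acceptance, swaps, moves,
determinism and flat-energy invariants."""

import numpy as np
import pytest

from cgfold.forcefield import EnergyModel, Weights
from cgfold.geometry import CA_BOND_MAX, CA_BOND_MIN
from cgfold.sampler import (MoveEngine, MoveSpec, SamplerConfig,
                            metropolis_accept, propose_move, replica_swap,
                            run_remc, temperature_ladder)


class TestLadder:
    def test_two_replicas_are_the_endpoints(self):
        lad = temperature_ladder(2, 1.0, 4.0)
        assert np.allclose(lad.temperatures, [1.0, 4.0])

    def test_three_replicas_geometric_mean(self):
        lad = temperature_ladder(3, 1.0, 4.0)
        assert np.allclose(lad.temperatures, [1.0, 2.0, 4.0])

    def test_forty_replicas_increasing_with_exact_endpoints(self):
        lad = temperature_ladder(40, 0.2, 3.7)
        t = lad.temperatures
        assert len(t) == 40
        assert t[0] == pytest.approx(0.2) and t[-1] == pytest.approx(3.7)
        assert np.all(np.diff(t) > 0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            temperature_ladder(5, 2.0, 1.0)
        with pytest.raises(ValueError):
            temperature_ladder(1, 1.0, 2.0)


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-1.0, 1.0, rng) for _ in range(100))

    def test_acceptance_rate_at_ln2(self):
        """dE = T·ln2 accepts with probability 1/2."""
        rng = np.random.default_rng(1)
        T = 1.7
        n = 10 ** 5
        acc = sum(metropolis_accept(T * np.log(2), T, rng) for _ in range(n))
        assert acc / n == pytest.approx(0.5, abs=0.01)

    def test_huge_uphill_rejected(self):
        rng = np.random.default_rng(2)
        assert not any(metropolis_accept(1e3, 1.0, rng) for _ in range(100))


class TestReplicaSwap:
    def _ladder(self):
        return temperature_ladder(2, 1.0, 2.0)

    def test_energy_inversion_always_swaps(self):
        rng = np.random.default_rng(0)
        lad = self._ladder()
        assert replica_swap(np.array([5.0, 1.0]), lad, 0, rng) == [(0, 1)]

    def test_equal_energies_always_swap(self):
        rng = np.random.default_rng(0)
        lad = self._ladder()
        assert replica_swap(np.array([2.0, 2.0]), lad, 0, rng) == [(0, 1)]

    def test_swap_rate_at_minus_ln2(self):
        """(1/T1 − 1/T2)(E1 − E2) = −ln 2 swaps at rate 1/2."""
        lad = self._ladder()
        dE = -np.log(2) / (1.0 / 1.0 - 1.0 / 2.0)
        energies = np.array([0.0, -dE])
        rng = np.random.default_rng(3)
        n = 10 ** 5
        hits = sum(bool(replica_swap(energies, lad, 0, rng)) for _ in range(n))
        assert hits / n == pytest.approx(0.5, abs=0.01)


class TestMoves:
    def test_m1_moves_only_downstream(self, bundle):
        native, _ = bundle
        rng = np.random.default_rng(0)
        out = propose_move(native, MoveSpec("M1"), rng)
        cand, moved = out
        pivot = moved.min()
        assert np.allclose(cand.coords[:pivot], native.coords[:pivot])
        assert not np.allclose(cand.coords[pivot:], native.coords[pivot:])

    def test_m9_tail_is_rigid(self, bundle):
        native, _ = bundle
        rng = np.random.default_rng(1)
        for _ in range(10):
            out = propose_move(native, MoveSpec("M9"), rng)
            if out is None:
                continue
            cand, moved = out
            sub_old = native.coords[moved]
            sub_new = cand.coords[moved]
            d_old = np.linalg.norm(sub_old[:, None] - sub_old[None], axis=-1)
            d_new = np.linalg.norm(sub_new[:, None] - sub_new[None], axis=-1)
            assert np.allclose(d_old, d_new, atol=1e-9)

    def test_m5_respects_bond_bounds(self, bundle, bundle_fragments):
        native, _ = bundle
        rng = np.random.default_rng(2)
        seen = 0
        for _ in range(50):
            out = propose_move(native, MoveSpec("M5"), rng,
                               flib=bundle_fragments)
            if out is None:
                continue
            cand, moved = out
            d = np.linalg.norm(np.diff(cand.coords, axis=0), axis=1)
            assert np.all((d >= CA_BOND_MIN) & (d <= CA_BOND_MAX))
            seen += 1
        assert seen > 0

    def test_move_levels(self):
        assert MoveSpec("M2").level == "residue"
        assert MoveSpec("M5").level == "segmental"
        assert MoveSpec("M11").level == "topology"

    def test_input_never_modified(self, bundle):
        native, _ = bundle
        before = native.coords.copy()
        rng = np.random.default_rng(3)
        for mid in ("M1", "M2", "M6", "M9"):
            propose_move(native, MoveSpec(mid), rng)
        assert np.array_equal(native.coords, before)


class TestFlatEnergy:
    def test_all_moves_accepted_and_bonds_hold(self, bundle, bundle_sse):
        """With all weights zero every proposal that passes its own
        closure check is accepted, and chain bonds stay within bounds."""
        native, _ = bundle
        w = Weights(w_con=0, w_dp=0, w_ca=0, w_ev=0, w_ss=0, w_rg=0)
        model = EnergyModel(native.sequence, weights=w)
        engine = MoveEngine(native.sequence, native.ss)
        rng = np.random.default_rng(4)
        coords = native.coords.copy()
        moves = ["M1", "M2", "M3", "M4", "M6", "M7", "M8", "M9", "M10", "M11"]
        accepted = attempted = 0
        for k in range(10 ** 4):
            out = engine.propose(coords, MoveSpec(moves[k % 10]), rng)
            if out is None:
                continue
            attempted += 1
            nc, moved = out
            dE = model.delta(coords, nc, moved)
            if metropolis_accept(dE, 1.0, rng):
                accepted += 1
                coords = nc
        assert accepted == attempted
        d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        assert np.all((d >= CA_BOND_MIN) & (d <= CA_BOND_MAX))


class TestRunRemc:
    def _tiny_cfg(self):
        return SamplerConfig(n_replicas=2, n_cycles=4, snapshot_stride=2)

    def test_moves_per_cycle_default(self, bundle, bundle_sse,
                                     bundle_restraints):
        native, _ = bundle
        model = EnergyModel(native.sequence, restraints=bundle_restraints)
        d = run_remc(native.sequence, bundle_sse, model, None,
                     self._tiny_cfg(), seed=0)
        assert d.provenance["moves_per_cycle"] == round(30 * np.sqrt(52))

    def test_zero_cycles_returns_initial_states(self, bundle, bundle_sse):
        native, _ = bundle
        model = EnergyModel(native.sequence)
        cfg = SamplerConfig(n_replicas=2, n_cycles=0)
        d = run_remc(native.sequence, bundle_sse, model, None, cfg, seed=0)
        assert len(d) == 1  # cold half of a 2-replica ladder
        assert d.snapshots[0].cycle == 0

    def test_same_seed_bitwise_identical(self, bundle, bundle_sse,
                                         bundle_restraints):
        native, _ = bundle
        model = EnergyModel(native.sequence, restraints=bundle_restraints)
        d1 = run_remc(native.sequence, bundle_sse, model, None,
                      self._tiny_cfg(), seed=9)
        d2 = run_remc(native.sequence, bundle_sse, model, None,
                      self._tiny_cfg(), seed=9)
        assert len(d1) == len(d2)
        for a, b in zip(d1.snapshots, d2.snapshots):
            assert np.array_equal(a.coords, b.coords)
            assert a.energy == b.energy

    def test_snapshot_energies_match_reevaluation(self, bundle, bundle_sse,
                                                  bundle_restraints):
        native, _ = bundle
        model = EnergyModel(native.sequence, restraints=bundle_restraints)
        d = run_remc(native.sequence, bundle_sse, model, None,
                     self._tiny_cfg(), seed=3)
        for snap in d.snapshots:
            assert snap.energy == pytest.approx(model.energy(snap.coords),
                                                abs=1e-6)

    def test_wall_clock_cap_stops_early(self, bundle, bundle_sse,
                                        bundle_restraints):
        native, _ = bundle
        model = EnergyModel(native.sequence, restraints=bundle_restraints)
        cfg = SamplerConfig(n_replicas=2, n_cycles=500, snapshot_stride=1,
                            wall_clock_seconds=0.0)
        d = run_remc(native.sequence, bundle_sse, model, None, cfg, seed=0)
        assert max(s.cycle for s in d.snapshots) < 500

    def test_replica_energies_ordered_with_temperature(self, bundle,
                                                       bundle_sse,
                                                       bundle_restraints):
        """After burn-in, mean snapshot energy does not decrease with
        replica temperature."""
        native, _ = bundle
        model = EnergyModel(native.sequence, restraints=bundle_restraints)
        cfg = SamplerConfig(n_replicas=4, n_cycles=30, snapshot_stride=2)
        d = run_remc(native.sequence, bundle_sse, model, None, cfg, seed=5)
        by_rep = {}
        for s in d.snapshots:
            if s.cycle > 15:
                by_rep.setdefault(s.replica, []).append(s.energy)
        means = [np.mean(by_rep[k]) for k in sorted(by_rep)]
        assert means[0] <= means[-1] + 1e-9
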