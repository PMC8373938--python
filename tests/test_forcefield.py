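"""Composite energy: 3G contact potential, profile term, chain terms,
and the incremental-evaluation oracle."""

import numpy as np
import pytest

from cgfold import forcefield as ff
from cgfold.forcefield import EnergyModel, Perturbation, ThreeGParams, Weights
from cgfold.fragments import DistanceProfile
from cgfold.geometry import CoarseStructure, extended_chain
from cgfold.sampler import MoveEngine, MoveSpec
from cgfold.selection import Restraint, RestraintSet

GRID = [(U, db) for U in (0.1, 1.0, 5.0) for db in (6.0, 9.0, 12.0)]


class TestThreeG:
    @pytest.mark.parametrize("U,db", GRID)
    def test_plateaus_and_midpoints(self, U, db):
        p = ThreeGParams(d_b=db, U=U)
        D = p.D
        assert ff.econ(5.0, p) == -U
        assert ff.econ(85.0, p) == U
        assert ff.econ((8 + D) / 2, p) == pytest.approx(-U / 2, abs=1e-12)
        assert ff.econ((D + 80) / 2, p) == pytest.approx(U / 2, abs=1e-12)

    @pytest.mark.parametrize("U,db", GRID)
    def test_continuity_and_zero_slope_at_transitions(self, U, db):
        p = ThreeGParams(d_b=db, U=U)
        h = 1e-5
        for x in (8.0, p.D, 80.0):
            left, right = ff.econ(x - h, p), ff.econ(x + h, p)
            assert abs(left - right) < 1e-6 * U
            slope = (right - left) / (2 * h)
            assert abs(slope) < 1e-6 * U

    @pytest.mark.parametrize("U,db", GRID)
    def test_monotone_nondecreasing_between_wells(self, U, db):
        p = ThreeGParams(d_b=db, U=U)
        d = np.arange(8.0, 80.0, 0.01)
        e = ff.econ(d, p)
        assert np.all(np.diff(e) >= -1e-12)
        assert np.all(e >= -U - 1e-12) and np.all(e <= U + 1e-12)

    @pytest.mark.parametrize("U,db", GRID)
    def test_inner_force_stronger_than_outer(self, U, db):
        """The pull toward the well is stronger on (8, D) than on (D, 80)
        at mirrored offsets."""
        p = ThreeGParams(d_b=db, U=U)
        h = 1e-6
        for frac in (0.25, 0.5, 0.75):
            din = 8.0 + frac * (p.D - 8.0)
            dout = p.D + frac * (80.0 - p.D)
            fin = abs(ff.econ(din + h, p) - ff.econ(din - h, p)) / (2 * h)
            fout = abs(ff.econ(dout + h, p) - ff.econ(dout - h, p)) / (2 * h)
            assert fin > fout

    def test_transition_at_d_from_both_branches(self):
        p = ThreeGParams(d_b=6.0, U=1.0)
        assert ff.econ(p.D, p) == pytest.approx(0.0, abs=1e-12)
        assert ff.econ(p.D - 1e-9, p) == pytest.approx(0.0, abs=1e-6)


class TestGradientWidth:
    @pytest.mark.parametrize("L,db", [(80, 6.0), (99, 6.0), (250, 12.0),
                                      (201, 12.0), (150, 9.0)])
    def test_schedule(self, L, db):
        assert ff.gradient_width(L) == pytest.approx(db)

    def test_monotone_in_length(self):
        vals = [ff.gradient_width(L) for L in range(50, 300)]
        assert vals == sorted(vals)


class TestCaPenalty:
    @pytest.mark.parametrize("d,e", [(3.8, 0.0), (4.0, 0.0), (5.0, 1.0)])
    def test_ramp(self, d, e):
        assert ff.e_ca(d) == pytest.approx(e)


class TestProfileTerm:
    def _profile(self):
        counts = np.zeros(80)
        counts[12] = 200.0   # mode at 6.25 A
        counts[13] = 50.0
        return DistanceProfile(1, 9, counts)

    def test_modal_bin_scores_zero(self):
        prof = self._profile()
        assert ff.e_dp(prof.peak, prof) == pytest.approx(0.0, abs=1e-9)

    def test_empty_bin_penalty_matches_closed_form(self):
        counts = np.zeros(80)
        counts[2] = 200.0    # support starts early; far bins empty
        prof = DistanceProfile(1, 9, counts)
        table, _ = ff.profile_energy_table(prof)
        hmax = max(np.convolve(counts, _kernel(), mode="same"))
        expected = -np.log(1e-3 / (hmax + 1e-3))
        assert table[30] == pytest.approx(expected, rel=1e-6)

    def test_outside_support_scores_zero(self):
        prof = self._profile()
        assert ff.e_dp(25.0, prof) == 0.0
        assert ff.e_dp(0.4, prof) == 0.0   # below first populated bin

    def test_unusable_profile_rejected(self):
        counts = np.zeros(80)
        counts[24] = 10.0    # mode at 12.25 A
        prof = DistanceProfile(1, 9, counts)
        assert not prof.usable
        with pytest.raises(ValueError):
            ff.e_dp(5.0, prof)


def _kernel():
    k = np.exp(-0.5 * (np.arange(-3, 4) / 1.5) ** 2)
    return k / k.sum()


def _simple_model(L=20, with_restraints=True, weights=None):
    seq = "A" * L
    restraints = None
    if with_restraints:
        rs = [Restraint(2, 10, 0.9, 0.9, "x", "very_high"),
              Restraint(5, 15, 0.5, 0.5, "x", "very_high")]
        restraints = RestraintSet(L, rs)
    return EnergyModel(seq, restraints=restraints, weights=weights, d_b=6.0)


class TestTotalEnergy:
    def test_satisfied_restraints_give_minus_sum_of_depths(self):
        L = 20
        m = _simple_model(L, weights=Weights(w_con=1.0, w_dp=0, w_ca=0,
                                             w_ev=0, w_ss=0, w_rg=0))
        # compact blob: all pairwise distances < 8
        rng = np.random.default_rng(0)
        coords = rng.normal(0, 1.2, (L, 3))
        s = CoarseStructure("A" * L, coords)
        bd = ff.total_energy(s, m)
        assert bd.total == pytest.approx(-(0.9 + 0.5))

    def test_extended_chain_has_zero_break_penalty(self):
        s = extended_chain("A" * 30)
        m = EnergyModel("A" * 30, weights=Weights(w_con=0, w_dp=0, w_ca=1.0,
                                                  w_ev=0, w_ss=0, w_rg=0))
        assert ff.total_energy(s, m).total == pytest.approx(0.0)

    def test_zero_weights_give_zero_terms(self, bundle):
        native, _ = bundle
        w = Weights(w_con=0, w_dp=0, w_ca=0, w_ev=0, w_ss=0, w_rg=0)
        m = EnergyModel(native.sequence, weights=w)
        bd = ff.total_energy(native, m)
        assert bd.total == 0.0
        assert all(v == 0.0 for v in bd.terms.values())

    def test_breakdown_sums_to_total(self, bundle, bundle_restraints,
                                     bundle_sse):
        native, _ = bundle
        m = EnergyModel(native.sequence, restraints=bundle_restraints,
                        sse=bundle_sse)
        bd = ff.total_energy(native, m)
        assert bd.total == pytest.approx(sum(bd.terms.values()), rel=1e-9)

    def test_rigid_motion_invariance(self, bundle, bundle_restraints,
                                     bundle_sse):
        from scipy.spatial.transform import Rotation
        native, _ = bundle
        m = EnergyModel(native.sequence, restraints=bundle_restraints,
                        sse=bundle_sse)
        e0 = m.energy(native.coords)
        R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        moved = native.coords @ R.T + np.array([5.0, -3.0, 11.0])
        assert m.energy(moved) == pytest.approx(e0, abs=1e-8)

    def test_length_mismatch_rejected(self, bundle):
        native, _ = bundle
        m = _simple_model(20)
        with pytest.raises(ValueError):
            ff.total_energy(native, m)


class TestDeltaEnergy:
    def test_null_move_is_zero(self, bundle, bundle_restraints, bundle_sse):
        native, _ = bundle
        m = EnergyModel(native.sequence, restraints=bundle_restraints,
                        sse=bundle_sse)
        move = Perturbation(native.coords.copy(), np.array([5]))
        assert ff.delta_energy(native, m, move) == pytest.approx(0.0, abs=1e-12)

    def test_matches_full_recomputation_over_random_moves(
            self, bundle, bundle_restraints, bundle_sse, bundle_fragments):
        """Incremental and full evaluation agree to 1e-8 for every move
        type, including fragment swaps."""
        native, _ = bundle
        m = EnergyModel(native.sequence, restraints=bundle_restraints,
                        sse=bundle_sse)
        engine = MoveEngine(native.sequence, native.ss, bundle_fragments)
        rng = np.random.default_rng(1)
        coords = native.coords.copy()
        moves = ["M1", "M2", "M3", "M4", "M5", "M6", "M7", "M8", "M9",
                 "M10", "M11"]
        checked = 0
        for k in range(300):
            out = engine.propose(coords, MoveSpec(moves[k % 11]), rng)
            if out is None:
                continue
            new_coords, moved = out
            dE = m.delta(coords, new_coords, moved)
            full = m.energy(new_coords) - m.energy(coords)
            assert dE == pytest.approx(full, abs=1e-8)
            checked += 1
            if k % 3 == 0:
                coords = new_coords
        assert checked > 150

    def test_reference_path_agrees_with_kernel(self, bundle,
                                               bundle_restraints, bundle_sse):
        native, _ = bundle
        m = EnergyModel(native.sequence, restraints=bundle_restraints,
                        sse=bundle_sse)
        engine = MoveEngine(native.sequence, native.ss)
        rng = np.random.default_rng(2)
        coords = native.coords.copy()
        for k in range(40):
            out = engine.propose(coords, MoveSpec("M6"), rng)
            if out is None:
                continue
            nc, moved = out
            assert m.delta(coords, nc, moved) == pytest.approx(
                m.delta_reference(coords, nc, moved), abs=1e-9)
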