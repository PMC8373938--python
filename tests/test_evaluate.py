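"""Evaluation metrics and decoy clustering, checked against independent
oracles (quaternion superposition; exhaustive-seed TM search)."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cgfold import evaluate
from cgfold.evaluate import (cluster_decoys, contact_precision, kabsch_rmsd,
                             satisfaction_rate, tm_d0, tm_score)
from cgfold.formats import ContactMap, ContactPrediction
from cgfold.geometry import CoarseStructure
from cgfold.selection import Restraint, RestraintSet


from tests_support_oracles import quaternion_rmsd, tm_brute_force


@pytest.fixture(scope="module")
def decoy_pairs(bundle):
    native, _ = bundle
    rng = np.random.default_rng(7)
    pairs = []
    for k in range(20):
        a = native.coords + rng.normal(0, 0.5 + 0.2 * (k % 5), native.coords.shape)
        b = native.coords + rng.normal(0, 0.5 + 0.3 * (k % 3), native.coords.shape)
        pairs.append((a, b))
    return pairs


class TestKabsch:
    def test_identical_structures(self, bundle):
        native, _ = bundle
        assert kabsch_rmsd(native, native) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_rotation_gives_zero(self, bundle):
        native, _ = bundle
        R = Rotation.from_rotvec([0.4, 1.2, -0.6]).as_matrix()
        moved = CoarseStructure(native.sequence,
                                native.coords @ R.T + [3, -7, 2])
        assert kabsch_rmsd(native, moved) == pytest.approx(0.0, abs=1e-6)

    def test_agrees_with_quaternion_oracle(self, decoy_pairs):
        rng = np.random.default_rng(11)
        checked = 0
        for a, b in decoy_pairs:
            assert kabsch_rmsd(a, b) == pytest.approx(quaternion_rmsd(a, b),
                                                      abs=1e-6)
            checked += 1
        # additional random clouds, 50 pairs total
        for _ in range(50 - checked):
            a = rng.normal(0, 5, (30, 3))
            b = rng.normal(0, 5, (30, 3))
            assert kabsch_rmsd(a, b) == pytest.approx(quaternion_rmsd(a, b),
                                                      abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((5, 3)), np.zeros((6, 3)))


class TestTmScore:
    def test_identity_is_one(self, bundle):
        native, _ = bundle
        assert tm_score(native, native) == pytest.approx(1.0)

    def test_rigid_motion_is_one(self, bundle):
        native, _ = bundle
        R = Rotation.from_rotvec([-0.9, 0.1, 0.5]).as_matrix()
        moved = CoarseStructure(native.sequence,
                                native.coords @ R.T + [1, 2, 3])
        assert tm_score(native, moved) == pytest.approx(1.0, abs=1e-9)

    def test_d0_for_length_100(self):
        assert tm_d0(100) == pytest.approx(1.24 * 85 ** (1 / 3) - 1.8,
                                           abs=1e-6)
        assert tm_d0(10) == 0.5

    def test_agrees_with_brute_force_oracle(self, decoy_pairs):
        for a, b in decoy_pairs:
            assert tm_score(a, b) == pytest.approx(tm_brute_force(a, b),
                                                   abs=1e-3)

    def test_at_least_single_superposition_bound(self, decoy_pairs):
        for a, b in decoy_pairs[:5]:
            d0 = tm_d0(len(a))
            sup = evaluate._superpose_on(a, b, np.arange(len(a)))
            d = np.linalg.norm(sup - b, axis=1)
            lower = np.mean(1.0 / (1.0 + (d / d0) ** 2))
            assert tm_score(a, b) >= lower - 1e-9

    def test_symmetric_for_equal_lengths(self, decoy_pairs):
        for a, b in decoy_pairs[:5]:
            assert tm_score(a, b) == pytest.approx(tm_score(b, a), abs=2e-3)


class TestSatisfaction:
    def _rs(self, L, pairs):
        return RestraintSet(L, [Restraint(i, j, 1.0, 1.0, "x", "high")
                                for i, j in pairs])

    def test_hand_counted_case(self):
        # residues far apart along a straight line; pick pairs at 7, 9, 6 A
        coords = np.zeros((30, 3))
        coords[:, 0] = np.arange(30) * 3.8
        s = CoarseStructure("G" * 30, coords)  # glycine: Cb = Ca
        cb = s.cbeta()
        assert np.array_equal(cb, coords)
        # craft distances via direct placement
        coords[9] = coords[0] + [7.0, 0, 0]
        coords[19] = coords[10] + [9.0, 0, 0]
        coords[29] = coords[20] + [6.0, 0, 0]
        rs = self._rs(30, [(1, 10), (11, 20), (21, 30)])
        assert satisfaction_rate(rs, s) == pytest.approx(2 / 3)

    def test_all_and_none(self, bundle):
        native, nmap = bundle
        pairs = sorted(nmap.pairs())[:10]
        rs = self._rs(len(native), pairs)
        assert satisfaction_rate(rs, native) == 1.0
        stretched = CoarseStructure(native.sequence, native.coords * 10.0)
        assert satisfaction_rate(rs, stretched) == 0.0

    def test_empty_restraints_rejected(self, bundle):
        native, _ = bundle
        with pytest.raises(ValueError):
            satisfaction_rate(RestraintSet(len(native), []), native)

    def test_rigid_motion_invariance(self, bundle, bundle_restraints):
        native, _ = bundle
        R = Rotation.from_rotvec([0.2, 0.4, 0.8]).as_matrix()
        moved = CoarseStructure(native.sequence,
                                native.coords @ R.T + [10, 0, -4])
        assert satisfaction_rate(bundle_restraints, moved) == pytest.approx(
            satisfaction_rate(bundle_restraints, native))


class TestContactPrecision:
    def test_exact_native_map_scores_one(self, bundle):
        native, nmap = bundle
        for rng_class in ("short", "medium", "long", "all"):
            rate, k = contact_precision(nmap, native, range_class=rng_class)
            if k:
                assert rate == 1.0

    def test_top5_with_two_native(self, bundle):
        native, nmap = bundle
        nat = sorted(nmap.pairs())
        good = [p for p in nat if p[1] - p[0] >= 6][:2]
        bad = [(1, 40), (2, 45), (3, 50)]
        bad = [p for p in bad if p not in set(nat)][:3]
        preds = ([ContactPrediction(i, j, 0.9) for i, j in good]
                 + [ContactPrediction(i, j, 0.8) for i, j in bad])
        cmap = ContactMap(len(native), preds, "x")
        rate, k = contact_precision(cmap, native, top_k=5, range_class="all")
        assert k == 5
        assert rate == pytest.approx(len(good) / 5)

    def test_planted_precision_recovered(self, bundle):
        from cgfold.synthetic import CorruptionSpec, corrupt_contacts
        native, nmap = bundle
        spec = CorruptionSpec(precision=0.3, coverage=1.0, seed=8)
        corrupted = corrupt_contacts(nmap, spec)
        rate, k = contact_precision(corrupted, native, range_class="all")
        n = len(corrupted)
        assert rate == pytest.approx(round(0.3 * n) / n, abs=1e-9)

    def test_top_k_larger_than_pool_uses_all(self, bundle):
        native, nmap = bundle
        rate, k = contact_precision(nmap, native, top_k=10 ** 6,
                                    range_class="all")
        assert k == len([p for p in nmap.predictions if p.separation >= 6])


class TestClustering:
    def test_identical_decoys_form_one_cluster(self):
        coords = np.tile(np.random.default_rng(0).normal(0, 5, (20, 3)),
                         (100, 1, 1))
        res = cluster_decoys(coords)
        assert len(res.clusters) == 1
        assert res.clusters[0].size == 100

    def test_single_decoy(self):
        coords = np.random.default_rng(1).normal(0, 5, (1, 20, 3))
        res = cluster_decoys(coords)
        assert len(res.clusters) == 1 and res.clusters[0].size == 1

    def test_planted_70_30_mixture_recovered(self, bundle):
        """Two well-separated conformations with 0.5 A jitter cluster into
        exactly the planted 70/30 split with correct ranking."""
        native, _ = bundle
        rng = np.random.default_rng(2)
        other = native.coords[::-1].copy()  # reversed trace: far from native
        decoys, labels = [], []
        for k in range(100):
            if k < 70:
                decoys.append(native.coords + rng.normal(0, 0.5,
                                                         native.coords.shape))
                labels.append(0)
            else:
                decoys.append(other + rng.normal(0, 0.5, other.shape))
                labels.append(1)
        res = cluster_decoys(np.array(decoys))
        assert res.clusters[0].size == 70
        assert res.clusters[1].size == 30
        assert all(labels[m] == 0 for m in res.clusters[0].members)
        assert all(labels[m] == 1 for m in res.clusters[1].members)

    def test_ranking_breaks_ties_by_energy(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 8, (15, 3))
        b = rng.normal(0, 8, (15, 3))  # unrelated shape: large RMSD to a
        decoys, energies = [], []
        for k in range(20):
            decoys.append(a + rng.normal(0, 0.3, a.shape))
            energies.append(5.0)
        for k in range(20):
            decoys.append(b + rng.normal(0, 0.3, b.shape))
            energies.append(-5.0)
        res = cluster_decoys(np.array(decoys), np.array(energies))
        assert res.clusters[0].size == res.clusters[1].size == 20
        assert res.clusters[0].mean_energy < res.clusters[1].mean_energy

    def test_precision_invariant_under_rigid_motion(self, bundle):
        native, nmap = bundle
        R = Rotation.from_rotvec([1.0, -0.2, 0.3]).as_matrix()
        moved = CoarseStructure(native.sequence,
                                native.coords @ R.T + [4, 4, 4])
        a, _ = contact_precision(nmap, native, range_class="all")
        b, _ = contact_precision(nmap, moved, range_class="all")
        assert a == b
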