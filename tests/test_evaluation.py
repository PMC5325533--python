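import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import fisher_exact

from aquabridge.evaluation import (
    ContingencyTable2x2,
    boschloo_test,
    consensus_waters,
    gini_split_cutoff,
    kendall_tau,
    match_predictions,
    superpose,
)
from aquabridge.structure_io import ProteinStructure, WaterRecord


def toy_protein(coords):
    coords = np.asarray(coords, float).reshape(-1, 3)
    n = len(coords)
    return ProteinStructure(
        serial=np.arange(1, n + 1), name=["O"] * n, residue_name=["PSA"] * n,
        residue_id=np.arange(1, n + 1), chain=["A"] * n, element=["O"] * n,
        coords=coords, occupancy=np.ones(n),
    )


def cryst(coords, tag):
    return WaterRecord(coords=coords, source="crystallographic", structure_tag=tag)


class TestConsensusWaters:
    def setup_method(self):
        self.protein = toy_protein([[0.0, 0, 0]])
        self.ligand = np.array([[3.0, 0, 0]])

    def test_shared_water_is_consensus(self):
        w = [1.5, 0.0, 0.0]  # 1.5 A from both protein and ligand atoms
        structures = [
            (self.protein, self.ligand, [cryst(w, "a")]),
            (self.protein, self.ligand, [cryst(w, "b")]),
        ]
        (c,) = consensus_waters(structures)
        np.testing.assert_allclose(c.coords, w)
        assert c.supporting_structures == {"a", "b"}

    def test_single_structure_support_excluded(self):
        structures = [
            (self.protein, self.ligand, [cryst([1.5, 0, 0], "a")]),
            (self.protein, self.ligand, []),
        ]
        assert consensus_waters(structures) == []

    def test_water_too_far_from_ligand_not_candidate(self):
        w = [-3.0, 0.0, 0.0]  # 3.0 A from protein but 6.0 A from ligand
        structures = [
            (self.protein, self.ligand, [cryst(w, "a")]),
            (self.protein, self.ligand, [cryst(w, "b")]),
        ]
        assert consensus_waters(structures) == []

    def test_nearby_candidates_merge_to_centroid(self):
        structures = [
            (self.protein, self.ligand, [cryst([1.4, 0, 0], "a")]),
            (self.protein, self.ligand, [cryst([1.6, 0, 0], "b")]),
        ]
        (c,) = consensus_waters(structures)
        np.testing.assert_allclose(c.coords, [1.5, 0, 0])

    def test_fewer_than_two_structures_rejected(self):
        with pytest.raises(ValueError):
            consensus_waters([(self.protein, self.ligand, [])])


class TestMatchPredictions:
    def test_simple_true_positive(self):
        r = match_predictions([np.array([1.9, 0, 0])], [np.array([0.0, 0, 0])], 2.0)
        assert (r.n_true_positive, r.n_false_positive) == (1, 0)
        assert r.mean_error == pytest.approx(1.9)

    def test_chaining_counts_one_tp_one_fp(self):
        """Two predictions flanking one reference water: greedy one-to-one
        matching credits one and charges the other as a false positive."""
        preds = [np.array([1.0, 0, 0]), np.array([-1.5, 0, 0])]
        r = match_predictions(preds, [np.array([0.0, 0, 0])], 2.0)
        assert (r.n_true_positive, r.n_false_positive) == (1, 1)
        assert r.mean_error == pytest.approx(1.0)  # the closer one matched

    def test_no_predictions(self):
        r = match_predictions([], [np.array([0.0, 0, 0])], 2.0)
        assert (r.n_true_positive, r.n_false_positive) == (0, 0)

    def test_stricter_radius_flips_match(self):
        preds = [np.array([1.7, 0, 0])]
        cons = [np.array([0.0, 0, 0])]
        assert match_predictions(preds, cons, 2.0).n_true_positive == 1
        assert match_predictions(preds, cons, 1.4).n_true_positive == 0

    def test_relabeling_and_jitter_stability(self, rng):
        preds = [rng.uniform(0, 10, 3) for _ in range(6)]
        cons = [p + rng.uniform(-1, 1, 3) for p in preds[:4]]
        a = match_predictions(preds, cons, 2.0)
        jit = [c + 1e-10 for c in reversed(cons)]
        b = match_predictions(preds, jit, 2.0)
        assert (a.n_true_positive, a.n_false_positive) == \
            (b.n_true_positive, b.n_false_positive)


class TestGiniSplit:
    def test_perfectly_separable(self):
        t = gini_split_cutoff([-1.0, -0.9, -0.1, 0.0], [True, True, False, False])
        assert t == pytest.approx(-0.5)

    def test_matches_brute_force_on_random_sets(self, rng):
        """Stump threshold equals an exhaustive O(n^2) impurity scan."""
        for _ in range(5):
            scores = rng.normal(-0.5, 0.5, size=200)
            conserved = scores + rng.normal(0, 0.4, size=200) < -0.5

            def brute(scores, labels):
                s = np.sort(np.unique(scores))
                best = (np.inf, None)
                for t in (s[:-1] + s[1:]) / 2:
                    left = labels[scores <= t]
                    right = labels[scores > t]
                    gini = lambda l: 2 * l.mean() * (1 - l.mean()) if len(l) else 0.0
                    imp = (len(left) * gini(left) + len(right) * gini(right)) / len(scores)
                    if imp < best[0] - 1e-15:
                        best = (imp, t)
                return best[1]

            if conserved.all() or (~conserved).all():
                continue
            assert gini_split_cutoff(scores, conserved) == \
                pytest.approx(brute(scores, conserved))

    def test_matches_sklearn_stump(self, rng):
        """Cross-check against an independent depth-1 decision tree."""
        from sklearn.tree import DecisionTreeClassifier

        scores = rng.normal(-0.5, 0.4, size=120)
        conserved = (scores < -0.45) ^ (rng.uniform(size=120) < 0.1)
        t = gini_split_cutoff(scores, conserved)
        clf = DecisionTreeClassifier(max_depth=1, criterion="gini")
        clf.fit(scores.reshape(-1, 1), conserved)
        # sklearn stores features as float32, so thresholds agree to ~1e-6
        assert t == pytest.approx(float(clf.tree_.threshold[0]), abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            gini_split_cutoff([-1.0, -0.5], [True, True])


class TestKendall:
    def test_perfect_concordance(self):
        tau, _ = kendall_tau([1, 2, 3, 4], [10, 20, 30, 40])
        assert tau == pytest.approx(1.0)

    def test_perfect_discordance(self):
        tau, _ = kendall_tau([1, 2, 3, 4], [40, 30, 20, 10])
        assert tau == pytest.approx(-1.0)

    def test_matches_pair_counting_oracle_with_ties(self, rng):
        """tau-b equals direct O(n^2) concordant/discordant counting."""
        x = rng.integers(0, 10, size=50).astype(float)
        y = rng.integers(0, 10, size=50).astype(float)
        nc = nd = tx = ty = 0
        for i in range(50):
            for j in range(i + 1, 50):
                dx, dy = x[i] - x[j], y[i] - y[j]
                if dx == 0 and dy == 0:
                    continue
                if dx == 0:
                    tx += 1
                elif dy == 0:
                    ty += 1
                elif dx * dy > 0:
                    nc += 1
                else:
                    nd += 1
        expected = (nc - nd) / np.sqrt((nc + nd + tx) * (nc + nd + ty))
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(expected, abs=1e-12)

    def test_exact_small_sample_p(self):
        """For n <= 8 without ties the p-value is the exact permutation
        tail: for n=4, perfect concordance has p = 2/4! * 2 ... compare to
        enumeration."""
        import itertools

        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 3.0, 2.0, 4.0]
        tau_obs, p = kendall_tau(x, y)
        taus = []
        for perm in itertools.permutations(y):
            t, _ = kendall_tau(x, list(perm))
            taus.append(t)
        exact = np.mean([abs(t) >= abs(tau_obs) - 1e-12 for t in taus])
        assert p == pytest.approx(exact, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 2], [1, 2, 3])


class TestBoschloo:
    def test_false_positive_worked_example(self):
        """8 false among 100 predictions vs 19 among 114, one-sided."""
        p = boschloo_test(ContingencyTable2x2(8, 92, 19, 95), "less")
        assert p == pytest.approx(0.033, abs=5e-4)

    def test_true_positive_worked_example(self):
        p = boschloo_test(ContingencyTable2x2(92, 8, 95, 19), "less")
        assert p == pytest.approx(0.979, abs=5e-4)

    @given(
        n1=st.integers(2, 12), n2=st.integers(2, 12),
        data=st.data(),
    )
    def test_at_least_as_powerful_as_fisher(self, n1, n2, data):
        a = data.draw(st.integers(0, n1))
        c = data.draw(st.integers(0, n2))
        table = ContingencyTable2x2(a, n1 - a, c, n2 - c)
        p = boschloo_test(table, "less", grid_points=201)
        assert 0.0 < p <= 1.0
        fisher = fisher_exact([[a, n1 - a], [c, n2 - c]], alternative="less")[1]
        assert p <= fisher + 1e-9

    def test_monotone_in_observed_count(self):
        ps = [boschloo_test(ContingencyTable2x2(a, 20 - a, 10, 10), "less")
              for a in range(0, 8)]
        assert all(x <= y + 1e-12 for x, y in zip(ps, ps[1:]))

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 3, 4)


def test_superpose_recovers_rigid_motion(rng):
    from scipy.spatial.transform import Rotation

    ref = rng.normal(size=(8, 3))
    rot = Rotation.from_euler("xyz", [10, 40, -30], degrees=True).as_matrix()
    mobile = (ref - ref.mean(0)) @ rot + ref.mean(0) + [1.0, -2.0, 0.5]
    r, t, rmsd = superpose(mobile, ref)
    np.testing.assert_allclose(mobile @ r.T + t, ref, atol=1e-8)
    assert rmsd < 1e-8
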