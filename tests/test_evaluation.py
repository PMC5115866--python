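import itertools

import networkx as nx
import numpy as np
import pytest

from ppilr.core import InputError, PairKey, Protein, ReferenceSets
from ppilr.evaluation import (ComplexDefinition, build_compartment_negatives,
                              complex_recovery_lr, probability_true_vs_lr,
                              random_complex_null, recovery_curve,
                              recovery_fraction, roc_curve,
                              seeded_member_prediction, shared_label_fraction)


def _pairs(names):
    return {PairKey(a, b) for a, b in names}


def _score_map(pos_scores, neg_scores):
    """Labelled pairs with given score lists; returns (scores, refs)."""
    scores, pos, neg = {}, set(), set()
    for i, s in enumerate(pos_scores):
        p = PairKey(f"p{i}", f"q{i}")
        scores[p] = s
        pos.add(p)
    for i, s in enumerate(neg_scores):
        p = PairKey(f"u{i}", f"v{i}")
        scores[p] = s
        neg.add(p)
    return scores, ReferenceSets(pos, neg, role="evaluate")


def _auc_oracle(pos_scores, neg_scores):
    """Brute-force rank statistic: P(pos > neg) + 0.5 P(tie)."""
    wins = ties = 0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))


class TestRocCurve:
    def test_perfect_separation(self):
        scores, refs = _score_map([10, 9, 8], [1, 2, 3])
        assert roc_curve(scores, refs).auc == 1.0

    def test_no_discrimination(self):
        scores, refs = _score_map([5, 5], [5, 5])
        assert roc_curve(scores, refs).auc == 0.5

    def test_frozen_oracle_example(self):
        pos, neg = [3, 2], [1, 0, 0.5, 2.5]
        assert _auc_oracle(pos, neg) == 0.875  # enumeration of 8 comparisons
        scores, refs = _score_map(pos, neg)
        assert roc_curve(scores, refs).auc == pytest.approx(0.875)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            pos = list(rng.integers(0, 8, size=rng.integers(2, 10)))
            neg = list(rng.integers(0, 8, size=rng.integers(2, 10)))
            scores, refs = _score_map(pos, neg)
            assert roc_curve(scores, refs).auc == \
                pytest.approx(_auc_oracle(pos, neg), abs=1e-12)

    def test_unscored_pairs_count_as_unit_lr(self):
        scores, refs = _score_map([10.0], [0.1])
        extra = PairKey("zz", "zy")
        refs.negatives.add(extra)  # never scored -> behaves as LR = 1
        curve = roc_curve(scores, refs)
        assert curve.auc == 1.0
        # threshold just above 1 keeps the unscored negative out of FP
        tprs = {t: (tpr, fpr) for t, tpr, fpr in curve.points}
        assert tprs[1.0][1] == 0.0

    def test_tpr_fpr_definitions(self):
        scores, refs = _score_map([3, 1], [2, 0])
        points = {t: (tpr, fpr) for t, tpr, fpr in roc_curve(scores, refs).points}
        assert points[2.0] == (0.5, 0.0)  # only pos=3 above; neg 2 not (strict)
        assert points[1.0] == (0.5, 0.5)

    def test_curve_monotone(self):
        rng = np.random.default_rng(1)
        scores, refs = _score_map(list(rng.random(20)), list(rng.random(20)))
        pts = roc_curve(scores, refs).points
        for (t1, tpr1, fpr1), (t2, tpr2, fpr2) in zip(pts, pts[1:]):
            assert t2 <= t1 and tpr2 >= tpr1 and fpr2 >= fpr1
        assert pts[0][1:] == (0.0, 0.0)
        assert pts[-1][1:] == (1.0, 1.0)

    def test_requires_eval_role_and_nonempty(self):
        scores, refs = _score_map([1], [0])
        with pytest.raises(InputError):
            roc_curve(scores, ReferenceSets(refs.positives, refs.negatives,
                                            "train"))
        with pytest.raises(InputError):
            roc_curve(scores, ReferenceSets(set(), refs.negatives, "evaluate"))


class TestRecoveryFraction:
    def test_all_above(self):
        scores = {PairKey("a", "b"): 700.0, PairKey("c", "d"): 900.0}
        assert recovery_fraction(set(scores), scores, 600) == 1.0

    def test_none_scored(self):
        assert recovery_fraction({PairKey("a", "b")}, {}, 600) == 0.0

    def test_three_of_four(self):
        pairs = [PairKey(f"a{i}", f"b{i}") for i in range(4)]
        scores = {pairs[0]: 700, pairs[1]: 800, pairs[2]: 601, pairs[3]: 600}
        assert recovery_fraction(set(pairs), scores, 600) == 0.75

    def test_empty_set_error(self):
        with pytest.raises(InputError):
            recovery_fraction(set(), {}, 600)


def _proteins(spec):
    return [Protein(id=pid, compartments=frozenset(comps))
            for pid, comps in spec]


class TestCompartmentNegatives:
    RULES = [("m", "n"), ("n", "t"), ("n", "e"), ("t", "e")]

    def test_small_enumeration(self):
        prots = _proteins([("m1", {"m"}), ("m2", {"m"}), ("n1", {"n"}),
                           ("t1", {"t"}), ("e1", {"e"})])
        pairs = build_compartment_negatives(
            prots, {"m": 2, "n": 1, "t": 1, "e": 1}, self.RULES, seed=0)
        assert len(pairs) == 5  # 2*1 + 1*1 + 1*1 + 1*1

    def test_dual_annotated_excluded(self):
        prots = _proteins([("m1", {"m"}), ("dual", {"m", "n"}), ("n1", {"n"})])
        pairs = build_compartment_negatives(
            prots, {"m": 1, "n": 1}, [("m", "n")], seed=0)
        assert pairs == {PairKey("m1", "n1")}

    def test_explicit_exclusions(self):
        prots = _proteins([("m1", {"m"}), ("m2", {"m"}), ("n1", {"n"})])
        pairs = build_compartment_negatives(
            prots, {"m": 1, "n": 1}, [("m", "n")], exclusions={"m1"}, seed=0)
        assert pairs == {PairKey("m2", "n1")}

    def test_unsatisfiable_quota_names_compartment(self):
        prots = _proteins([("m1", {"m"}), ("n1", {"n"})])
        with pytest.raises(InputError, match="'m'"):
            build_compartment_negatives(prots, {"m": 2, "n": 1},
                                        [("m", "n")], seed=0)

    def test_deterministic(self):
        prots = _proteins([(f"m{i}", {"m"}) for i in range(20)]
                          + [(f"n{i}", {"n"}) for i in range(20)])
        a = build_compartment_negatives(prots, {"m": 5, "n": 5},
                                        [("m", "n")], seed=42)
        b = build_compartment_negatives(prots, {"m": 5, "n": 5},
                                        [("m", "n")], seed=42)
        assert a == b
        c = build_compartment_negatives(prots, {"m": 5, "n": 5},
                                        [("m", "n")], seed=43)
        assert a != c

    def test_full_scale_pair_count(self):
        # quotas 2000/500/500/383 under the four cross rules
        spec = [(f"m{i}", {"m"}) for i in range(2000)]
        spec += [(f"n{i}", {"n"}) for i in range(500)]
        spec += [(f"t{i}", {"t"}) for i in range(500)]
        spec += [(f"e{i}", {"e"}) for i in range(383)]
        pairs = build_compartment_negatives(
            _proteins(spec), {"m": 2000, "n": 500, "t": 500, "e": 383},
            self.RULES, seed=0)
        assert len(pairs) == 2000 * 500 + 500 * 500 + 500 * 383 + 500 * 383
        assert len(pairs) == 1_633_000


class TestSharedLabelFraction:
    def test_all_shared(self):
        labels = {"a": {"x"}, "b": {"x"}, "c": {"x", "y"}}
        res = shared_label_fraction(_pairs([("a", "b"), ("b", "c")]), labels)
        assert res.fraction == 1.0
        assert res.per_label["x"] == 1.0

    def test_disjoint(self):
        labels = {"a": {"x"}, "b": {"y"}}
        assert shared_label_fraction(_pairs([("a", "b")]), labels).fraction == 0.0

    def test_counted_fraction(self):
        labels = {}
        pairs = set()
        for i in range(100):
            a, b = f"a{i:03d}", f"b{i:03d}"
            pairs.add(PairKey(a, b))
            labels[a] = {"L"}
            labels[b] = {"L"} if i < 89 else {"M"}
        assert shared_label_fraction(pairs, labels).fraction == 0.89

    def test_empty_error(self):
        with pytest.raises(InputError):
            shared_label_fraction(set(), {})


class TestProbabilityTrueVsLr:
    def test_pure_positive_bin(self):
        scores = {PairKey("a", "b"): 700.0}
        out = probability_true_vs_lr(scores, set(scores), [(600, 1000)])
        assert out[(600, 1000)] == 1.0

    def test_partial_bin(self):
        scores = {PairKey(f"a{i}", f"b{i}"): 50.0 for i in range(8)}
        positives = set(list(sorted(scores, key=lambda p: p.a))[:2])
        out = probability_true_vs_lr(scores, positives, [(0, 100)])
        assert out[(0, 100)] == 0.25

    def test_empty_bin_absent(self):
        scores = {PairKey("a", "b"): 5.0}
        out = probability_true_vs_lr(scores, set(), [(0, 1), (2, 10)])
        assert (0, 1) not in out and (2, 10) in out


def _recovery_oracle(members, scores):
    """Threshold sweep using networkx connectivity."""
    weights = {}
    for u, v in itertools.combinations(sorted(members), 2):
        weights[(u, v)] = scores.get(PairKey(u, v), 0.0)
    best = None
    for t in sorted(set(weights.values()), reverse=True):
        g = nx.Graph()
        g.add_nodes_from(members)
        g.add_edges_from(e for e, w in weights.items() if w >= t)
        if nx.is_connected(g):
            best = t
            break
    return 0.0 if best is None else best


class TestComplexRecovery:
    def test_three_member_bottleneck(self):
        scores = {PairKey("A", "B"): 1000.0, PairKey("B", "C"): 700.0,
                  PairKey("A", "C"): 10.0}
        c = ComplexDefinition("c1", frozenset("ABC"))
        assert complex_recovery_lr(c, scores) == 700.0
        assert _recovery_oracle({"A", "B", "C"}, scores) == 700.0

    def test_two_member(self):
        c = ComplexDefinition("c2", frozenset(["A", "B"]))
        assert complex_recovery_lr(c, {PairKey("A", "B"): 850.0}) == 850.0

    def test_isolated_member(self):
        c = ComplexDefinition("c3", frozenset(["A", "B", "C"]))
        scores = {PairKey("A", "B"): 900.0}  # C has no edges at all
        assert complex_recovery_lr(c, scores) == 0.0

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(5)
        universe = [f"P{i}" for i in range(30)]
        for _ in range(50):
            size = int(rng.integers(2, 9))
            members = list(rng.choice(universe, size=size, replace=False))
            scores = {}
            for u, v in itertools.combinations(sorted(members), 2):
                if rng.random() < 0.7:
                    scores[PairKey(u, v)] = float(rng.integers(0, 2000))
            c = ComplexDefinition("c", frozenset(members))
            assert complex_recovery_lr(c, scores) == \
                _recovery_oracle(set(members), scores)

    def test_min_members(self):
        with pytest.raises(InputError):
            ComplexDefinition("bad", frozenset(["A"]))


class TestRandomComplexNull:
    def _world(self):
        rng = np.random.default_rng(9)
        universe = [f"P{i:03d}" for i in range(60)]
        scores = {}
        for u, v in itertools.combinations(universe, 2):
            if rng.random() < 0.02:
                scores[PairKey(u, v)] = float(rng.integers(1, 2000))
        complexes = [ComplexDefinition(f"c{i}", frozenset(
            rng.choice(universe, size=5, replace=False))) for i in range(20)]
        return universe, scores, complexes

    def test_sparse_null_not_recovered_at_reliable_cutoff(self):
        universe, scores, complexes = self._world()
        curve = dict(random_complex_null(complexes, universe, scores, seed=1,
                                         thresholds=[600.0]))
        assert curve[600.0] <= 0.05

    def test_threshold_zero_full_recovery(self):
        universe = ["A", "B", "C", "D"]
        scores = {PairKey(u, v): 5.0
                  for u, v in itertools.combinations(universe, 2)}
        complexes = [ComplexDefinition("c", frozenset(["A", "B", "C"]))]
        curve = dict(random_complex_null(complexes, universe, scores, seed=0,
                                         thresholds=[0.0]))
        assert curve[0.0] == 1.0

    def test_seed_determinism(self):
        universe, scores, complexes = self._world()
        a = random_complex_null(complexes, universe, scores, seed=3)
        b = random_complex_null(complexes, universe, scores, seed=3)
        assert a == b

    def test_universe_too_small(self):
        with pytest.raises(InputError):
            random_complex_null(
                [ComplexDefinition("c", frozenset(["A", "B"]))],
                ["A", "B"], {}, seed=0)


class TestSeededMemberPrediction:
    def test_clean_recovery(self):
        members = ["A", "B", "C", "D", "E"]
        c = ComplexDefinition("c", frozenset(members))
        scores = {PairKey("A", m): 1000.0 for m in members[1:]}
        res = seeded_member_prediction(c, ("A", "B"), scores)
        assert res.found_all
        assert res.rank_of_last_member == len(members) - 2

    def test_member_below_threshold(self):
        c = ComplexDefinition("c", frozenset(["A", "B", "C"]))
        scores = {PairKey("A", "C"): 100.0}
        res = seeded_member_prediction(c, ("A", "B"), scores)
        assert not res.found_all
        assert res.rank_of_last_member is None

    def test_interleaved_distractors_hand_ranked(self):
        c = ComplexDefinition("c", frozenset(["A", "B", "m1", "m2", "m3"]))
        scores = {
            PairKey("A", "m1"): 5000.0,
            PairKey("A", "x1"): 4000.0,
            PairKey("B", "m2"): 3000.0,
            PairKey("A", "x2"): 2000.0,
            PairKey("B", "m3"): 1500.0,
        }
        res = seeded_member_prediction(c, ("A", "B"), scores, k=5)
        assert res.candidates == ["m1", "x1", "m2", "x2", "m3"]
        assert res.found_all
        assert res.rank_of_last_member == 5
        assert res.within_k

    def test_tie_breaks_lexicographic(self):
        c = ComplexDefinition("c", frozenset(["A", "B", "z", "a"]))
        scores = {PairKey("A", "z"): 700.0, PairKey("B", "a"): 700.0}
        res = seeded_member_prediction(c, ("A", "B"), scores)
        assert res.candidates == ["a", "z"]

    def test_seed_not_in_complex(self):
        c = ComplexDefinition("c", frozenset(["A", "B"]))
        with pytest.raises(InputError):
            seeded_member_prediction(c, ("A", "X"), {})


class TestRecoveryCurveOnWorld:
    def test_real_complexes_beat_null(self, small_world, small_lrs):
        real = dict(recovery_curve(small_world.complexes, small_lrs,
                                   thresholds=[600.0]))
        null = dict(random_complex_null(
            small_world.complexes, sorted(small_world.proteins), small_lrs,
            seed=0, thresholds=[600.0]))
        assert null[600.0] <= 0.02
        assert real[600.0] > null[600.0] + 0.3
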