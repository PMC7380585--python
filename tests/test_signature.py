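"""Signature training: ranking, breakpoint, ensemble, cutoff, typing."""

import numpy as np
import pandas as pd
import pytest

from fecalsig.signature import (
    ClassifierType,
    CutoffResult,
    GiniRanking,
    breakpoint_select,
    calibrate_cutoff,
    classify_type,
    gini_ranking,
    one_vs_rest_labels,
    renormalize,
    train_ensemble,
    voting_probability,
)


def oracle_cutoff(probs, labels, min_perf=0.70):
    """Independent brute-force calibration oracle.

    Same candidate set and stated objective/tie-break as the production
    code, implemented naively: feasibility sens,spec >= min_perf; maximize
    min(sens, spec); ties -> higher sens, higher spec, larger margin to the
    nearest observed probability, lower cutoff.
    """
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    uniq = sorted(set(probs))
    candidates = set(np.arange(1, 101) / 100.0)
    for a, b in zip(uniq, uniq[1:]):
        candidates.add((a + b) / 2)
    best, best_key = None, None
    for c in sorted(candidates):
        called = probs > c
        pos, neg = labels == 1, labels == 0
        sens = called[pos].sum() / pos.sum()
        spec = (~called[neg]).sum() / neg.sum()
        if sens < min_perf or spec < min_perf:
            continue
        margin = min(abs(u - c) for u in uniq)
        key = (min(sens, spec), sens, spec, margin, -c)
        if best_key is None or key > best_key:
            best_key, best = key, (c, sens, spec)
    return best


class TestOneVsRest:
    def test_focal_positive_everything_else_negative(self):
        labels = pd.Series(
            {"a1": "sewage", "a2": "sewage", "b1": "dog", "c1": "pig"}
        )
        y = one_vs_rest_labels(labels, "sewage")
        assert y.to_dict() == {"a1": 1, "a2": 1, "b1": 0, "c1": 0}

    def test_single_source_errors(self):
        with pytest.raises(ValueError):
            one_vs_rest_labels(pd.Series({"a": "dog", "b": "dog"}), "dog")

    def test_composite_diet_labels(self):
        labels = pd.Series({"c1": "cattle", "d1": "deer", "h1": "horse"})
        y = one_vs_rest_labels(labels, ["cattle", "deer"])
        assert y.to_dict() == {"c1": 1, "d1": 1, "h1": 0}

    def test_absent_focal_errors(self):
        with pytest.raises(ValueError, match="absent"):
            one_vs_rest_labels(pd.Series({"a": "dog", "b": "pig"}), "sewage")


class TestGiniRanking:
    def _planted(self, rng, n_signal=10, n_noise=90, n_samples=40):
        """Signal ASVs present only in positives; noise everywhere."""
        y = pd.Series([1] * (n_samples // 2) + [0] * (n_samples // 2),
                      index=[f"s{i}" for i in range(n_samples)])
        X = rng.integers(50, 150, size=(n_samples, n_signal + n_noise)).astype(float)
        X[y.to_numpy() == 0, :n_signal] = 0
        cols = [f"asv{i}" for i in range(n_signal + n_noise)]
        return pd.DataFrame(X, index=y.index, columns=cols), y

    def test_planted_features_take_top_ranks(self, rng):
        table, y = self._planted(rng)
        ranking = gini_ranking(table, y, n_replicates=5, n_trees=50, seed=0)
        top10 = set(ranking.importances.nlargest(10).index)
        assert top10 == {f"asv{i}" for i in range(10)}

    def test_all_zero_feature_has_zero_importance(self, rng):
        table, y = self._planted(rng, n_noise=20)
        table["dead"] = 0.0
        ranking = gini_ranking(table, y, n_replicates=3, n_trees=20, seed=0)
        assert ranking.importances["dead"] == 0.0

    def test_same_seed_identical_ranking(self, rng):
        table, y = self._planted(rng, n_noise=20)
        r1 = gini_ranking(table, y, n_replicates=3, n_trees=20, seed=5)
        r2 = gini_ranking(table, y, n_replicates=3, n_trees=20, seed=5)
        assert r1.importances.equals(r2.importances)

    def test_single_class_errors(self, rng):
        table, y = self._planted(rng, n_noise=10)
        with pytest.raises(ValueError):
            gini_ranking(table, (y * 0) + 1, n_replicates=2, n_trees=10)


def exhaustive_breakpoint(values):
    """Oracle: split index minimizing two-segment SSE (means as fits)."""
    v = np.sort(np.asarray(values, float))[::-1]
    best_k, best_sse = None, np.inf
    for k in range(1, len(v)):
        left, right = v[:k], v[k:]
        sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if sse < best_sse:
            best_k, best_sse = k, sse
    return best_k


class TestBreakpointSelect:
    def _ranking(self, values, ids=None):
        ids = ids or [f"a{i}" for i in range(len(values))]
        return GiniRanking(pd.Series(values, index=ids), 1, 1)

    def test_two_level_importances_select_the_high_block(self, rng):
        vals = np.concatenate([
            5.0 + rng.normal(0, 0.05, 20), 0.01 + rng.normal(0, 0.002, 480)
        ])
        ranking = self._ranking(vals)
        selected, fallback = breakpoint_select(ranking)
        assert not fallback
        assert set(selected) == {f"a{i}" for i in range(20)}
        assert exhaustive_breakpoint(vals) == 20

    def test_feature_order_invariance(self, rng):
        vals = np.concatenate([5 + rng.normal(0, 0.1, 10), rng.normal(0.01, 0.001, 50)])
        ids = [f"a{i}" for i in range(60)]
        r1 = self._ranking(vals, ids)
        perm = rng.permutation(60)
        r2 = self._ranking(vals[perm], [ids[i] for i in perm])
        s1, _ = breakpoint_select(r1)
        s2, _ = breakpoint_select(r2)
        assert set(s1) == set(s2)

    def test_geometric_decay_falls_back_with_warning(self):
        vals = 0.5 ** np.arange(60)
        with pytest.warns(UserWarning, match="no breakpoint"):
            selected, fallback = breakpoint_select(self._ranking(vals))
        assert fallback
        # smallest head carrying >= 90% of the mass
        k = len(selected)
        assert vals[:k].sum() / vals.sum() >= 0.90
        assert vals[: k - 1].sum() / vals.sum() < 0.90

    def test_single_asv_selected_trivially(self):
        selected, fallback = breakpoint_select(self._ranking([3.0]))
        assert selected == ["a0"] and not fallback


class TestEnsemble:
    def _tiny(self, rng, n=24, p=6):
        y = pd.Series([1] * (n // 2) + [0] * (n // 2), index=[f"s{i}" for i in range(n)])
        X = rng.integers(10, 100, size=(n, p)).astype(float)
        X[y.to_numpy() == 0, : p // 2] = 0
        X[y.to_numpy() == 1, p // 2:] = 0
        return pd.DataFrame(X, index=y.index, columns=[f"a{i}" for i in range(p)]), y

    def test_renormalized_profiles_sum_to_one(self):
        t = pd.DataFrame([[30.0, 10.0, 0.0]], index=["s"], columns=list("abc"))
        out = renormalize(t)
        assert out.loc["s"].tolist() == pytest.approx([0.75, 0.25, 0.0])

    def test_zero_profile_is_flagged_and_left_zero(self):
        t = pd.DataFrame([[0.0, 0.0]], index=["s"], columns=list("ab"))
        with pytest.warns(UserWarning, match="no reads"):
            out = renormalize(t)
        assert out.loc["s"].sum() == 0.0

    def test_pooled_tree_count(self, rng):
        table, y = self._tiny(rng)
        ens = train_ensemble(table, y, n_replicates=4, n_trees=25, seed=0)
        assert ens.n_trees == 100

    def test_same_seed_identical_votes(self, rng):
        table, y = self._tiny(rng)
        q = np.array([0.5, 0.3, 0.2, 0.0, 0.0, 0.0])
        e1 = train_ensemble(table, y, n_replicates=3, n_trees=20, seed=9)
        e2 = train_ensemble(table, y, n_replicates=3, n_trees=20, seed=9)
        assert voting_probability(e1, q) == voting_probability(e2, q)

    def test_vote_fraction_definition(self, rng):
        """The voting probability equals positive tree votes / total trees."""
        table, y = self._tiny(rng)
        ens = train_ensemble(table, y, n_replicates=2, n_trees=15, seed=1)
        q = np.array([0.4, 0.4, 0.2, 0.0, 0.0, 0.0])[None, :]
        votes = 0
        for forest in ens.forests:
            for tree in forest.estimators_:
                cls = forest.classes_[np.argmax(tree.predict_proba(q), axis=1)][0]
                votes += cls == 1
        assert voting_probability(ens, q[0]) == pytest.approx(votes / ens.n_trees)
        held_out_pos = np.array([0.6, 0.2, 0.2, 0.0, 0.0, 0.0])
        assert voting_probability(ens, held_out_pos) > 0.5


class TestCalibrateCutoff:
    def test_separated_scores_reach_perfect_performance(self):
        probs = [0.60, 0.75, 0.90, 0.10, 0.05, 0.02]
        labels = [1, 1, 1, 0, 0, 0]
        res = calibrate_cutoff(probs, labels)
        assert res.defined
        assert 0.10 < res.cutoff <= 0.60
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_inverted_scores_are_undefined(self):
        res = calibrate_cutoff([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert not res.defined

    def test_coincident_single_scores_undefined(self):
        res = calibrate_cutoff([0.5, 0.5], [1, 0])
        assert not res.defined

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            calibrate_cutoff([0.5, 0.6], [1, 1])

    def test_matches_exhaustive_oracle_on_random_vectors(self, rng):
        for trial in range(300):
            n = int(rng.integers(4, 30))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # mix of well-separated, noisy and coarse-grained scores
            kind = trial % 3
            if kind == 0:
                probs = rng.random(n)
            elif kind == 1:
                probs = np.round(rng.random(n), 1)
            else:
                probs = np.clip(labels * 0.6 + rng.normal(0, 0.3, n), 0, 1)
            expected = oracle_cutoff(probs, labels)
            got = calibrate_cutoff(probs, labels)
            if expected is None:
                assert not got.defined, f"trial {trial}"
            else:
                assert got.defined, f"trial {trial}"
                assert got.cutoff == pytest.approx(expected[0], abs=1e-12)
                assert got.sensitivity == pytest.approx(expected[1])
                assert got.specificity == pytest.approx(expected[2])


class TestClassifyType:
    @pytest.mark.parametrize(
        "cutoff,expected",
        [
            (0.14, ClassifierType.GLOBAL),
            (0.11, ClassifierType.GLOBAL),
            (0.10, ClassifierType.DRAFT),
            (0.09, ClassifierType.DRAFT),
            (0.06, ClassifierType.DRAFT),
            (0.05, ClassifierType.DISCARDED),
            (0.04, ClassifierType.DISCARDED),
            (None, ClassifierType.DISCARDED),
        ],
    )
    def test_typing_boundaries(self, cutoff, expected):
        assert classify_type(cutoff) is expected
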