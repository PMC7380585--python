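"""Cohort screening, Bray-Curtis, train/test split, subgroup detection."""

import numpy as np
import pandas as pd
import pytest

from fecalsig.cohort import (
    InsufficientCohortError,
    SourceCohort,
    bray_curtis,
    bray_curtis_matrix,
    build_cohort,
    detect_subgroups,
    flag_extreme_outliers,
    flag_low_depth,
    mean_intrasource_bc,
    split_train_test,
)


def dirichlet_table(rng, n_samples, n_asvs, depth=10_000, conc=50.0, prefix="s"):
    rows = {}
    for i in range(n_samples):
        p = rng.dirichlet(np.full(n_asvs, conc))
        rows[f"{prefix}{i:03d}"] = rng.multinomial(depth, p)
    return pd.DataFrame.from_dict(rows, orient="index")


class TestBrayCurtis:
    def test_identical_samples_are_zero(self):
        assert bray_curtis([3, 1, 0], [3, 1, 0]) == pytest.approx(0.0)

    def test_disjoint_supports_are_one(self):
        assert bray_curtis([5, 0, 2, 0], [0, 3, 0, 9]) == pytest.approx(1.0)

    def test_closed_form_on_relative_abundances(self):
        assert bray_curtis([0.5, 0.5, 0.0], [0.5, 0.0, 0.5]) == pytest.approx(0.5)

    def test_depth_invariance(self):
        # relative-abundance convention: scaling one sample changes nothing
        assert bray_curtis([10, 30], [100, 300]) == pytest.approx(0.0)

    def test_all_zero_sample_errors(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [1, 2])

    def test_matrix_is_symmetric_zero_diagonal(self, rng):
        table = dirichlet_table(rng, 6, 20)
        dm = bray_curtis_matrix(table)
        assert np.allclose(dm, dm.T)
        assert np.allclose(np.diag(dm), 0.0)


class TestLowDepth:
    def test_planted_shallow_sample_excluded(self):
        totals = {f"s{i}": 10_000 for i in range(9)}
        totals["shallow"] = 10
        assert flag_low_depth(totals) == ["shallow"]

    def test_equal_totals_exclude_nothing(self):
        assert flag_low_depth({f"s{i}": 5_000 for i in range(8)}) == []

    def test_fewer_than_four_samples_warns_and_skips(self):
        with pytest.warns(UserWarning, match="3 samples"):
            out = flag_low_depth({"a": 10, "b": 10_000, "c": 9_000})
        assert out == []

    def test_quartile_rule_matches_oracle(self, rng):
        totals = pd.Series(
            10 ** rng.normal(4, 0.2, size=30), index=[f"s{i}" for i in range(30)]
        )
        logs = np.log10(totals.to_numpy())
        q1, q3 = np.quantile(logs, [0.25, 0.75])
        expected = sorted(totals.index[logs < q1 - 1.5 * (q3 - q1)])
        assert sorted(flag_low_depth(totals)) == expected


class TestExtremeOutliers:
    def test_planted_outlier_recovered(self, rng):
        table = dirichlet_table(rng, 12, 30)
        # one sample from a disjoint community: mean BC ~1 vs ~0.1 others
        alien = pd.DataFrame(
            [np.concatenate([np.zeros(30), [5_000, 5_000]])],
            index=["alien"], columns=range(32),
        )
        full = pd.concat([table.reindex(columns=range(32), fill_value=0), alien])
        mbc = mean_intrasource_bc(full)
        assert mbc["alien"] > 0.95
        assert flag_extreme_outliers(mbc) == ["alien"]

    def test_identical_cohort_has_none(self):
        table = pd.DataFrame(
            [[100, 200, 300]] * 8, index=[f"s{i}" for i in range(8)]
        )
        assert flag_extreme_outliers(mean_intrasource_bc(table)) == []

    def test_quartile_rule_matches_oracle(self, rng):
        mbc = pd.Series(rng.beta(2, 5, size=25), index=[f"s{i}" for i in range(25)])
        q1, q3 = np.quantile(mbc.to_numpy(), [0.25, 0.75])
        expected = sorted(mbc.index[mbc > q3 + 1.5 * (q3 - q1)])
        assert sorted(flag_extreme_outliers(mbc)) == expected


class TestSplitTrainTest:
    def _cohort(self, rng, n):
        table = dirichlet_table(rng, n, 30)
        return SourceCohort(
            source="x",
            sample_ids=list(table.index),
            mean_intra_bc=mean_intrasource_bc(table),
        )

    def test_26_usable_gives_20_train_6_test(self, rng):
        c = split_train_test(self._cohort(rng, 26), train_size=20)
        assert len(c.train_ids) == 20 and len(c.test_ids) == 6

    def test_30_usable_gives_20_train_10_test(self, rng):
        c = split_train_test(self._cohort(rng, 30), train_size=20)
        assert len(c.train_ids) == 20 and len(c.test_ids) == 10

    def test_20_usable_is_insufficient(self, rng):
        with pytest.raises(InsufficientCohortError):
            split_train_test(self._cohort(rng, 20), train_size=20)

    def test_22_usable_reduces_train_size(self, rng):
        # 22 = 16 + 6: train shrinks toward 15 to protect the test floor
        c = split_train_test(self._cohort(rng, 22), train_size=20)
        assert len(c.train_ids) == 16 and len(c.test_ids) == 6

    def test_train_is_most_cohesive_and_split_deterministic(self, rng):
        c = split_train_test(self._cohort(rng, 28), train_size=20)
        mbc = c.mean_intra_bc
        assert max(mbc[s] for s in c.train_ids) <= min(mbc[s] for s in c.test_ids)
        # permuting the sample order changes nothing
        c2 = SourceCohort(
            source="x",
            sample_ids=list(reversed(c.sample_ids)),
            mean_intra_bc=c.mean_intra_bc,
        )
        c2 = split_train_test(c2, train_size=20)
        assert c2.train_ids == c.train_ids and c2.test_ids == c.test_ids


class TestSubgroups:
    def _bifurcated(self, rng, n_per=10):
        a = dirichlet_table(rng, n_per, 30, prefix="a")
        b = dirichlet_table(rng, n_per, 30, prefix="b")
        a = a.reindex(columns=range(60), fill_value=0)
        b.columns = range(30, 60)
        b = b.reindex(columns=range(60), fill_value=0)
        return pd.concat([a, b])

    def test_planted_bifurcation_found(self, rng):
        table = self._bifurcated(rng)
        sub = detect_subgroups(table)
        assert sub.nunique() == 2
        # the two subgroups are exactly the two planted community types
        groups = {tuple(sorted(sub.index[sub == g])) for g in sub.unique()}
        assert groups == {
            tuple(f"a{i:03d}" for i in range(10)),
            tuple(f"b{i:03d}" for i in range(10)),
        }

    def test_homogeneous_cohort_is_one_subgroup(self, rng):
        assert detect_subgroups(dirichlet_table(rng, 20, 30)).nunique() == 1

    def test_balanced_training_draw(self, rng):
        table = self._bifurcated(rng, n_per=12)
        sub = detect_subgroups(table)
        cohort = SourceCohort(
            source="x",
            sample_ids=list(table.index),
            mean_intra_bc=mean_intrasource_bc(table),
            subgroups=sub,
        )
        cohort = split_train_test(cohort, train_size=16)
        drawn = pd.Series(
            [sub[s] for s in cohort.train_ids]
        ).value_counts()
        assert sorted(drawn.tolist()) == [8, 8]


class TestBuildCohort:
    def test_exclusion_reasons_are_exclusive_and_exhaustive(self, rng):
        table = dirichlet_table(rng, 30, 40)
        table.iloc[0] = np.concatenate([[3], np.zeros(39)]).astype(int)  # shallow
        retention = pd.Series(1.0, index=table.index)
        retention.iloc[1] = 0.3  # fails the 50% discard rule
        c = build_cohort("x", table, retention=retention)
        assert set(c.excluded.values()) <= {"low_depth", "low_retention", "extreme_outlier"}
        assert c.excluded[table.index[0]] == "low_depth"
        assert c.excluded[table.index[1]] == "low_retention"
        roles = set(c.train_ids) | set(c.test_ids) | set(c.excluded)
        assert roles == set(table.index)
        assert not (set(c.train_ids) & set(c.test_ids))
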