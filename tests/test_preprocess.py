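import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pglscan.preprocess import (
    PCAResult,
    TraitMatrix,
    aggregate_peptides,
    correlate,
    filter_metabolites,
    knn_impute,
    run_pca,
    standardize,
    top_contributors,
)
from pglscan import synthetic as syn


def tm(data, strains=None, features=None, **kw):
    df = pd.DataFrame(
        data,
        index=strains or [f"s{i}" for i in range(len(data))],
        columns=features,
    )
    return TraitMatrix(df, **kw)


class TestStandardize:
    def test_simple_column(self):
        out = standardize(tm([[1.0], [2.0], [3.0]]))
        assert np.allclose(out.values[:, 0], [-1, 0, 1])
        assert out.standardized

    def test_constant_dropped_with_warning(self):
        m = tm([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]], features=["const", "ok"])
        with pytest.warns(UserWarning, match="constant"):
            out = standardize(m)
        assert out.feature_ids == ["ok"]

    def test_moments(self, rng):
        out = standardize(tm(rng.normal(size=(10, 5))))
        assert np.allclose(out.values.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(out.values.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_idempotent(self, rng):
        m = tm(rng.normal(size=(8, 4)))
        once = standardize(m)
        twice = standardize(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_missing_stays_missing(self):
        m = tm([[1.0, 1.0], [2.0, np.nan], [3.0, 3.0]])
        out = standardize(m)
        assert np.isnan(out.values[1, 1])

    def test_too_few_observed(self):
        m = tm([[1.0], [np.nan], [np.nan]])
        with pytest.raises(ValueError, match="< 2 observed"):
            standardize(m)


class TestFilterMetabolites:
    def _matrix(self):
        # f_drop: missing in 2 non-excluded strains; f_excl: missing only in
        # the excluded strain; f_one: missing in exactly one other strain;
        # f_both: missing in one other strain plus the excluded one
        df = pd.DataFrame(
            {
                "f_drop": [np.nan, np.nan, 1.0, 1.0],
                "f_excl": [1.0, 1.0, 1.0, np.nan],
                "f_one": [np.nan, 1.0, 1.0, 1.0],
                "f_both": [np.nan, 1.0, 1.0, np.nan],
            },
            index=["s1", "s2", "s3", "378604X"],
        )
        return TraitMatrix(df)

    def test_rules(self):
        out = filter_metabolites(self._matrix(), excluded_strain="378604X")
        assert out.feature_ids == ["f_excl", "f_one", "f_both"]

    def test_absent_excluded_strain_means_no_exclusion(self):
        out = filter_metabolites(self._matrix(), excluded_strain="nope")
        assert out.feature_ids == ["f_excl", "f_one"]


class TestKnnImpute:
    def test_exact_match_neighbor(self):
        m = tm([[1.0, 1.0], [1.0, np.nan], [5.0, 5.0]], strains=["A", "B", "C"])
        out = knn_impute(m, k=1)
        assert out.values[1, 1] == pytest.approx(1.0)

    def test_equidistant_neighbors_average(self):
        # d(B,A) = d(B,C) = 1 on the observed column -> equal weights
        m = tm([[0.0, 0.0], [1.0, np.nan], [2.0, 2.0]], strains=["A", "B", "C"])
        out = knn_impute(m, k=2)
        assert out.values[1, 1] == pytest.approx(1.0)

    def test_k_clamped_with_warning(self):
        m = tm([[0.0, 0.0], [1.0, np.nan], [2.0, 2.0]], strains=["A", "B", "C"])
        with pytest.warns(UserWarning, match="neighbors"):
            out = knn_impute(m, k=10)
        assert out.values[1, 1] == pytest.approx(1.0)

    def test_observed_entries_untouched_and_range(self, rng):
        X = rng.normal(size=(12, 6))
        mask = rng.random((12, 6)) < 0.15
        mask[:4] = False  # keep some complete donors
        Xm = X.copy()
        Xm[mask] = np.nan
        m = tm(Xm)
        out = knn_impute(m, k=3)
        assert out.n_missing == 0
        assert np.allclose(out.values[~mask], X[~mask])
        donors = X[~np.isnan(Xm).any(axis=1)]
        for i, j in zip(*np.where(mask)):
            assert donors[:, j].min() - 1e-12 <= out.values[i, j] <= donors[:, j].max() + 1e-12

    def test_no_complete_neighbor_errors(self):
        m = tm([[1.0, np.nan], [np.nan, 1.0]], strains=["A", "B"])
        with pytest.raises(ValueError, match="no complete neighbor"):
            knn_impute(m, k=1)


class TestAggregatePeptides:
    def test_mean_of_opposite_profiles(self):
        m = tm(
            [[-1.0, 1.0], [0.0, 0.0], [1.0, -1.0]],
            features=["p1", "p2"],
            standardized=True,
        )
        out = aggregate_peptides(m, {"p1": "G1", "p2": "G1"})
        assert out.feature_ids == ["G1"]
        assert np.allclose(out.values[:, 0], 0.0)

    def test_single_peptide_passthrough(self):
        m = tm([[-1.0], [0.0], [1.0]], features=["p1"], standardized=True)
        out = aggregate_peptides(m, {"p1": "G1"})
        assert np.allclose(out.values[:, 0], [-1, 0, 1])

    def test_unmapped_counted(self):
        m = tm(
            np.zeros((3, 6)),
            features=[f"p{i}" for i in range(6)],
            standardized=True,
        )
        gene_map = {"p0": "G1", "p1": "G1", "p2": "G1", "p3": "G2", "p4": "G2"}
        with pytest.warns(UserWarning, match="1 peptide"):
            out = aggregate_peptides(m, gene_map)
        assert out.feature_ids == ["G1", "G2"]

    def test_requires_standardized(self):
        m = tm([[1.0]], features=["p1"])
        with pytest.raises(ValueError, match="standardized"):
            aggregate_peptides(m, {"p1": "G1"})


class TestPCA:
    def test_rank_one_data(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = tm(np.column_stack([x, 2 * x]), features=["a", "b"])
        p = run_pca(m)
        assert p.variance_fraction[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self, rng):
        p = run_pca(tm(rng.normal(size=(10, 6))))
        assert p.variance_fraction.sum() == pytest.approx(1.0)
        assert (np.diff(p.variance_fraction) <= 1e-12).all()

    def test_loadings_orthonormal(self, rng):
        p = run_pca(tm(rng.normal(size=(10, 6))))
        assert np.allclose(p.loadings.T @ p.loadings, np.eye(p.n_components), atol=1e-8)

    def test_scores_reconstruct_centered_data(self, rng):
        X = rng.normal(size=(9, 20))
        p = run_pca(tm(X))
        Xc = X - X.mean(axis=0)
        assert np.allclose(p.scores @ p.loadings.T, Xc, atol=1e-8)

    def test_missing_values_rejected(self):
        m = tm([[1.0, np.nan], [2.0, 1.0], [0.0, 2.0]])
        with pytest.raises(ValueError, match="impute"):
            run_pca(m)


class TestTopContributors:
    def _pca(self, n_features, rng):
        return run_pca(tm(rng.normal(size=(30, n_features))))

    def test_floor_rule_392(self, rng):
        p = self._pca(392, rng)
        assert len(top_contributors(p, 0, 0.10)) == 39

    def test_single_largest(self, rng):
        p = self._pca(10, rng)
        top = top_contributors(p, 0, 0.10)
        assert len(top) == 1
        idx = int(np.argmax(np.abs(p.loadings[:, 0])))
        assert top[0] == p.feature_ids[idx]

    def test_fraction_one_returns_all_ranked(self, rng):
        p = self._pca(10, rng)
        top = top_contributors(p, 0, 1.0)
        assert len(top) == 10
        mags = [abs(p.loadings[p.feature_ids.index(f), 0]) for f in top]
        assert mags == sorted(mags, reverse=True)

    def test_bad_fraction(self, rng):
        p = self._pca(5, rng)
        for frac in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                top_contributors(p, 0, frac)

    def test_component_out_of_range(self, rng):
        p = self._pca(5, rng)
        with pytest.raises(IndexError):
            top_contributors(p, 99)


class TestCorrelate:
    def test_self_correlation(self, rng):
        x = rng.normal(size=10)
        assert correlate(x, x) == pytest.approx(1.0)

    def test_table1_mean_vs_max(self):
        nat = syn.natural_isolates(syn.table1_fixture())
        r = correlate(nat["mean_rls"], nat["max_rls"])
        assert round(r, 2) == 0.95

    def test_table1_doubling_vs_mean(self):
        nat = syn.natural_isolates(syn.table1_fixture())
        r = correlate(nat["doubling_glucose_mean"], nat["mean_rls"])
        assert round(r, 2) == -0.42

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            correlate([1, 2, 3], [3, 2, 1], method="kendall")

    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(st.integers(-100, 100), min_size=4, max_size=20, unique=True),
        st.integers(0, 3),
    )
    def test_spearman_monotone_invariance(self, xs, which):
        rng = np.random.default_rng(sum(abs(v) for v in xs) + which)
        x = np.array(xs, dtype=float)
        y = rng.permutation(x)
        transforms = [lambda v: v, np.exp, lambda v: v**3, lambda v: 2 * v + 7]
        t = transforms[which]
        base = correlate(x, y, method="spearman")
        assert correlate(t(x / 10), y, method="spearman") == pytest.approx(base, abs=1e-12)


class TestCombineBlocks:
    def _std(self, rng, strains, features):
        return standardize(
            tm(rng.normal(size=(len(strains), len(features))), strains=strains, features=features)
        )

    def test_concatenates_with_prefixes(self, rng):
        strains = [f"s{i}" for i in range(6)]
        a = self._std(rng, strains, ["x", "y"])
        b = self._std(rng, strains, ["x", "z"])
        from pglscan.preprocess import combine_blocks

        out = combine_blocks({"t": a, "p": b})
        assert out.feature_ids == ["t:x", "t:y", "p:x", "p:z"]
        assert out.strain_ids == sorted(strains)

    def test_partial_block_excluded(self, rng):
        strains = [f"s{i}" for i in range(6)]
        a = self._std(rng, strains, ["x", "y"])
        b = self._std(rng, strains[:-1], ["m1", "m2"])  # one strain missing
        from pglscan.preprocess import combine_blocks

        with pytest.warns(UserWarning, match="lacking strains"):
            out = combine_blocks({"t": a, "metabolite": b})
        assert all(f.startswith("t:") for f in out.feature_ids)
        assert len(out.strain_ids) == 6

    def test_requires_standardized(self, rng):
        from pglscan.preprocess import combine_blocks

        with pytest.raises(ValueError, match="standardized"):
            combine_blocks({"t": tm(rng.normal(size=(4, 2)))})
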