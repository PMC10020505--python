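"""MGIDI chain: rescaling, EFA, varimax, scores, index, omega, gains."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.multivariate.factor_rotation import rotate_factors

from metsel import (MetDataError, ScoreTable, TraitSpec, compute_mgidi,
                    cross_regime_overlap, factor_scores, fit_efa,
                    rescale_traits, select_genotypes, selection_gains,
                    selection_differential_pct, strengths_weaknesses,
                    varimax_rotate)
from metsel.mgidi import varimax_criterion, eigen_variance_table, assign_factors


def specs(names, decrease=()):
    return [TraitSpec(n, "decrease" if n in decrease else "increase")
            for n in names]


def random_table(seed, g=40, p=5):
    rng = np.random.default_rng(seed)
    cols = [f"T{i}" for i in range(p)]
    base = rng.normal(size=(g, 3)) @ rng.normal(size=(3, p))
    return pd.DataFrame(base + 0.3 * rng.normal(size=(g, p)),
                        index=[f"G{i:02d}" for i in range(g)], columns=cols)


class TestRescale:
    def test_increase_linear_map(self):
        df = pd.DataFrame({"A": [2.0, 4.0, 6.0]}, index=list("xyz"))
        rt = rescale_traits(df, specs(["A"]))
        assert rt.values["A"].tolist() == [0.0, 50.0, 100.0]

    def test_decrease_reverses(self):
        df = pd.DataFrame({"ASI": [2.0, 4.0, 6.0]}, index=list("xyz"))
        rt = rescale_traits(df, specs(["ASI"], decrease={"ASI"}))
        assert rt.values["ASI"].tolist() == [100.0, 50.0, 0.0]

    def test_range_and_extrema(self):
        df = random_table(0)
        rt = rescale_traits(df, specs(df.columns, decrease={"T1"}))
        v = rt.values
        assert (v.to_numpy() >= -1e-9).all() and (v.to_numpy() <= 100 + 1e-9).all()
        for t in df.columns:
            assert v[t].min() == pytest.approx(0.0)
            assert v[t].max() == pytest.approx(100.0)

    def test_abs_correlation_preserved(self):
        df = random_table(1)
        rt = rescale_traits(df, specs(df.columns, decrease={"T0", "T3"}))
        assert np.allclose(df.corr().abs(), rt.values.corr().abs(), atol=1e-12)

    def test_constant_trait_rejected(self):
        df = pd.DataFrame({"A": [1.0, 1.0, 1.0]})
        with pytest.raises(MetDataError, match="'A'"):
            rescale_traits(df, specs(["A"]))


class TestEfa:
    def test_variance_percent_arithmetic(self):
        tab = eigen_variance_table([6.0, 3.0, 2.0, 1.0], p=12)
        assert tab["variance_pct"].tolist() == [50.0, 25.0, 50.0 / 3, 100.0 / 12]
        assert tab["cumulative_pct"].iloc[-1] == pytest.approx(100.0)

    def test_kaiser_retention_and_invariants(self):
        rt = rescale_traits(random_table(2, g=60, p=6), specs(
            [f"T{i}" for i in range(6)]))
        fm = fit_efa(rt)
        p = rt.values.shape[1]
        assert fm.eigenvalues.sum() == pytest.approx(p)
        assert fm.n_factors == (fm.eigenvalues > 1.0).sum()
        # rotation orthogonal, communalities preserved
        assert np.allclose(fm.rotation.T @ fm.rotation, np.eye(fm.n_factors),
                           atol=1e-10)
        comm0 = (fm.initial_loadings ** 2).sum(axis=1)
        assert np.allclose(comm0, fm.communalities, atol=1e-10)
        # sign convention: dominant loading of every column negative
        for c in fm.loadings.columns:
            col = fm.loadings[c]
            assert col.iloc[np.argmax(col.abs().to_numpy())] <= 0

    def test_exact_identity_correlation_errors(self):
        df = pd.DataFrame({"A": [0.0, 0.0, 100.0, 100.0],
                           "B": [0.0, 100.0, 0.0, 100.0]})
        rt = rescale_traits(df, specs(["A", "B"]))
        with pytest.raises(MetDataError, match="n_factors"):
            fit_efa(rt)
        fm = fit_efa(rt, n_factors=1)
        assert fm.n_factors == 1


class TestVarimax:
    def test_single_factor_identity(self):
        L = np.array([[0.8], [0.6], [-0.4]])
        rot, T = varimax_rotate(L)
        assert np.allclose(rot, L)
        assert T.shape == (1, 1) and T[0, 0] == 1.0

    def test_communalities_preserved(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            L = rng.normal(size=(8, 3))
            rot, T = varimax_rotate(L)
            assert np.allclose((L ** 2).sum(axis=1), (rot ** 2).sum(axis=1),
                               atol=1e-10)
            assert np.allclose(T.T @ T, np.eye(3), atol=1e-10)

    def test_criterion_never_decreases(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            L = rng.normal(size=(rng.integers(4, 10), rng.integers(2, 4)))
            rot, _ = varimax_rotate(L, kaiser=False)
            assert varimax_criterion(rot) >= varimax_criterion(L) - 1e-12

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(5)
        L = rng.normal(size=(10, 3))
        ours, _ = varimax_rotate(L, kaiser=False)
        theirs, _ = rotate_factors(L, "varimax")
        assert varimax_criterion(ours) == pytest.approx(
            varimax_criterion(theirs), abs=1e-8)


class TestScoresAndIndex:
    def _chain(self, seed=6, g=40, p=5, decrease=("T1",)):
        df = random_table(seed, g=g, p=p)
        sp = specs(df.columns, decrease=set(decrease))
        rt = rescale_traits(df, sp)
        fm = fit_efa(rt)
        st = factor_scores(rt, fm)
        return df, sp, rt, fm, st

    def test_z_standardization(self):
        *_, st = self._chain()
        assert np.allclose(st.z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(st.z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_mean_genotype_scores_zero(self):
        df, sp, rt, fm, st = self._chain()
        rt2 = rt.values.copy()
        rt2.loc["MEAN"] = rt.values.mean(axis=0)
        # scoring the column-mean row with the same mu/sd gives exactly zero
        z = (rt2.loc["MEAN"] - rt.values.mean(axis=0)) / rt.values.std(axis=0, ddof=1)
        assert np.allclose(z, 0.0)

    def test_one_dimensional_closed_form(self):
        df = pd.DataFrame({"A": [0.0, 100.0]}, index=["lo", "hi"])
        rt = rescale_traits(df, specs(["A"]))
        fm = fit_efa(rt, n_factors=1)
        st = factor_scores(rt, fm)
        s = 100.0 / np.sqrt(2) / 100.0 * 100 / np.sqrt(2)  # |z| = 1/sqrt(2)
        assert np.allclose(st.scores.abs().to_numpy().ravel(),
                           1.0 / np.sqrt(2), atol=1e-10)
        # ideotype (value 100) scores identically to the 'hi' genotype
        assert st.ideotype_scores.iloc[0] == pytest.approx(
            st.scores.loc["hi"].iloc[0])
        mr = compute_mgidi(st)
        assert mr.mgidi["hi"] == pytest.approx(0.0, abs=1e-12)
        assert mr.ranks["hi"] == 1

    def test_factor_sign_flip_invariance(self):
        df, sp, rt, fm, st = self._chain(seed=7)
        mr = compute_mgidi(st)
        flipped = fm.loadings.copy()
        flipped.iloc[:, 0] *= -1.0
        fm2 = type(fm)(correlation=fm.correlation, eigenvalues=fm.eigenvalues,
                       variance_pct=fm.variance_pct,
                       cumulative_pct=fm.cumulative_pct,
                       n_factors=fm.n_factors,
                       initial_loadings=fm.initial_loadings, loadings=flipped,
                       rotation=fm.rotation, communalities=fm.communalities)
        st2 = factor_scores(rt, fm2)
        # score column and ideotype flip together
        assert np.allclose(st2.scores.iloc[:, 0], -st.scores.iloc[:, 0])
        assert st2.ideotype_scores.iloc[0] == pytest.approx(
            -st.ideotype_scores.iloc[0])
        mr2 = compute_mgidi(st2)
        assert np.allclose(mr.mgidi, mr2.mgidi, atol=1e-10)

    def test_dominant_genotype_has_zero_mgidi(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.uniform(0, 10, size=(10, 3)),
                          columns=["A", "B", "C"],
                          index=[f"G{i}" for i in range(10)])
        df.loc["G0"] = [df["A"].max() + 1, df["B"].max() + 1, df["C"].min() - 1]
        sp = specs(["A", "B", "C"], decrease={"C"})
        rt = rescale_traits(df, sp)
        assert np.allclose(rt.values.loc["G0"], 100.0)
        fm = fit_efa(rt, n_factors=1)
        st = factor_scores(rt, fm)
        mr = compute_mgidi(st)
        assert mr.mgidi["G0"] == pytest.approx(0.0, abs=1e-10)
        assert mr.ranks["G0"] == 1

    def test_pythagorean_distance(self):
        st = ScoreTable(
            z=pd.DataFrame(),
            scores=pd.DataFrame({"FA1": [3.0], "FA2": [4.0]}, index=["g"]),
            ideotype_scores=pd.Series({"FA1": 0.0, "FA2": 0.0}))
        mr = compute_mgidi(st)
        assert mr.mgidi["g"] == pytest.approx(5.0)


class TestSelection:
    def _mr(self, values):
        st = ScoreTable(z=pd.DataFrame(),
                        scores=pd.DataFrame({"FA1": values},
                                            index=[f"G{i}" for i in
                                                   range(len(values))]),
                        ideotype_scores=pd.Series({"FA1": 0.0}))
        return compute_mgidi(st)

    def test_count_75_at_15_pct(self):
        mr = self._mr(list(np.linspace(1, 10, 75)))
        out = select_genotypes(mr, 0.15)
        assert out.n_selected == 11 and len(out.selected) == 11

    def test_singleton_selection(self):
        mr = self._mr(list(np.linspace(1, 10, 10)))
        out = select_genotypes(mr, 0.10)
        assert out.selected == ["G0"]

    def test_zero_count_rejected(self):
        mr = self._mr([1.0, 2.0, 3.0])
        with pytest.raises(MetDataError):
            select_genotypes(mr, 0.05)

    def test_tie_warns(self):
        mr = self._mr([1.0, 2.0, 2.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0])
        with pytest.warns(UserWarning, match="tie"):
            out = select_genotypes(mr, 0.2)
        assert out.selected == ["G0", "G1"]


class TestOmega:
    def test_three_four_split(self):
        st = ScoreTable(
            z=pd.DataFrame(),
            scores=pd.DataFrame({"FA1": [3.0], "FA2": [4.0]}, index=["g"]),
            ideotype_scores=pd.Series({"FA1": 0.0, "FA2": 0.0}))
        mr = strengths_weaknesses(st, compute_mgidi(st))
        assert mr.omega.loc["g", "FA1"] == pytest.approx(0.36)
        assert mr.omega.loc["g", "FA2"] == pytest.approx(0.64)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(9)
        st = ScoreTable(
            z=pd.DataFrame(),
            scores=pd.DataFrame(rng.normal(size=(20, 3)),
                                columns=["FA1", "FA2", "FA3"]),
            ideotype_scores=pd.Series({"FA1": 1.0, "FA2": -1.0, "FA3": 0.5}))
        mr = strengths_weaknesses(st, compute_mgidi(st))
        assert np.allclose(mr.omega.sum(axis=1), 1.0, atol=1e-12)

    def test_at_ideotype_uniform_with_warning(self):
        st = ScoreTable(
            z=pd.DataFrame(),
            scores=pd.DataFrame({"FA1": [1.0], "FA2": [-1.0]}, index=["g"]),
            ideotype_scores=pd.Series({"FA1": 1.0, "FA2": -1.0}))
        with pytest.warns(UserWarning, match="ideotype"):
            mr = strengths_weaknesses(st, compute_mgidi(st))
        assert np.allclose(mr.omega.loc["g"], 0.5)


class TestGains:
    def test_hand_differentials(self):
        assert selection_differential_pct(170.96, 174.14) == pytest.approx(
            1.86, abs=0.005)
        assert selection_differential_pct(25.04, 28.52) == pytest.approx(
            13.90, abs=0.005)
        assert selection_differential_pct(10.0, 10.0) == 0.0

    def test_gain_rows(self):
        df = random_table(10, g=30, p=4)
        sp = specs(df.columns, decrease={"T3"})
        rt = rescale_traits(df, sp)
        fm = fit_efa(rt)
        rows = selection_gains(df, list(df.index[:5]), fm, sp)
        assert len(rows) == 4
        for r in rows:
            assert r.sd == pytest.approx(r.xs - r.xo)
            assert r.sd_pct == pytest.approx(100 * r.sd / r.xo)
            expected_goal = r.sd >= 0 if r.sense == "increase" else r.sd <= 0
            assert r.goal_met == expected_goal
        fac = assign_factors(fm)
        assert all(r.factor == fac[r.trait] for r in rows)

    def test_empty_selection_rejected(self):
        df = random_table(11, g=10, p=3)
        sp = specs(df.columns)
        fm = fit_efa(rescale_traits(df, sp))
        with pytest.raises(MetDataError, match="empty"):
            selection_gains(df, [], fm, sp)


class TestOverlap:
    def test_identical_sets(self):
        out = cross_regime_overlap({"a": ["x", "y"], "b": ["x", "y"],
                                    "c": ["x", "y"]})
        assert out["all"]["members"] == ["x", "y"]
        assert out["all"]["count"] == 2

    def test_disjoint_sets(self):
        out = cross_regime_overlap({"a": ["1"], "b": ["2"], "c": ["3"]})
        assert out["all"]["count"] == 0
        assert all(v["count"] == 0 for v in out["pairwise"].values())

    def test_requires_two_regimes(self):
        with pytest.raises(MetDataError):
            cross_regime_overlap({"a": ["x"]})
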