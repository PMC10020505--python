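"""EM-REML engine: oracles, invariants, genetic parameters, BLUP table."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from metsel import (METDataset, MetDataError, TraitSpec, VarianceComponents,
                    blup_table, fit_trait_model, genetic_parameters,
                    h2_genotype_mean, lrt_random_term, simulate_met,
                    subset_regime)
from metsel.mixed import _em_reml, build_design, restricted_loglik_dense

from conftest import anova_rcbd_components, rcbd_config, small_sim_config


class TestLoglik:
    def test_mme_matches_dense_evaluation(self, small_ds):
        sub = subset_regime(small_ds, "optimal")
        fit = fit_trait_model(sub, "GY")
        y, X, _, _, Z, _, _ = build_design(sub, "GY")
        s2 = {"genotype": fit.vc.sigma2_g, "gei": fit.vc.sigma2_ge,
              "block": fit.vc.sigma2_block}
        dense = restricted_loglik_dense(y, X, Z, s2, fit.vc.sigma2_e)
        assert fit.loglik == pytest.approx(dense, abs=1e-8)

    def test_monotone_history_plain_and_accelerated(self, small_ds):
        sub = subset_regime(small_ds, "optimal")
        y, X, _, _, Z, _, _ = build_design(sub, "GY")
        for acc in (False, True):
            res = _em_reml(y, X, Z, accelerate=acc, max_iter=200)
            h = np.array(res["history"])
            assert (np.diff(h) >= -1e-9).all()


class TestOracles:
    def test_em_equals_anova_on_balanced_rcbd(self):
        ds, _ = simulate_met(rcbd_config(seed=3, g=20, e=3, r=2))
        fit = fit_trait_model(ds, "Y", tol=1e-13, max_iter=4000)
        s2g, s2ge, s2e = anova_rcbd_components(ds, "Y")
        assert fit.vc.sigma2_g == pytest.approx(s2g, abs=1e-6)
        assert fit.vc.sigma2_ge == pytest.approx(s2ge, abs=1e-6)
        assert fit.vc.sigma2_e == pytest.approx(s2e, abs=1e-6)

    def test_em_matches_direct_optimizer(self):
        # small instance: maximize the dense restricted likelihood with a
        # general-purpose optimizer, an independent code path
        ds, _ = simulate_met(rcbd_config(seed=9, g=10, e=2, r=2))
        y, X, _, _, Z, _, _ = build_design(ds, "Y")
        fit = fit_trait_model(ds, "Y", tol=1e-13, max_iter=4000)

        def neg(theta_log):
            s2 = {"genotype": np.exp(theta_log[0]), "gei": np.exp(theta_log[1])}
            return -restricted_loglik_dense(y, X, Z, s2, np.exp(theta_log[2]))

        res = optimize.minimize(neg, np.log([0.5, 0.5, 0.5]),
                                method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14,
                                         "maxiter": 5000})
        opt = np.exp(res.x)
        assert fit.vc.sigma2_g == pytest.approx(opt[0], abs=1e-6)
        assert fit.vc.sigma2_ge == pytest.approx(opt[1], abs=1e-6)
        assert fit.vc.sigma2_e == pytest.approx(opt[2], abs=1e-6)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)

    def test_null_genotype_variance_hits_boundary(self):
        ds, _ = simulate_met(rcbd_config(seed=20, g=20, e=3, r=2, s2g=0.0,
                                         s2ge=0.3))
        fit = fit_trait_model(ds, "Y")
        assert fit.vc.sigma2_g < 0.05
        res = lrt_random_term(ds, "Y", "genotype", full=fit)
        assert res.statistic < 3.0

    def test_nonconvergence_warns(self, small_ds):
        sub = subset_regime(small_ds, "optimal")
        with pytest.warns(UserWarning, match="did not converge"):
            fit = fit_trait_model(sub, "GY", max_iter=2)
        assert not fit.converged


class TestLrt:
    def test_zero_statistic_gives_p_one(self):
        ds, _ = simulate_met(rcbd_config(seed=21, g=15, e=2, r=2, s2g=0.0))
        res = lrt_random_term(ds, "Y", "genotype")
        if res.statistic == 0.0:
            assert res.p_value == 1.0
        assert res.df == 1
        assert res.statistic >= 0.0

    def test_boundary_mixture_halves_p(self):
        ds, _ = simulate_met(rcbd_config(seed=4, g=15, e=2, r=2, s2g=1.0))
        plain = lrt_random_term(ds, "Y", "genotype")
        mixed = lrt_random_term(ds, "Y", "genotype", boundary=True)
        if plain.statistic > 0:
            assert mixed.p_value == pytest.approx(plain.p_value / 2)

    def test_unknown_term_rejected(self, small_ds):
        with pytest.raises(MetDataError):
            lrt_random_term(subset_regime(small_ds, "optimal"), "GY", "block")


class TestGeneticParameters:
    def test_h2_hand_case(self):
        assert h2_genotype_mean(4.0, 2.0, 2.0, e=4, b=2) == pytest.approx(
            4.0 / 4.75, abs=1e-10)

    def test_accuracy_is_root_h2(self, small_ds):
        sub = subset_regime(small_ds, "optimal")
        fit = fit_trait_model(sub, "GY")
        gp = genetic_parameters(fit.vc, sub, "GY", fit)
        assert 0.0 <= gp.h2mg <= 1.0
        assert gp.accuracy == pytest.approx(np.sqrt(gp.h2mg))
        assert 0.0 <= gp.r2ge <= 1.0
        assert gp.env_f is not None and gp.env_f >= 0

    def test_zero_genetic_variance(self, small_ds):
        sub = subset_regime(small_ds, "optimal")
        vc = VarianceComponents(0.0, 1.0, None, 1.0)
        gp = genetic_parameters(vc, sub, "GY")
        assert gp.h2mg == 0.0 and gp.accuracy == 0.0

    def test_zero_mean_rejected(self):
        rows = [("G1", "E1", "optimal", 1, "B1", -1.0),
                ("G2", "E1", "optimal", 1, "B1", 1.0)]
        df = pd.DataFrame(rows, columns=["genotype", "environment", "regime",
                                         "replicate", "block", "Y"])
        ds = METDataset(df, [TraitSpec("Y", "increase")])
        with pytest.raises(MetDataError, match="CV undefined"):
            genetic_parameters(VarianceComponents(1, 1, None, 1), ds, "Y")


class TestBlupTable:
    def test_zero_variance_shrinks_to_grand_mean(self):
        cfg = rcbd_config(seed=5, g=10, e=2, r=2, s2g=0.0, s2ge=0.0, s2e=1.0)
        ds, _ = simulate_met(cfg)
        fit = fit_trait_model(ds, "Y")
        bt = blup_table({"Y": fit}, ds)
        if fit.vc.sigma2_g == 0.0:
            assert np.allclose(bt.values["Y"], fit.fixed_mean)
        assert list(bt.values.index) == ds.genotypes

    def test_high_heritability_approaches_raw_means(self):
        cfg = rcbd_config(seed=6, g=12, e=2, r=2, s2g=1.0, s2ge=0.0, s2e=1e-6)
        ds, _ = simulate_met(cfg)
        fit = fit_trait_model(ds, "Y")
        bt = blup_table({"Y": fit}, ds)
        raw = ds.table.groupby("genotype")["Y"].mean()
        dev = (bt.values["Y"] - raw).abs().max()
        assert dev < 0.01

    def test_blups_centered_on_balanced_data(self):
        ds, _ = simulate_met(rcbd_config(seed=8, g=15, e=2, r=2))
        fit = fit_trait_model(ds, "Y")
        assert abs(fit.u["genotype"].mean()) < 1e-8

    def test_missing_fit_rejected(self, small_ds):
        sub = subset_regime(small_ds, "optimal")
        fit = fit_trait_model(sub, "GY")
        with pytest.raises(MetDataError, match="missing fits"):
            blup_table({"GY": fit}, sub)

    def test_shrinkage_monotone_in_residual_variance(self):
        spreads = []
        for s2e in (0.2, 2.0, 8.0):
            out = []
            for seed in range(5):
                ds, _ = simulate_met(rcbd_config(seed=50 + seed, g=15, e=2,
                                                 r=2, s2e=s2e))
                fit = fit_trait_model(ds, "Y")
                out.append(fit.u["genotype"].std(ddof=1))
            spreads.append(np.mean(out))
        assert spreads[0] > spreads[1] > spreads[2]
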