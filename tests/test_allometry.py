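"""Tests of the Brownian covariance, PGLS with Pagel's lambda, isometry
t-tests and the method-comparison ANCOVA."""

import dendropy
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from parrotbite import allometry, simulate
from parrotbite.allometry import (
    InvalidRowError,
    brownian_covariance,
    isometry_t_test,
    log10_table,
    pgls_fit,
    phylo_ancova,
)


def _tree(newick):
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


class TestBrownianCovariance:
    def test_two_tip_cherry(self):
        cov = brownian_covariance(_tree("(A:1,B:1);"))
        assert np.allclose(cov.matrix, np.eye(2))

    def test_hand_built_three_tip(self, hand_tree):
        cov = brownian_covariance(hand_tree)
        i = {t: k for k, t in enumerate(cov.tip_order)}
        C = cov.matrix
        assert C[i["A"], i["B"]] == pytest.approx(1.0)
        assert C[i["A"], i["C"]] == pytest.approx(0.0)
        assert np.allclose(np.diag(C), 2.0)

    def test_star_tree_is_diagonal(self):
        cov = brownian_covariance(_tree("(A:1,B:1,C:1,D:1);"))
        assert np.allclose(cov.matrix, np.eye(4))

    def test_symmetric_positive_semidefinite(self, five_tip_tree):
        C = brownian_covariance(five_tip_tree).matrix
        assert np.allclose(C, C.T)
        assert np.min(np.linalg.eigvalsh(C)) > -1e-12
        assert np.min(C) >= 0

    def test_missing_branch_length_rejected(self):
        with pytest.raises(ValueError):
            brownian_covariance(_tree("((A:1,B),C:2);"))

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            brownian_covariance(_tree("((A:0,B:0):0,C:0);"))


class TestPgls:
    def test_lambda_zero_equals_ols(self, five_tip_tree, rng):
        cov = brownian_covariance(five_tip_tree)
        x = rng.normal(size=5)
        y = 1.0 + 2.0 * x + rng.normal(size=5)
        fit = pgls_fit(x, y, cov=cov, lam=0.0)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.intercept == pytest.approx(ols.params[0], abs=1e-10)
        assert fit.slope == pytest.approx(ols.params[1], abs=1e-10)
        assert fit.slope_se == pytest.approx(ols.bse[1], abs=1e-10)
        assert fit.r_squared == pytest.approx(ols.rsquared, abs=1e-10)

    def test_lambda_one_matches_brute_force_gls(self, five_tip_tree, rng):
        """At lambda = 1 the fit must equal the explicit-inverse GLS solve."""
        cov = brownian_covariance(five_tip_tree)
        V = cov.matrix
        x = rng.normal(size=5)
        y = 0.5 + 1.5 * x + rng.multivariate_normal(np.zeros(5), V)
        fit = pgls_fit(x, y, cov=cov, lam=1.0)
        X = np.column_stack([np.ones(5), x])
        Vinv = np.linalg.inv(V)
        beta = np.linalg.inv(X.T @ Vinv @ X) @ X.T @ Vinv @ y
        resid = y - X @ beta
        sigma2 = resid @ Vinv @ resid / (5 - 2)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ Vinv @ X)))
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        assert fit.intercept_se == pytest.approx(se[0], abs=1e-10)
        assert fit.slope_se == pytest.approx(se[1], abs=1e-10)

    def test_star_tree_gls_equals_ols_for_any_lambda(self, rng):
        cov = brownian_covariance(_tree("(A:1,B:1,C:1,D:1,E:1);"))
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        for lam in (0.0, 0.5, 1.0):
            fit = pgls_fit(x, y, cov=cov, lam=lam)
            ols = sm.OLS(y, sm.add_constant(x)).fit()
            assert fit.slope == pytest.approx(ols.params[1], abs=1e-10)

    def test_ml_lambda_invariant_to_tip_reordering(self, rng):
        tree = simulate.simulate_tree(12, seed=5)
        cov = brownian_covariance(tree)
        x = rng.normal(size=12)
        y = 0.3 * x + np.linalg.cholesky(cov.matrix) @ rng.normal(size=12)
        fit = pgls_fit(x, y, cov=cov, lam="ML")
        perm = rng.permutation(12)
        cov_p = cov.reordered([cov.tip_order[i] for i in perm])
        fit_p = pgls_fit(x[perm], y[perm], cov=cov_p, lam="ML")
        assert fit_p.lam == pytest.approx(fit.lam, abs=1e-6)
        assert fit_p.slope == pytest.approx(fit.slope, rel=1e-8)

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            pgls_fit([1.0, 2.0], [1.0, 2.0])

    def test_slope_recovery_on_brownian_simulations(self, rng):
        """PGLS is unbiased for the generating slope and finds lambda near 1
        when residuals are fully Brownian (light version of the acceptance
        simulation)."""
        slopes, lams = [], []
        for rep in range(60):
            tree = simulate.simulate_tree(30, seed=1000 + rep)
            cov = brownian_covariance(tree)
            L = np.linalg.cholesky(cov.matrix + 1e-12 * np.eye(30))
            x = rng.normal(size=30)
            y = 1.0 + 0.9 * x + 0.3 * (L @ rng.normal(size=30))
            fit = pgls_fit(x, y, cov=cov, lam="ML")
            slopes.append(fit.slope)
            lams.append(fit.lam)
        assert abs(np.mean(slopes) - 0.9) < 0.03
        assert np.median(lams) > 0.6


class TestIsometry:
    def test_exact_match_gives_zero(self):
        t, p = isometry_t_test(0.66, 0.1, 0.66, 17)
        assert t == 0.0 and p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "slope,se,expected,t_expected",
        [(2.574, 0.191, 2.0, 3.01), (2.195, 0.178, 2.0, 1.09)],
    )
    def test_published_skull_length_and_scar_statistics(
        self, slope, se, expected, t_expected
    ):
        t, _ = isometry_t_test(slope, se, expected, 18)
        assert t == pytest.approx(t_expected, abs=0.02)

    def test_reduces_to_hand_formula(self):
        t, p = isometry_t_test(0.828, 0.042, 0.66, 18)
        assert t == (0.828 - 0.66) / 0.042

    def test_isometric_expectations_table(self):
        assert allometry.ISOMETRIC_EXPONENTS["force~mass"] == 0.66
        assert allometry.ISOMETRIC_EXPONENTS["force~length"] == 2.0


class TestLog10Table:
    def test_transforms_and_keeps_missing(self):
        df = pd.DataFrame(
            {"species": ["a", "b"], "body_mass": [1000.0, 10.0],
             "scar_length": [np.nan, 5.0]}
        )
        out = log10_table(df)
        assert out.loc[0, "log10_body_mass"] == pytest.approx(3.0)
        assert np.isnan(out.loc[0, "log10_scar_length"])

    def test_nonpositive_value_names_species_and_field(self):
        df = pd.DataFrame({"species": ["a", "b"], "body_mass": [0.0, 10.0]})
        with pytest.raises(InvalidRowError, match="a: body_mass"):
            log10_table(df)


def _ancova_frame(tree, rng, delta=0.0, noise=0.05, slope=0.9):
    cov = brownian_covariance(tree)
    n = cov.n
    L = np.linalg.cholesky(cov.matrix + 1e-12 * np.eye(n))
    x = rng.normal(2.5, 0.5, size=n)
    y_calc = -0.4 + slope * x + 0.15 * (L @ rng.normal(size=n))
    y_meas = y_calc + delta + noise * rng.normal(size=n)
    return pd.concat(
        [
            pd.DataFrame(
                {"species": cov.tip_order, "log10_body_mass": x,
                 "log10_bite_force": y_calc, "bite_force_source": "calculated"}
            ),
            pd.DataFrame(
                {"species": cov.tip_order, "log10_body_mass": x,
                 "log10_bite_force": y_meas, "bite_force_source": "measured"}
            ),
        ],
        ignore_index=True,
    ), cov


class TestPhyloAncova:
    def test_identical_responses_give_zero_method_effect(self, rng):
        tree = simulate.simulate_tree(10, seed=2)
        data, cov = _ancova_frame(tree, rng, delta=0.0, noise=0.0)
        rep = phylo_ancova(data, cov)
        assert rep.method_effect.estimate == pytest.approx(0.0, abs=1e-8)

    def test_recovers_known_offset(self, rng):
        tree = simulate.simulate_tree(30, seed=7)
        data, cov = _ancova_frame(tree, rng, delta=0.2, noise=0.05)
        rep = phylo_ancova(data, cov)
        assert rep.method_effect.ci_low <= 0.2 <= rep.method_effect.ci_high
        assert rep.method_effect.p < 0.05

    def test_single_level_factor_rejected(self, rng):
        tree = simulate.simulate_tree(5, seed=3)
        data, cov = _ancova_frame(tree, rng)
        data = data[data.bite_force_source == "calculated"]
        with pytest.raises(ValueError):
            phylo_ancova(data, cov)

    def test_packaged_tables_show_no_method_effect(self):
        """The dissection-calculated and transducer-measured bite forces do
        not differ once body mass and relatedness are controlled for."""
        from parrotbite import datasets

        t1 = datasets.load_species_means()
        t3 = datasets.load_bite_force_comparison()
        data = pd.concat(
            [
                pd.DataFrame(
                    {"species": t1.species,
                     "log10_body_mass": np.log10(t1.body_mass_g),
                     "log10_bite_force": np.log10(t1.bite_force_n),
                     "bite_force_source": "calculated"}
                ),
                pd.DataFrame(
                    {"species": t3.species,
                     "log10_body_mass": np.log10(t3.body_mass_g),
                     "log10_bite_force": np.log10(t3.measured_bite_force_n),
                     "bite_force_source": "measured"}
                ),
            ],
            ignore_index=True,
        )
        species = sorted(set(data.species))
        tree = simulate.simulate_tree(len(species), seed=0)
        for leaf, sp in zip(tree.leaf_node_iter(), species):
            leaf.taxon.label = sp
        rep = phylo_ancova(data, brownian_covariance(tree))
        assert rep.simplified
        assert rep.method_effect.p > 0.05


class TestAlignSpecies:
    def test_normalizes_and_drops_unmatched(self, hand_tree, caplog):
        cov = brownian_covariance(hand_tree)
        df = pd.DataFrame(
            {"species": ["a", "B", "Zed"], "body_mass": [1.0, 2.0, 3.0]}
        )
        with caplog.at_level("WARNING"):
            aligned, cov2 = allometry.align_species(df, cov)
        assert list(aligned.species) == ["a", "B"]
        assert cov2.tip_order == ("A", "B")
        assert "Zed" in caplog.text
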