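import numpy as np
import pandas as pd
import pytest

from splitbrood.pedigree import additive_relationship_matrix, build_pedigree
from splitbrood.reml import (
    MixedModelSpec,
    REMLOptions,
    VarianceComponents,
    _Design,
    _LikelihoodState,
    _em_update,
    predicted_environment_means,
    reml_fit,
    restricted_log_likelihood,
    wald_f_tests,
)
from splitbrood.simulate import (
    DesignConfig,
    TrueParameters,
    correlation_to_covariance,
    simulate_breeding_design,
)

from conftest import make_truth, small_dataset
from oracles import reml_loglik_dense

ENVS = ("ripe", "unripe", "none")
SPEC = MixedModelSpec(trait="value", env_levels=ENVS)


class TestVarianceComponents:
    def test_vector_round_trip(self):
        G = correlation_to_covariance((2.0, 1.0, 0.5), 0.3)
        vc = VarianceComponents(G=G, sigma2_e=1.7, env_labels=ENVS)
        back = VarianceComponents.from_vector(vc.as_vector(), ENVS)
        np.testing.assert_allclose(back.G, G)
        assert back.sigma2_e == 1.7

    def test_asymmetric_G_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            VarianceComponents(G=np.array([[1.0, 0.5], [0.2, 1.0]]),
                               sigma2_e=1.0, env_labels=("a", "b"))


class TestRestrictedLogLikelihood:
    def test_two_unrelated_individuals_closed_form(self):
        """With G = 0 the model collapses to an i.i.d. normal sample whose
        REML log-likelihood has a textbook closed form."""
        ped = build_pedigree([("a", "", ""), ("b", "", "")])
        A = additive_relationship_matrix(ped)
        df = pd.DataFrame({"id": ["a", "b"], "environment": ["ripe"] * 2,
                           "block": ["d1"] * 2, "y": [1.0, 3.0]})
        spec = MixedModelSpec(trait="y", env_levels=("ripe",))
        s2 = 2.0
        vc = VarianceComponents(G=np.zeros((1, 1)), sigma2_e=s2, env_labels=("ripe",))
        n, ybar = 2, 2.0
        ss = float(((np.array([1.0, 3.0]) - ybar) ** 2).sum())
        closed = -0.5 * ((n - 1) * np.log(2 * np.pi) + (n - 1) * np.log(s2)
                         + np.log(n) + ss / s2)
        assert restricted_log_likelihood(df, A, spec, vc) == pytest.approx(closed, rel=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_dense_first_principles_oracle(self, seed):
        ped, pheno, A, _ = small_dataset(seed=seed, n_sires=3, dams=2, kids=2)
        assert len(pheno) <= 50
        G = correlation_to_covariance((2.0, 1.0, 1.5), 0.4)
        vc = VarianceComponents(G=G, sigma2_e=3.0, env_labels=ENVS)
        mine = restricted_log_likelihood(pheno, A, SPEC, vc)
        oracle = reml_loglik_dense(pheno, A.values, list(A.ids), "value", ENVS, G, 3.0)
        assert mine == pytest.approx(oracle, rel=1e-8)

    def test_scaling_identity(self):
        """Scaling y by c and all components by c^2 shifts the restricted
        log-likelihood by exactly -(n - p) log c."""
        ped, pheno, A, _ = small_dataset(seed=4, n_sires=4, dams=2, kids=3)
        G = correlation_to_covariance((2.0, 1.0, 1.5), 0.4)
        vc = VarianceComponents(G=G, sigma2_e=3.0, env_labels=ENVS)
        base = restricted_log_likelihood(pheno, A, SPEC, vc)
        c = 2.0
        scaled = pheno.copy()
        scaled["value"] = c * scaled["value"]
        vc2 = VarianceComponents(G=c ** 2 * G, sigma2_e=c ** 2 * 3.0, env_labels=ENVS)
        design = _Design(pheno, A, SPEC)
        n, p = design.n, design.p
        shifted = restricted_log_likelihood(scaled, A, SPEC, vc2)
        assert shifted == pytest.approx(base - (n - p) * np.log(c), rel=1e-10)

    def test_singular_V_raises(self):
        ped, pheno, A, _ = small_dataset(seed=4, n_sires=3, dams=2, kids=2)
        vc = VarianceComponents(G=np.zeros((3, 3)), sigma2_e=0.0, env_labels=ENVS)
        with pytest.raises(np.linalg.LinAlgError):
            restricted_log_likelihood(pheno, A, SPEC, vc)

    def test_phenotyped_individual_missing_from_pedigree(self):
        ped, pheno, A, _ = small_dataset(seed=4, n_sires=3, dams=2, kids=2)
        pheno = pd.concat(
            [pheno, pheno.iloc[[0]].assign(id="stranger")], ignore_index=True
        )
        vc = VarianceComponents(G=np.eye(3), sigma2_e=1.0, env_labels=ENVS)
        with pytest.raises(ValueError, match="absent from the pedigree"):
            restricted_log_likelihood(pheno, A, SPEC, vc)


class TestEMIterations:
    def test_em_never_decreases_loglik(self):
        ped, pheno, A, _ = small_dataset(seed=8, n_sires=6, dams=2, kids=4)
        design = _Design(pheno, A, SPEC)
        design.y = design.y / design.y.std()
        theta = np.concatenate([np.full(3, 1 / 3), np.zeros(3), [2 / 3]])
        state = _LikelihoodState(design, theta)
        for _ in range(30):
            new = _LikelihoodState(design, _em_update(design, state, 1e-10, 1e-8))
            assert new.ll >= state.ll - 1e-9
            state = new


class TestRemlFit:
    def test_zero_genetic_truth_gives_negligible_heritability(self):
        """With no genetic variance in the truth the fitted genetic
        variances collapse toward the boundary and h2 stays near zero."""
        truth = TrueParameters(G=np.zeros((3, 3)), sigma2_e=2.0,
                               env_means=(5.0, 4.0, 3.0), block_effects={})
        cfg = DesignConfig(n_sires=35, dams_per_sire=3, offspring_per_dam=10,
                           missing_cell_rate=0.0, seed=3)
        ped, pheno = simulate_breeding_design(cfg, truth)
        A = additive_relationship_matrix(ped)
        fit = reml_fit(pheno, A, SPEC, REMLOptions(on_nonconvergence="warn"))
        h2 = np.diag(fit.components.G) / (np.diag(fit.components.G) + fit.components.sigma2_e)
        assert np.all(h2 < 0.2)
        assert fit.components.sigma2_e == pytest.approx(2.0, rel=0.2)

    def test_grid_search_oracle_single_environment(self):
        """On a tiny one-environment instance the fitted (sigma2_a, sigma2_e)
        agree with a dense grid search over the restricted log-likelihood."""
        truth = TrueParameters(G=np.array([[2.0]]), sigma2_e=1.0,
                               env_means=(0.0,), block_effects={})
        cfg = DesignConfig(n_sires=6, dams_per_sire=2, offspring_per_dam=3,
                           env_labels=("ripe",), env_weights=(1.0,),
                           missing_cell_rate=0.0, seed=12)
        ped, pheno = simulate_breeding_design(cfg, truth)
        assert len(pheno) <= 40
        A = additive_relationship_matrix(ped)
        spec = MixedModelSpec(trait="value", env_levels=("ripe",))
        fit = reml_fit(pheno, A, spec, REMLOptions(on_nonconvergence="warn"))
        sa = np.linspace(0.01, 6.0, 80)
        se = np.linspace(0.05, 6.0, 80)
        best, arg = -np.inf, None
        for a in sa:
            for e in se:
                vc = VarianceComponents(G=np.array([[a]]), sigma2_e=e, env_labels=("ripe",))
                ll = restricted_log_likelihood(pheno, A, spec, vc)
                if ll > best:
                    best, arg = ll, (a, e)
        step_a = sa[1] - sa[0]
        step_e = se[1] - se[0]
        assert abs(fit.components.G[0, 0] - arg[0]) <= step_a
        assert abs(fit.components.sigma2_e - arg[1]) <= step_e
        assert fit.reml_loglik >= best - 1e-6

    def test_fit_is_deterministic(self):
        ped, pheno, A, _ = small_dataset(seed=5)
        f1 = reml_fit(pheno, A, SPEC, REMLOptions(on_nonconvergence="warn"))
        f2 = reml_fit(pheno, A, SPEC, REMLOptions(on_nonconvergence="warn"))
        np.testing.assert_array_equal(f1.components.G, f2.components.G)
        assert f1.reml_loglik == f2.reml_loglik

    def test_sire_model_moment_estimator_consistency(self):
        """In a large balanced single-environment half-sib design,
        4 x the between-sire variance component from the classical
        one-way moment estimator agrees with the REML sigma2_a."""
        truth = TrueParameters(G=np.array([[8.0]]), sigma2_e=16.0,
                               env_means=(0.0,), block_effects={})
        cfg = DesignConfig(n_sires=120, dams_per_sire=12, offspring_per_dam=1,
                           env_labels=("ripe",), env_weights=(1.0,),
                           missing_cell_rate=0.0, seed=31)
        ped, pheno = simulate_breeding_design(cfg, truth)
        A = additive_relationship_matrix(ped)
        spec = MixedModelSpec(trait="value", env_levels=("ripe",))
        fit = reml_fit(pheno, A, spec, REMLOptions(on_nonconvergence="warn", em_iters=10))
        g = pheno.groupby("sire")["value"]
        k = g.size().iloc[0]
        fam_means = g.mean()
        grand = pheno["value"].mean()
        s = len(fam_means)
        msb = k * ((fam_means - grand) ** 2).sum() / (s - 1)
        msw = sum(((v - v.mean()) ** 2).sum() for _, v in g) / (len(pheno) - s)
        sigma2_sire = (msb - msw) / k
        assert 4 * sigma2_sire == pytest.approx(fit.components.G[0, 0], abs=3.0)

    def test_boundary_estimates_flagged_not_fatal(self):
        truth = TrueParameters(
            G=np.diag([3.0, 0.0, 0.0]), sigma2_e=2.0,
            env_means=(5.0, 4.0, 3.0), block_effects={},
        )
        cfg = DesignConfig(n_sires=25, dams_per_sire=3, offspring_per_dam=8,
                           missing_cell_rate=0.0, seed=17)
        ped, pheno = simulate_breeding_design(cfg, truth)
        A = additive_relationship_matrix(ped)
        fit = reml_fit(pheno, A, SPEC, REMLOptions(on_nonconvergence="warn"))
        assert fit.converged
        assert isinstance(fit.boundary, tuple) and len(fit.boundary) == 3


class TestWaldAndMeans:
    def test_single_level_factor_errors(self):
        ped, pheno, A, _ = small_dataset(seed=4, n_sires=4, dams=2, kids=3)
        pheno = pheno[pheno["environment"] == "ripe"].copy()
        spec = MixedModelSpec(trait="value", env_levels=("ripe",))
        fit = reml_fit(pheno, A, spec, REMLOptions(on_nonconvergence="warn"))
        with pytest.raises(ValueError, match="estimable contrasts"):
            wald_f_tests(fit)

    def test_strong_environment_effect_detected(self):
        truth = make_truth(env_means=(20.0, 4.0, 3.0), sigma2_e=1.0)
        ped, pheno, A, _ = small_dataset(seed=6, n_sires=10, dams=2, kids=5, truth=truth)
        fit = reml_fit(pheno, A, SPEC, REMLOptions(on_nonconvergence="warn"))
        w = wald_f_tests(fit).set_index("term")
        assert w.loc["environment", "p"] < 1e-3
        assert w.loc["environment", "df_num"] == 2
        assert w.loc["environment", "df_den"] == fit.n_obs - fit.rank_X

    def test_adjusted_means_equal_raw_means_without_blocks(self):
        truth = make_truth(blocks=False)
        cfg = DesignConfig(n_sires=10, dams_per_sire=2, offspring_per_dam=6,
                           n_blocks=1, missing_cell_rate=0.0, seed=9)
        ped, pheno = simulate_breeding_design(cfg, truth)
        A = additive_relationship_matrix(ped)
        fit = reml_fit(pheno, A, SPEC, REMLOptions(on_nonconvergence="warn"))
        adj = predicted_environment_means(fit).set_index("environment")
        # GLS adjusted means equal raw means only approximately (the
        # genetic covariance reweights records), but with no blocks and a
        # near-balanced design they should be very close
        raw = pheno.groupby("environment")["value"].mean()
        for env in ENVS:
            assert adj.loc[env, "mean"] == pytest.approx(raw[env], abs=3 * adj.loc[env, "se"])

    def test_recovers_true_environment_means(self):
        truth = make_truth(env_means=(23.51, 12.96, 12.29), variances=(3.0, 1.0, 1.5),
                           sigma2_e=5.0)
        ped, pheno, A, _ = small_dataset(seed=10, n_sires=20, dams=3, kids=6, truth=truth)
        fit = reml_fit(pheno, A, SPEC, REMLOptions(on_nonconvergence="warn"))
        adj = predicted_environment_means(fit).set_index("environment")
        for env, mu in zip(ENVS, truth.env_means):
            row = adj.loc[env]
            # truth includes a zero-mean block-effect average of 0
            assert abs(row["mean"] - mu) < 3 * row["se"] + 0.5

    def test_environment_label_permutation_equivariance(self):
        ped, pheno, A, _ = small_dataset(seed=11)
        fit = reml_fit(pheno, A, SPEC, REMLOptions(on_nonconvergence="warn"))
        perm = {"ripe": "none", "unripe": "ripe", "none": "unripe"}
        pheno2 = pheno.assign(environment=pheno["environment"].map(perm))
        fit2 = reml_fit(pheno2, A, SPEC, REMLOptions(on_nonconvergence="warn"))
        a1 = predicted_environment_means(fit).set_index("environment")
        a2 = predicted_environment_means(fit2).set_index("environment")
        for old, new in perm.items():
            assert a1.loc[old, "mean"] == pytest.approx(a2.loc[new, "mean"], abs=1e-5)
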