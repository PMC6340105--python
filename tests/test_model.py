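"""Design assembly, Gibbs sampler correctness and the EM-REML oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from penmates.model import (GibbsChains, GibbsConfig, ModelSpec,
                            VarianceComponents, build_design, em_reml,
                            gibbs_sampler, posterior_summary)
from penmates.pedigree import (build_pedigree, inverse_relationship_matrix,
                               relationship_matrix)
from penmates.simulate import SimulationParams, simulate_dataset



def _one_way_design(n_groups, per_group, s2_group, s2_e, seed,
                    group_effects=None):
    """Balanced one-way layout with intercept-only fixed effects, no
    genetic term: the classical variance-components testbed."""
    rng = np.random.default_rng(seed)
    n = n_groups * per_group
    code = np.repeat(np.arange(n_groups), per_group)
    g = (group_effects if group_effects is not None
         else rng.normal(0, np.sqrt(s2_group), n_groups))
    y = g[code] + rng.normal(0, np.sqrt(s2_e), n)
    from penmates.model import DesignMatrices
    return DesignMatrices(
        y=y, X=np.ones((n, 1)), x_names=["intercept"], pen_code=code,
        pen_ids=list(range(n_groups)), rec_animal=np.zeros(n, dtype=int),
        S=None, q=1, animal_ids=list(range(n)), spec=ModelSpec("AM"))


class TestBuildDesign:
    def test_am_design_columns(self, small_ige_fit):
        data = small_ige_fit["data"]
        design = build_design(data.phenotypes, ModelSpec("AM"),
                              small_ige_fit["ped"])
        assert design.S is None
        n_batches = data.phenotypes["batch"].nunique()
        # intercept + reference-coded batches + 3 covariates
        assert len(design.x_names) == 1 + (n_batches - 1) + 3
        assert np.linalg.matrix_rank(design.X) == design.X.shape[1]

    def test_classical_social_rows_count_pen_mates(self, small_ige_fit):
        data = small_ige_fit["data"]
        design = build_design(data.phenotypes, ModelSpec("AM_IGE"),
                              small_ige_fit["ped"])
        row_sums = np.asarray(design.S.sum(axis=1)).ravel()
        sizes = data.phenotypes.groupby("pen")["animal"].transform("count")
        assert np.array_equal(row_sums, sizes.to_numpy() - 1)

    def test_pair_specific_rows_carry_degrees(self, small_ige_fit):
        data, design = small_ige_fit["data"], small_ige_fit["design"]
        C = data.C
        ped = small_ige_fit["ped"]
        row0 = design.S[0].toarray().ravel()
        a0 = data.phenotypes["animal"].iloc[0]
        pen0 = data.phenotypes["pen"].iloc[0]
        mates = data.phenotypes.loc[(data.phenotypes["pen"] == pen0)
                                    & (data.phenotypes["animal"] != a0),
                                    "animal"]
        for m in mates:
            assert row0[ped.index[m]] == pytest.approx(
                C.C[C.position(a0), C.position(m)])
        assert row0[ped.index[a0]] == 0.0

    def test_animal_missing_from_pedigree_errors(self):
        ped = build_pedigree([(1, 0, 0), (2, 0, 0)])
        data = pd.DataFrame({"animal": [1, 99], "pen": ["p", "p"],
                             "batch": ["b", "b"], "age_on": [70, 71.0],
                             "age_off": [175, 170.0], "adg": [1.0, 2.0]})
        with pytest.raises(ValueError, match="missing from pedigree"):
            build_design(data, ModelSpec("AM"), ped)


class TestGibbsSampler:
    def test_reproducible_given_seed(self, small_ige_fit):
        cfg = GibbsConfig(1200, 200, 2, seed=99)
        c1 = gibbs_sampler(small_ige_fit["design"], small_ige_fit["Ainv"],
                           cfg)
        c2 = gibbs_sampler(small_ige_fit["design"], small_ige_fit["Ainv"],
                           cfg)
        assert np.array_equal(c1.vc, c2.vc)
        assert np.array_equal(c1.a_D, c2.a_D)

    def test_variance_samples_positive(self, small_ige_fit):
        vc = small_ige_fit["chains"].vc
        assert (vc[:, [0, 1, 3, 4]] > 0).all()

    def test_am_recovery_on_simulated_data(self):
        # 60 pens x 12 generated from known variances
        vc = VarianceComponents(0.5, 0.0, 0.0, 0.2, 0.3)
        params = SimulationParams(
            n_phenotyped=720, n_pens=60, pen_size_range=(12, 12),
            n_founders=60, n_generations=2, n_sires=20, n_dams=40,
            vc_true=vc, interaction_mode="CLASSICAL", seed=23)
        data = simulate_dataset(params)
        design = build_design(data.phenotypes, ModelSpec("AM"),
                              data.pedigree)
        chains = gibbs_sampler(design,
                               inverse_relationship_matrix(data.pedigree),
                               GibbsConfig(50_000, 10_000, 10, seed=2))
        m = chains.vc.mean(axis=0)
        # pilot runs: direct and residual means recover within 30%; the
        # flat-prior posterior mean of a 60-level pen variance sits
        # systematically above the simulated value, so its band is wider
        for got, true, tol in zip(m[[0, 3, 4]], [0.5, 0.2, 0.3],
                                  [0.30, 0.45, 0.30]):
            assert abs(got - true) / true < tol

    def test_zeroed_social_incidence_reduces_to_am(self, small_ige_fit):
        # AM within AM_IGE: with S = 0 the direct-variance posterior must
        # match the plain AM fit on the same data up to MC error
        design = small_ige_fit["design"]
        from penmates.model import DesignMatrices
        d0 = DesignMatrices(
            y=design.y, X=design.X, x_names=design.x_names,
            pen_code=design.pen_code, pen_ids=design.pen_ids,
            rec_animal=design.rec_animal,
            S=sparse.csr_matrix(design.S.shape), q=design.q,
            animal_ids=design.animal_ids, spec=ModelSpec("AM_IGE_i", "OT"))
        cfg = GibbsConfig(12_000, 3_000, 5, seed=6)
        ch0 = gibbs_sampler(d0, small_ige_fit["Ainv"], cfg)
        dam = DesignMatrices(
            y=design.y, X=design.X, x_names=design.x_names,
            pen_code=design.pen_code, pen_ids=design.pen_ids,
            rec_animal=design.rec_animal, S=None, q=design.q,
            animal_ids=design.animal_ids, spec=ModelSpec("AM"))
        cham = gibbs_sampler(dam, small_ige_fit["Ainv"], cfg)
        m0, mam = ch0.vc[:, 0].mean(), cham.vc[:, 0].mean()
        mc = 3 * (ch0.vc[:, 0].std() + cham.vc[:, 0].std()) / np.sqrt(50)
        assert abs(m0 - mam) < max(mc, 0.15 * mam)

    def test_residual_variance_matches_anova_oracle(self):
        # no genetic term: the posterior mean of sigma2_e must agree with
        # the within-group mean square of the balanced one-way ANOVA
        design = _one_way_design(40, 15, 0.5, 1.0, seed=3)
        chains = gibbs_sampler(design, None, GibbsConfig(8000, 2000, 2,
                                                         seed=5))
        y = design.y
        groups = y.reshape(40, 15)
        within_ms = (((groups - groups.mean(axis=1, keepdims=True)) ** 2)
                     .sum() / (40 * 14))
        assert abs(chains.vc[:, 4].mean() - within_ms) / within_ms < 0.05

    def test_posterior_concentration_with_sample_size(self):
        sds = []
        for n_groups, per in ((20, 10), (80, 40)):
            design = _one_way_design(n_groups, per, 0.4, 1.0, seed=8)
            ch = gibbs_sampler(design, None, GibbsConfig(4000, 1000, 2,
                                                         seed=8))
            sds.append(ch.vc[:, 4].std())
        # 16x the records: posterior SD of sigma2_e should shrink ~4x
        assert sds[1] < 0.5 * sds[0]


class TestPosteriorSummary:
    def _chains(self, vc_rows):
        vc = np.asarray(vc_rows, dtype=float)
        m = vc.shape[0]
        return GibbsChains(vc, np.zeros((m, 1)), np.zeros((m, 1)),
                           np.zeros((m, 1)), np.zeros((m, 1)),
                           GibbsConfig(2000, 0, 1, 0),
                           ModelSpec("AM_IGE"))

    def test_constant_chain_zero_sd(self):
        ch = self._chains([[0.4, 0.01, -0.01, 0.1, 0.5]] * 200)
        summ = posterior_summary(ch)
        assert summ.loc["sigma2_D", "sd"] == 0.0
        assert summ.loc["sigma2_D", "mean"] == 0.4

    def test_simple_chain_moments(self):
        rows = [[v, 0.01, 0.0, 0.1, 0.5] for v in (1.0, 2.0, 3.0)] * 40
        summ = posterior_summary(self._chains(rows))
        assert summ.loc["sigma2_D", "mean"] == pytest.approx(2.0)
        assert summ.loc["sigma2_D", "median"] == pytest.approx(2.0)

    def test_samplewise_correlation_differs_from_ratio_of_means(self):
        # heavy-tailed sigma2_D: E[cov/sqrt(vD*vS)] != cov/sqrt(E[vD]E[vS])
        rng = np.random.default_rng(0)
        vD = np.exp(rng.normal(0, 1.2, 4000))
        rows = np.column_stack([vD, np.ones(4000), 0.5 * np.ones(4000),
                                np.ones(4000), np.ones(4000)])
        summ = posterior_summary(self._chains(rows))
        samplewise = summ.loc["corr_DS", "mean"]
        ratio_of_means = 0.5 / np.sqrt(vD.mean())
        assert abs(samplewise - ratio_of_means) > 0.05


class TestEmReml:
    def test_no_random_effects_is_ols(self):
        rng = np.random.default_rng(1)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta = np.array([1.0, 2.0])
        y = X @ beta + rng.normal(0, 1.5, n)
        from penmates.model import DesignMatrices
        design = DesignMatrices(
            y=y, X=X, x_names=["i", "x"], pen_code=np.zeros(n, dtype=int),
            pen_ids=[0], rec_animal=np.zeros(n, dtype=int), S=None, q=1,
            animal_ids=list(range(n)), spec=ModelSpec("AM"))
        vc, conv, _ = em_reml(design, None, include_pen=False, tol=1e-10)
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        ols = resid @ resid / (n - 2)
        assert conv
        assert vc.sigma2_e == pytest.approx(ols, rel=1e-5)

    def test_am_recovery(self):
        vc_true = VarianceComponents(0.5, 0.0, 0.0, 0.2, 0.3)
        params = SimulationParams(
            n_phenotyped=720, n_pens=60, pen_size_range=(12, 12),
            n_founders=60, n_generations=2, n_sires=20, n_dams=40,
            vc_true=vc_true, interaction_mode="CLASSICAL", seed=23)
        data = simulate_dataset(params)
        design = build_design(data.phenotypes, ModelSpec("AM"),
                              data.pedigree)
        vc, _, _ = em_reml(design, relationship_matrix(data.pedigree))
        for got, true in ((vc.sigma2_D, 0.5), (vc.sigma2_pen, 0.2),
                          (vc.sigma2_e, 0.3)):
            assert abs(got - true) / true < 0.30

    def test_gibbs_and_reml_genetic_correlation_agree(self, small_ige_fit):
        vc, _, _ = em_reml(small_ige_fit["design"],
                           relationship_matrix(small_ige_fit["ped"]))
        chains = small_ige_fit["chains"]
        corr_gibbs = np.mean(
            chains.vc[:, 2] / np.sqrt(chains.vc[:, 0] * chains.vc[:, 1]))
        assert abs(corr_gibbs - vc.genetic_correlation) <= 0.15
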