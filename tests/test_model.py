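import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from qlseq import (
    build_design,
    fit_gene,
    fit_genes,
    interaction_contrasts,
    ql_f_test,
    within_species_contrasts,
)
from qlseq.io import SampleTable
from qlseq.model import (
    LN2,
    DispersionModel,
    contrast_null_design,
    estimate_dispersion,
    squeeze_var,
)
from qlseq.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="module")
def full_design(full_sample_table_module):
    return build_design(SampleTable(full_sample_table_module))


@pytest.fixture(scope="module")
def full_sample_table_module():
    rows = [
        {
            "sample_id": f"{sp}{i}_{p}",
            "individual": f"{sp}{i}",
            "species": sp,
            "brain_part": p,
        }
        for sp in ("Na", "Ve")
        for i in range(1, 6)
        for p in ("BS", "CE", "DI", "OB", "OT", "TE")
    ]
    return pd.DataFrame(rows)


class TestDesign:
    def test_full_layout_20_columns_rank_20(self, full_design):
        assert full_design.matrix.shape == (60, 20)
        assert full_design.rank == 20

    def test_single_species_has_no_interactions(self, full_sample_table_module):
        st = SampleTable(full_sample_table_module[full_sample_table_module.species == "Na"])
        d = build_design(st)
        assert d.matrix.shape[1] == 10  # 5 individuals + 5 parts
        assert not any(c.startswith("int_") for c in d.columns)

    def test_species_main_effect_absorbed(self, full_design):
        # a species indicator lies in the span of the individual columns,
        # so adding it would not increase the rank
        X = full_design.X
        sp = np.array([1.0] * 30 + [0.0] * 30)
        assert np.linalg.matrix_rank(np.column_stack([X, sp])) == full_design.rank

    def test_rank_deficient_dropout_names_coefficients(self, full_sample_table_module):
        # keep only two parts for one individual but drop one of them
        # everywhere else, making its part effect inestimable
        t = full_sample_table_module
        keep = (t.brain_part != "TE") | (t.individual == "Na1")
        st = SampleTable(t[keep])  # TE observed only in species Na
        with pytest.raises(ValueError, match="non-estimable"):
            build_design(st)


class TestContrasts:
    def test_twelve_within_species_contrasts(self, full_design):
        assert len(within_species_contrasts(full_design)) == 12

    def test_fifteen_interaction_contrasts(self, full_design):
        assert len(interaction_contrasts(full_design)) == 15

    def test_within_contrast_annihilates_equal_part_effects(self, full_design):
        cs = within_species_contrasts(full_design)
        # all six parts at the same expression level (the reference part is
        # pinned at 0, so equal effects means zero part coefficients), with
        # arbitrary individual effects
        rng = np.random.default_rng(0)
        beta = np.zeros(full_design.n_coef)
        for j, c in enumerate(full_design.columns):
            if c.startswith("ind_"):
                beta[j] = rng.normal()
        v = cs.vectors["CE-avg_Na"]
        assert v @ beta == pytest.approx(0.0, abs=1e-12)

    def test_within_contrasts_sum_to_zero_per_species(self, full_design):
        # the six part-vs-average contrasts of one species are linearly
        # dependent: they sum to the zero vector
        cs = within_species_contrasts(full_design)
        total = sum(v for n, v in cs.vectors.items() if n.endswith("_Na"))
        np.testing.assert_allclose(total, 0.0, atol=1e-12)

    def test_three_part_toy_weights_match_hand_construction(self):
        rows = [
            {
                "sample_id": f"I{i}_{p}",
                "individual": f"I{i}",
                "species": "Na",
                "brain_part": p,
            }
            for i in range(1, 3)
            for p in ("BS", "CE", "DI")
        ]
        d = build_design(SampleTable(pd.DataFrame(rows)))
        cs = within_species_contrasts(d)
        # effect basis: ref BS=0, so CE-avg = CE - (BS + DI)/2 = CE - DI/2
        v = cs.vectors["CE-avg_Na"]
        expect = {"part_CE": 1.0, "part_DI": -0.5}
        for j, c in enumerate(d.columns):
            assert v[j] == pytest.approx(expect.get(c, 0.0))
        assert len(cs) == 3  # p parts -> p contrasts for one species

    def test_interaction_contrast_on_known_beta(self, full_design):
        cs = interaction_contrasts(full_design)
        beta = np.zeros(full_design.n_coef)
        cols = full_design.columns
        beta[cols.index("int_CE")] = 1.5
        # (BS - CE)_Na - (BS - CE)_Ve = -(int_BS - int_CE) = +1.5 (BS is ref)
        name = "BSvCE_Na-BSvCE_Ve"
        assert cs.vectors[name] @ beta == pytest.approx(1.5)
        # zero interaction coefficients -> all 15 evaluate to 0
        beta2 = np.zeros(full_design.n_coef)
        beta2[cols.index("part_CE")] = 2.0
        for v in cs.vectors.values():
            assert v @ beta2 == pytest.approx(0.0, abs=1e-12)


class TestFitGene:
    def test_group_means_recovered_with_one_factor_design(self):
        rows = [
            {"sample_id": f"I{i}_{p}", "individual": f"I{i}", "species": "Na", "brain_part": p}
            for i in (1,)
            for p in ("BS", "CE")
        ]
        rows = rows * 1
        # two groups, three replicates each, equal offsets
        t = pd.DataFrame(
            [
                {"sample_id": f"s{k}", "individual": "I1", "species": "Na",
                 "brain_part": "BS" if k < 3 else "CE"}
                for k in range(6)
            ]
        )
        d = build_design(SampleTable(t))
        y = np.array([4, 6, 8, 20, 22, 24], dtype=float)
        fit = fit_gene(y, d, np.zeros(6), dispersion=0.3)
        np.testing.assert_allclose(fit.mu[:3], 6.0, rtol=1e-6)
        np.testing.assert_allclose(fit.mu[3:], 22.0, rtol=1e-6)

    def test_poisson_limit_matches_statsmodels(self, full_design):
        rng = np.random.default_rng(9)
        X = full_design.X
        offs = np.log(rng.uniform(5e5, 2e6, size=60))
        beta_true = rng.normal(0, 0.3, size=X.shape[1])
        mu = np.exp(offs + X @ beta_true + 3)
        y = rng.poisson(mu).astype(float)
        fit = fit_gene(y, full_design, offs, dispersion=0.0)
        ref = sm.GLM(y, X, family=sm.families.Poisson(), offset=offs).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-8)

    def test_all_zero_row_flagged_degenerate(self, full_design):
        fit = fit_gene(np.zeros(60), full_design, np.zeros(60), 0.1)
        assert fit.degenerate
        assert fit.deviance == pytest.approx(0.0, abs=1e-6)


class TestDispersion:
    def test_poisson_data_yields_near_zero_trend(self, full_design):
        rng = np.random.default_rng(10)
        G, X = 800, full_design.X
        offs = np.full(60, np.log(1e6))
        mu = np.exp(offs[None, :] + rng.normal(-9, 1.5, size=G)[:, None])
        Y = rng.poisson(mu)
        disp = estimate_dispersion(Y, full_design, offs)
        assert np.median(disp.phi_trend) < 0.05

    def test_nb_dispersion_recovered_at_high_counts(self, full_design):
        rng = np.random.default_rng(12)
        G, X = 600, full_design.X
        offs = np.full(60, np.log(1e6))
        mu = np.exp(offs[None, :] - 7.0) * np.ones((G, 60))  # ~900 counts
        phi = 0.1
        r = 1 / phi
        Y = rng.negative_binomial(r, r / (r + mu))
        disp = estimate_dispersion(Y, full_design, offs)
        med = float(np.median(disp.phi_gene))
        assert 0.08 <= med <= 0.12

    def test_identical_s2_means_infinite_prior_df(self):
        s2 = np.full(50, 0.8)
        shrunk, d0, s0 = squeeze_var(s2, df=40)
        assert np.isinf(d0)
        np.testing.assert_allclose(shrunk, 0.8, rtol=1e-6)

    def test_shrinkage_lies_between_raw_and_prior(self, fitted):
        disp = fitted["dispersions"]
        s0 = disp.prior_s2
        assert np.all(disp.s2_shrunk <= np.maximum(disp.s2_raw, s0) + 1e-8)
        assert np.all(disp.s2_shrunk >= np.minimum(disp.s2_raw, s0) - 1e-8)


class TestQlFTest:
    def _lrt_oracle_setup(self, full_design):
        rng = np.random.default_rng(13)
        G = 5
        offs = np.full(60, np.log(1e6))
        mu = np.exp(offs[None, :] - 8.0) * np.ones((G, 60))
        phi = 0.08
        r = 1 / phi
        Y = rng.negative_binomial(r, r / (r + mu)).astype(float)
        fits = fit_genes(Y, full_design, offs, phi)
        disp = DispersionModel(
            phi_gene=np.full(G, phi),
            phi_trend=np.full(G, phi),
            abundance=np.zeros(G),
            s2_raw=np.ones(G),
            s2_shrunk=np.ones(G),
            prior_df=np.inf,
            df_residual=60 - full_design.n_coef,
        )
        return Y, fits, disp, offs, phi

    def test_matches_independent_likelihood_ratio(self, full_design):
        """With infinite prior df and unit QL dispersion, F*df1 equals the
        NB likelihood-ratio statistic from an independent pair of fits."""
        Y, fits, disp, offs, phi = self._lrt_oracle_setup(full_design)
        cs = within_species_contrasts(full_design)
        c = cs.vectors["CE-avg_Na"]
        res = ql_f_test(fits, disp, c[None, :])
        X = full_design.X
        X0, df1 = contrast_null_design(X, c[None, :])
        for g in range(Y.shape[0]):
            full = sm.GLM(
                Y[g], X, family=sm.families.NegativeBinomial(alpha=phi), offset=offs
            ).fit(tol=1e-12, maxiter=300)
            red = sm.GLM(
                Y[g], X0, family=sm.families.NegativeBinomial(alpha=phi), offset=offs
            ).fit(tol=1e-12, maxiter=300)
            lrt = 2 * (full.llf - red.llf)
            assert res.F.iloc[g] * res.df1.iloc[g] == pytest.approx(lrt, abs=1e-6)

    def test_constrained_deviance_never_below_full(self, fitted):
        fits, disp = fitted["fits"], fitted["dispersions"]
        cs = within_species_contrasts(fitted["design"])
        res = ql_f_test(fits, disp, cs)
        assert (res.F >= 0).all()

    def test_zero_contrast_rejected(self, fitted):
        with pytest.raises(ValueError, match="zero contrast"):
            ql_f_test(
                fitted["fits"],
                fitted["dispersions"],
                np.zeros(fitted["design"].n_coef)[None, :],
            )

    def test_results_invariant_to_reference_part(self, small_experiment):
        cm, st, _ = small_experiment
        sub = cm.counts.iloc[:40]
        offs = np.log(cm.lib_sizes.to_numpy(float))
        out = {}
        for ref in ("BS", "CE"):
            d = build_design(st, reference_part=ref)
            disp = estimate_dispersion(sub.to_numpy(), d, offs)
            fits = fit_genes(sub.to_numpy(), d, offs, disp.phi_trend, list(sub.index))
            cs = within_species_contrasts(d)
            out[ref] = ql_f_test(fits, disp, cs.vectors["DI-avg_Na"][None, :])
        np.testing.assert_allclose(out["BS"].p, out["CE"].p, rtol=1e-4)
        np.testing.assert_allclose(
            out["BS"].filter(like="log2FC").to_numpy(),
            out["CE"].filter(like="log2FC").to_numpy(),
            atol=1e-5,
        )

    def test_offset_shift_leaves_log2fc_unchanged(self, full_design):
        rng = np.random.default_rng(14)
        offs = np.full(60, np.log(1e6))
        mu = np.exp(offs - 8.0)
        Y = rng.poisson(mu, size=(3, 60)).astype(float)
        f1 = fit_genes(Y, full_design, offs, 0.05)
        f2 = fit_genes(Y, full_design, offs + 1.3, 0.05)
        c = within_species_contrasts(full_design).vectors["OT-avg_Ve"]
        np.testing.assert_allclose(f1.log2fc(c), f2.log2fc(c), atol=1e-6)

    def test_null_pvalues_roughly_uniform(self, full_design):
        """Omnibus p-values under a pure null are approximately uniform."""
        from scipy import stats as sps

        rng = np.random.default_rng(15)
        G = 2000
        offs = np.full(60, np.log(1e6))
        base = rng.normal(-8.5, 1.0, size=G)
        mu = np.exp(offs[None, :] + base[:, None])
        phi = rng.gamma(4.0, 0.025, size=G)
        Y = rng.negative_binomial(1 / phi[:, None], 1 / (1 + phi[:, None] * mu))
        disp = estimate_dispersion(Y, full_design, offs)
        fits = fit_genes(Y, full_design, offs, disp.phi_trend)
        cs = within_species_contrasts(full_design)
        res = ql_f_test(fits, disp, cs)
        ks = sps.kstest(res.p, "uniform").statistic
        assert ks < 0.05
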