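import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qlseq import (
    build_design,
    estimate_dispersion,
    fit_genes,
    interaction_contrasts,
    within_species_contrasts,
)
from qlseq.effects import (
    equivalence_global,
    equivalence_per_contrast,
    tost_equivalence,
    tost_matrix,
    treat_test,
)
from qlseq.model import LN2, contrast_se
from qlseq.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="module")
def interaction_fit():
    """Experiment where a third of genes carry a 3-log2-unit interaction
    effect and the rest are fully null between species."""
    cfg = SimConfig(
        genes=250, seed=21, frac_part_de=0.0, frac_interaction=0.3,
        interaction_lfc_low=3.0, interaction_lfc_high=3.0,
    )
    cm, st, truth = simulate_experiment(cfg)
    design = build_design(st)
    offs = np.log(cm.lib_sizes.to_numpy(float))
    disp = estimate_dispersion(cm, design, offs)
    fits = fit_genes(cm, design, offs, disp.phi_trend)
    return {"design": design, "fits": fits, "disp": disp, "truth": truth}


class TestTreat:
    def test_negative_threshold_rejected(self, fitted):
        cs = within_species_contrasts(fitted["design"])
        with pytest.raises(ValueError):
            treat_test(fitted["fits"], fitted["dispersions"], cs.matrix()[0], -1)

    def test_null_estimate_gives_p_near_one(self, fitted):
        """Genes with a true fold change of zero should essentially never
        clear a 2-log2-unit threshold."""
        cs = within_species_contrasts(fitted["design"])
        name, vec = next(iter(cs.vectors.items()))
        truth = fitted["truth"].within_lfc[name].reindex(fitted["fits"].gene_ids)
        null = (truth.abs() < 1e-12).to_numpy()
        res = treat_test(fitted["fits"], fitted["dispersions"], vec, 2.0)
        assert res.p.to_numpy()[null].min() > 0.5

    def test_tau_zero_reduces_to_two_sided(self, fitted):
        fits, disp = fitted["fits"], fitted["dispersions"]
        vec = next(iter(within_species_contrasts(fitted["design"]).vectors.values()))
        res = treat_test(fits, disp, vec, 0.0)
        est = fits.beta @ vec
        se = contrast_se(fits, disp, vec)
        t = np.abs(est) / se
        p2 = 2 * stats.t.sf(t, disp.df_total)
        np.testing.assert_allclose(res.p, p2, atol=1e-8)

    def test_estimate_at_threshold_gives_half(self):
        """|estimate| = tau with small SE: the near-boundary tail is 1/2 and
        the far tail vanishes."""
        # direct construction through the formula's inputs: a synthetic fit
        # with known estimate and tiny SE is emulated by an exact NB mean
        cfg = SimConfig(genes=1, seed=3, frac_part_de=0.0, frac_interaction=0.0)
        cm, st, _ = simulate_experiment(cfg)
        design = build_design(st)
        offs = np.log(cm.lib_sizes.to_numpy(float))
        # plant a CE effect of exactly 2 log2 units in both species
        ce = design.matrix["part_CE"].to_numpy()
        mu = np.exp(offs - 6.0 + 2.0 * LN2 * ce)
        rng = np.random.default_rng(4)
        Y = rng.poisson(mu * 50)[None, :]  # huge counts -> tiny SE
        disp = estimate_dispersion(Y, design, offs, common_only=True)
        fits = fit_genes(Y, design, offs, disp.phi_trend)
        # test against the realised estimate: the near-boundary tail is
        # exactly 1/2 and the far tail is negligible at this SE
        c = design.part_effect_vector("CE", design.species[0])
        est = abs(float((fits.beta @ c)[0]) / LN2)
        res = treat_test(fits, disp, c, tau_log2=est)
        assert res.p.iloc[0] == pytest.approx(0.5, abs=0.01)
        # and a 2-unit threshold is not rejected for a 2-unit true effect
        assert treat_test(fits, disp, c, 2.0).p.iloc[0] > 0.05


class TestTost:
    def test_sign_flip_invariance(self, interaction_fit):
        f = interaction_fit
        vec = next(iter(interaction_contrasts(f["design"]).vectors.values()))
        p1 = tost_equivalence(f["fits"], f["disp"], vec, 2.0).p
        p2 = tost_equivalence(f["fits"], f["disp"], -vec, 2.0).p
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_true_zero_difference_yields_small_p(self, interaction_fit):
        f = interaction_fit
        itc = interaction_contrasts(f["design"])
        name, vec = next(iter(itc.vectors.items()))
        truth = f["truth"].interaction_lfc[name]
        null = (truth.abs() < 1e-12).to_numpy()
        res = tost_equivalence(f["fits"], f["disp"], vec, 2.0)
        # most truly-equivalent genes should have small TOST p
        assert np.median(res.p.to_numpy()[null]) < 0.05

    def test_large_true_difference_never_equivalent(self, interaction_fit):
        f = interaction_fit
        itc = interaction_contrasts(f["design"])
        for name, vec in list(itc.vectors.items())[:3]:
            truth = f["truth"].interaction_lfc[name]
            big = (truth.abs() >= 3.0 - 1e-9).to_numpy()
            if not big.any():
                continue
            res = tost_equivalence(f["fits"], f["disp"], vec, 2.0)
            assert res.p.to_numpy()[big].min() > 0.05

    def test_p_is_max_of_one_sided(self, interaction_fit):
        f = interaction_fit
        vec = next(iter(interaction_contrasts(f["design"]).vectors.values()))
        res = tost_equivalence(f["fits"], f["disp"], vec, 2.0)
        np.testing.assert_allclose(res.p, np.maximum(res.p_lower, res.p_upper))

    def test_agrees_with_wald_tost(self, interaction_fit):
        """Offset-shift TOST tracks a Wald-style TOST (estimate +- Delta over
        QL SE on the same df) on well-behaved genes."""
        f = interaction_fit
        vec = next(iter(interaction_contrasts(f["design"]).vectors.values()))
        res = tost_equivalence(f["fits"], f["disp"], vec, 2.0)
        est = f["fits"].beta @ vec
        se = contrast_se(f["fits"], f["disp"], vec)
        df = f["disp"].df_total
        d = 2.0 * LN2
        p_lo = stats.t.sf((est + d) / se, df)
        p_hi = stats.t.cdf((est - d) / se, df)
        wald = np.maximum(p_lo, p_hi)
        mid = (res.p.to_numpy() > 0.01) & (res.p.to_numpy() < 0.99)
        rel = np.abs(res.p.to_numpy()[mid] - wald[mid]) / wald[mid]
        assert np.median(rel) < 0.10

    def test_contrast_outside_row_space_rejected(self, interaction_fit):
        f = interaction_fit
        bad = np.zeros(f["design"].n_coef + 1)
        with pytest.raises(Exception):
            tost_equivalence(f["fits"], f["disp"], bad, 2.0)


class TestEquivalenceAggregation:
    def test_all_zero_p_all_equivalent(self):
        tp = pd.DataFrame(np.zeros((10, 3)), columns=list("abc"))
        res = equivalence_per_contrast(tp)
        assert (res.summary.prop_equivalent == 1.0).all()
        glob = equivalence_global(tp)
        assert glob.equivalent.all()

    def test_gene_with_one_p_of_one_never_globally_equivalent(self):
        tp = pd.DataFrame({"a": [0.0, 0.0], "b": [1.0, 0.0]}, index=["g1", "g2"])
        glob = equivalence_global(tp)
        assert not glob.loc["g1", "equivalent"]
        assert glob.loc["g2", "equivalent"]

    def test_uniform_p_yields_no_flags(self):
        rng = np.random.default_rng(5)
        tp = pd.DataFrame({"a": rng.uniform(size=500)})
        res = equivalence_per_contrast(tp)
        assert res.summary.prop_equivalent.iloc[0] < 0.02

    def test_na_entries_rejected(self):
        tp = pd.DataFrame({"a": [0.1, np.nan]})
        with pytest.raises(ValueError):
            equivalence_global(tp)
        with pytest.raises(ValueError):
            equivalence_per_contrast(tp)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            equivalence_per_contrast(pd.DataFrame(columns=["a"]))

    def test_equivalence_power_grows_with_replication(self):
        """With no true between-species differences, the equivalent
        proportion rises with the number of individuals per species."""
        props = []
        for n_ind in (3, 5, 8):
            cfg = SimConfig(
                genes=120, seed=31, individuals_per_species=n_ind,
                frac_part_de=0.0, frac_interaction=0.0,
            )
            cm, st, _ = simulate_experiment(cfg)
            design = build_design(st)
            offs = np.log(cm.lib_sizes.to_numpy(float))
            disp = estimate_dispersion(cm, design, offs)
            fits = fit_genes(cm, design, offs, disp.phi_trend)
            itc = interaction_contrasts(design)
            name, vec = next(iter(itc.vectors.items()))
            res = tost_equivalence(fits, disp, vec, 2.0)
            props.append(float((res.p <= 0.05).mean()))
        assert props[0] <= props[1] + 0.05
        assert props[1] <= props[2] + 0.05
        assert props[2] > props[0]


class TestMutualExclusion:
    def test_not_both_equivalent_and_beyond_threshold(self, interaction_fit):
        """No gene/contrast can be flagged equivalent within [-2, 2] and
        simultaneously significantly |log2FC| > 2."""
        f = interaction_fit
        itc = interaction_contrasts(f["design"])
        tp = tost_matrix(f["fits"], f["disp"], itc, 2.0)
        eq_flags = equivalence_per_contrast(tp).flags
        violations = 0
        for name, vec in itc.vectors.items():
            tr = treat_test(f["fits"], f["disp"], vec, 2.0)
            beyond = tr.p.to_numpy() <= 0.05
            violations += int((eq_flags[name].to_numpy() & beyond).sum())
        assert violations == 0
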