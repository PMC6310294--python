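"""Gaussian animal-model REML, BLUP and heritability."""

import numpy as np
import pandas as pd
import pytest

from pigquant.gaussian import (
    DegenerateDataError,
    VarianceComponents,
    fit_bivariate,
    fit_univariate,
    heritability,
    reml_loglik,
    solve_mme,
)
from pigquant.model import DesignError, ModelSpec, build_design, preset_model
from pigquant.pedigree import validate_pedigree
from pigquant.simdata import SimulationConfig, TraitSimSpec, simulate_herd


def _vc(a, pe, e, cov=None):
    return VarianceComponents(
        trait="t", sigma2_a=a, sigma2_pe=pe, sigma2_e=e,
        cov=np.zeros((3, 3)) if cov is None else cov,
        converged=True, n_iterations=1, restricted_loglik=0.0,
        boundary=(False, False, False),
    )


class TestHeritability:
    def test_all_genetic(self):
        h2, se = heritability(_vc(1.0, 0.0, 0.0))
        assert h2 == 1.0 and se == 0.0

    def test_se_propagation_positive(self):
        cov = np.diag([0.01, 0.001, 0.01])
        _, se = heritability(_vc(0.5, 0.1, 0.9, cov))
        assert se > 0

    def test_zero_total_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            heritability(_vc(0.0, 0.0, 0.0))


class TestModelSpec:
    def test_study_presets_fixed_factors(self):
        assert preset_model("bt2").fixed_factors == ("sex", "breed")
        assert preset_model("ls2").fixed_factors == ("sex", "breed", "rearing", "familiar")
        assert preset_model("adg").fixed_factors == ("sex", "breed", "rearing", "finishing")

    def test_unknown_trait_and_factor_rejected(self):
        with pytest.raises(DesignError):
            preset_model("nope")
        with pytest.raises(DesignError):
            ModelSpec(trait="t", fixed_factors=("weather",))

    def test_constant_trait_rejected(self, small_herd):
        df = small_herd.phenotypes.copy()
        df["t"] = 1.0
        with pytest.raises(DesignError, match="constant"):
            build_design(df, small_herd.pedigree, ModelSpec(trait="t"))

    def test_confounded_factors_named(self, small_herd):
        df = small_herd.phenotypes.copy()
        df["breed"] = df["sex"]  # perfectly confounded
        with pytest.raises(DesignError, match="confounded.*(sex|breed)"):
            build_design(df, small_herd.pedigree,
                         ModelSpec(trait="t", fixed_factors=("sex", "breed")))


class TestRemlAgainstMixedLMOracle:
    def test_litter_only_model_matches_statsmodels(self):
        # with sigma2_a forced to ~0 the animal model reduces to a random-
        # intercept model that statsmodels MixedLM fits by its own REML
        import statsmodels.formula.api as smf

        spec = TraitSimSpec(name="t", sigma2_a=0.0, sigma2_le=0.3, sigma2_e=0.7,
                            fixed_effects={"sex": (0.0, 0.5)})
        cfg = SimulationConfig(n_sires=10, n_dams=60, litter_size_mean=6,
                               seed=21, traits={"t": spec})
        herd = simulate_herd(cfg)
        fit = fit_univariate(herd.phenotypes, herd.pedigree, ModelSpec("t", ("sex",)))
        df = herd.phenotypes
        sm_fit = smf.mixedlm("t ~ C(sex)", df, groups=df["litter"]).fit(reml=True)
        # our model carries an extra (near-boundary) animal component; the
        # litter and residual variances must agree closely
        assert fit.components.sigma2_pe == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), abs=0.02
        )
        assert (
            fit.components.sigma2_e + fit.components.sigma2_a
            == pytest.approx(float(sm_fit.scale), abs=0.02)
        )


class TestUnivariateFit:
    def test_zero_additive_variance_hits_boundary(self):
        spec = TraitSimSpec(name="t", sigma2_a=0.0, sigma2_le=0.2, sigma2_e=0.8)
        cfg = SimulationConfig(n_sires=10, n_dams=40, seed=22, traits={"t": spec})
        herd = simulate_herd(cfg)
        fit = fit_univariate(herd.phenotypes, herd.pedigree, ModelSpec("t"))
        h2, _ = heritability(fit.components)
        assert h2 < 0.08

    def test_row_order_and_level_label_invariance(self, small_herd):
        ped = small_herd.pedigree
        spec = ModelSpec("t", ("sex",))
        base = fit_univariate(small_herd.phenotypes, ped, spec).components
        shuffled = small_herd.phenotypes.sample(frac=1.0, random_state=5).reset_index(drop=True)
        shuffled["sex"] = shuffled["sex"].map({0: 9, 1: 4})  # reverses level order
        alt = fit_univariate(shuffled, ped, spec).components
        for key in ("sigma2_a", "sigma2_pe", "sigma2_e"):
            assert getattr(alt, key) == pytest.approx(getattr(base, key), abs=1e-5)

    def test_missing_rows_dropped_but_animals_keep_ebv(self, small_herd):
        df = small_herd.phenotypes.copy()
        dropped = df["animal"].iloc[:30]
        df.loc[df["animal"].isin(dropped), "t"] = np.nan
        fit = fit_univariate(df, small_herd.pedigree, ModelSpec("t", ("sex",)))
        assert fit.ebv.index.size == small_herd.pedigree.n
        assert fit.ebv.loc[dropped].notna().all()
        assert not fit.mme.with_own_record.loc[dropped].any()

    def test_reported_optimum_beats_local_grid(self, small_herd):
        from pigquant.gaussian import _univariate_parts
        from pigquant.pedigree import relationship_matrix

        fit = fit_univariate(small_herd.phenotypes, small_herd.pedigree, ModelSpec("t", ("sex",)))
        d = build_design(small_herd.phenotypes, small_herd.pedigree, ModelSpec("t", ("sex",)))
        parts, _ = _univariate_parts(d, relationship_matrix(small_herd.pedigree))
        th = np.array([fit.components.sigma2_a, fit.components.sigma2_pe, fit.components.sigma2_e])
        opt = reml_loglik(d.y, d.X, parts, th)
        rng = np.random.default_rng(0)
        for _ in range(40):
            probe = th * np.exp(rng.uniform(-0.15, 0.15, size=3))
            assert opt >= reml_loglik(d.y, d.X, parts, probe) - 1e-6


class TestMME:
    def test_uninformed_founder_has_zero_ebv(self):
        ped = validate_pedigree(
            [("s", "", ""), ("d", "", ""), ("x", "s", "d"), ("lone", "", "")]
        )
        df = pd.DataFrame({"animal": ["x", "s"], "litter": ["L1", "L0"],
                           "t": [1.3, 0.2]})
        comps = _vc(0.4, 0.1, 0.5)
        sol = solve_mme(df, ped, ModelSpec("t"), comps)
        assert sol.ebv.loc["lone"] == pytest.approx(0.0, abs=1e-12)
        assert sol.ebv.loc["x"] != 0.0
        assert sol.relative_residual <= 1e-8

    def test_large_additive_variance_limit(self):
        # sigma2_a >> sigma2_e: a phenotyped animal's EBV approaches its
        # intercept-corrected phenotype
        ped = validate_pedigree([(f"x{i}", "", "") for i in range(6)])
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"animal": [f"x{i}" for i in range(6)],
                           "litter": [f"L{i}" for i in range(6)],
                           "t": rng.normal(size=6)})
        comps = _vc(1e6, 1e-6, 1.0)
        sol = solve_mme(df, ped, ModelSpec("t"), comps)
        expected = df["t"] - sol.fixed_effects["intercept"]
        assert np.allclose(sol.ebv.loc[df["animal"]].to_numpy(), expected, atol=1e-3)

    def test_blup_regression_on_true_breeding_values(self):
        # regression of true BV on EBV ~ 1 (BLUP property), n = 2000
        spec = TraitSimSpec(name="t", sigma2_a=0.5, sigma2_le=0.1, sigma2_e=0.4,
                            fixed_effects={"sex": (0.0, 0.3)})
        cfg = SimulationConfig(n_sires=62, n_dams=270, litter_size_mean=7.4,
                               seed=23, traits={"t": spec})
        herd = simulate_herd(cfg)
        sol = solve_mme(herd.phenotypes, herd.pedigree, ModelSpec("t", ("sex",)),
                        _vc(0.5, 0.1, 0.4))
        tb = herd.true_breeding_values.set_index("animal")["t"]
        ebv = sol.ebv.loc[tb.index]
        slope = np.cov(tb, ebv)[0, 1] / np.var(ebv.to_numpy())
        assert slope == pytest.approx(1.0, abs=0.1)
        assert sol.relative_residual <= 1e-8


class TestBivariate:
    def _spec(self, name):
        return TraitSimSpec(name=name, sigma2_a=0.3, sigma2_le=0.1, sigma2_e=0.6,
                            fixed_effects={"sex": (0.0, 0.2)})

    def _herd(self, seed, rg):
        cfg = SimulationConfig(
            n_sires=16, n_dams=68, litter_size_mean=7.4, seed=seed,
            traits={"u": self._spec("u"), "v": self._spec("v")},
            genetic_corr={("u", "v"): rg} if rg else {},
        )
        return simulate_herd(cfg)

    def test_trait_with_own_copy_fully_correlated(self, small_herd):
        df = small_herd.phenotypes.copy()
        df["w"] = df["t"]
        bi = fit_bivariate(df, small_herd.pedigree, ModelSpec("t"), ModelSpec("w"))
        assert bi.genetic_correlation == pytest.approx(1.0, abs=0.01)
        assert bi.phenotypic_correlation == pytest.approx(1.0, abs=0.01)

    def test_genetic_correlation_recovery(self):
        # scaled-down recovery: rg = 0.8, 5 replicates of ~500 pigs
        ms_u, ms_v = ModelSpec("u", ("sex",)), ModelSpec("v", ("sex",))
        rgs = []
        for seed in range(5):
            herd = self._herd(seed, 0.8)
            bi = fit_bivariate(herd.phenotypes, herd.pedigree, ms_u, ms_v)
            rgs.append(bi.genetic_correlation)
        assert np.mean(rgs) == pytest.approx(0.8, abs=0.15)

    def test_independent_traits_centred_on_zero(self):
        ms_u, ms_v = ModelSpec("u", ("sex",)), ModelSpec("v", ("sex",))
        rgs = []
        for seed in range(30, 35):
            herd = self._herd(seed, 0.0)
            bi = fit_bivariate(herd.phenotypes, herd.pedigree, ms_u, ms_v)
            rgs.append(bi.genetic_correlation)
        assert abs(np.mean(rgs)) < 0.2

    def test_disjoint_records_fix_residual_covariance(self, small_herd):
        df = small_herd.phenotypes.copy()
        n = len(df)
        df["u"] = df["t"]
        df["v"] = df["t"] + 0.1
        df.loc[: n // 2, "v"] = np.nan
        df.loc[n // 2 + 1 :, "u"] = np.nan
        bi = fit_bivariate(df, small_herd.pedigree, ModelSpec("u"), ModelSpec("v"))
        assert not bi.components.residual_cov_estimated
        assert bi.components.theta[7] == 0.0
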