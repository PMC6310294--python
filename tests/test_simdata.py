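"""Synthetic-herd generator: structure, moments, determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pigquant.simdata import (
    FACTOR_LEVELS,
    STUDY_TRAITS,
    SimulationConfig,
    TraitSimSpec,
    apply_missingness,
    calibrate_thresholds,
    discretize,
    study_herd_config,
    study_trait_spec,
    simulate_breeding_values,
    simulate_herd,
    simulate_liabilities,
    simulate_pedigree,
)


class TestPedigreeSimulation:
    def test_study_scale_offspring_count(self):
        # 31 sires x 135 dams aiming at ~1004 phenotyped offspring
        counts = []
        for seed in range(3):
            ped = simulate_pedigree(study_herd_config(seed=seed, traits=["pss"]))
            counts.append(sum(a.startswith("P") for a in ped.animals))
        assert all(abs(c - 1004) < 0.10 * 1004 for c in counts)

    def test_depth_zero_parents_are_founders(self):
        cfg = SimulationConfig(n_sires=2, n_dams=2, litter_size_mean=3,
                               generation_depth=0, seed=1, traits={})
        ped = simulate_pedigree(cfg)
        founders = {a for a, f in zip(ped.animals, ped.is_founder()) if f}
        assert {"S0001", "S0002", "D0001", "D0002"} <= founders

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=9, traits={})
        p1, p2 = simulate_pedigree(cfg), simulate_pedigree(cfg)
        assert p1.animals == p2.animals
        assert np.array_equal(p1.sire, p2.sire)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_sires=0)


class TestLiabilities:
    def test_no_genetics_moment_recovery(self):
        # sigma2_a = 0: total variance ~ sigma2_le + sigma2_e at n = 10,000
        spec = TraitSimSpec(name="t", sigma2_a=0.0, sigma2_le=0.2, sigma2_e=0.8)
        cfg = SimulationConfig(n_sires=60, n_dams=700, litter_size_mean=14.3,
                               seed=3, traits={"t": spec})
        herd = simulate_herd(cfg)
        y = herd.phenotypes["t"]
        assert len(y) > 8000
        assert herd.true_breeding_values["t"].abs().max() == 0.0
        assert y.var() == pytest.approx(1.0, rel=0.05)

    def test_full_sib_covariance(self):
        # cov(full sibs) ~ 0.5 sigma2_a + sigma2_le
        spec = TraitSimSpec(name="t", sigma2_a=0.5, sigma2_le=0.1, sigma2_e=0.4)
        cfg = SimulationConfig(n_sires=100, n_dams=2000, litter_size_mean=2.5,
                               generation_depth=0, seed=4, traits={"t": spec})
        herd = simulate_herd(cfg)
        df = herd.phenotypes
        pairs = []
        for _, grp in df.groupby("litter"):
            v = grp["t"].to_numpy()
            if len(v) >= 2:
                pairs.append((v[0], v[1]))
        a, b = np.array(pairs).T
        cov = np.cov(a, b)[0, 1]
        assert cov == pytest.approx(0.35, abs=0.05)

    def test_all_zero_variances_gives_exact_mean(self):
        spec = TraitSimSpec(name="t", mu=3.0, sigma2_a=0.0, sigma2_le=0.0,
                            sigma2_e=0.0, fixed_effects={"sex": (0.0, 1.0)})
        cfg = SimulationConfig(n_sires=4, n_dams=10, seed=5, traits={"t": spec})
        herd = simulate_herd(cfg)
        expected = 3.0 + herd.phenotypes["sex"].to_numpy() * 1.0
        assert np.array_equal(herd.phenotypes["t"].to_numpy(), expected)

    def test_mendelian_sampling_variance_halved_for_nonfounders(self):
        # trio-only pedigrees: offspring BV variance = 0.5 var around parent mean
        from pigquant.pedigree import validate_pedigree

        recs = [("s", "", ""), ("d", "", "")] + [(f"x{i}", "s", "d") for i in range(4000)]
        ped = validate_pedigree(recs)
        bv = simulate_breeding_values(ped, np.array([[1.0]]), np.random.default_rng(6))[:, 0]
        parent_mean = 0.5 * (bv[0] + bv[1])
        dev = bv[2:] - parent_mean
        assert dev.var() == pytest.approx(0.5, rel=0.1)

    def test_liabilities_standalone_deterministic(self, small_herd):
        spec = small_herd.config.traits["t"]
        args = (small_herd.pedigree, spec, small_herd.phenotypes)
        y1 = simulate_liabilities(*args, seed=11)
        y2 = simulate_liabilities(*args, seed=11)
        assert np.array_equal(y1, y2)


class TestDiscretize:
    def test_no_thresholds_single_category(self):
        assert set(discretize(np.random.default_rng(0).normal(size=50), [])) == {0}

    def test_monotone_in_latent(self):
        x = np.sort(np.random.default_rng(1).normal(size=200))
        s = discretize(x, [-1.0, 0.3, 2.0])
        assert (np.diff(s) >= 0).all()

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_monotone_property(self, xs):
        s = discretize(np.array(xs), [-1.0, 1.0], support=(1, 3))
        order = np.argsort(xs, kind="stable")
        assert (np.diff(s[order]) >= 0).all()
        assert set(s) <= {1, 2, 3}

    def test_decreasing_thresholds_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.zeros(3), [1.0, 0.5])

    def test_piglet_scale_score_moments(self):
        # thresholds calibrated for the piglet scale score: mean 2.0, SD 0.8
        spec = study_trait_spec("pss", missing_rate=0.0)
        cfg = SimulationConfig(n_sires=40, n_dams=700, litter_size_mean=7.4,
                               seed=7, traits={"pss": spec})
        herd = simulate_herd(cfg)
        y = herd.phenotypes["pss"]
        assert len(y) > 5000
        assert y.mean() == pytest.approx(2.0, abs=0.05)
        assert y.std() == pytest.approx(0.8, abs=0.05)

    def test_calibrated_thresholds_increasing(self):
        for trait in ("bt1", "inj", "rss", "ls2"):
            t = calibrate_thresholds(study_trait_spec(trait))
            assert (np.diff(t) > 0).all()


class TestMissingness:
    def test_zero_rate_unchanged(self, small_herd):
        out = apply_missingness(small_herd.phenotypes, {"t": 0.0}, seed=0)
        pd.testing.assert_frame_equal(out, small_herd.phenotypes)

    def test_backtest2_rate(self):
        df = pd.DataFrame({"x": np.ones(1004)})
        out = apply_missingness(df, {"x": 0.234}, seed=1)
        remaining = out["x"].notna().sum()
        # binomial: 769 expected, 3 sigma ~ 40
        assert abs(remaining - 769) < 45

    def test_masked_cells_are_nan_not_sentinel(self):
        df = pd.DataFrame({"x": np.arange(100, dtype=float)})
        out = apply_missingness(df, {"x": 0.5}, seed=2)
        masked = out["x"].isna()
        assert masked.any()
        assert np.array_equal(out.loc[~masked, "x"], df.loc[~masked, "x"])

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            apply_missingness(pd.DataFrame({"x": [1.0]}), {"x": 1.0})


class TestWholeHerd:
    def test_full_chain_determinism(self):
        cfg = study_herd_config(seed=13, traits=["bt1", "pss", "pdg"])
        h1, h2 = simulate_herd(cfg), simulate_herd(cfg)
        pd.testing.assert_frame_equal(h1.phenotypes, h2.phenotypes)
        assert h1.pedigree.animals == h2.pedigree.animals
        h3 = simulate_herd(study_herd_config(seed=14, traits=["bt1", "pss", "pdg"]))
        assert not h1.phenotypes["bt1"].equals(h3.phenotypes["bt1"])

    def test_score_supports_respected(self):
        herd = simulate_herd(study_herd_config(seed=15))
        df = herd.phenotypes
        for trait, meta in STUDY_TRAITS.items():
            support = meta[5]
            if support is not None:
                vals = df[trait].dropna()
                assert vals.min() >= support[0] and vals.max() <= support[1], trait
        for factor, nlev in FACTOR_LEVELS.items():
            assert set(df[factor].unique()) <= set(range(nlev))

    def test_litter_level_factor_assignment(self):
        herd = simulate_herd(study_herd_config(seed=16, traits=["pss"]))
        df = herd.phenotypes
        for factor in ("breed", "rearing", "finishing", "familiar"):
            assert (df.groupby("litter")[factor].nunique() == 1).all()

    def test_every_phenotyped_animal_in_pedigree(self):
        herd = simulate_herd(study_herd_config(seed=17, traits=["pss"]))
        assert set(herd.phenotypes["animal"]) <= set(herd.pedigree.animals)

    def test_genetic_correlation_realized(self):
        s = dict(sigma2_a=0.5, sigma2_le=0.0, sigma2_e=0.01)
        cfg = SimulationConfig(
            n_sires=30, n_dams=400, litter_size_mean=5, seed=18,
            traits={"u": TraitSimSpec(name="u", **s), "v": TraitSimSpec(name="v", **s)},
            genetic_corr={("u", "v"): 0.8},
        )
        herd = simulate_herd(cfg)
        tb = herd.true_breeding_values
        r = np.corrcoef(tb["u"], tb["v"])[0, 1]
        assert r == pytest.approx(0.8, abs=0.05)
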