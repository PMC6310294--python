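"""Synthetic-herd generator.

Emulates the data structure of an on-farm pig behaviour study: a two-line
herd of ~1,000 fattening pigs descended from 31 boars and 135 sows, with an
optional grandparental layer, litter (common-environment) structure, group-
level housing treatments, and behaviour scores produced by thresholding a
Gaussian liability.  The generative model per trait is

    y* = mu + fixed effects + litter + a + e

with ``litter ~ N(0, sigma2_le)`` shared within litter, ``a`` the additive
breeding value generated down the pedigree (founders ``N(0, sigma2_a)``,
non-founders parent-average plus Mendelian sampling with variance
``0.5 * sigma2_a * (1 - (F_s + F_d)/2)``), and ``e`` i.i.d. residual, either
Gaussian or logistic (the latter for liability-scale binary traits).
Discrete scores are the liability cut at ordered thresholds.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import Pedigree, inbreeding, validate_pedigree

__all__ = [
    "TraitSimSpec",
    "SimulationConfig",
    "Herd",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_liabilities",
    "discretize",
    "apply_missingness",
    "simulate_herd",
    "study_herd_config",
    "STUDY_TRAITS",
    "FACTOR_PROBS",
    "FACTOR_LEVELS",
]

#: factor levels of the study design (sex 2, breed 2, rearing 3, finishing 2,
#: number-of-unfamiliar-pigs class 4)
FACTOR_LEVELS = {"sex": 2, "breed": 2, "rearing": 3, "finishing": 2, "familiar": 4}

#: marginal probabilities used when assigning factor levels.  Breed reflects
#: the 190:814 purebred:crossbred split; housing groups are filled roughly
#: evenly; most finishing pens are the smaller system.
FACTOR_PROBS = {
    "sex": (0.5, 0.5),
    "breed": (0.19, 0.81),
    "rearing": (1 / 3, 1 / 3, 1 / 3),
    "finishing": (0.75, 0.25),
    "familiar": (0.25, 0.25, 0.25, 0.25),
}

#: factors assigned at the litter (group) level rather than per animal —
#: housing and mixing are group treatments, and breed is a property of the dam
LITTER_LEVEL_FACTORS = ("breed", "rearing", "finishing", "familiar")


@dataclass
class TraitSimSpec:
    """Generative parameters for one trait.

    Parameters
    ----------
    mu : trait mean on the latent scale (trait units).
    sigma2_a, sigma2_le, sigma2_e :
        Additive-genetic, common-litter and residual variances.
    fixed_effects :
        Map factor name -> per-level additive effects (first level is the
        reference 0 by convention).  Only listed factors enter the liability.
    score_type : "gaussian", "ordinal" or "count".
        Ordinal scores live on ``support = (lo, hi)`` (e.g. 1..3), counts on
        0..hi.  Gaussian traits are returned as-is.
    thresholds :
        Ordered cut-points on the latent scale.  If None for a discrete
        trait, they are calibrated so the realized score distribution matches
        ``target_mean``/``target_sd`` on the declared support.
    residual : "gaussian" or "logistic" residual distribution (the logistic
        option, with ``sigma2_e = pi**2/3``, generates data exactly under the
        logit liability model).
    """

    name: str
    mu: float = 0.0
    sigma2_a: float = 1.0
    sigma2_le: float = 0.0
    sigma2_e: float = 1.0
    fixed_effects: dict = field(default_factory=dict)
    score_type: str = "gaussian"
    support: tuple | None = None
    target_mean: float | None = None
    target_sd: float | None = None
    thresholds: tuple | None = None
    missing_rate: float = 0.0
    residual: str = "gaussian"

    def __post_init__(self):
        for v in (self.sigma2_a, self.sigma2_le, self.sigma2_e):
            if v < 0:
                raise ValueError(f"{self.name}: variances must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"{self.name}: missing_rate must be in [0, 1)")
        if self.thresholds is not None:
            t = np.asarray(self.thresholds, dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{self.name}: thresholds must be strictly increasing")
        if self.score_type not in ("gaussian", "ordinal", "count"):
            raise ValueError(f"{self.name}: unknown score_type {self.score_type!r}")
        if self.score_type != "gaussian" and self.support is None:
            raise ValueError(f"{self.name}: discrete traits need a support range")

    @property
    def sigma2_total(self) -> float:
        return self.sigma2_a + self.sigma2_le + self.sigma2_e


@dataclass
class SimulationConfig:
    """Full specification of a simulated herd.

    Defaults are the study conditions: 31 sires, 135 dams, one litter per
    dam with Poisson litter size averaging 7.44 (so the expected number of
    phenotyped offspring is ~1,004), and one grandparental generation.
    """

    n_sires: int = 31
    n_dams: int = 135
    litters_per_dam: int = 1
    litter_size_mean: float = 7.44
    generation_depth: int = 1
    seed: int = 0
    traits: dict = field(default_factory=dict)
    genetic_corr: dict = field(default_factory=dict)
    litter_corr: dict = field(default_factory=dict)
    residual_corr: dict = field(default_factory=dict)

    def __post_init__(self):
        if min(self.n_sires, self.n_dams, self.litters_per_dam) < 1:
            raise ValueError("counts must be positive")
        if self.litter_size_mean <= 0:
            raise ValueError("litter_size_mean must be positive")
        if self.generation_depth < 0:
            raise ValueError("generation_depth must be >= 0")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class Herd:
    """A simulated herd: pedigree, phenotypes, and simulation truth."""

    pedigree: Pedigree
    phenotypes: pd.DataFrame
    true_breeding_values: pd.DataFrame
    config: SimulationConfig


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

def _simulate_structure(config: SimulationConfig, rng: np.random.Generator):
    """Build pedigree records plus offspring litter metadata."""
    records: list[tuple[str, str, str]] = []

    def make_layer(prefix, count, parent_sires, parent_dams):
        ids = [f"{prefix}{i + 1:04d}" for i in range(count)]
        for a in ids:
            if parent_sires is None:
                records.append((a, "", ""))
            else:
                s = parent_sires[rng.integers(len(parent_sires))]
                d = parent_dams[rng.integers(len(parent_dams))]
                records.append((a, s, d))
        return ids

    # ancestor layers, oldest first; generation_depth layers above the parents
    prev_sires = prev_dams = None
    for g in range(config.generation_depth, 0, -1):
        layer_sires = make_layer(f"GS{g}_", config.n_sires, prev_sires, prev_dams)
        layer_dams = make_layer(f"GD{g}_", config.n_dams, prev_sires, prev_dams)
        prev_sires, prev_dams = layer_sires, layer_dams

    sires = make_layer("S", config.n_sires, prev_sires, prev_dams)
    dams = make_layer("D", config.n_dams, prev_sires, prev_dams)

    meta = []  # (animal, litter, sire, dam)
    counter = 0
    for d_i, dam in enumerate(dams):
        for li in range(config.litters_per_dam):
            sire = sires[rng.integers(len(sires))]
            litter = f"L{d_i + 1:04d}_{li + 1}"
            size = rng.poisson(config.litter_size_mean)
            for _ in range(size):
                counter += 1
                animal = f"P{counter:05d}"
                records.append((animal, sire, dam))
                meta.append((animal, litter, sire, dam))
    if counter == 0:
        raise ValueError("configuration produced zero offspring")
    meta = pd.DataFrame(meta, columns=["animal", "litter", "sire", "dam"])
    return records, meta


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Simulate a herd pedigree (founders, optional grandparents, litters)."""
    rng = np.random.default_rng(config.seed)
    records, _ = _simulate_structure(config, rng)
    return validate_pedigree(records)


# ---------------------------------------------------------------------------
# genetic values and liabilities
# ---------------------------------------------------------------------------

def simulate_breeding_values(
    ped: Pedigree, sigma_a: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Simulate (possibly multi-trait) breeding values down the pedigree.

    ``sigma_a`` is the t x t additive covariance matrix (a scalar is accepted
    for t = 1).  Founders are N(0, sigma_a); a non-founder is the average of
    its known parents plus Mendelian sampling with relative variance 1 for
    founders, ``0.75 - 0.25 F_p`` with one known parent and
    ``0.5 - 0.25 (F_s + F_d)`` with both known.
    """
    sigma_a = np.atleast_2d(np.asarray(sigma_a, dtype=float))
    t = sigma_a.shape[0]
    L = np.linalg.cholesky(sigma_a + 1e-12 * np.eye(t)) if np.any(sigma_a) else np.zeros((t, t))
    F = inbreeding(ped)
    n = ped.n
    a = np.zeros((n, t))
    z = rng.standard_normal((n, t))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        known = [p for p in (s, d) if p >= 0]
        mean = 0.5 * sum(a[p] for p in known) if known else 0.0
        msv = 1.0 - 0.25 * sum(1.0 + F[p] for p in known)
        a[i] = mean + np.sqrt(msv) * (z[i] @ L.T)
    return a


def _fixed_effect_values(
    spec: TraitSimSpec, assignments: pd.DataFrame
) -> np.ndarray:
    """Sum of per-factor level effects for each row of ``assignments``."""
    out = np.zeros(len(assignments))
    for factor, effects in spec.fixed_effects.items():
        effects = np.asarray(effects, dtype=float)
        levels = assignments[factor].to_numpy()
        out += effects[levels]
    return out


def simulate_liabilities(
    ped: Pedigree,
    spec: TraitSimSpec,
    assignments: pd.DataFrame,
    seed=None,
    breeding_values: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Latent trait values for the phenotyped animals in ``assignments``.

    ``assignments`` must carry columns ``animal``, ``litter`` and any factor
    named in ``spec.fixed_effects`` (integer-coded levels).  Pre-simulated
    breeding values (one row per pedigree animal) may be passed to share
    genetics across traits; otherwise they are generated here.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if breeding_values is None:
        breeding_values = simulate_breeding_values(ped, spec.sigma2_a, rng)[:, 0]
    pos = ped.positions(assignments["animal"])
    a = np.asarray(breeding_values)[pos]

    litters = assignments["litter"].to_numpy()
    uniq, inv = np.unique(litters, return_inverse=True)
    litter_eff = rng.normal(0.0, np.sqrt(spec.sigma2_le), size=len(uniq))[inv]

    n = len(assignments)
    if spec.residual == "logistic":
        scale = np.sqrt(spec.sigma2_e) * np.sqrt(3.0) / np.pi
        e = rng.logistic(0.0, scale, size=n)
    else:
        e = rng.normal(0.0, np.sqrt(spec.sigma2_e), size=n)

    return spec.mu + _fixed_effect_values(spec, assignments) + litter_eff + a + e


# ---------------------------------------------------------------------------
# discretisation
# ---------------------------------------------------------------------------

def discretize(latent: np.ndarray, thresholds, support=None) -> np.ndarray:
    """Cut a latent value into ordered categories.

    ``k`` strictly increasing thresholds give ``k + 1`` categories.  With a
    ``support = (lo, hi)`` the categories are labelled ``lo .. lo + k``
    (which must fit in the support); otherwise 0-based codes are returned.
    Monotone: a larger latent value never maps to a smaller category.
    """
    t = np.asarray(thresholds, dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    codes = np.digitize(np.asarray(latent, dtype=float), t)
    lo = 0 if support is None else int(support[0])
    if support is not None and lo + t.size > int(support[1]):
        raise ValueError("more categories than the declared support allows")
    return codes + lo


def _discretized_normal_probs(m, s, lo, hi):
    """Bin probabilities of N(m, s^2) cut at half-integers, tails lumped."""
    edges = np.arange(lo, hi) + 0.5
    cdf = stats.norm.cdf(edges, loc=m, scale=s)
    return np.diff(np.concatenate([[0.0], cdf, [1.0]]))

def category_probs_for_moments(support, target_mean, target_sd):
    """Probabilities over an integer support matching target moments.

    Solves for the (mean, sd) of an underlying normal whose half-integer
    discretisation (tails lumped into the end categories) has the requested
    mean and standard deviation.  Falls back to the best least-squares match
    when the target is not exactly attainable on the support.
    """
    lo, hi = int(support[0]), int(support[1])
    values = np.arange(lo, hi + 1)

    def moments(params):
        p = _discretized_normal_probs(params[0], np.exp(params[1]), lo, hi)
        m = p @ values
        sd = np.sqrt(max(p @ (values - m) ** 2, 1e-12))
        return np.array([m - target_mean, sd - target_sd])

    x0 = np.array([target_mean, np.log(max(target_sd, 0.05))])
    sol = optimize.least_squares(moments, x0, xtol=1e-12, ftol=1e-12)
    return _discretized_normal_probs(sol.x[0], np.exp(sol.x[1]), lo, hi)


def calibrate_thresholds(spec: TraitSimSpec, latent_mean=None, latent_var=None):
    """Thresholds on the latent scale hitting the trait's target moments.

    Categories get the probabilities of :func:`category_probs_for_moments`;
    thresholds sit at the corresponding quantiles of the (approximately
    normal) latent distribution, whose mean/variance include the fixed-effect
    contribution under the default level frequencies.
    """
    if spec.thresholds is not None:
        return np.asarray(spec.thresholds, dtype=float)
    if latent_mean is None or latent_var is None:
        fm, fv = _fixed_effect_moments(spec)
        latent_mean = spec.mu + fm
        latent_var = spec.sigma2_total + fv
    probs = category_probs_for_moments(spec.support, spec.target_mean, spec.target_sd)
    cum = np.clip(np.cumsum(probs)[:-1], 1e-12, 1 - 1e-12)
    return latent_mean + np.sqrt(latent_var) * stats.norm.ppf(cum)


def _fixed_effect_moments(spec: TraitSimSpec):
    """Mean and variance added by the fixed effects under FACTOR_PROBS."""
    m = v = 0.0
    for factor, effects in spec.fixed_effects.items():
        p = np.asarray(FACTOR_PROBS[factor])
        e = np.asarray(effects, dtype=float)
        mu_f = p @ e
        m += mu_f
        v += p @ (e - mu_f) ** 2
    return m, v


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def apply_missingness(table: pd.DataFrame, rates: dict, seed=None, rng=None) -> pd.DataFrame:
    """Mask trait cells completely at random, per-trait, reproducibly.

    Masked cells become NaN (pandas missing), never a sentinel number.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out = table.copy()
    for trait, rate in rates.items():
        if not 0 <= rate < 1:
            raise ValueError(f"missing rate for {trait} must be in [0, 1)")
        if rate == 0 or trait not in out.columns:
            continue
        mask = rng.random(len(out)) < rate
        col = out[trait].astype(float)
        col[mask] = np.nan
        out[trait] = col
    return out


# ---------------------------------------------------------------------------
# whole-herd generation
# ---------------------------------------------------------------------------

def _assign_factors(meta: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Assign design-factor levels; group treatments vary at litter level."""
    out = meta[["animal", "litter"]].copy()
    litters = out["litter"].unique()
    litter_ix = {l: i for i, l in enumerate(litters)}
    for factor, nlev in FACTOR_LEVELS.items():
        p = FACTOR_PROBS[factor]
        if factor in LITTER_LEVEL_FACTORS:
            per_litter = rng.choice(nlev, size=len(litters), p=p)
            out[factor] = [per_litter[litter_ix[l]] for l in out["litter"]]
        else:
            out[factor] = rng.choice(nlev, size=len(out), p=p)
    return out


def _corr_matrix(names, variances, corr: dict) -> np.ndarray:
    """Covariance matrix across traits from per-trait variances + pair corr."""
    t = len(names)
    C = np.diag(np.asarray(variances, dtype=float))
    sd = np.sqrt(np.asarray(variances, dtype=float))
    for (t1, t2), r in corr.items():
        i, j = names.index(t1), names.index(t2)
        C[i, j] = C[j, i] = r * sd[i] * sd[j]
    return C


def simulate_herd(config: SimulationConfig) -> Herd:
    """Generate pedigree + phenotype table for every configured trait.

    The random stream is split per stage so the pedigree is identical across
    configs that share structure and seed regardless of the trait list.
    """
    root = np.random.SeedSequence(config.seed)
    s_ped, s_fac, s_gen, s_tr, s_miss = root.spawn(5)
    rng_ped = np.random.default_rng(s_ped)
    records, meta = _simulate_structure(config, rng_ped)
    ped = validate_pedigree(records)

    table = _assign_factors(meta, np.random.default_rng(s_fac))

    names = list(config.traits)
    specs = [config.traits[t] for t in names]

    # shared multi-trait breeding values (genetic correlations honoured)
    sigma_a = _corr_matrix(names, [s.sigma2_a for s in specs], config.genetic_corr)
    bv = simulate_breeding_values(ped, sigma_a, np.random.default_rng(s_gen))

    # litter and residual effects, possibly correlated across traits
    litters = table["litter"].to_numpy()
    uniq, inv = np.unique(litters, return_inverse=True)
    rng_tr = np.random.default_rng(s_tr)
    sigma_le = _corr_matrix(names, [s.sigma2_le for s in specs], config.litter_corr)
    le = _safe_mvn(rng_tr, sigma_le, len(uniq))[inv]

    n = len(table)
    pos = ped.positions(table["animal"])
    true_bv = pd.DataFrame({"animal": table["animal"]})
    for k, (name, spec) in enumerate(zip(names, specs)):
        if spec.residual == "logistic":
            scale = np.sqrt(spec.sigma2_e) * np.sqrt(3.0) / np.pi
            e = rng_tr.logistic(0.0, scale, size=n)
        else:
            e = rng_tr.normal(0.0, np.sqrt(spec.sigma2_e), size=n)
        latent = (
            spec.mu
            + _fixed_effect_values(spec, table)
            + le[:, k]
            + bv[pos, k]
            + e
        )
        if spec.score_type == "gaussian":
            table[name] = latent
        else:
            thresholds = calibrate_thresholds(spec)
            table[name] = discretize(latent, thresholds, spec.support).astype(float)
        true_bv[name] = bv[pos, k]

    rates = {t: s.missing_rate for t, s in zip(names, specs)}
    table = apply_missingness(table, rates, rng=np.random.default_rng(s_miss))
    return Herd(ped, table, true_bv, config)


def _safe_mvn(rng, cov, size):
    """Multivariate normal draws tolerating zero-variance components."""
    t = cov.shape[0]
    if not np.any(cov):
        return np.zeros((size, t))
    w, U = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return rng.standard_normal((size, t)) @ (U * np.sqrt(w)).T


# ---------------------------------------------------------------------------
# study presets
# ---------------------------------------------------------------------------

def _fx(sd, factors):
    """Modest group-level fixed effects scaled to the trait SD."""
    shapes = {
        "sex": (0.0, 0.25),
        "breed": (0.0, 0.3),
        "rearing": (0.0, 0.15, 0.3),
        "finishing": (0.0, -0.2),
        "familiar": (0.0, 0.1, 0.2, 0.3),
    }
    return {f: tuple(sd * x for x in shapes[f]) for f in factors}


#: trait registry: components from the study's linear animal-model estimates,
#: observed score moments/support from its phenotype summary, missingness
#: from the per-trait record counts (out of 1,004), and the fixed factors of
#: the per-stage models.
STUDY_TRAITS = {
    #              mu     s2a    s2le    s2e    type      supp     mean   sd   miss   factors
    "bt1": (2.4, 0.32, 0.12, 1.04, "count", (0, 9), 2.4, 1.2, 0.000, ("sex", "breed")),
    "bt2": (2.5, 0.52, 0.08, 0.87, "count", (0, 9), 2.5, 1.2, 0.234, ("sex", "breed")),
    "inj": (2.8, 0.03, 0.13, 0.34, "ordinal", (1, 4), 2.8, 0.8, 0.234, ("sex", "breed")),
    "pss": (2.0, 0.04, 0.13, 0.46, "ordinal", (1, 3), 2.0, 0.8, 0.129, ("sex", "breed")),
    "rls": (1.8, 0.05, 0.04, 0.55, "ordinal", (1, 3), 1.8, 0.8, 0.017, ("sex", "breed", "rearing")),
    "rss": (2.0, 0.07, 0.02, 0.48, "ordinal", (1, 3), 2.0, 0.8, 0.017, ("sex", "breed", "rearing")),
    "ls1": (2.3, 0.08, 0.05, 0.43, "ordinal", (1, 4), 2.3, 0.8, 0.000, ("sex", "breed", "rearing")),
    "ls2": (2.9, 0.07, 0.09, 0.45, "ordinal", (1, 4), 2.9, 0.9, 0.017, ("sex", "breed", "rearing", "familiar")),
    "lsd": (0.6, 0.05, 0.02, 0.34, "gaussian", None, None, None, 0.017, ("sex", "breed", "rearing", "familiar")),
    "fls": (1.5, 0.02, 0.00, 0.44, "ordinal", (1, 3), 1.5, 0.7, 0.028, ("sex", "breed", "finishing")),
    "fss": (1.5, 0.09, 0.00, 0.33, "ordinal", (1, 3), 1.5, 0.7, 0.028, ("sex", "breed", "finishing")),
    "pdg": (224.0, 112.1, 1120.8, 1686.8, "gaussian", None, None, None, 0.008, ("sex", "breed")),
    "rdg": (413.0, 79.5, 1078.8, 1717.6, "gaussian", None, None, None, 0.226, ("sex", "breed", "rearing")),
    "fdg": (760.0, 5707.2, 1234.3, 2859.2, "gaussian", None, None, None, 0.399, ("sex", "breed", "finishing")),
    "adg": (600.0, 1228.5, 313.5, 1010.8, "gaussian", None, None, None, 0.399, ("sex", "breed", "rearing", "finishing")),
}


def study_trait_spec(trait: str, **overrides) -> TraitSimSpec:
    """A TraitSimSpec preset for one of the study's traits."""
    mu, s2a, s2le, s2e, kind, supp, tm, tsd, miss, factors = STUDY_TRAITS[trait]
    sd = np.sqrt(s2a + s2le + s2e)
    kw = dict(
        name=trait,
        mu=mu,
        sigma2_a=s2a,
        sigma2_le=s2le,
        sigma2_e=s2e,
        fixed_effects=_fx(sd, factors),
        score_type=kind,
        support=supp,
        target_mean=tm,
        target_sd=tsd,
        missing_rate=miss,
    )
    kw.update(overrides)
    return TraitSimSpec(**kw)


def study_herd_config(seed: int = 0, traits=None, **overrides) -> SimulationConfig:
    """The study-scale herd: 31 sires x 135 dams, ~1,004 offspring."""
    traits = list(STUDY_TRAITS) if traits is None else list(traits)
    cfg = SimulationConfig(
        seed=seed,
        traits={t: study_trait_spec(t) for t in traits},
        genetic_corr={("bt1", "bt2"): 0.84} if {"bt1", "bt2"} <= set(traits) else {},
    )
    return cfg.replace(**overrides) if overrides else cfg
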