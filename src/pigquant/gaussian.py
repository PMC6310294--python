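"""Gaussian animal-model REML, BLUP and heritability.

The univariate model is ``y = Xb + Pl + Za + e`` with ``var(l) = I sigma2_pe``
(litter / common environment), ``var(a) = A sigma2_a`` over the pedigree's
numerator relationship matrix, and ``var(e) = I sigma2_e``.  Variance
components maximise the restricted likelihood; the estimation scheme is
average-information (AI) REML with Newton steps on log-variances, damped so
that the restricted log-likelihood never decreases, and a classical EM-REML
update as fallback when the AI matrix is unusable.  Standard errors come from
the inverse AI matrix at convergence; heritability standard errors use the
first-order delta method.

Breeding values (BLUP/EBV) for *all* pedigree animals — phenotyped or not —
solve Henderson's mixed-model equations at fixed components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .model import Design, ModelSpec, build_design
from .pedigree import Pedigree, relationship_inverse, relationship_matrix

__all__ = [
    "DegenerateDataError",
    "VarianceComponents",
    "BivariateComponents",
    "UnivariateFit",
    "BivariateFit",
    "MMESolution",
    "fit_univariate",
    "fit_bivariate",
    "heritability",
    "solve_mme",
    "reml_loglik",
    "reml_loglik_many",
]


class DegenerateDataError(ValueError):
    """The data cannot identify the requested quantity."""


# ---------------------------------------------------------------------------
# restricted likelihood machinery (V linear in the parameters)
# ---------------------------------------------------------------------------

def _rll_pieces(y, X, V):
    """(log|V|, log|X'V⁻¹X|, y'Py, Py, chol) for one covariance matrix."""
    c, low = sla.cho_factor(V, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    vinv_x = sla.cho_solve((c, low), X)
    vinv_y = sla.cho_solve((c, low), y)
    xtvx = X.T @ vinv_x
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V⁻¹X not positive definite")
    beta = np.linalg.solve(xtvx, X.T @ vinv_y)
    py = vinv_y - vinv_x @ beta
    return logdet_v, logdet_x, float(y @ py), py, (c, low), vinv_x, xtvx


def _assemble(parts, theta):
    V = theta[0] * parts[0]
    for t, Pk in zip(theta[1:], parts[1:]):
        V = V + t * Pk
    return V


def reml_loglik(y, X, parts, theta) -> float:
    """Restricted log-likelihood (up to an additive constant) at ``theta``.

    ``V = sum_i theta[i] * parts[i]`` must be positive definite.
    """
    theta = np.asarray(theta, dtype=float)
    ld_v, ld_x, quad, *_ = _rll_pieces(y, X, _assemble(parts, theta))
    return -0.5 * (ld_v + ld_x + quad)


def reml_loglik_many(y, X, parts, thetas) -> np.ndarray:
    """Restricted log-likelihoods at many parameter points.

    Points that are positive multiples of one another share a single
    factorisation (the likelihood pieces scale analytically), which makes
    log-spaced grids around an optimum cheap to evaluate.
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    n, p = X.shape
    out = np.empty(len(thetas))
    groups: dict[tuple, list[int]] = {}
    scales = thetas.sum(axis=1)
    for i, (th, s) in enumerate(zip(thetas, scales)):
        key = tuple(np.round(th / s, 10))
        groups.setdefault(key, []).append(i)
    for key, idx in groups.items():
        base = np.array(key)
        ld_v, ld_x, quad, *_ = _rll_pieces(y, X, _assemble(parts, base))
        for i in idx:
            c = scales[i]
            out[i] = -0.5 * (ld_v + n * np.log(c) + ld_x - p * np.log(c) + quad / c)
    return out


@dataclass
class _ReemlState:
    theta: np.ndarray
    cov: np.ndarray
    rll: float
    converged: bool
    n_iterations: int
    boundary: np.ndarray


def _scores_ai(y, X, parts, theta):
    """Gradient, AI matrix, traces and rll at ``theta`` (raw scale)."""
    n = len(y)
    V = _assemble(parts, theta)
    ld_v, ld_x, quad, py, cho, vinv_x, xtvx = _rll_pieces(y, X, V)
    vinv = sla.cho_solve(cho, np.eye(n))
    # projection matrix P = V⁻¹ − V⁻¹X (X'V⁻¹X)⁻¹ X'V⁻¹
    proj = vinv - vinv_x @ np.linalg.solve(xtvx, vinv_x.T)
    k = len(parts)
    w = np.empty((k, n))
    tr = np.empty(k)
    for i, Pk in enumerate(parts):
        w[i] = Pk @ py
        tr[i] = np.sum(proj * Pk)
    score = -0.5 * (tr - w @ py)
    ai = 0.5 * (w @ proj @ w.T)
    rll = -0.5 * (ld_v + ld_x + quad)
    return score, ai, tr, w @ py, rll


def _ai_reml(
    y,
    X,
    parts,
    theta0,
    var_idx,
    q_ranks=None,
    max_iter=200,
    tol=1e-8,
    constrain=None,
    em_start=2,
):
    """Average-information REML for V = sum theta_i parts_i.

    ``var_idx`` flags which parameters are variances (log-scale Newton steps,
    floored at 1e-8 x var(y)); the rest are covariances (raw scale).
    ``q_ranks`` (per-part effective level counts) enable the EM fallback for
    variance parameters.  ``constrain`` is applied to theta after each step
    (used to keep implied correlations inside (-1, 1)).
    """
    theta = np.asarray(theta0, dtype=float).copy()
    var_idx = np.asarray(var_idx, dtype=bool)
    floor = 1e-8 * float(np.var(y))
    theta[var_idx] = np.maximum(theta[var_idx], floor)

    score, ai, tr, ypvpy, rll = _scores_ai(y, X, parts, theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        use_em = it <= em_start and q_ranks is not None and var_idx.all()
        if use_em:
            new = theta + theta**2 * (ypvpy - tr) / np.asarray(q_ranks, dtype=float)
            new = np.maximum(new, floor)
        else:
            new = _ai_step(theta, score, ai, var_idx, floor, y, X, parts, rll, constrain)
        if constrain is not None:
            new = constrain(new)
        new[var_idx] = np.maximum(new[var_idx], floor)
        delta = np.max(np.abs(new - theta) / np.maximum(np.abs(theta), floor))
        theta = new
        score, ai, tr, ypvpy, rll = _scores_ai(y, X, parts, theta)
        if delta < tol:
            converged = True
            break

    # covariance of the estimates: inverse AI on the raw scale
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:  # boundary cases
        cov = np.linalg.pinv(ai)
    boundary = var_idx & (theta <= floor * 1.001)
    return _ReemlState(theta, cov, rll, converged, it, boundary)


def _ai_step(theta, score, ai, var_idx, floor, y, X, parts, rll, constrain):
    """One damped Newton step on the transformed scale (log for variances).

    Parameters pinned at the floor with a gradient pointing further down are
    held out of the Newton system (active set), so the remaining components
    keep moving at full quadratic speed along the boundary.
    """
    jac = np.where(var_idx, theta, 1.0)
    score_t = jac * score
    ai_t = ai * np.outer(jac, jac)
    pinned = var_idx & (theta <= floor * 1.001) & (score < 0)
    free = ~pinned
    if not np.any(free):
        return theta
    lam = 0.0
    idx = np.where(free)[0]
    for _ in range(12):
        sub = ai_t[np.ix_(idx, idx)]
        try:
            step_free = np.linalg.solve(
                sub + lam * np.diag(np.maximum(np.diag(sub), 1e-12)), score_t[idx]
            )
        except np.linalg.LinAlgError:
            lam = max(lam * 10.0, 1e-6)
            continue
        step = np.zeros_like(theta)
        step[idx] = np.clip(step_free, -2.0, 2.0)
        cand = theta.copy()
        cand[var_idx] = np.exp(np.log(theta[var_idx]) + step[var_idx])
        cand[~var_idx] = theta[~var_idx] + step[~var_idx] * jac[~var_idx]
        cand[var_idx] = np.maximum(cand[var_idx], floor)
        if constrain is not None:
            cand = constrain(cand)
        try:
            new_rll = reml_loglik(y, X, parts, cand)
        except np.linalg.LinAlgError:
            new_rll = -np.inf
        if np.isfinite(new_rll) and new_rll >= rll - 1e-9:
            return cand
        lam = max(lam * 10.0, 1e-6)
    return theta  # no acceptable step: stay (treated as converged next check)


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """Univariate variance components with uncertainty and diagnostics."""

    trait: str
    sigma2_a: float
    sigma2_pe: float
    sigma2_e: float
    cov: np.ndarray                 # 3x3 sampling covariance (a, pe, e)
    converged: bool
    n_iterations: int
    restricted_loglik: float
    boundary: tuple                  # per-component at-floor flags

    @property
    def sigma2_total(self) -> float:
        return self.sigma2_a + self.sigma2_pe + self.sigma2_e

    @property
    def se(self) -> tuple:
        return tuple(np.sqrt(np.maximum(np.diag(self.cov), 0.0)))


@dataclass
class BivariateComponents:
    """Bivariate components: per-trait variances plus component covariances."""

    traits: tuple
    theta: np.ndarray               # (a1, ca12, a2, pe1, cpe12, pe2, e1, ce12, e2)
    cov: np.ndarray
    converged: bool
    n_iterations: int
    restricted_loglik: float
    boundary: tuple
    residual_cov_estimated: bool


@dataclass
class MMESolution:
    """Solution of Henderson's mixed-model equations at fixed components."""

    fixed_effects: pd.Series
    litter_effects: pd.Series
    ebv: pd.Series                   # every pedigree animal
    with_own_record: pd.Series
    relative_residual: float


@dataclass
class UnivariateFit:
    components: VarianceComponents
    mme: MMESolution

    @property
    def ebv(self) -> pd.Series:
        return self.mme.ebv


@dataclass
class BivariateFit:
    components: BivariateComponents
    genetic_correlation: float
    se_genetic_correlation: float
    phenotypic_correlation: float
    se_phenotypic_correlation: float
    reliable: bool


# ---------------------------------------------------------------------------
# univariate fit
# ---------------------------------------------------------------------------

def _univariate_parts(design: Design, A: np.ndarray):
    n = len(design.y)
    G = A[np.ix_(design.animal_pos, design.animal_pos)]
    B = design.P @ design.P.T
    return [G, B, np.eye(n)], [n, design.P.shape[1], n]


def fit_univariate(
    data: pd.DataFrame,
    ped: Pedigree,
    spec: ModelSpec,
    theta0=None,
    max_iter: int = 200,
    tol: float = 1e-8,
    A: np.ndarray | None = None,
    Ainv: np.ndarray | None = None,
) -> UnivariateFit:
    """REML fit of the univariate animal model plus BLUP at the optimum.

    Missing phenotypes are dropped from the record set; all pedigree animals
    receive an EBV.  Non-convergence within ``max_iter`` is reported through
    ``components.converged``, not raised.
    """
    design = build_design(data, ped, spec)
    if A is None:
        A = relationship_matrix(ped)
    parts, qs = _univariate_parts(design, A)
    if theta0 is None:
        vy = float(np.var(design.y))
        theta0 = np.array([0.3, 0.1, 0.6]) * vy
    state = _ai_reml(
        design.y, design.X, parts, theta0,
        var_idx=[True, True, True], q_ranks=qs,
        max_iter=max_iter, tol=tol,
    )
    if not state.converged:
        warnings.warn(f"REML for {spec.trait!r} did not converge in {state.n_iterations} iterations")
    comps = VarianceComponents(
        trait=spec.trait,
        sigma2_a=state.theta[0],
        sigma2_pe=state.theta[1],
        sigma2_e=state.theta[2],
        cov=state.cov,
        converged=state.converged,
        n_iterations=state.n_iterations,
        restricted_loglik=state.rll,
        boundary=tuple(bool(b) for b in state.boundary),
    )
    mme = solve_mme(data, ped, spec, comps, design=design, Ainv=Ainv)
    return UnivariateFit(comps, mme)


def heritability(vc: VarianceComponents):
    """h² = sigma2_a / (sigma2_a + sigma2_pe + sigma2_e), with delta-method SE.

    Returns ``(h2, se)``.
    """
    tot = vc.sigma2_total
    if tot <= 0:
        raise DegenerateDataError("total variance must be positive")
    h2 = vc.sigma2_a / tot
    grad = np.array([(tot - vc.sigma2_a), -vc.sigma2_a, -vc.sigma2_a]) / tot**2
    se = float(np.sqrt(max(grad @ vc.cov @ grad, 0.0)))
    return h2, se


# ---------------------------------------------------------------------------
# mixed-model equations / BLUP
# ---------------------------------------------------------------------------

def solve_mme(
    data: pd.DataFrame,
    ped: Pedigree,
    spec: ModelSpec,
    components: VarianceComponents,
    design: Design | None = None,
    Ainv: np.ndarray | None = None,
) -> MMESolution:
    """Solve Henderson's MME at fixed components (no re-estimation).

    The animal block carries ``A⁻¹ (sigma2_e / sigma2_a)`` over the *full*
    pedigree, so unphenotyped animals are predicted from relatives; an animal
    with no information has EBV exactly 0.
    """
    if design is None:
        design = build_design(data, ped, spec)
    if Ainv is None:
        Ainv = relationship_inverse(ped)
    elif hasattr(Ainv, "toarray"):
        Ainv = Ainv.toarray()
    y, X, P = design.y, design.X, design.P
    n, p = X.shape
    q = P.shape[1]
    m = ped.n
    Z = np.zeros((n, m))
    Z[np.arange(n), design.animal_pos] = 1.0

    lam_pe = components.sigma2_e / max(components.sigma2_pe, 1e-12)
    lam_a = components.sigma2_e / max(components.sigma2_a, 1e-12)

    size = p + q + m
    lhs = np.empty((size, size))
    sl_b, sl_l, sl_a = slice(0, p), slice(p, p + q), slice(p + q, size)
    lhs[sl_b, sl_b] = X.T @ X
    lhs[sl_b, sl_l] = X.T @ P
    lhs[sl_b, sl_a] = X.T @ Z
    lhs[sl_l, sl_b] = lhs[sl_b, sl_l].T
    lhs[sl_l, sl_l] = P.T @ P + lam_pe * np.eye(q)
    lhs[sl_l, sl_a] = P.T @ Z
    lhs[sl_a, sl_b] = lhs[sl_b, sl_a].T
    lhs[sl_a, sl_l] = lhs[sl_l, sl_a].T
    lhs[sl_a, sl_a] = Z.T @ Z + lam_a * Ainv
    rhs = np.concatenate([X.T @ y, P.T @ y, Z.T @ y])

    try:
        sol = sla.solve(lhs, rhs, assume_a="sym")
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError(f"mixed-model equations singular: {exc}") from exc
    rel = float(np.linalg.norm(lhs @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))

    observed = set(design.animals)
    return MMESolution(
        fixed_effects=pd.Series(sol[sl_b], index=design.x_names),
        litter_effects=pd.Series(sol[sl_l], index=design.litters),
        ebv=pd.Series(sol[sl_a], index=list(ped.animals), name=f"ebv_{spec.trait}"),
        with_own_record=pd.Series([a in observed for a in ped.animals], index=list(ped.animals)),
        relative_residual=rel,
    )


# ---------------------------------------------------------------------------
# bivariate fit
# ---------------------------------------------------------------------------

def _embed(block, N, r0, c0):
    M = np.zeros((N, N))
    M[r0 : r0 + block.shape[0], c0 : c0 + block.shape[1]] = block
    return M


def _bivariate_parts(d1: Design, d2: Design, A: np.ndarray):
    n1, n2 = len(d1.y), len(d2.y)
    N = n1 + n2
    G11 = A[np.ix_(d1.animal_pos, d1.animal_pos)]
    G22 = A[np.ix_(d2.animal_pos, d2.animal_pos)]
    G12 = A[np.ix_(d1.animal_pos, d2.animal_pos)]

    litters = np.unique(np.concatenate([d1.litters, d2.litters]))
    ix = {l: i for i, l in enumerate(litters)}
    P1 = np.zeros((n1, len(litters)))
    P1[:, [ix[l] for l in d1.litters]] = d1.P
    P2 = np.zeros((n2, len(litters)))
    P2[:, [ix[l] for l in d2.litters]] = d2.P

    same = np.zeros((n1, n2))
    rows2 = {a: j for j, a in enumerate(d2.animals)}
    overlap = 0
    for i, a in enumerate(d1.animals):
        j = rows2.get(a)
        if j is not None:
            same[i, j] = 1.0
            overlap += 1

    def sym_cross(C):
        M = np.zeros((N, N))
        M[:n1, n1:] = C
        M[n1:, :n1] = C.T
        return M

    parts = [
        _embed(G11, N, 0, 0),            # sigma2_a1
        sym_cross(G12),                  # cov_a12
        _embed(G22, N, n1, n1),          # sigma2_a2
        _embed(P1 @ P1.T, N, 0, 0),      # sigma2_pe1
        sym_cross(P1 @ P2.T),            # cov_pe12
        _embed(P2 @ P2.T, N, n1, n1),    # sigma2_pe2
        _embed(np.eye(n1), N, 0, 0),     # sigma2_e1
        sym_cross(same),                 # cov_e12
        _embed(np.eye(n2), N, n1, n1),   # sigma2_e2
    ]
    return parts, overlap


_VAR_OF_COV = {1: (0, 2), 4: (3, 5), 7: (6, 8)}


def _constrain_corrs(theta, active_covs, rmax=0.999):
    out = theta.copy()
    for c, (i, j) in _VAR_OF_COV.items():
        if c in active_covs:
            bound = rmax * np.sqrt(out[i] * out[j])
            out[c] = np.clip(out[c], -bound, bound)
    return out


def fit_bivariate(
    data: pd.DataFrame,
    ped: Pedigree,
    spec1: ModelSpec,
    spec2: ModelSpec,
    max_iter: int = 200,
    tol: float = 1e-8,
    A: np.ndarray | None = None,
) -> BivariateFit:
    """Bivariate REML: genetic and phenotypic correlation between two traits.

    The residual covariance is estimated only when some animals carry records
    for both traits (otherwise it is not identifiable and is fixed at 0).
    When either trait's additive variance sits on the zero boundary the
    correlation is reported but flagged unreliable.
    """
    d1 = build_design(data, ped, spec1)
    d2 = build_design(data, ped, spec2)
    if A is None:
        A = relationship_matrix(ped)
    parts9, overlap = _bivariate_parts(d1, d2, A)
    est_ce = overlap > 0

    keep = list(range(9)) if est_ce else [i for i in range(9) if i != 7]
    parts = [parts9[i] for i in keep]
    var_idx = [i in (0, 2, 3, 5, 6, 8) for i in keep]
    active_covs = {keep.index(c) for c in (1, 4, 7) if c in keep}
    remap = {full: k for k, full in enumerate(keep)}

    def constrain(theta):
        out = theta.copy()
        for c_full, (i_full, j_full) in _VAR_OF_COV.items():
            if c_full in remap:
                c, i, j = remap[c_full], remap[i_full], remap[j_full]
                bound = 0.999 * np.sqrt(out[i] * out[j])
                out[c] = np.clip(out[c], -bound, bound)
        return out

    y = np.concatenate([d1.y, d2.y])
    # scale traits to unit variance internally for conditioning, undo after
    s1, s2 = np.std(d1.y), np.std(d2.y)
    scale = np.concatenate([np.full(len(d1.y), 1.0 / s1), np.full(len(d2.y), 1.0 / s2)])
    ys = y * scale
    X = sla.block_diag(d1.X, d2.X)
    parts_s = [Pk * np.outer(scale, scale) for Pk in parts]

    v1, v2 = 1.0, 1.0
    theta0_full = {
        0: 0.3 * v1, 2: 0.3 * v2, 3: 0.1 * v1, 5: 0.1 * v2,
        6: 0.6 * v1, 8: 0.6 * v2, 1: 0.0, 4: 0.0, 7: 0.0,
    }
    theta0 = np.array([theta0_full[i] for i in keep])

    state = _ai_reml(
        ys, X, parts_s, theta0, var_idx,
        q_ranks=None, max_iter=max_iter, tol=tol,
        constrain=constrain, em_start=0,
    )
    if not state.converged:
        warnings.warn(
            f"bivariate REML for ({spec1.trait!r}, {spec2.trait!r}) did not converge"
        )

    # back to original trait scales
    unscale = {0: s1 * s1, 1: s1 * s2, 2: s2 * s2, 3: s1 * s1, 4: s1 * s2,
               5: s2 * s2, 6: s1 * s1, 7: s1 * s2, 8: s2 * s2}
    theta = np.zeros(9)
    cov = np.zeros((9, 9))
    for k, full in enumerate(keep):
        theta[full] = state.theta[k] * unscale[full]
        for k2, full2 in enumerate(keep):
            cov[full, full2] = state.cov[k, k2] * unscale[full] * unscale[full2]

    comps = BivariateComponents(
        traits=(spec1.trait, spec2.trait),
        theta=theta,
        cov=cov,
        converged=state.converged,
        n_iterations=state.n_iterations,
        restricted_loglik=state.rll,
        boundary=tuple(bool(b) for k, b in zip(keep, state.boundary)),
        residual_cov_estimated=est_ce,
    )

    a1, ca, a2 = theta[0], theta[1], theta[2]
    rg, se_rg = _corr_delta(ca, a1, a2, cov[np.ix_([1, 0, 2], [1, 0, 2])])
    t1 = theta[0] + theta[3] + theta[6]
    t2 = theta[2] + theta[5] + theta[8]
    cp = theta[1] + theta[4] + theta[7]
    # delta method on the summed phenotypic (co)variances
    Jm = np.zeros((3, 9))
    Jm[0, [1, 4, 7]] = 1.0
    Jm[1, [0, 3, 6]] = 1.0
    Jm[2, [2, 5, 8]] = 1.0
    rp, se_rp = _corr_delta(cp, t1, t2, Jm @ cov @ Jm.T)

    floor_boundary = state.boundary[remap[0]] or state.boundary[remap[2]]
    return BivariateFit(
        components=comps,
        genetic_correlation=rg,
        se_genetic_correlation=se_rg,
        phenotypic_correlation=rp,
        se_phenotypic_correlation=se_rp,
        reliable=not floor_boundary,
    )


def _corr_delta(c, v1, v2, cov3):
    """Correlation c/sqrt(v1 v2) and its delta-method SE.

    ``cov3`` is the sampling covariance of (c, v1, v2).
    """
    if v1 <= 0 or v2 <= 0:
        return np.nan, np.nan
    r = c / np.sqrt(v1 * v2)
    grad = np.array([
        1.0 / np.sqrt(v1 * v2),
        -0.5 * c / (v1 ** 1.5 * np.sqrt(v2)),
        -0.5 * c / (v2 ** 1.5 * np.sqrt(v1)),
    ])
    se = float(np.sqrt(max(grad @ cov3 @ grad, 0.0)))
    return float(r), se
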