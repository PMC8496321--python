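"""Bayesian multi-trait genomic mixed model (matrix-variate Gibbs sampler).

The model for the trait matrix Y (records x traits, one record per line in
its own environment/cycle) is

    Y = 1 mu' + X_E beta_E + Z_L b1 + Z_LE b2 + e

with b1 ~ MN(0, G, Sigma_T) the line main effects, b2 ~ MN(0, I ⊗ G,
Sigma_TE) the genotype-by-environment effects, and residual rows
e_i ~ N(0, R) independent across records.  Priors: flat on the fixed
effects, inverse-Wishart on each of Sigma_T, Sigma_TE and R.  Everything
is sampled from full conditionals; missing phenotype cells (including the
fully-masked testing lines of the cross-validation) are data-augmented
each sweep, which is what lets unphenotyped lines borrow information
through G.

Implementation notes
--------------------
* G (plus a small PD ridge) is eigendecomposed once; in the rotated basis
  the b1 full conditional factorises into independent per-line trait-block
  Gaussians, updated with batched T x T linear algebra.  This relies on
  each line having exactly one phenotype record, which is the two-cycle
  trial structure; a line phenotyped in several environments is rejected.
* b2 is sampled per environment over that environment's lines with prior
  MN(0, G_sub, Sigma_TE) — the marginal of the Kronecker prior for the
  blocks that any two-cycle prediction actually uses.
* Fixed effects are parameterised as per-environment trait means and
  reported as mu (first environment) plus corner-constrained beta_E.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .genomics import GRM
from .io import PhenotypeTable

log = logging.getLogger(__name__)

__all__ = [
    "MCMCSettings",
    "PriorSpec",
    "ModelSpec",
    "PosteriorSummary",
    "Predictions",
    "fit_multitrait",
    "fit_singletrait",
    "predict_lines",
    "estimate_heritability",
    "closed_form_gblup",
    "sample_cov_conditional",
    "effective_sample_size",
]


@dataclass
class MCMCSettings:
    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError(f"burn_in ({self.burn_in}) must be < n_iter ({self.n_iter})")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return len(range(self.burn_in, self.n_iter, self.thin))


@dataclass
class PriorSpec:
    """Inverse-Wishart hyper-parameters for Sigma_T, Sigma_TE and R.

    Defaults (filled at fit time for the trait dimension T): nu = T + 2 and
    scale 0.5 * I, a weak prior centred near variance 0.5 on unit-scale
    traits.  ``fixed_*`` pins a covariance at a known value and skips its
    update — used by the closed-form oracle comparisons.
    """

    nu_T: float | None = None
    S_T: np.ndarray | None = None
    nu_TE: float | None = None
    S_TE: np.ndarray | None = None
    nu_R: float | None = None
    S_R: np.ndarray | None = None
    fixed_sigma_T: np.ndarray | None = None
    fixed_sigma_TE: np.ndarray | None = None
    fixed_R: np.ndarray | None = None

    def resolved(self, n_traits: int) -> "PriorSpec":
        T = n_traits

        def _nu(v):
            v = float(v) if v is not None else T + 2.0
            if v <= T - 1:
                raise ValueError(f"inverse-Wishart df {v} must exceed n_traits - 1 = {T - 1}")
            return v

        def _S(v):
            S = np.asarray(v, dtype=float) if v is not None else 0.5 * np.eye(T)
            if S.shape == ():
                S = float(S) * np.eye(T)
            if S.shape != (T, T):
                raise ValueError(f"prior scale must be {T}x{T}")
            if np.linalg.eigvalsh((S + S.T) / 2).min() <= 0:
                raise ValueError("prior scale matrix must be positive definite")
            return (S + S.T) / 2

        def _fix(v):
            if v is None:
                return None
            F = np.asarray(v, dtype=float)
            if F.shape == ():
                F = float(F) * np.eye(T)
            return F.reshape(T, T)

        return PriorSpec(
            nu_T=_nu(self.nu_T), S_T=_S(self.S_T),
            nu_TE=_nu(self.nu_TE), S_TE=_S(self.S_TE),
            nu_R=_nu(self.nu_R), S_R=_S(self.S_R),
            fixed_sigma_T=_fix(self.fixed_sigma_T),
            fixed_sigma_TE=_fix(self.fixed_sigma_TE),
            fixed_R=_fix(self.fixed_R),
        )


@dataclass
class ModelSpec:
    """What to fit: traits, environments, kernel, priors, chain settings."""

    grm: GRM
    traits: list[str]
    environments: list[str]
    include_gxe: bool = True
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    ridge: float = 1e-6


@dataclass
class PosteriorSummary:
    """Posterior means, retained draws of the global parameters, diagnostics."""

    traits: list[str]
    environments: list[str]
    line_ids: list[str]
    env_of_line: np.ndarray  # int codes into environments
    mu: np.ndarray  # (T,)
    beta: np.ndarray  # (I, T), first row identically 0
    b1: np.ndarray  # (J, T) posterior means
    b2: np.ndarray  # (J, T) posterior means, line's own environment
    sigma_T: np.ndarray
    sigma_TE: np.ndarray
    R: np.ndarray
    draws: dict[str, np.ndarray]
    ess: dict[str, float]
    mcmc: MCMCSettings
    include_gxe: bool

    def line_index(self, lines: list[str]) -> np.ndarray:
        lookup = {l: i for i, l in enumerate(self.line_ids)}
        try:
            return np.array([lookup[l] for l in lines], dtype=int)
        except KeyError as e:
            raise KeyError(f"line {e.args[0]!r} was not in the fitted model") from None


@dataclass
class Predictions:
    """Posterior-mean predictions: full linear predictor and genetic part."""

    total: pd.DataFrame  # mu + beta_env + b1 + b2
    genetic: pd.DataFrame  # b1 + b2 (the estimated breeding values)


def _pivot_records(phen: PhenotypeTable, traits: list[str], environments: list[str], grm: GRM):
    df = phen.df[phen.df["trait"].isin(traits)]
    if df.empty:
        raise ValueError(f"no phenotype records for traits {traits}")
    unknown_env = set(df["env"]) - set(environments)
    if unknown_env:
        raise ValueError(f"environments {sorted(unknown_env)} not in model spec")
    wide = df.pivot(index=["line", "env"], columns="trait", values="value")
    wide = wide.reindex(columns=traits)
    lines_rec = wide.index.get_level_values("line")
    if lines_rec.duplicated().any():
        bad = lines_rec[lines_rec.duplicated()][0]
        raise ValueError(
            f"line {bad!r} has records in more than one environment; the sampler "
            "supports the two-cycle design with one record per line"
        )
    in_grm = set(grm.line_ids)
    missing = [l for l in lines_rec if l not in in_grm]
    if missing:
        raise ValueError(f"phenotyped lines absent from GRM: {missing[:5]}")
    # order lines to follow the GRM ordering for reproducible linear algebra
    rec_map = {l: e for l, e in wide.index}
    model_lines = [l for l in grm.line_ids if l in rec_map]
    wide = wide.reindex(pd.MultiIndex.from_tuples([(l, rec_map[l]) for l in model_lines],
                                                  names=["line", "env"]))
    env_codes = np.array([environments.index(rec_map[l]) for l in model_lines])
    Y = wide.to_numpy(dtype=float)
    for t, trait in enumerate(traits):
        obs = Y[:, t][~np.isnan(Y[:, t])]
        if obs.size == 0:
            raise ValueError(f"trait {trait!r} has no observed values")
        if obs.size >= 2 and np.std(obs) == 0.0:
            raise ValueError(f"trait {trait!r} has zero variance in the observed values")
    return Y, model_lines, env_codes


def sample_cov_conditional(
    rng: np.random.Generator, nu0: float, S0: np.ndarray, n: int, scatter: np.ndarray
) -> np.ndarray:
    """One draw of Sigma | effects ~ IW(nu0 + n, S0 + scatter).

    The conjugate full-conditional update shared by Sigma_T, Sigma_TE and R.
    Exposed so the conjugacy can be checked against the analytic
    inverse-Wishart mean (S_post / (nu_post - T - 1)).
    """
    S_post = S0 + scatter
    S_post = (S_post + S_post.T) / 2
    return invwishart.rvs(df=nu0 + n, scale=S_post, random_state=rng).reshape(S0.shape)


def _mn_rows_update(Yt, dvals, Sigma, R, rng):
    """Sample independent rows b_j with prior N(0, d_j Sigma), data y_j ~ N(b_j, R).

    Uses b | y ~ N(A (A + R)^-1 y, A - A (A + R)^-1 A) with A = d_j Sigma,
    batched over rows.
    """
    J, T = Yt.shape
    A = dvals[:, None, None] * Sigma[None, :, :]
    S = A + R[None, :, :]
    K = np.linalg.solve(S, A)  # (J, T, T) = S^-1 A
    mean = np.einsum("jst,js->jt", K, Yt)  # (K' y)_t = (A S^-1 y)_t by symmetry
    C = A - A @ K
    C = 0.5 * (C + C.transpose(0, 2, 1)) + 1e-13 * np.eye(T)
    L = np.linalg.cholesky(C)
    z = rng.standard_normal((J, T))
    return mean + np.einsum("jts,js->jt", L, z)


def _augment_missing(Ycur, mean_r, patterns, R, rng):
    for rows, obs, mis in patterns:
        if len(mis) == 0:
            continue
        m = mean_r[rows]
        if len(obs) == 0:
            L = np.linalg.cholesky(R)
            Ycur[np.ix_(rows, mis)] = m[:, mis] + rng.standard_normal((len(rows), len(mis))) @ L.T
            continue
        Roo = R[np.ix_(obs, obs)]
        Rmo = R[np.ix_(mis, obs)]
        W = np.linalg.solve(Roo, Rmo.T).T  # (miss, obs)
        C = R[np.ix_(mis, mis)] - W @ Rmo.T
        C = 0.5 * (C + C.T) + 1e-13 * np.eye(len(mis))
        L = np.linalg.cholesky(C)
        resid_obs = Ycur[np.ix_(rows, obs)] - m[:, obs]
        cm = m[:, mis] + resid_obs @ W.T
        Ycur[np.ix_(rows, mis)] = cm + rng.standard_normal((len(rows), len(mis))) @ L.T


def fit_multitrait(
    phenotypes: PhenotypeTable, spec: ModelSpec, _allow_single: bool = False
) -> PosteriorSummary:
    """Gibbs-sample the multi-trait model and return posterior summaries.

    Missing phenotype cells anywhere (partially-recorded lines, fully
    masked testing lines) are handled by data augmentation.  Reproducible
    from ``spec.mcmc.seed``.
    """
    traits = list(spec.traits)
    if len(traits) < 2 and not _allow_single:
        raise ValueError("fit_multitrait needs >= 2 traits; use fit_singletrait for one")
    T = len(traits)
    I = len(spec.environments)
    Y0, model_lines, env_codes = _pivot_records(phenotypes, traits, spec.environments, spec.grm)
    J = len(model_lines)
    G = spec.grm.submatrix(model_lines).values
    priors = spec.priors.resolved(T)
    mcmc = spec.mcmc
    rng = np.random.default_rng(mcmc.seed)

    if spec.ridge > 0:
        log.debug("adding ridge %g to G diagonal before factorisation", spec.ridge)
    Gr = G + spec.ridge * np.eye(J)
    dvals, U = np.linalg.eigh(Gr)
    dvals = np.maximum(dvals, 1e-12)

    env_groups = []  # (idx, d_e, U_e) per environment with records
    for e in range(I):
        idx = np.flatnonzero(env_codes == e)
        if idx.size == 0:
            env_groups.append(None)
            continue
        de, Ue = np.linalg.eigh(Gr[np.ix_(idx, idx)])
        env_groups.append((idx, np.maximum(de, 1e-12), Ue))

    mask = np.isnan(Y0)
    patterns = []
    if mask.any():
        uniq, inv = np.unique(mask, axis=0, return_inverse=True)
        for k, pat in enumerate(uniq):
            rows = np.flatnonzero(inv == k)
            obs = np.flatnonzero(~pat)
            mis = np.flatnonzero(pat)
            patterns.append((rows, obs, mis))

    # initial state
    col_mean = np.zeros(T)
    for t in range(T):
        col_mean[t] = np.nanmean(Y0[:, t])
    Ycur = Y0.copy()
    Ycur[mask] = np.broadcast_to(col_mean, Y0.shape)[mask]
    m_env = np.tile(col_mean, (I, 1))
    b1 = np.zeros((J, T))
    b2 = np.zeros((J, T))
    Sigma_T = priors.fixed_sigma_T if priors.fixed_sigma_T is not None else priors.S_T.copy()
    Sigma_TE = priors.fixed_sigma_TE if priors.fixed_sigma_TE is not None else priors.S_TE.copy()
    Rmat = priors.fixed_R if priors.fixed_R is not None else priors.S_R.copy()

    n_env_records = np.array([np.sum(env_codes == e) for e in range(I)])
    kept = 0
    n_kept = mcmc.n_kept
    d_mu = np.empty((n_kept, T))
    d_beta = np.empty((n_kept, I, T))
    d_ST = np.empty((n_kept, T, T))
    d_STE = np.empty((n_kept, T, T))
    d_R = np.empty((n_kept, T, T))
    sum_b1 = np.zeros((J, T))
    sum_b2 = np.zeros((J, T))

    for it in range(mcmc.n_iter):
        mean_r = m_env[env_codes] + b1 + b2
        if patterns:
            _augment_missing(Ycur, mean_r, patterns, Rmat, rng)

        # fixed effects: per-environment trait means, flat prior
        resid = Ycur - b1 - b2
        L_R = np.linalg.cholesky(Rmat)
        for e in range(I):
            n_e = n_env_records[e]
            if n_e == 0:
                continue
            rbar = resid[env_codes == e].mean(axis=0)
            m_env[e] = rbar + (L_R @ rng.standard_normal(T)) / np.sqrt(n_e)

        # line main effects in the eigenbasis of G
        Ystar = Ycur - m_env[env_codes] - b2
        Yt = U.T @ Ystar
        bt = _mn_rows_update(Yt, dvals, Sigma_T, Rmat, rng)
        b1 = U @ bt
        scatter_T = bt.T @ (bt / dvals[:, None])

        # G x E effects, per environment block
        scatter_TE = np.zeros((T, T))
        if spec.include_gxe:
            Ystar2 = Ycur - m_env[env_codes] - b1
            for grp in env_groups:
                if grp is None:
                    continue
                idx, de, Ue = grp
                Yte = Ue.T @ Ystar2[idx]
                bte = _mn_rows_update(Yte, de, Sigma_TE, Rmat, rng)
                b2[idx] = Ue @ bte
                scatter_TE += bte.T @ (bte / de[:, None])

        # covariance components (conjugate inverse-Wishart updates)
        if priors.fixed_sigma_T is None:
            Sigma_T = sample_cov_conditional(rng, priors.nu_T, priors.S_T, J, scatter_T)
        if spec.include_gxe and priors.fixed_sigma_TE is None:
            Sigma_TE = sample_cov_conditional(rng, priors.nu_TE, priors.S_TE, J, scatter_TE)
        E = Ycur - m_env[env_codes] - b1 - b2
        if priors.fixed_R is None:
            Rmat = sample_cov_conditional(rng, priors.nu_R, priors.S_R, J, E.T @ E)

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            d_mu[kept] = m_env[0]
            d_beta[kept] = m_env - m_env[0]
            d_ST[kept] = Sigma_T
            d_STE[kept] = Sigma_TE if spec.include_gxe else np.zeros((T, T))
            d_R[kept] = Rmat
            sum_b1 += b1
            sum_b2 += b2
            kept += 1

    draws = {"mu": d_mu, "beta": d_beta, "sigma_T": d_ST, "sigma_TE": d_STE, "R": d_R}
    ess = {
        "sigma_T": float(np.mean([effective_sample_size(d_ST[:, t, t]) for t in range(T)])),
        "R": float(np.mean([effective_sample_size(d_R[:, t, t]) for t in range(T)])),
    }
    if spec.include_gxe:
        ess["sigma_TE"] = float(
            np.mean([effective_sample_size(d_STE[:, t, t]) for t in range(T)])
        )
    return PosteriorSummary(
        traits=traits,
        environments=list(spec.environments),
        line_ids=model_lines,
        env_of_line=env_codes,
        mu=d_mu.mean(axis=0),
        beta=d_beta.mean(axis=0),
        b1=sum_b1 / kept,
        b2=sum_b2 / kept,
        sigma_T=d_ST.mean(axis=0),
        sigma_TE=d_STE.mean(axis=0),
        R=d_R.mean(axis=0),
        draws=draws,
        ess=ess,
        mcmc=mcmc,
        include_gxe=spec.include_gxe,
    )


def fit_singletrait(phenotypes: PhenotypeTable, trait: str, spec: ModelSpec) -> PosteriorSummary:
    """The model restricted to one trait (inverse-Wishart collapses to
    a scaled inverse-chi-squared on each variance)."""
    one = replace(spec, traits=[trait])
    return fit_multitrait(phenotypes, one, _allow_single=True)


def predict_lines(post: PosteriorSummary, lines: list[str], env: str) -> Predictions:
    """Posterior-mean predictions for lines modelled in ``env``.

    ``total`` is mu + beta_env + b1 + b2 (phenotype scale); ``genetic`` is
    b1 + b2, the estimated breeding values.  Within one environment the two
    differ by a constant, so correlation-based metrics agree on either.
    """
    if env not in post.environments:
        raise KeyError(f"environment {env!r} not in fitted model")
    e = post.environments.index(env)
    idx = post.line_index(list(lines))
    wrong = [l for l, i in zip(lines, idx) if post.env_of_line[i] != e]
    if wrong:
        raise KeyError(
            f"lines {wrong[:5]} were not modelled in environment {env!r}; "
            "include (possibly all-missing) records for them before fitting"
        )
    genetic = post.b1[idx] + post.b2[idx]
    total = post.mu + post.beta[e] + genetic
    cols = post.traits
    ix = pd.Index(list(lines), name="line")
    return Predictions(
        total=pd.DataFrame(total, index=ix, columns=cols),
        genetic=pd.DataFrame(genetic, index=ix, columns=cols),
    )


def estimate_heritability(
    phenotypes: PhenotypeTable,
    trait: str,
    spec: ModelSpec,
    gxe_in_denominator: bool = True,
) -> float:
    """Posterior-mean heritability of one trait from the whole dataset.

    Fits the single-trait model on all supplied records and averages
    sigma_g2 / (sigma_g2 + sigma_gxe2 + sigma_e2) over the retained draws.
    The G-by-E variance enters the denominator by default (total
    phenotypic variance); ``gxe_in_denominator=False`` gives the narrower
    sigma_g2 / (sigma_g2 + sigma_e2) reading.
    """
    post = fit_singletrait(phenotypes, trait, spec)
    sg = post.draws["sigma_T"][:, 0, 0]
    se = post.draws["R"][:, 0, 0]
    sge = post.draws["sigma_TE"][:, 0, 0] if spec.include_gxe else 0.0
    denom = sg + se + (sge if gxe_in_denominator else 0.0)
    return float(np.mean(sg / denom))


def closed_form_gblup(
    phenotypes: PhenotypeTable,
    trait: str,
    grm: GRM,
    sigma_g2: float,
    sigma_e2: float,
) -> pd.Series:
    """Exact single-environment GBLUP at fixed variance components.

    Solves the mixed-model problem directly: the GLS intercept
    mu = (1'V^-1 y)/(1'V^-1 1) with V = sigma_g2 G + sigma_e2 I, then
    b = sigma_g2 G V^-1 (y - mu).  Serves as the independent oracle for the
    Gibbs sampler at fixed variances.
    """
    df = phenotypes.df[(phenotypes.df["trait"] == trait) & phenotypes.df["value"].notna()]
    if df.empty:
        raise ValueError(f"no observed records for trait {trait!r}")
    if df["env"].nunique() != 1:
        raise ValueError("closed-form GBLUP expects a single environment")
    lines = [l for l in grm.line_ids if l in set(df["line"])]
    y = df.set_index("line")["value"].reindex(lines).to_numpy(dtype=float)
    G = grm.submatrix(lines).values
    n = len(lines)
    V = sigma_g2 * G + sigma_e2 * np.eye(n)
    Vinv_y = np.linalg.solve(V, y)
    Vinv_1 = np.linalg.solve(V, np.ones(n))
    mu = float(np.ones(n) @ Vinv_y / (np.ones(n) @ Vinv_1))
    b = sigma_g2 * (G @ np.linalg.solve(V, y - mu))
    return pd.Series(b, index=pd.Index(lines, name="line"), name="blup")


def effective_sample_size(x: np.ndarray) -> float:
    """ESS by Geyer's initial-monotone-sequence estimator (FFT autocovariance)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.std(x) == 0:
        return float(n)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # sums of adjacent pairs must be positive and non-increasing
    k = (n - 1) // 2
    pair = rho[1:2 * k:2] + rho[2:2 * k + 1:2]
    tau = 1.0
    prev = np.inf
    for p in pair:
        if p < 0:
            break
        p = min(p, prev)
        prev = p
        tau += 2.0 * p
    return float(min(n, n / max(tau, 1e-12)))
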