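"""Prediction-accuracy estimators for genomic selection.

Four Pearson-type estimators of how well predicted breeding values track
the (unobservable) true genetic values of testing lines:

* PC1 — predictive ability: Cor(y, g_hat), the raw correlation between
  observed phenotypes and predictions.  Because y = mu + g + e and
  Cov(g_hat, e) = 0 for predictions built from the training cycle only,
  Cor(g_hat, y) = Cor(g_hat, g) * sqrt(h2): PC1 systematically
  underestimates the true accuracy.
* PC2 — PC1 / sqrt(h2), the classical heritability correction; a
  nonparametric estimate of Cor(g_hat, g).
* PC3 — a parametric estimate from a bivariate genomic model treating the
  observed phenotype and its prediction as two "traits" sharing the
  relationship kernel G, with genetic covariance Sigma (2x2) free and the
  non-genetic cross-covariance constrained to zero (predictions carry no
  residual information about the testing phenotypes).  Per posterior draw,
  PC3 = [sigma_gop / sqrt(sigma_go2 * sigma_gp2)] * sqrt(h_p2) with
  h_p2 = sigma_gp2 / (sigma_gp2 + sigma_ep2): the genetic correlation
  attenuated by the prediction channel's own reliability (equal to the
  genetic correlation when sigma_ep2 = 0).
* PC4 — PC3 * sqrt(h2), mapping the corrected estimate back to the
  phenotype scale (the parametric counterpart of PC1).

Plus the error metrics MSEP (mean squared error of prediction) and MAAPE
(mean arctangent absolute percentage error, bounded in [0, pi/2]).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import invwishart

from .genomics import GRM
from .model import MCMCSettings

log = logging.getLogger(__name__)

__all__ = [
    "AccuracyRecord",
    "BivariateFit",
    "pc1",
    "pc2",
    "pc3",
    "pc4",
    "fit_bivariate_accuracy",
    "msep",
    "maape",
    "relative_difference",
]


def _validate_pair(observed, predicted, min_n=3):
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.size != p.size:
        raise ValueError(f"length mismatch: {o.size} observed vs {p.size} predicted")
    if np.isnan(o).any() or np.isnan(p).any():
        raise ValueError("missing values in observed/predicted vectors")
    if o.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {o.size}")
    return o, p


def pc1(observed, predicted) -> float:
    """Predictive ability: sample Pearson correlation of y with g_hat."""
    o, p = _validate_pair(observed, predicted)
    if np.std(o) == 0.0 or np.std(p) == 0.0:
        raise ValueError("zero variance in observed or predicted values")
    return float(np.corrcoef(o, p)[0, 1])


def pc2(pc1_value: float, h2: float) -> float:
    """Heritability-corrected correlation PC1 / sqrt(h2).

    Values above 1 can occur in finite samples and are passed through with
    a warning rather than clipped.
    """
    if not (0.0 < h2 <= 1.0):
        raise ValueError(f"h2 must be in (0, 1], got {h2}")
    out = pc1_value / np.sqrt(h2)
    if abs(out) > 1.0:
        warnings.warn(
            f"PC2 = {out:.4f} exceeds 1 in magnitude (finite-sample artifact)",
            stacklevel=2,
        )
    return float(out)


def pc4(pc3_value: float, h2: float) -> float:
    """Map the corrected correlation back to the phenotype scale: PC3 * sqrt(h2)."""
    if not (0.0 < h2 <= 1.0):
        raise ValueError(f"h2 must be in (0, 1], got {h2}")
    return float(pc3_value * np.sqrt(h2))


def msep(observed, predicted) -> float:
    """Mean squared error of prediction."""
    o, p = _validate_pair(observed, predicted, min_n=1)
    return float(np.mean((o - p) ** 2))


def maape(observed, predicted) -> float:
    """Mean arctangent absolute percentage error, in radians.

    Each record contributes arctan(|(y - y_hat) / y|); a zero observed
    value contributes the limiting arctan(inf) = pi/2.
    """
    o, p = _validate_pair(observed, predicted, min_n=1)
    out = np.empty(o.size)
    zero = o == 0.0
    out[zero] = np.pi / 2
    nz = ~zero
    out[nz] = np.arctan(np.abs((o[nz] - p[nz]) / o[nz]))
    exact = (o == p)
    out[exact] = 0.0
    return float(np.mean(out))


def relative_difference(corrected: float, uncorrected: float) -> float:
    """Percent relative difference 100 * (corrected - uncorrected) / uncorrected.

    For PC2 vs PC1 (or PC3 vs PC4) this equals 100 * (1/sqrt(h2) - 1)
    identically, since the pairs differ exactly by the sqrt(h2) factor.
    """
    if uncorrected == 0.0:
        raise ZeroDivisionError("uncorrected value is zero")
    return float(100.0 * (corrected - uncorrected) / uncorrected)


@dataclass
class BivariateFit:
    """Posterior summary of the two-"trait" (observed, predicted) model."""

    sigma_go2: float
    sigma_gp2: float
    sigma_gop: float
    sigma_eo2: float
    sigma_ep2: float
    h2_p: float
    draws: dict  # "sigma": (K,2,2) genetic covariance, "resid": (K,2) variances
    n_lines: int

    def __post_init__(self) -> None:
        S = self.draws["sigma"]
        cs = S[:, 0, 1] ** 2 - S[:, 0, 0] * S[:, 1, 1]
        if (cs > 1e-10).any():
            raise ValueError("a genetic covariance draw violates Cauchy-Schwarz")


def fit_bivariate_accuracy(
    observed,
    predicted,
    grm: GRM | np.ndarray,
    mcmc: MCMCSettings | None = None,
    ridge: float = 1e-6,
) -> BivariateFit:
    """Gibbs sampler for the bivariate accuracy model on the testing lines.

    y_i = (y_obs, y_pred) = mu + g_i + e_i with g ~ MN(0, G, Sigma),
    Sigma a free 2x2 genetic covariance, and diagonal residual covariance
    diag(sigma_eo2, sigma_ep2) — the residual cross term is fixed at zero
    because predictions share no non-genetic information with the held-out
    phenotypes.

    Sigma carries a parameter-expanded prior, Sigma = Lambda Psi Lambda
    with Psi ~ IW(nu=3, diag(0.5, 0.5)) and Lambda = diag(lambda_o,
    lambda_p), lambda_k ~ N(0, 1): approximately uniform on the genetic
    correlation and far less shrinking of the genetic variances than a
    plain inverse-Wishart, which matters because the genetic/residual
    split of the observed side is only weakly identified on a testing set
    of a few hundred lines.  Residual variances get scaled
    inverse-chi-squared priors with prior scale 0.5 on the observed side
    and 0.01 on the prediction side (posterior-mean predictions have
    nearly no residual of their own).
    """
    o, p = _validate_pair(observed, predicted)
    n = o.size
    if n < 30:
        warnings.warn(f"bivariate accuracy model fitted on only {n} lines", stacklevel=2)
    G = grm.values if isinstance(grm, GRM) else np.asarray(grm, dtype=float)
    if G.shape != (n, n):
        raise ValueError(f"GRM shape {G.shape} does not match {n} lines")
    if np.std(o) == 0.0 or np.std(p) == 0.0:
        raise ValueError("zero variance in observed or predicted values")
    mcmc = mcmc or MCMCSettings(n_iter=3000, burn_in=1000, thin=2)
    rng = np.random.default_rng(mcmc.seed)

    Y = np.column_stack([o, p])
    d, U = np.linalg.eigh(G + ridge * np.eye(n))
    d = np.maximum(d, 1e-12)

    nu0_S, S0 = 3.0, np.diag([0.5, 0.5])
    nu0_r, s0 = 3.0, np.array([0.5, 0.01])

    mu = Y.mean(axis=0)
    u = np.zeros((n, 2))  # expanded-scale genetic values, g = u @ Lambda
    lam = np.ones(2)
    Psi = S0.copy()
    rvar = np.array([np.var(o), max(np.var(p) * 0.01, 1e-6)])

    kept = 0
    n_kept = mcmc.n_kept
    d_sigma = np.empty((n_kept, 2, 2))
    d_resid = np.empty((n_kept, 2))
    eye2 = np.eye(2)

    for it in range(mcmc.n_iter):
        g = u * lam
        # intercepts (flat prior)
        resid = Y - g
        mu = resid.mean(axis=0) + np.sqrt(rvar / n) * rng.standard_normal(2)

        # expanded genetic values in the eigenbasis of G: y~ = Lambda u~ + e
        Yt = U.T @ (Y - mu)
        A = d[:, None, None] * Psi[None, :, :]  # prior row covariances of u~
        B = A * lam[None, None, :]  # A @ Lambda
        M = lam[:, None] * A * lam[None, None, :] + np.diag(rvar)[None, :, :]
        K = np.linalg.solve(M, np.transpose(B, (0, 2, 1)))  # M^-1 B'
        C = A - B @ K
        C = 0.5 * (C + C.transpose(0, 2, 1)) + 1e-13 * eye2
        mean = np.einsum("jst,js->jt", K, Yt)  # (K' y~)_t = (B M^-1 y~)_t
        L = np.linalg.cholesky(C)
        ut = mean + np.einsum("jts,js->jt", L, rng.standard_normal((n, 2)))
        u = U @ ut

        # working scale parameters, lambda_k ~ N(0, 1) a priori
        resid = Y - mu
        for k in range(2):
            prec = u[:, k] @ u[:, k] / rvar[k] + 1.0
            mlam = (u[:, k] @ resid[:, k] / rvar[k]) / prec
            lam[k] = mlam + rng.standard_normal() / np.sqrt(prec)

        # non-working covariance, then Sigma = Lambda Psi Lambda
        scatter = ut.T @ (ut / d[:, None])
        S_post = S0 + scatter
        Psi = invwishart.rvs(df=nu0_S + n, scale=(S_post + S_post.T) / 2, random_state=rng)

        # residual variances, independent scaled inverse-chi-squared
        E = Y - mu - u * lam
        for k in range(2):
            shape = (nu0_r + n) / 2.0
            scale = (nu0_r * s0[k] + float(E[:, k] @ E[:, k])) / 2.0
            rvar[k] = scale / rng.gamma(shape)

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            d_sigma[kept] = (lam[:, None] * Psi) * lam[None, :]
            d_resid[kept] = rvar
            kept += 1

    h2p_draws = d_sigma[:, 1, 1] / (d_sigma[:, 1, 1] + d_resid[:, 1])
    return BivariateFit(
        sigma_go2=float(d_sigma[:, 0, 0].mean()),
        sigma_gp2=float(d_sigma[:, 1, 1].mean()),
        sigma_gop=float(d_sigma[:, 0, 1].mean()),
        sigma_eo2=float(d_resid[:, 0].mean()),
        sigma_ep2=float(d_resid[:, 1].mean()),
        h2_p=float(h2p_draws.mean()),
        draws={"sigma": d_sigma, "resid": d_resid},
        n_lines=n,
    )


def pc3(fit: BivariateFit) -> float:
    """Corrected correlation from the bivariate fit, averaged over draws.

    Per draw: [sigma_gop / sqrt(sigma_go2 * sigma_gp2)] * sqrt(h_p2).
    Averaging the per-draw ratio (rather than taking ratios of posterior
    means) keeps the estimate invariant to per-draw rescalings.
    """
    S = fit.draws["sigma"]
    rp = fit.draws["resid"][:, 1]
    var_prod = S[:, 0, 0] * S[:, 1, 1]
    bad = var_prod <= 1e-300
    if bad.mean() > 0.5:
        raise ValueError("genetic variance is zero in most posterior draws")
    rho = S[:, 0, 1] / np.sqrt(np.where(bad, np.nan, var_prod))
    h2p = S[:, 1, 1] / (S[:, 1, 1] + rp)
    return float(np.nanmean(rho * np.sqrt(h2p)))


@dataclass
class AccuracyRecord:
    """All metrics for one trait in one cross-validation partition.

    Construct via :meth:`from_estimates` so that the exact algebraic
    identities pc1 = pc2 * sqrt(h2) and pc4 = pc3 * sqrt(h2) hold by
    construction.
    """

    trait: str
    partition: int
    pc1: float
    pc2: float
    pc3: float
    pc4: float
    msep: float
    maape: float
    h2_used: float

    @classmethod
    def from_estimates(
        cls,
        trait: str,
        partition: int,
        pc1_value: float,
        pc3_value: float,
        h2: float,
        msep_value: float,
        maape_value: float,
    ) -> "AccuracyRecord":
        return cls(
            trait=trait,
            partition=partition,
            pc1=pc1_value,
            pc2=pc2(pc1_value, h2),
            pc3=pc3_value,
            pc4=pc4(pc3_value, h2),
            msep=msep_value,
            maape=maape_value,
            h2_used=h2,
        )

    def check_identities(self, tol: float = 1e-12) -> None:
        rh = np.sqrt(self.h2_used)
        if abs(self.pc1 - self.pc2 * rh) > tol:
            raise AssertionError("pc1 != pc2 * sqrt(h2)")
        if abs(self.pc4 - self.pc3 * rh) > tol:
            raise AssertionError("pc4 != pc3 * sqrt(h2)")
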