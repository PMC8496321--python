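"""Two-cycle multi-trait breeding-trial simulator.

Emulates the structure of a wheat breeding program in which a large
first-year yield-trial cohort (the training cycle) is phenotyped for a
panel of traits in one season, and a smaller elite cohort (the testing
cycle) is phenotyped the next season.  Phenotypes follow the multi-trait
genomic mixed model

    Y = mu + beta_env + b1 + b2 + e

with line main effects b1 ~ MN(0, G, Sigma_T), genotype-by-environment
effects b2 ~ MN(0, I ⊗ G, Sigma_TE) and i.i.d. residual rows
e ~ N(0, residual_cov).  G is the VanRaden relationship matrix computed
from simulated independent biallelic markers, so relatedness between the
two cycles arises purely through shared marker sampling — exactly the
channel the prediction model exploits.  The simulator records the realised
total genetic value g = b1 + b2 of every line in its own environment, so
the otherwise-unobservable true prediction accuracy Cor(g, g_hat) is
directly computable and the bias of phenotype-based accuracy estimators
is measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomics import GRM, GenotypeMatrix, compute_grm
from .io import PhenotypeTable

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_genotypes",
    "simulate_dataset",
    "true_accuracy",
]


def _as_cov(x, n: int, name: str) -> np.ndarray:
    S = np.asarray(x, dtype=float)
    if S.shape == ():
        S = np.eye(n) * float(S)
    if S.shape != (n, n):
        raise ValueError(f"{name} must be {n}x{n}, got {S.shape}")
    if np.max(np.abs(S - S.T)) > 1e-10:
        raise ValueError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh((S + S.T) / 2)
    if w.min() < -1e-8 * max(1.0, float(w.max())):
        raise ValueError(f"{name} is not positive semidefinite (min eig {w.min():.3g})")
    return (S + S.T) / 2


def _psd_sqrt(S: np.ndarray) -> np.ndarray:
    """A with A A' = S for positive semidefinite S (eigen square root)."""
    w, V = np.linalg.eigh(S)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


@dataclass
class SimulationConfig:
    """Generating parameters for a two-cycle multi-trait dataset.

    Defaults mirror the scale of the study design this simulator emulates:
    a training cycle of 1,386 lines and a testing cycle of 509 lines (the
    2017-2018/2018-2019 pair of trials), a 2,000-marker relatedness panel,
    unit-scale traits with genetic and residual variance 0.5 each, and a
    G-by-E trait covariance defaulting to a copy of ``sigma_T`` (the model
    treats both with the same kind of prior; keeping them as two separate
    parameters makes either reading testable).
    """

    n_train_lines: int = 1386
    n_test_lines: int = 509
    n_markers: int = 2000
    n_traits: int = 1
    maf_range: tuple[float, float] = (0.05, 0.5)
    sigma_T: np.ndarray | float | None = None
    sigma_TE: np.ndarray | float | None = None
    residual_cov: np.ndarray | float | None = None
    env_effects: np.ndarray | None = None
    grand_means: np.ndarray | None = None
    trait_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train_lines < 1 or (self.n_test_lines < 0):
            raise ValueError("need n_train_lines >= 1 and n_test_lines >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        T = self.n_traits
        self.sigma_T = _as_cov(self.sigma_T if self.sigma_T is not None else 0.5, T, "sigma_T")
        self.sigma_TE = _as_cov(
            self.sigma_TE if self.sigma_TE is not None else self.sigma_T, T, "sigma_TE"
        )
        self.residual_cov = _as_cov(
            self.residual_cov if self.residual_cov is not None else 0.5, T, "residual_cov"
        )
        n_env = 2 if self.n_test_lines > 0 else 1
        if self.env_effects is None:
            # cycles differ by a season main effect of about one phenotypic SD
            self.env_effects = np.vstack([np.zeros(T), np.ones(T)])[:n_env]
        self.env_effects = np.asarray(self.env_effects, dtype=float).reshape(n_env, T)
        if self.grand_means is None:
            self.grand_means = np.zeros(T)
        self.grand_means = np.asarray(self.grand_means, dtype=float).reshape(T)
        if self.trait_names is None:
            self.trait_names = [f"T{t + 1}" for t in range(T)]
        if len(self.trait_names) != T:
            raise ValueError("trait_names length must equal n_traits")

    @property
    def envs(self) -> list[str]:
        return ["cycle1", "cycle2"][: self.env_effects.shape[0]]

    @property
    def true_h2(self) -> np.ndarray:
        """Heritability implied by the generating variances.

        Uses the total-phenotypic-variance denominator: the G-by-E variance
        counts as non-heritable (it is, for selection across seasons) —
        h2_t = sigma_T[t,t] / (sigma_T[t,t] + sigma_TE[t,t] + residual[t,t]).
        """
        gT = np.diag(self.sigma_T)
        gE = np.diag(self.sigma_TE)
        r = np.diag(self.residual_cov)
        return gT / (gT + gE + r)


def simulate_genotypes(
    n_lines: int, n_markers: int, maf_range: tuple[float, float], seed: int
) -> GenotypeMatrix:
    """Independent biallelic markers at Hardy-Weinberg dosage frequencies.

    Each marker's allele frequency is drawn uniformly from ``maf_range`` and
    dosages are Binomial(2, p) draws, independent across markers (no LD —
    the downstream model only consumes the relationship matrix, for which
    finite marker sampling already creates realistic relatedness noise).
    """
    if n_lines < 2 or n_markers < 1:
        raise ValueError("need n_lines >= 2 and n_markers >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie in (0, 0.5], got {maf_range}")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_markers)
    X = rng.binomial(2, p, size=(n_lines, n_markers)).astype(float)
    line_ids = [f"L{i + 1:05d}" for i in range(n_lines)]
    marker_ids = [f"M{j + 1:05d}" for j in range(n_markers)]
    return GenotypeMatrix(X, line_ids, marker_ids)


@dataclass
class SyntheticDataset:
    """A simulated two-cycle dataset with its generating truth attached."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    true_g: pd.DataFrame  # columns line, env, trait, g (total genetic value)
    true_h2: pd.Series  # per trait
    config: SimulationConfig
    grm: GRM
    components: dict = field(default_factory=dict)  # b1, b2, e arrays (lines x traits)

    def true_g_wide(self) -> pd.DataFrame:
        """Line-indexed wide table of total genetic values (own environment)."""
        return self.true_g.pivot(index="line", columns="trait", values="g")

    @property
    def train_lines(self) -> list[str]:
        return self.phenotypes.lines_in_env("cycle1")

    @property
    def test_lines(self) -> list[str]:
        return self.phenotypes.lines_in_env("cycle2") if "cycle2" in self.phenotypes.envs else []


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw genotypes, genetic effects and phenotypes for both cycles.

    Cycle-1 lines are phenotyped only in environment ``cycle1`` and cycle-2
    lines only in ``cycle2`` (one record per line, unreplicated line means).
    Phenotype = grand mean + environment effect + b1 + b2 + e, and
    ``true_g`` stores b1 + b2 per line in its own environment.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    J = cfg.n_train_lines + cfg.n_test_lines
    T = cfg.n_traits
    geno = simulate_genotypes(J, cfg.n_markers, cfg.maf_range, seed=int(rng.integers(2**31)))
    grm = compute_grm(geno)
    lines = geno.line_ids
    env_of_line = np.array([0] * cfg.n_train_lines + [1] * cfg.n_test_lines)
    envs = cfg.envs

    A_G = _psd_sqrt(grm.values)
    b1 = A_G @ rng.standard_normal((J, T)) @ _psd_sqrt(cfg.sigma_T).T

    b2 = np.zeros((J, T))
    A_TE = _psd_sqrt(cfg.sigma_TE)
    for e in range(len(envs)):
        idx = np.flatnonzero(env_of_line == e)
        A_Ge = _psd_sqrt(grm.values[np.ix_(idx, idx)])
        b2[idx] = A_Ge @ rng.standard_normal((len(idx), T)) @ A_TE.T

    e_mat = rng.standard_normal((J, T)) @ _psd_sqrt(cfg.residual_cov).T
    Y = cfg.grand_means + cfg.env_effects[env_of_line] + b1 + b2 + e_mat

    recs = []
    g_recs = []
    for i, line in enumerate(lines):
        env = envs[env_of_line[i]]
        for t, trait in enumerate(cfg.trait_names):
            recs.append((line, env, trait, Y[i, t]))
            g_recs.append((line, env, trait, b1[i, t] + b2[i, t]))
    phen = PhenotypeTable(pd.DataFrame(recs, columns=["line", "env", "trait", "value"]))
    true_g = pd.DataFrame(g_recs, columns=["line", "env", "trait", "g"])
    true_h2 = pd.Series(cfg.true_h2, index=cfg.trait_names, name="h2")
    return SyntheticDataset(
        genotypes=geno,
        phenotypes=phen,
        true_g=true_g,
        true_h2=true_h2,
        config=cfg,
        grm=grm,
        components={"b1": b1, "b2": b2, "e": e_mat, "env_of_line": env_of_line},
    )


def true_accuracy(
    dataset: SyntheticDataset,
    predictions: pd.DataFrame,
    trait: str,
    lines: list[str],
) -> float:
    """Pearson correlation of predictions with the true genetic values.

    ``predictions`` is a line-indexed frame with one column per trait (the
    shape returned by the model's prediction step).  This is the
    unobservable quantity that the corrected phenotype-based estimators
    try to recover.
    """
    if len(lines) < 3:
        raise ValueError("need at least 3 lines for a correlation")
    g = dataset.true_g_wide().loc[list(lines), trait].to_numpy(dtype=float)
    if np.isnan(g).any():
        missing = [l for l in lines if l not in set(dataset.true_g["line"])]
        raise KeyError(f"lines without true genetic values: {missing[:5]}")
    p = predictions.loc[list(lines), trait].to_numpy(dtype=float)
    if np.std(g) == 0.0 or np.std(p) == 0.0:
        raise ValueError("zero variance in true or predicted values")
    return float(np.corrcoef(g, p)[0, 1])
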