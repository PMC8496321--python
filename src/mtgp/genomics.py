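"""Marker quality control, imputation and the genomic relationship matrix.

Genotypes are biallelic allele dosages (0/1/2 copies of the minor allele)
for a panel of inbred-ish breeding lines.  Quality control applies the
standard per-marker filters (minor allele frequency, missing-data fraction,
heterozygote fraction), missing dosages are filled by marker means or a
low-rank EM scheme, and relatedness between lines is summarised by the
VanRaden genomic relationship matrix

    G = W W' / (2 * sum_j p_j (1 - p_j)),   W = X - 2p,

with p_j the allele frequency of marker j computed on the panel at hand.
G is the covariance kernel of every genetic effect downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.linalg import svds

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "MarkerQCReport",
    "GRM",
    "compute_marker_stats",
    "filter_markers",
    "impute_missing",
    "compute_grm",
]


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for x in ids:
            if x in seen:
                dup = x
                break
            seen.add(x)
        raise ValueError(f"duplicate {what} id: {dup!r}")


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix; NaN encodes a missing call.

    ``imputed=True`` relaxes the integer {0,1,2} constraint to real dosages
    in [0, 2] (the output of :func:`impute_missing`).
    """

    dosages: np.ndarray
    line_ids: list[str]
    marker_ids: list[str]
    imputed: bool = False

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D lines x markers array")
        self.line_ids = [str(x) for x in self.line_ids]
        self.marker_ids = [str(x) for x in self.marker_ids]
        n, m = self.dosages.shape
        if len(self.line_ids) != n:
            raise ValueError(f"{len(self.line_ids)} line ids for {n} rows")
        if len(self.marker_ids) != m:
            raise ValueError(f"{len(self.marker_ids)} marker ids for {m} columns")
        _check_unique(self.line_ids, "line")
        _check_unique(self.marker_ids, "marker")
        vals = self.dosages[~np.isnan(self.dosages)]
        if self.imputed:
            if vals.size and (vals.min() < -1e-9 or vals.max() > 2 + 1e-9):
                raise ValueError("imputed dosages must lie in [0, 2]")
        else:
            if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
                bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
                raise ValueError(f"non-{{0,1,2}} dosage value {bad!r}")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.dosages).sum())

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.line_ids,
            [self.marker_ids[i] for i in idx],
            imputed=self.imputed,
        )


@dataclass
class MarkerQCReport:
    """Per-marker QC statistics and pass/fail flags.

    ``table`` is indexed by marker id with columns ``maf``, ``missing``,
    ``het``, ``pass_maf``, ``pass_missing``, ``pass_het``, ``retained`` and
    ``fail_reasons`` (comma-joined names of the violated filters).
    """

    table: pd.DataFrame
    maf_min: float
    max_missing: float
    max_het: float

    @property
    def n_retained(self) -> int:
        return int(self.table["retained"].sum())

    @property
    def n_removed(self) -> int:
        return len(self.table) - self.n_retained


def compute_marker_stats(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.5,
    max_het: float = 0.05,
) -> MarkerQCReport:
    """Per-marker MAF, missing fraction and heterozygote fraction.

    MAF is min(p, 1-p) with p = mean dosage over non-missing calls / 2.
    Missing and heterozygote fractions are taken over all lines.  A marker
    with no non-missing calls has undefined (NaN) MAF and fails every
    filter.
    """
    if geno.n_lines < 1 or geno.n_markers < 1:
        raise ValueError("empty genotype matrix")
    X = geno.dosages
    miss = np.isnan(X)
    miss_frac = miss.mean(axis=0)
    n_obs = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, np.nansum(X, axis=0) / np.maximum(n_obs, 1) / 2.0, np.nan)
        p[n_obs == 0] = np.nan
    maf = np.minimum(p, 1.0 - p)
    het = (X == 1.0).mean(axis=0)

    pass_maf = np.where(np.isnan(maf), False, maf > maf_min)
    pass_missing = miss_frac < max_missing
    pass_het = het < max_het
    # fully-missing markers fail all three filters by convention
    fully = n_obs == 0
    pass_missing = pass_missing & ~fully
    pass_het = pass_het & ~fully
    retained = pass_maf & pass_missing & pass_het

    reasons = []
    for i in range(geno.n_markers):
        r = []
        if not pass_maf[i]:
            r.append("maf")
        if not pass_missing[i]:
            r.append("missing")
        if not pass_het[i]:
            r.append("het")
        reasons.append(",".join(r))
    table = pd.DataFrame(
        {
            "maf": maf,
            "missing": miss_frac,
            "het": het,
            "pass_maf": pass_maf,
            "pass_missing": pass_missing,
            "pass_het": pass_het,
            "retained": retained,
            "fail_reasons": reasons,
        },
        index=pd.Index(geno.marker_ids, name="marker"),
    )
    return MarkerQCReport(table, maf_min, max_missing, max_het)


def filter_markers(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.5,
    max_het: float = 0.05,
) -> tuple[GenotypeMatrix, MarkerQCReport]:
    """Drop markers failing MAF > maf_min, missing < max_missing, het < max_het.

    All three comparisons are strict.  Raises if no marker survives, naming
    the filter that removed the most markers.
    """
    for name, v in (("maf_min", maf_min), ("max_missing", max_missing), ("max_het", max_het)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    report = compute_marker_stats(geno, maf_min, max_missing, max_het)
    keep = report.table["retained"].to_numpy()
    if not keep.any():
        fails = {
            "maf": int((~report.table["pass_maf"]).sum()),
            "missing": int((~report.table["pass_missing"]).sum()),
            "het": int((~report.table["pass_het"]).sum()),
        }
        binding = max(fails, key=fails.get)
        raise ValueError(
            f"all {geno.n_markers} markers removed by QC; binding filter: "
            f"{binding} ({fails[binding]} failures)"
        )
    out = GenotypeMatrix(
        geno.dosages[:, keep],
        geno.line_ids,
        [m for m, k in zip(geno.marker_ids, keep) if k],
        imputed=geno.imputed,
    )
    log.info("marker QC retained %d / %d markers", report.n_retained, geno.n_markers)
    return out, report


def impute_missing(
    geno: GenotypeMatrix,
    method: str = "mean",
    max_iter: int = 50,
    tol: float = 1e-4,
    rank: int | None = None,
) -> GenotypeMatrix:
    """Fill missing dosages by marker means or low-rank EM.

    ``"mean"`` replaces each missing call by its marker's non-missing mean.
    ``"em"`` iterates a soft-impute-style scheme: starting from the mean
    fill, alternately fit a rank-``rank`` SVD approximation of the
    column-centred matrix and refill only the originally-missing cells,
    until the largest refilled-cell change drops below ``tol`` or
    ``max_iter`` sweeps.  Output dosages are real-valued, clipped to [0, 2].
    """
    if method not in ("mean", "em"):
        raise ValueError(f"unknown imputation method {method!r}")
    X = geno.dosages.copy()
    miss = np.isnan(X)
    if not miss.any():
        return GenotypeMatrix(X, geno.line_ids, geno.marker_ids, imputed=True)
    n_obs = (~miss).sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.argmin(n_obs))
        raise ValueError(
            f"marker {geno.marker_ids[j]!r} has no observed calls; filter before imputing"
        )
    col_mean = np.nansum(X, axis=0) / n_obs
    X[miss] = np.broadcast_to(col_mean, X.shape)[miss]
    if method == "em":
        n, m = X.shape
        k = rank if rank is not None else min(10, m - 1, n - 1)
        if k >= min(n, m):
            raise ValueError(f"rank {k} must be < min(lines, markers) = {min(n, m)}")
        for it in range(max_iter):
            mu = X.mean(axis=0)
            C = X - mu
            U, s, Vt = svds(C, k=k)
            approx = (U * s) @ Vt + mu
            new_vals = np.clip(approx[miss], 0.0, 2.0)
            delta = np.max(np.abs(new_vals - X[miss]))
            X[miss] = new_vals
            if delta < tol:
                log.debug("EM imputation converged after %d iterations", it + 1)
                break
    X = np.clip(X, 0.0, 2.0)
    return GenotypeMatrix(X, geno.line_ids, geno.marker_ids, imputed=True)


@dataclass
class GRM:
    """Symmetric line x line genomic relationship matrix."""

    values: np.ndarray
    line_ids: list[str]
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = [str(x) for x in self.line_ids]
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"GRM shape {self.values.shape} does not match {n} line ids")
        _check_unique(self.line_ids, "line")
        if np.max(np.abs(self.values - self.values.T)) > 1e-10:
            raise ValueError("GRM is not symmetric within 1e-10")
        self._index = {l: i for i, l in enumerate(self.line_ids)}

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def indices(self, lines: list[str]) -> np.ndarray:
        try:
            return np.array([self._index[l] for l in lines], dtype=int)
        except KeyError as e:
            raise KeyError(f"line {e.args[0]!r} not in GRM") from None

    def submatrix(self, lines: list[str]) -> "GRM":
        idx = self.indices(lines)
        return GRM(self.values[np.ix_(idx, idx)], list(lines))

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


def compute_grm(geno: GenotypeMatrix) -> GRM:
    """VanRaden method-1 genomic relationship matrix.

    Columns are centred at twice the panel allele frequency and the Gram
    matrix is scaled by 2 * sum_j p_j (1 - p_j), so the diagonal averages
    near 1 for an equilibrium panel.  Requires a complete (imputed) matrix
    with at least one polymorphic marker.
    """
    X = geno.dosages
    if np.isnan(X).any():
        raise ValueError("genotype matrix has missing values; impute first")
    if geno.n_lines < 2:
        raise ValueError("need at least 2 lines for a relationship matrix")
    p = X.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all markers are monomorphic on this panel (zero denominator)")
    W = X - 2.0 * p
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0
    return GRM(G, geno.line_ids)
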