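"""Tabular readers/writers and run configuration.

Formats handled: genotype matrices as CSV/TSV (first column line id, header
of marker ids) or the PLINK ``.raw`` dialect (FID/IID/PAT/MAT/SEX/PHENOTYPE
then one column per marker); phenotypes as long-format CSV with columns
``line, env, trait, value``; relationship matrices as square TSV with line
ids on both axes; accuracy reports as tidy CSV plus an aligned text table;
posterior draws as HDF5.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genomics import GRM, GenotypeMatrix

__all__ = [
    "PhenotypeTable",
    "TRAIT_REGISTRY",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "widen_phenotypes",
    "longify_phenotypes",
    "read_grm",
    "write_grm",
    "write_report",
    "save_draws",
    "load_config",
    "RunConfig",
]

#: Trait abbreviations of the wheat quality / grain yield panel this
#: pipeline was designed around.  Informational only — arbitrary trait
#: names are accepted everywhere; GY (grain yield) is merely the default
#: focal trait of the cross-validation.
TRAIT_REGISTRY = {
    "ALVPL": "curve configuration ratio (dough tenacity/extensibility)",
    "ALVW": "dough deformation energy (gluten strength)",
    "FLRPRO": "flour protein at 14% moisture",
    "FLRSDS": "sodium dodecyl sulfate sedimentation",
    "GRNHRD": "grain hardness",
    "GRNPRO": "grain protein",
    "GY": "grain yield (t/ha)",
    "LOFVOL": "bread loaf volume",
    "MIXTIM": "time to peak mixing strength",
    "MIXTORQ": "height at midline of peak mixing strength",
    "TESTWT": "test weight (kg/hL)",
    "TKW": "1000-kernel weight (g)",
    "L": "average abscissa at rupture (dough extensibility)",
    "P": "maximum overpressure (dough tenacity)",
}

_MISSING_TOKENS = {"NA", "na", "NaN", "nan", ".", ""}


@dataclass
class PhenotypeTable:
    """Long-format phenotype records: one row per (line, env, trait).

    Missing values (NaN) are allowed and are how unphenotyped cells are
    represented; a line to be predicted keeps its rows with NaN values.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["line", "env", "trait", "value"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"phenotype table missing column(s): {missing}")
        df = self.df[required].copy()
        for c in ("line", "env", "trait"):
            df[c] = df[c].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        dup = df.duplicated(subset=["line", "env", "trait"])
        if dup.any():
            r = df[dup].iloc[0]
            raise ValueError(
                f"duplicate phenotype record for (line={r['line']!r}, "
                f"env={r['env']!r}, trait={r['trait']!r})"
            )
        self.df = df.reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return sorted(self.df["trait"].unique())

    @property
    def envs(self) -> list[str]:
        return sorted(self.df["env"].unique())

    @property
    def lines(self) -> list[str]:
        return sorted(self.df["line"].unique())

    def lines_in_env(self, env: str) -> list[str]:
        return sorted(self.df.loc[self.df["env"] == env, "line"].unique())

    def mask_lines(self, lines: list[str], traits: list[str] | None = None) -> "PhenotypeTable":
        """Return a copy with the values of the given lines set to missing."""
        df = self.df.copy()
        sel = df["line"].isin(set(lines))
        if traits is not None:
            sel &= df["trait"].isin(set(traits))
        df.loc[sel, "value"] = np.nan
        return PhenotypeTable(df)

    def values_for(self, lines: list[str], env: str, trait: str) -> pd.Series:
        sub = self.df[(self.df["env"] == env) & (self.df["trait"] == trait)]
        s = sub.set_index("line")["value"]
        return s.reindex(lines)


# ---------------------------------------------------------------------------
# genotypes


def _parse_dosage_frame(df: pd.DataFrame, path: str) -> np.ndarray:
    vals = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        raw = df[col].astype(str).str.strip()
        is_missing = raw.isin(_MISSING_TOKENS)
        num = pd.to_numeric(raw.where(~is_missing), errors="coerce")
        bad = (~is_missing) & (num.isna() | ~num.isin([0.0, 1.0, 2.0]))
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: invalid dosage token {raw.iloc[i]!r} at line "
                f"{df.index[i]!r}, marker column {col!r} (expected 0/1/2 or NA)"
            )
        vals[:, j] = num.to_numpy()
    return vals


def read_genotypes(path: str | os.PathLike, dialect: str = "csv") -> GenotypeMatrix:
    """Read a genotype matrix from CSV/TSV or PLINK ``.raw``.

    CSV/TSV: first column holds line ids, header holds marker ids.
    PLINK raw: whitespace-delimited with FID IID PAT MAT SEX PHENOTYPE
    leading columns; IID is used as the line id.
    """
    path = str(path)
    if dialect == "csv":
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    elif dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
        lead = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        missing_cols = [c for c in lead if c not in df.columns]
        if missing_cols:
            raise ValueError(f"{path}: PLINK .raw header missing column(s) {missing_cols}")
        df = df.set_index("IID").drop(columns=[c for c in lead if c != "IID"])
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate line id {df.index[df.index.duplicated()][0]!r}")
    vals = _parse_dosage_frame(df, path)
    return GenotypeMatrix(vals, list(df.index), list(df.columns))


def write_genotypes(geno: GenotypeMatrix, path: str | os.PathLike, dialect: str = "csv") -> None:
    path = str(path)
    X = geno.dosages
    out = pd.DataFrame(X, index=geno.line_ids, columns=geno.marker_ids)
    if not geno.imputed:
        out = out.astype("Int64")  # keeps NA while printing integers
    if dialect == "csv":
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        out.index.name = "line"
        out.to_csv(path, sep=sep, na_rep="NA")
    elif dialect == "plink_raw":
        out = out.reset_index(names="IID")
        out.insert(0, "FID", out["IID"])
        for i, c in enumerate(["PAT", "MAT", "SEX", "PHENOTYPE"]):
            out.insert(2 + i, c, 0)
        out.to_csv(path, sep=" ", index=False, na_rep="NA")
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path: str | os.PathLike) -> PhenotypeTable:
    df = pd.read_csv(path)
    return PhenotypeTable(df)


def write_phenotypes(phen: PhenotypeTable, path: str | os.PathLike) -> None:
    phen.df.to_csv(path, index=False)


def widen_phenotypes(phen: PhenotypeTable) -> pd.DataFrame:
    """Long -> wide: one row per (line, env), one column per trait."""
    return phen.df.pivot(index=["line", "env"], columns="trait", values="value")


def longify_phenotypes(wide: pd.DataFrame) -> PhenotypeTable:
    """Wide table (line, env index or columns; trait columns) -> PhenotypeTable."""
    df = wide.copy()
    if not isinstance(df.index, pd.MultiIndex):
        df = df.set_index(["line", "env"])
    long = df.stack(future_stack=True).rename("value").reset_index()
    long.columns = ["line", "env", "trait", "value"]
    return PhenotypeTable(long)


# ---------------------------------------------------------------------------
# relationship matrices


def read_grm(path: str | os.PathLike) -> GRM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: GRM row and column ids differ")
    return GRM(df.to_numpy(dtype=float), [str(x) for x in df.index])


def write_grm(grm: GRM, path: str | os.PathLike) -> None:
    df = pd.DataFrame(grm.values, index=grm.line_ids, columns=grm.line_ids)
    df.index.name = "line"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# reports


def write_report(report, outdir: str | os.PathLike, stem: str = "accuracy") -> dict[str, str]:
    """Write an AccuracyReport as tidy CSV plus an aligned text table.

    The text table prints one row per (model, trait) and one ``mean (SD)``
    column per method in fixed order; floats at 6 significant digits.
    Output is deterministic for identical reports.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tidy_path = outdir / f"{stem}_tidy.csv"
    text_path = outdir / f"{stem}_table.txt"

    tidy = report.values.sort_values(["model", "trait", "method", "partition"]).reset_index(drop=True)
    tidy.to_csv(tidy_path, index=False)

    summ = report.summary()
    methods = [m for m in ("M1", "M2", "M3", "M4", "MSEP", "MAAPE") if m in set(summ["method"])]
    buf = _io.StringIO()
    n_part = report.n_partitions
    header = ["model", "trait"] + [f"{m} mean (SD)" for m in methods]
    rows = []
    for (model, trait), g in summ.groupby(["model", "trait"], sort=True):
        row = [model, trait]
        by_m = g.set_index("method")
        for m in methods:
            if m in by_m.index:
                mu, sd = by_m.loc[m, "mean"], by_m.loc[m, "sd"]
                row.append(f"{mu:.6g} ({sd:.6g})")
            else:
                row.append("-")
        rows.append(row)
    widths = [max(len(str(r[i])) for r in [header] + rows) for i in range(len(header))]
    for r in [header] + rows:
        buf.write("  ".join(str(x).ljust(w) for x, w in zip(r, widths)).rstrip() + "\n")
    if n_part == 1:
        buf.write("note: single partition; SD over n=1 reported as 0\n")
    text_path.write_text(buf.getvalue())
    return {"tidy": str(tidy_path), "table": str(text_path)}


def save_draws(draws: dict[str, np.ndarray], path: str | os.PathLike) -> None:
    """Posterior draw arrays to an HDF5 file (one dataset per parameter)."""
    import h5py

    with h5py.File(path, "w") as f:
        for k, v in draws.items():
            f.create_dataset(k, data=np.asarray(v))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Master configuration for a cross-validation run."""

    genotypes: str
    phenotypes: str
    outdir: str
    seed: int
    grm: str | None = None
    traits: list[str] | None = None
    environments: list[str] | None = None
    focal_trait: str = "GY"
    include_gxe: bool = True
    n_partitions: int = 5
    train_fraction_current: float = 0.10
    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 5
    maf_min: float = 0.05
    max_missing: float = 0.5
    max_het: float = 0.05
    impute: str = "mean"
    ridge: float = 1e-6
    extras: dict = field(default_factory=dict)


def load_config(path: str | os.PathLike) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if "seed" not in raw:
        raise ValueError("config must set an explicit seed")
    known = {k for k in RunConfig.__dataclass_fields__ if k != "extras"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    extras = {k: v for k, v in raw.items() if k not in known}
    cfg = RunConfig(extras=extras, **kwargs)
    return cfg
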