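"""Two-cycle cross-validation of multi- and single-trait genomic prediction.

The evaluation scheme mirrors how a breeding program would actually deploy
the model: the full previous cycle is always in the training set, a random
10% of the current cycle is added (it anchors the current season's
environment effect), and the remaining 90% of current-cycle lines are
predicted with all their traits masked.  The random 10% selection is
repeated five times, giving five values of every metric, reported as mean
and SD.  The same five partitions are used for the multi-trait and the
single-trait (focal-trait-only) arms so their comparison is paired.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .accuracy import (
    AccuracyRecord,
    fit_bivariate_accuracy,
    maape,
    msep,
    pc1,
    pc3,
)
from .genomics import GenotypeMatrix
from .io import PhenotypeTable
from .model import (
    MCMCSettings,
    ModelSpec,
    estimate_heritability,
    fit_multitrait,
    fit_singletrait,
    predict_lines,
)

log = logging.getLogger(__name__)

__all__ = ["CVPlan", "AccuracyReport", "make_partitions", "run_dataset_cv", "aggregate_results"]

_METHOD_ORDER = ["M1", "M2", "M3", "M4", "MSEP", "MAAPE"]


def _child_seed(master: int, *tags: int) -> int:
    ss = np.random.SeedSequence([int(master), *map(int, tags)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class CVPlan:
    """Five (by default) random 10% augment / 90% test splits of the current cycle.

    The five selections are independent random draws, not disjoint folds —
    five 10% selections cannot tile the cycle, and the scheme's point is
    five replicate evaluations of the same deployment rule.
    """

    dataset_id: str
    seed: int
    train_fraction_current: float
    partitions: list[dict] = field(default_factory=list)  # {"augment": [...], "test": [...]}

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)

    def check(self) -> None:
        for part in self.partitions:
            aug, test = set(part["augment"]), set(part["test"])
            if aug & test:
                raise AssertionError("augment and test sets overlap")


def make_partitions(
    current_lines: list[str],
    n_partitions: int = 5,
    fraction: float = 0.10,
    seed: int = 0,
    dataset_id: str = "dataset",
) -> CVPlan:
    """Draw the augment/test splits of the current cycle.

    The augment size is round-half-up of fraction * n (so 509 lines at 10%
    give 51 augmented / 458 tested); each partition is an independent
    uniform draw without replacement, reproducible from ``seed``.
    """
    n = len(current_lines)
    if n < 10:
        raise ValueError(f"need at least 10 current-cycle lines, got {n}")
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n_aug = int(math.floor(fraction * n + 0.5))
    if n_aug < 1 or n - n_aug < 1:
        raise ValueError(f"fraction {fraction} leaves an empty augment or test set at n={n}")
    rng = np.random.default_rng(seed)
    current = list(current_lines)
    partitions = []
    for _ in range(n_partitions):
        aug_idx = rng.choice(n, size=n_aug, replace=False)
        aug = sorted(current[i] for i in aug_idx)
        test = sorted(set(current) - set(aug))
        partitions.append({"augment": aug, "test": test})
    return CVPlan(
        dataset_id=dataset_id,
        seed=seed,
        train_fraction_current=fraction,
        partitions=partitions,
    )


@dataclass
class AccuracyReport:
    """Per-partition metric values with their summaries.

    ``values`` is tidy: columns dataset, model, trait, method, partition,
    value.  ``h2`` maps trait -> heritability used for the M2/M4
    corrections (estimated once from the whole dataset).
    """

    dataset_id: str
    values: pd.DataFrame
    h2: dict[str, float]
    n_partitions: int
    focal_trait: str

    def summary(self) -> pd.DataFrame:
        g = self.values.groupby(["model", "trait", "method"], sort=True)["value"]
        out = g.agg(mean="mean", sd=lambda s: float(np.std(s, ddof=1)) if len(s) > 1 else 0.0)
        out = out.reset_index()
        out["dataset"] = self.dataset_id
        return out[["dataset", "model", "trait", "method", "mean", "sd"]]

    def relative_differences(self) -> pd.DataFrame:
        """Percent relative differences between method means, per model and trait,
        plus the multi-vs-single comparison for the focal trait."""
        summ = self.summary().pivot_table(
            index=["model", "trait"], columns="method", values="mean"
        )
        rows = []
        for (model, trait), r in summ.iterrows():
            for a, b, name in (("M3", "M2", "M3_vs_M2"), ("M2", "M1", "M2_vs_M1"),
                               ("M3", "M4", "M3_vs_M4")):
                if a in r and b in r and r[b] != 0:
                    rows.append((self.dataset_id, model, trait, name,
                                 100.0 * (r[a] - r[b]) / r[b]))
        if {"multi_trait", "single_trait"} <= set(summ.index.get_level_values("model")):
            for m in ("M1", "M2", "M3", "M4", "MSEP"):
                try:
                    mt = summ.loc[("multi_trait", self.focal_trait), m]
                    st = summ.loc[("single_trait", self.focal_trait), m]
                except KeyError:
                    continue
                if st != 0:
                    rows.append((self.dataset_id, "multi_vs_single", self.focal_trait,
                                 f"{m}_multi_vs_single", 100.0 * (mt - st) / st))
        return pd.DataFrame(rows, columns=["dataset", "model", "trait", "comparison", "pct"])


def _metrics_for_trait(
    trait, part_idx, obs, pred_genetic, pred_total, grm_test, h2, bivariate_mcmc, seed
) -> AccuracyRecord:
    ok = ~np.isnan(obs)
    o, gg, tt = obs[ok], pred_genetic[ok], pred_total[ok]
    m1 = pc1(o, gg)
    biv = fit_bivariate_accuracy(
        o, gg, grm_test[np.ix_(ok.nonzero()[0], ok.nonzero()[0])],
        mcmc=replace(bivariate_mcmc, seed=seed),
    )
    m3 = pc3(biv)
    return AccuracyRecord.from_estimates(
        trait=trait,
        partition=part_idx,
        pc1_value=m1,
        pc3_value=m3,
        h2=h2,
        msep_value=msep(o, tt),
        maape_value=maape(o, tt),
    )


def run_dataset_cv(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    plan: CVPlan,
    spec: ModelSpec,
    focal_trait: str = "GY",
    bivariate_mcmc: MCMCSettings | None = None,
    h2_override: dict[str, float] | None = None,
) -> AccuracyReport:
    """Run the two-cycle evaluation for both model arms on one dataset.

    Per partition: mask every trait of the test lines, fit the multi-trait
    model on previous cycle + 10% augment, predict the test lines, and
    score PC1-PC4, MSEP and MAAPE per trait; then do the same with the
    single-trait model for the focal trait on the identical partition.
    Heritabilities for the M2/M4 corrections are estimated once per trait
    from the whole (unmasked) dataset; ``h2_override`` can inject known
    values (e.g. simulation truth) instead.
    """
    del genotypes  # the model consumes relatedness only through spec.grm
    traits = list(spec.traits)
    if focal_trait not in traits:
        raise ValueError(f"focal trait {focal_trait!r} not among model traits {traits}")
    envs = phenotypes.envs
    current_env = None
    part_lines = set(plan.partitions[0]["augment"]) | set(plan.partitions[0]["test"])
    for env in envs:
        if part_lines <= set(phenotypes.lines_in_env(env)):
            current_env = env
            break
    if current_env is None:
        raise ValueError("partition lines are not all phenotyped in a single environment")
    bivariate_mcmc = bivariate_mcmc or MCMCSettings(n_iter=3000, burn_in=1000, thin=2)

    if h2_override is not None:
        h2 = {t: float(h2_override[t]) for t in traits}
    else:
        h2 = {}
        for t in traits:
            h2_spec = replace(spec, mcmc=replace(spec.mcmc, seed=_child_seed(plan.seed, 900, traits.index(t))))
            h2[t] = estimate_heritability(phenotypes, t, h2_spec)
            log.info("whole-data heritability of %s: %.3f", t, h2[t])

    rows = []
    for k, part in enumerate(plan.partitions):
        test = part["test"]
        masked = phenotypes.mask_lines(test)
        grm_test = spec.grm.submatrix(test).values

        # multi-trait arm
        mt_spec = replace(spec, mcmc=replace(spec.mcmc, seed=_child_seed(plan.seed, 1, k)))
        post_mt = (
            fit_multitrait(masked, mt_spec)
            if len(traits) > 1
            else fit_singletrait(masked, traits[0], mt_spec)
        )
        preds = predict_lines(post_mt, test, current_env)
        for t_i, t in enumerate(traits):
            obs = phenotypes.values_for(test, current_env, t).to_numpy(dtype=float)
            rec = _metrics_for_trait(
                t, k, obs,
                preds.genetic[t].to_numpy(), preds.total[t].to_numpy(),
                grm_test, h2[t], bivariate_mcmc, _child_seed(plan.seed, 2, k, t_i),
            )
            for meth, val in (("M1", rec.pc1), ("M2", rec.pc2), ("M3", rec.pc3),
                              ("M4", rec.pc4), ("MSEP", rec.msep), ("MAAPE", rec.maape)):
                rows.append((plan.dataset_id, "multi_trait", t, meth, k, val))

        # single-trait arm, same partition and predictors
        st_spec = replace(spec, mcmc=replace(spec.mcmc, seed=_child_seed(plan.seed, 3, k)))
        post_st = fit_singletrait(masked, focal_trait, st_spec)
        preds_st = predict_lines(post_st, test, current_env)
        obs = phenotypes.values_for(test, current_env, focal_trait).to_numpy(dtype=float)
        rec = _metrics_for_trait(
            focal_trait, k, obs,
            preds_st.genetic[focal_trait].to_numpy(), preds_st.total[focal_trait].to_numpy(),
            grm_test, h2[focal_trait], bivariate_mcmc, _child_seed(plan.seed, 4, k),
        )
        for meth, val in (("M1", rec.pc1), ("M2", rec.pc2), ("M3", rec.pc3),
                          ("M4", rec.pc4), ("MSEP", rec.msep), ("MAAPE", rec.maape)):
            rows.append((plan.dataset_id, "single_trait", focal_trait, meth, k, val))
        log.info("partition %d/%d scored", k + 1, plan.n_partitions)

    values = pd.DataFrame(
        rows, columns=["dataset", "model", "trait", "method", "partition", "value"]
    )
    return AccuracyReport(
        dataset_id=plan.dataset_id,
        values=values,
        h2=h2,
        n_partitions=plan.n_partitions,
        focal_trait=focal_trait,
    )


def aggregate_results(reports: list[AccuracyReport]) -> pd.DataFrame:
    """Cross-dataset summary of the percent relative differences.

    Stacks each report's per-trait relative differences (M3 vs M2, M2 vs
    M1, multi vs single) and adds min/max/mean across datasets per
    comparison and trait.
    """
    if not reports:
        raise ValueError("need at least one report")
    per = pd.concat([r.relative_differences() for r in reports], ignore_index=True)
    summ = (
        per.groupby(["model", "trait", "comparison"])["pct"]
        .agg(["min", "max", "mean", "count"])
        .reset_index()
    )
    summ.insert(0, "dataset", "ALL")
    per = per.assign(min=per["pct"], max=per["pct"], mean=per["pct"], count=1)
    out = pd.concat(
        [per[["dataset", "model", "trait", "comparison", "min", "max", "mean", "count"]], summ],
        ignore_index=True,
    )
    return out
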