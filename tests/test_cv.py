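import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtgp import (
    MCMCSettings,
    ModelSpec,
    SimulationConfig,
    aggregate_results,
    make_partitions,
    run_dataset_cv,
    simulate_dataset,
    write_report,
)


class TestPartitions:
    def test_ten_percent_of_100(self):
        plan = make_partitions([f"l{i}" for i in range(100)], seed=1)
        for p in plan.partitions:
            assert len(p["augment"]) == 10
            assert len(p["test"]) == 90

    def test_round_half_up_at_509(self):
        # the 2018-2019 elite-trial cohort size: 10% of 509 rounds to 51
        plan = make_partitions([f"l{i}" for i in range(509)], seed=2)
        for p in plan.partitions:
            assert len(p["augment"]) == 51
            assert len(p["test"]) == 458

    def test_determinism_and_seed_sensitivity(self):
        lines = [f"l{i}" for i in range(100)]
        a = make_partitions(lines, seed=5)
        b = make_partitions(lines, seed=5)
        c = make_partitions(lines, seed=6)
        assert a.partitions == b.partitions
        assert a.partitions != c.partitions
        # independent draws: partitions within a plan differ too
        assert a.partitions[0] != a.partitions[1]

    @given(
        n=st.integers(10, 600),
        seed=st.integers(0, 2**31 - 1),
        frac=st.floats(0.05, 0.5),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_bookkeeping_invariants(self, n, seed, frac):
        import math

        lines = [f"l{i}" for i in range(n)]
        try:
            plan = make_partitions(lines, fraction=frac, seed=seed)
        except ValueError:
            assert math.floor(frac * n + 0.5) < 1 or n - math.floor(frac * n + 0.5) < 1
            return
        for p in plan.partitions:
            aug, test = set(p["augment"]), set(p["test"])
            assert aug | test == set(lines)
            assert not (aug & test)
            assert len(aug) == math.floor(frac * n + 0.5)

    def test_validation(self):
        with pytest.raises(ValueError, match="at least 10"):
            make_partitions(["a"] * 5, seed=0)
        with pytest.raises(ValueError, match="fraction"):
            make_partitions([f"l{i}" for i in range(20)], fraction=1.5, seed=0)


@pytest.fixture(scope="module")
def tiny_cv():
    """A small but complete two-arm CV run shared by the bookkeeping tests."""
    cfg = SimulationConfig(
        n_train_lines=70, n_test_lines=40, n_markers=250, n_traits=2,
        sigma_T=np.array([[0.6, 0.3], [0.3, 0.6]]),
        sigma_TE=np.zeros((2, 2)), residual_cov=0.4 * np.eye(2), seed=77,
    )
    ds = simulate_dataset(cfg)
    spec = ModelSpec(
        grm=ds.grm, traits=["T1", "T2"], environments=["cycle1", "cycle2"],
        include_gxe=False,
        mcmc=MCMCSettings(n_iter=400, burn_in=150, thin=2, seed=0),
    )
    plan = make_partitions(ds.test_lines, n_partitions=3, seed=9, dataset_id="tiny")
    report = run_dataset_cv(
        ds.genotypes, ds.phenotypes, plan, spec, focal_trait="T1",
        bivariate_mcmc=MCMCSettings(n_iter=400, burn_in=150, thin=2),
        h2_override={"T1": 0.6, "T2": 0.6},
    )
    return ds, spec, plan, report


class TestRunDatasetCV:
    def test_report_shape_and_mean_bookkeeping(self, tiny_cv):
        _, _, plan, report = tiny_cv
        v = report.values
        assert set(v["model"]) == {"multi_trait", "single_trait"}
        assert set(v[v["model"] == "multi_trait"]["trait"]) == {"T1", "T2"}
        assert set(v["method"]) == {"M1", "M2", "M3", "M4", "MSEP", "MAAPE"}
        summ = report.summary()
        for _, row in summ.iterrows():
            vals = v[
                (v["model"] == row["model"])
                & (v["trait"] == row["trait"])
                & (v["method"] == row["method"])
            ]["value"]
            assert len(vals) == plan.n_partitions
            assert row["mean"] == pytest.approx(vals.mean(), abs=1e-14)

    def test_exact_correction_identities_every_row(self, tiny_cv):
        _, _, _, report = tiny_cv
        piv = report.values.pivot_table(
            index=["model", "trait", "partition"], columns="method", values="value"
        )
        rh = {t: np.sqrt(h) for t, h in report.h2.items()}
        for (model, trait, part), row in piv.iterrows():
            assert row["M1"] == pytest.approx(row["M2"] * rh[trait], abs=1e-12)
            assert row["M4"] == pytest.approx(row["M3"] * rh[trait], abs=1e-12)

    def test_end_to_end_determinism(self, tiny_cv, tmp_path):
        ds, spec, plan, report = tiny_cv
        report2 = run_dataset_cv(
            ds.genotypes, ds.phenotypes, plan, spec, focal_trait="T1",
            bivariate_mcmc=MCMCSettings(n_iter=400, burn_in=150, thin=2),
            h2_override={"T1": 0.6, "T2": 0.6},
        )
        p1 = write_report(report, tmp_path / "a")
        p2 = write_report(report2, tmp_path / "b")
        for k in p1:
            assert open(p1[k], "rb").read() == open(p2[k], "rb").read()

    def test_unknown_focal_trait(self, tiny_cv):
        ds, spec, plan, _ = tiny_cv
        with pytest.raises(ValueError, match="focal trait"):
            run_dataset_cv(ds.genotypes, ds.phenotypes, plan, spec, focal_trait="GY")


class TestNoiselessPipeline:
    def test_pc1_near_one_when_heritability_is_one(self):
        # few markers relative to training lines: the genetic signal of the
        # testing cycle is determined by the training cycle, so with no
        # residual noise predictive ability approaches 1 for every trait
        cfg = SimulationConfig(
            n_train_lines=150, n_test_lines=40, n_markers=60, n_traits=2,
            sigma_T=np.array([[1.0, 0.4], [0.4, 1.0]]),
            sigma_TE=np.zeros((2, 2)), residual_cov=1e-8 * np.eye(2), seed=31,
        )
        ds = simulate_dataset(cfg)
        spec = ModelSpec(
            grm=ds.grm, traits=["T1", "T2"], environments=["cycle1", "cycle2"],
            include_gxe=False,
            mcmc=MCMCSettings(n_iter=600, burn_in=200, thin=2, seed=1),
        )
        plan = make_partitions(ds.test_lines, n_partitions=2, seed=3, dataset_id="clean")
        report = run_dataset_cv(
            ds.genotypes, ds.phenotypes, plan, spec, focal_trait="T1",
            bivariate_mcmc=MCMCSettings(n_iter=400, burn_in=150, thin=2),
            h2_override={"T1": 1.0, "T2": 1.0},
        )
        summ = report.summary().set_index(["model", "trait", "method"])
        for trait in ("T1", "T2"):
            m1 = summ.loc[("multi_trait", trait, "M1"), "mean"]
            m2 = summ.loc[("multi_trait", trait, "M2"), "mean"]
            assert m1 > 0.95
            assert m2 == pytest.approx(m1, abs=1e-12)  # h2 = 1


class TestAggregate:
    def test_single_report_passthrough(self, tiny_cv):
        _, _, _, report = tiny_cv
        agg = aggregate_results([report])
        own = report.relative_differences()
        merged = agg[agg["dataset"] == "tiny"]
        assert len(merged) == len(own)
        np.testing.assert_allclose(
            merged["mean"].to_numpy(), own["pct"].to_numpy(), atol=1e-12
        )

    def test_two_identical_reports_collapse(self, tiny_cv):
        _, _, _, report = tiny_cv
        agg = aggregate_results([report, report])
        allrows = agg[agg["dataset"] == "ALL"]
        np.testing.assert_allclose(allrows["min"], allrows["max"], atol=1e-12)
        np.testing.assert_allclose(allrows["min"], allrows["mean"], atol=1e-12)

    def test_spreadsheet_oracle_on_handbuilt_values(self, tiny_cv):
        _, _, _, report = tiny_cv
        rd = report.relative_differences().set_index(["model", "trait", "comparison"])
        summ = report.summary().set_index(["model", "trait", "method"])
        m2 = summ.loc[("multi_trait", "T1", "M2"), "mean"]
        m3 = summ.loc[("multi_trait", "T1", "M3"), "mean"]
        assert rd.loc[("multi_trait", "T1", "M3_vs_M2"), "pct"] == pytest.approx(
            100 * (m3 - m2) / m2
        )
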