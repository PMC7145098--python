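"""Scenario batches, synergy arithmetic and sensitivity sweeps."""

import json

import numpy as np
import pandas as pd
import pytest

from bflact.calibration import calibrate_baseline
from bflact.engine import OUTCOME_FIELDS
from bflact.experiments import (OutcomeSummary, SensitivitySpec,
                                run_scenario, sensitivity_sweep, synergy,
                                write_outcome_tables)
from bflact.interventions import PackageSpec, Scenario


@pytest.fixture(scope="module")
def baseline(params):
    """A cheap calibrated baseline for experiment plumbing tests."""
    return calibrate_baseline(params=params, n_agents=1000,
                              n_reference=5000, reps_per_point=3, seed=42)


def _fake_summary(name, any6, base_seed=0, replicates=10):
    means = {k: 50.0 for k in OUTCOME_FIELDS}
    means["any_bf_6m"] = any6
    return OutcomeSummary(scenario=Scenario(name=name, base_seed=base_seed),
                          replicates=replicates, means=means,
                          ses={k: 0.1 for k in OUTCOME_FIELDS})


class TestRunScenario:
    def test_summary_structure(self, baseline):
        s = run_scenario(Scenario(), baseline, n_agents=500, replicates=5,
                         seed=1)
        assert set(s.means) == set(OUTCOME_FIELDS)
        for k in OUTCOME_FIELDS:
            assert 0.0 <= s.means[k] <= 100.0
            assert np.isfinite(s.ses[k])
        for m in (1, 3, 6):
            assert s.means[f"excl_bf_{m}m"] <= s.means[f"any_bf_{m}m"]
        assert s.means["any_bf_1m"] >= s.means["any_bf_3m"] >= \
            s.means["any_bf_6m"]

    def test_single_replicate_se_flagged(self, baseline):
        s = run_scenario(Scenario(), baseline, n_agents=300, replicates=1,
                         seed=2)
        assert all(np.isnan(v) for v in s.ses.values())

    def test_se_shrinks_with_replicates(self, baseline):
        """Monte-Carlo scaling: quadrupling replicates roughly halves the
        standard error."""
        few = run_scenario(Scenario(), baseline, n_agents=500,
                           replicates=50, seed=3)
        many = run_scenario(Scenario(), baseline, n_agents=500,
                            replicates=200, seed=3)
        ratio = few.se("any_bf_6m") / many.se("any_bf_6m")
        assert 1.4 < ratio < 2.9  # ideal ratio 2, SE estimates are noisy

    def test_reproducible(self, baseline):
        a = run_scenario(Scenario(), baseline, n_agents=400, replicates=3,
                         seed=4)
        b = run_scenario(Scenario(), baseline, n_agents=400, replicates=3,
                         seed=4)
        assert a.means == b.means

    def test_crn_vs_independent_streams(self, baseline):
        sc = Scenario(name="PTR@0.95", cov_partner=0.95)
        crn = run_scenario(sc, baseline, n_agents=400, replicates=3,
                           seed=5, crn=True)
        ind = run_scenario(sc, baseline, n_agents=400, replicates=3,
                           seed=5, crn=False)
        assert crn.means != ind.means  # different streams
        assert abs(crn.mean("any_bf_6m") - ind.mean("any_bf_6m")) < 10.0

    def test_postpartum_levers_inert_on_prenatal_outcomes(self, baseline):
        """COUL/PTR/WP leave intent and initiation bitwise unchanged under
        common random numbers."""
        base = run_scenario(Scenario(), baseline, n_agents=2000,
                            replicates=3, seed=6)
        for name, field in [("COUL", "cov_counseling"),
                            ("PTR", "cov_partner"),
                            ("WP", "cov_workplace")]:
            lev = run_scenario(Scenario(name=name, **{field: 0.95}),
                               baseline, n_agents=2000, replicates=3,
                               seed=6)
            assert lev.mean("intent") == base.mean("intent")
            assert lev.mean("initiation") == base.mean("initiation")

    def test_knowledge_lever_moves_intent_only_prenatally(self, baseline):
        base = run_scenario(Scenario(), baseline, n_agents=2000,
                            replicates=3, seed=7)
        knwl = run_scenario(Scenario(name="KNWL", knowledge_mean=0.95),
                            baseline, n_agents=2000, replicates=3, seed=7)
        assert knwl.mean("intent") > base.mean("intent")
        assert knwl.mean("initiation") >= base.mean("initiation")

    def test_nested_packages_monotone(self, baseline):
        """Adding levers to a package never lowers 6-month any-BF (common
        random numbers, shared level)."""
        codes = ("KNWL", "BFHI", "COUL", "PTR", "WP")
        vals = []
        for k in range(1, 6):
            sc = PackageSpec(codes[:k], 0.95).to_scenario()
            s = run_scenario(sc, baseline, n_agents=2000, replicates=10,
                             seed=8)
            vals.append(s.mean("any_bf_6m"))
        assert np.all(np.diff(vals) >= -0.2)  # ties within MC noise


class TestSynergy:
    def test_reported_example_arithmetic(self):
        base = _fake_summary("base", 55.6)
        package = _fake_summary("pkg", 55.6 + 8.8)
        singles = [_fake_summary(f"s{i}", 55.6 + e)
                   for i, e in enumerate((1.5, 0.4, 1.5, 3.0))]  # sum 6.4
        assert synergy(package, singles, base) == pytest.approx(2.4)

    def test_single_lever_package_zero(self):
        base = _fake_summary("base", 55.6)
        single = _fake_summary("s", 58.0)
        assert synergy(single, [single], base) == 0.0

    def test_permutation_invariant(self):
        base = _fake_summary("base", 50.0)
        package = _fake_summary("pkg", 60.0)
        singles = [_fake_summary(f"s{i}", 50.0 + i) for i in range(4)]
        a = synergy(package, singles, base)
        b = synergy(package, singles[::-1], base)
        assert a == pytest.approx(b)

    def test_mismatched_baseline_rejected(self):
        base = _fake_summary("base", 50.0, base_seed=0)
        package = _fake_summary("pkg", 60.0, base_seed=1)
        with pytest.raises(ValueError, match="baseline configuration"):
            synergy(package, [], base)


class TestSensitivity:
    def test_spec_validation(self):
        with pytest.raises(ValueError, match="unknown"):
            SensitivitySpec(parameter="beta_workplace")
        with pytest.raises(ValueError, match="default"):
            SensitivitySpec(parameter="beta_bfhi", values=(0.1, 0.5))

    def test_default_value_reproduces_full_coverage_run(self, baseline):
        """The default-coefficient row of a sweep equals the 95%-coverage
        scenario run at shared seeds."""
        spec = SensitivitySpec("beta_bfhi", values=(0.155,))
        table = sensitivity_sweep(spec, baseline, n_agents=500,
                                  replicates=4, seed=9)
        direct = run_scenario(
            Scenario(name="all95", knowledge_mean=0.95, cov_bfhi=0.95,
                     cov_counseling=0.95, cov_partner=0.95,
                     cov_workplace=0.95),
            baseline, n_agents=500, replicates=4, seed=9, crn=True)
        row = table.iloc[0]
        for k in OUTCOME_FIELDS:
            assert row[k] == pytest.approx(direct.mean(k), abs=1e-12)

    def test_initiation_monotone_in_bfhi_coefficient(self, baseline):
        table = sensitivity_sweep(
            SensitivitySpec("beta_bfhi", values=(0.1, 0.155, 0.25, 0.5)),
            baseline, n_agents=2000, replicates=5, seed=10)
        assert np.all(np.diff(table["initiation"]) >= 0)


class TestWriteOutcomeTables:
    def test_files_written(self, baseline, tmp_path):
        summaries = [run_scenario(Scenario(), baseline, n_agents=200,
                                  replicates=2, seed=11)]
        paths = write_outcome_tables(summaries, tmp_path, name="t",
                                     metadata={"seed": 11})
        table = pd.read_csv(paths["table"])
        assert len(table) == 1
        assert set(OUTCOME_FIELDS) <= set(table.columns)
        meta = json.loads(paths["metadata"].read_text())
        assert meta["seed"] == 11
        assert meta["scenarios"][0]["name"] == "baseline"

    def test_empty_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no summaries"):
            write_outcome_tables([], tmp_path)
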