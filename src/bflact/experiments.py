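"""Scenario batches, effect aggregation and sensitivity sweeps.

A scenario run draws a fresh cohort per replicate, applies the scenario's
levers, simulates the 6-month horizon and averages the eight outcome rates
over replicates (mean and Monte-Carlo standard error).  By default
replicate random streams are shared across scenarios (common random
numbers), which sharpens between-scenario contrasts without biasing means;
an independent-streams mode mirrors a design where every experiment uses
its own seeds.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibratedBaseline
from .engine import OUTCOME_FIELDS, SimClock, run_cohort
from .interventions import Scenario, apply_scenario
from .network import build_network
from .population import PopulationParams, sample_cohort

__all__ = ["OutcomeSummary", "SensitivitySpec", "run_scenario", "synergy",
           "sensitivity_sweep", "write_outcome_tables"]

_STREAM_COHORT = 21
_STREAM_SCENARIO = 22
_STREAM_TRAJ = 23
_STREAM_NET = 24


@dataclass
class OutcomeSummary:
    """Replicate-averaged outcome rates (percent) for one scenario."""

    scenario: Scenario
    replicates: int
    means: dict[str, float]
    ses: dict[str, float]
    per_replicate: pd.DataFrame = field(repr=False, default=None)

    def mean(self, outcome: str) -> float:
        return self.means[outcome]

    def se(self, outcome: str) -> float:
        return self.ses[outcome]

    def to_series(self) -> pd.Series:
        row = {"scenario": self.scenario.name,
               "replicates": self.replicates}
        row.update({k: self.means[k] for k in OUTCOME_FIELDS})
        row.update({f"se_{k}": self.ses[k] for k in OUTCOME_FIELDS})
        return pd.Series(row)


def _scenario_stream(base_seed: int, stream: int, rep: int,
                     scenario_name: str, crn: bool) -> np.random.SeedSequence:
    if crn:
        return np.random.SeedSequence([base_seed, stream, rep])
    tag = zlib.crc32(scenario_name.encode()) & 0x7FFFFFFF
    return np.random.SeedSequence([base_seed, tag, stream, rep])


def run_scenario(scenario: Scenario,
                 baseline: CalibratedBaseline,
                 params: PopulationParams | None = None,
                 n_agents: int = 3845,
                 replicates: int | None = None,
                 seed: int | None = None,
                 clock: SimClock | None = None,
                 crn: bool = True,
                 use_network: bool = False,
                 mean_degree: float = 8.0,
                 homophily: float = 0.9,
                 **engine_kwargs) -> OutcomeSummary:
    """Run one scenario and aggregate the eight outcome rates.

    Each replicate samples a fresh cohort, applies the scenario, and
    simulates it with the calibrated models.  ``crn=True`` (default) reuses
    replicate streams across scenarios; ``crn=False`` derives them from the
    scenario name as well.  The peer network is only built when
    ``use_network`` is set (it is inert while the intent model's
    ``peer_weight`` is 0).
    """
    params = params or baseline.params
    replicates = scenario.replicates if replicates is None else replicates
    seed = scenario.base_seed if seed is None else seed
    if replicates < 1:
        raise ValueError("replicates must be at least 1")
    clock = clock or SimClock()
    intent_model = baseline.intent_model.with_(
        beta_knowledge=scenario.beta_knowledge)
    initiation_model = baseline.initiation_model.with_(
        beta_bfhi=scenario.beta_bfhi)

    rows = []
    for rep in range(replicates):
        cohort = sample_cohort(
            n_agents, params,
            _scenario_stream(seed, _STREAM_COHORT, rep, scenario.name, crn))
        cohort = apply_scenario(
            cohort, scenario, params,
            _scenario_stream(seed, _STREAM_SCENARIO, rep, scenario.name,
                             crn))
        network = None
        if use_network:
            network = build_network(
                cohort, mean_degree, homophily,
                _scenario_stream(seed, _STREAM_NET, rep, scenario.name,
                                 crn))
        result = run_cohort(
            cohort, intent_model, initiation_model, baseline.rates,
            baseline.exclusive_share, clock,
            seed=_scenario_stream(seed, _STREAM_TRAJ, rep, scenario.name,
                                  crn),
            network=network, **engine_kwargs)
        rows.append(result.outcome_rates())

    per_rep = pd.DataFrame(rows)
    means = {k: float(per_rep[k].mean()) for k in OUTCOME_FIELDS}
    if replicates > 1:
        ses = {k: float(per_rep[k].std(ddof=1) / np.sqrt(replicates))
               for k in OUTCOME_FIELDS}
    else:
        ses = {k: float("nan") for k in OUTCOME_FIELDS}
    return OutcomeSummary(scenario=scenario, replicates=replicates,
                          means=means, ses=ses, per_replicate=per_rep)


def synergy(package_summary: OutcomeSummary,
            single_summaries: list[OutcomeSummary],
            baseline_summary: OutcomeSummary,
            outcome: str = "any_bf_6m") -> float:
    """Excess of a package effect over the sum of its single-lever effects.

    ``(package - baseline) - sum(single - baseline)`` for the chosen
    outcome, in percentage points.  All summaries must share the baseline
    run configuration (same base seed and replicate count).
    """
    ref = (baseline_summary.scenario.base_seed, baseline_summary.replicates)
    for s in [package_summary, *single_summaries]:
        if (s.scenario.base_seed, s.replicates) != ref:
            raise ValueError(
                "summaries do not share the baseline configuration "
                f"(base_seed, replicates) = {ref}; got "
                f"{(s.scenario.base_seed, s.replicates)} for "
                f"{s.scenario.name!r}")
    base = baseline_summary.mean(outcome)
    package_effect = package_summary.mean(outcome) - base
    single_effects = sum(s.mean(outcome) - base for s in single_summaries)
    return float(package_effect - single_effects)


@dataclass(frozen=True)
class SensitivitySpec:
    """A one-parameter sweep at universal 95% intervention coverage."""

    parameter: str = "beta_knowledge"
    values: tuple[float, ...] = (1.0, 1.17, 1.25, 1.5)
    coverage: float = 0.95
    knowledge_mean: float = 0.95

    _DEFAULTS = {"beta_knowledge": 1.17, "beta_bfhi": 0.155}

    def __post_init__(self):
        if self.parameter not in self._DEFAULTS:
            raise ValueError(
                f"unknown sensitivity parameter {self.parameter!r}; "
                f"choose from {sorted(self._DEFAULTS)}")
        if self._DEFAULTS[self.parameter] not in self.values:
            raise ValueError(
                f"the in-model default {self._DEFAULTS[self.parameter]} "
                f"must appear in the swept values {self.values}")


def sensitivity_sweep(spec: SensitivitySpec,
                      baseline: CalibratedBaseline,
                      params: PopulationParams | None = None,
                      n_agents: int = 3845,
                      replicates: int = 100,
                      seed: int = 0,
                      **kwargs) -> pd.DataFrame:
    """Sweep one effect coefficient with all five levers at 95% coverage.

    All runs share replicate random streams (common random numbers), so
    differences between rows reflect only the swept coefficient.  Returns
    one row per parameter value with the eight outcome rates.
    """
    params = params or baseline.params
    rows = []
    for value in spec.values:
        scenario = Scenario(
            name="sensitivity-95",  # shared name keeps streams common
            knowledge_mean=spec.knowledge_mean,
            cov_bfhi=spec.coverage, cov_counseling=spec.coverage,
            cov_partner=spec.coverage, cov_workplace=spec.coverage,
            replicates=replicates, base_seed=seed,
            **{spec.parameter: value})
        summary = run_scenario(scenario, baseline, params, n_agents,
                               replicates, seed, crn=True, **kwargs)
        row = {"parameter": spec.parameter, "value": value}
        row.update(summary.means)
        rows.append(row)
    return pd.DataFrame(rows)


def write_outcome_tables(summaries: list[OutcomeSummary], out_dir,
                         name: str = "outcomes",
                         metadata: dict | None = None) -> dict[str, Path]:
    """Write scenario outcome tables and a run-metadata file.

    Produces ``<name>.csv`` (one row per scenario: the eight outcome means
    then their standard errors) and ``<name>_metadata.json`` recording the
    scenario definitions, replicate counts and seeds needed to reproduce
    the table.
    """
    if not summaries:
        raise ValueError("no summaries to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame([s.to_series() for s in summaries])
    csv_path = out_dir / f"{name}.csv"
    table.to_csv(csv_path, index=False)

    meta = {
        "scenarios": [
            {"name": s.scenario.name,
             "replicates": s.replicates,
             "base_seed": s.scenario.base_seed,
             "knowledge_mean": s.scenario.knowledge_mean,
             "knowledge_sd": s.scenario.knowledge_sd,
             "cov_bfhi": s.scenario.cov_bfhi,
             "cov_counseling": s.scenario.cov_counseling,
             "cov_partner": s.scenario.cov_partner,
             "cov_workplace": s.scenario.cov_workplace,
             "beta_knowledge": s.scenario.beta_knowledge,
             "beta_bfhi": s.scenario.beta_bfhi}
            for s in summaries
        ],
    }
    if metadata:
        meta.update(metadata)
    meta_path = out_dir / f"{name}_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    return {"table": csv_path, "metadata": meta_path}
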