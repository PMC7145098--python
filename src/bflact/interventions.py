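"""Intervention levers, coverage scenarios and packages.

Five levers are modeled: improving breastfeeding knowledge (KNWL, shifts
the mean of the Beta-distributed knowledge score), Baby-Friendly Hospital
Initiative practices (BFHI), postpartum breastfeeding counseling (COUL),
partner support (PTR) and a supportive workplace environment (WP).  A
scenario raises selected levers from their baseline — coverages by a
"top-up" that exposes currently-unexposed women with probability
``(target - base) / (1 - base)``, preserving existing exposures; knowledge
by re-drawing the score from a Beta with the scenario mean.  Interventions
only ever add coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .population import PopulationParams, beta_shape_from_moments

__all__ = ["LEVERS", "Scenario", "PackageSpec", "apply_scenario",
           "scenario_grid_published", "COVERAGE_LEVELS", "KNOWLEDGE_LEVELS"]

#: Lever short codes, in the published package-nesting order.
LEVERS = ("KNWL", "BFHI", "COUL", "PTR", "WP")

#: Coverage intervention levels studied for the binary levers.
COVERAGE_LEVELS = (0.80, 0.90, 0.95)
#: Knowledge-score mean levels studied for the KNWL lever.
KNOWLEDGE_LEVELS = (0.80, 0.90, 0.95)

_COVERAGE_FIELD = {"BFHI": "cov_bfhi", "COUL": "cov_counseling",
                   "PTR": "cov_partner", "WP": "cov_workplace"}
_COVERAGE_COLUMN = {"BFHI": "bfhi", "COUL": "counseling",
                    "PTR": "partner", "WP": "workplace"}


@dataclass(frozen=True)
class Scenario:
    """A fully specified experiment condition.

    Baseline defaults reproduce the published base level; raise individual
    fields to define an intervention scenario.  Coverages may never fall
    below their baseline values.
    """

    name: str = "baseline"
    knowledge_mean: float = 0.67
    knowledge_sd: float = 0.10
    cov_bfhi: float = 0.114
    cov_counseling: float = 0.7812
    cov_partner: float = 0.6774
    cov_workplace: float = 0.5205
    beta_knowledge: float = 1.17
    beta_bfhi: float = 0.155
    replicates: int = 100
    base_seed: int = 0

    def with_(self, **kwargs) -> "Scenario":
        return replace(self, **kwargs)

    def validate(self, base: PopulationParams) -> None:
        if not 0.0 < self.knowledge_mean < 1.0:
            raise ValueError("knowledge_mean must lie strictly in (0, 1)")
        for code, fld in _COVERAGE_FIELD.items():
            target = getattr(self, fld)
            base_val = getattr(base, fld)
            if not 0.0 <= target <= 1.0:
                raise ValueError(f"{fld}={target} is not a probability")
            if target < base_val - 1e-12:
                raise ValueError(
                    f"scenario {self.name!r} lowers {code} coverage below "
                    f"baseline ({target} < {base_val}); interventions only "
                    "add coverage")
        if self.knowledge_mean < base.knowledge_mean - 1e-12:
            raise ValueError(
                f"scenario {self.name!r} lowers the knowledge mean below "
                f"baseline ({self.knowledge_mean} < {base.knowledge_mean})")


@dataclass(frozen=True)
class PackageSpec:
    """A multi-lever package applied at one shared intervention level."""

    levers: tuple[str, ...]
    level: float  # coverage for binary levers, knowledge mean for KNWL

    def __post_init__(self):
        unknown = [c for c in self.levers if c not in LEVERS]
        if unknown:
            raise ValueError(f"unknown lever codes: {unknown}")
        if len(set(self.levers)) != len(self.levers):
            raise ValueError("duplicate lever in package")

    def to_scenario(self, name: str | None = None, **kwargs) -> Scenario:
        fields = {}
        if "KNWL" in self.levers:
            fields["knowledge_mean"] = self.level
        for code in self.levers:
            if code != "KNWL":
                fields[_COVERAGE_FIELD[code]] = self.level
        label = name or "+".join(self.levers) + f"@{self.level:g}"
        return Scenario(name=label, **fields, **kwargs)


def _feasible_sd(mean: float, sd: float) -> float:
    """Clip an SD to the Beta-family feasibility bound for a given mean."""
    bound = np.sqrt(mean * (1.0 - mean))
    return min(sd, 0.999 * bound)


def apply_scenario(cohort: pd.DataFrame, scenario: Scenario,
                   base: PopulationParams | None = None,
                   seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """Return a copy of the cohort with the scenario's levers applied.

    Knowledge scores are re-drawn from the scenario's Beta distribution
    when its mean or SD differs from baseline (the SD is clipped to the
    Beta feasibility bound).  Binary exposures are topped up: each
    currently-unexposed woman is flipped with probability
    ``(target - base) / (1 - base)``, so no woman is ever un-exposed.
    A scenario equal to the baseline returns the cohort unchanged.
    """
    base = base or PopulationParams()
    scenario.validate(base)
    rng = np.random.default_rng(seed)
    out = cohort.copy()

    if (scenario.knowledge_mean != base.knowledge_mean
            or scenario.knowledge_sd != base.knowledge_sd):
        sd = _feasible_sd(scenario.knowledge_mean, scenario.knowledge_sd)
        a, b = beta_shape_from_moments(scenario.knowledge_mean, sd)
        out["knowledge"] = stats.beta.ppf(rng.random(len(out)), a, b)

    for code, fld in _COVERAGE_FIELD.items():
        target = getattr(scenario, fld)
        base_val = getattr(base, fld)
        if target <= base_val + 1e-12:
            continue
        col = _COVERAGE_COLUMN[code]
        exposed = out[col].to_numpy(bool)
        p_flip = (target - base_val) / (1.0 - base_val)
        flip = (~exposed) & (rng.random(len(out)) < p_flip)
        out.loc[flip, col] = 1
    return out


def scenario_grid_published(replicates: int = 100, base_seed: int = 0
                        ) -> dict[str, list[Scenario]]:
    """The published experiment grid.

    Returns ``{"baseline": [...], "single": [...], "package": [...]}`` with
    one shared baseline scenario, 15 single-lever scenarios (5 levers x 3
    levels) and 15 package scenarios (5 nested packages x 3 levels).  The
    KNWL-only package coincides with the KNWL single-lever scenarios.
    """
    kw = dict(replicates=replicates, base_seed=base_seed)
    baseline = Scenario(name="baseline", **kw)
    singles: list[Scenario] = []
    for code in LEVERS:
        levels = KNOWLEDGE_LEVELS if code == "KNWL" else COVERAGE_LEVELS
        for lv in levels:
            singles.append(PackageSpec((code,), lv).to_scenario(
                name=f"{code}@{lv:g}", **kw))
    packages: list[Scenario] = []
    for k in range(1, len(LEVERS) + 1):
        subset = LEVERS[:k]
        for lv in COVERAGE_LEVELS:
            packages.append(PackageSpec(subset, lv).to_scenario(**kw))
    return {"baseline": [baseline], "single": singles, "package": packages}
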