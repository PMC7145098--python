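"""Discrete-time simulation engine.

Each woman moves through a perinatal stage sequence — pregnancy, childbirth
and a short hospital stay (days 0-2), then the postpartum period (day 3
through 6 months) — and, after initiation, through the feeding-status
sequence exclusive > partial > formula.  Time advances in daily steps;
monthly transition proportions are converted to per-day probabilities by
compounding.  Status changes arise from three sources: the residual
transition hazards, a scheduled lactation-problem event, and a scheduled
return-to-work event, the latter two resolved by the deterministic decision
trees in :mod:`bflact.behavior`.  Feeding status never increases and
formula feeding is absorbing.

Randomness contract: all stochastic draws for a cohort run come from a
single uniform matrix whose rows are assigned to women by the rank of their
agent id, so results are bitwise invariant to the iteration order of the
cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import (
    InitiationModel,
    IntentModel,
    initiation_probability,
    intent_probability,
)
from .network import PeerNetwork, peer_intent_fractions

__all__ = [
    "TransitionRates",
    "SimClock",
    "SimulationResult",
    "monthly_to_per_step",
    "run_cohort",
    "run_one_agent",
    "OUTCOME_FIELDS",
]

#: The eight outcome rates, in reporting order (percent).
OUTCOME_FIELDS = [
    "intent",
    "initiation",
    "any_bf_1m",
    "any_bf_3m",
    "any_bf_6m",
    "excl_bf_1m",
    "excl_bf_3m",
    "excl_bf_6m",
]

_EXCL, _PART, _FORM = 2, 1, 0

try:  # the compiled kernel is a drop-in replacement for the numpy path
    import numba as _numba
except ImportError:  # pragma: no cover - numba is a hard dependency in CI
    _numba = None


def _loop_kernel_py(status0, lact_day, lact_drop, rtw_day, rtw_drop,
                    u_daily, p_ep, p_ef, p_pf, first_day, horizon,
                    record_days, out):
    n = status0.shape[0]
    n_rec = record_days.shape[0]
    for i in range(n):
        s = status0[i]
        ld, rd = lact_day[i], rtw_day[i]
        k = 0
        for t in range(first_day, horizon + 1):
            if s > 0 and ld == t:
                s = s - lact_drop[i]
                if s < 0:
                    s = 0
            if s > 0 and rd == t:
                s = s - rtw_drop[i]
                if s < 0:
                    s = 0
            if s == 2:
                uu = u_daily[i, t - first_day]
                if uu < p_ep:
                    s = 1
                elif uu < p_ep + p_ef:
                    s = 0
            elif s == 1:
                if u_daily[i, t - first_day] < p_pf:
                    s = 0
            while k < n_rec and record_days[k] == t:
                out[i, k] = s
                k += 1
            if s == 0:
                # Formula feeding is absorbing; barrier events on it are
                # no-ops, so the remaining days cannot change anything.
                while k < n_rec:
                    out[i, k] = 0
                    k += 1
                break


if _numba is not None:
    _loop_kernel = _numba.njit(cache=False)(_loop_kernel_py)
else:  # pragma: no cover
    _loop_kernel = _loop_kernel_py


@dataclass(frozen=True)
class TransitionRates:
    """Residual monthly transition proportions between feeding states.

    These absorb reasons for stepping down other than the two modeled
    barriers; defaults are the published calibrated values.
    """

    excl_to_formula: float = 0.016
    partial_to_formula: float = 0.059
    excl_to_partial: float = 0.139

    def __post_init__(self):
        for name in ("excl_to_formula", "partial_to_formula",
                     "excl_to_partial"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} is not a proportion")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.excl_to_formula, self.partial_to_formula,
                self.excl_to_partial)


@dataclass(frozen=True)
class SimClock:
    """Daily clock over the 6-month postpartum horizon.

    Day 0 is childbirth; the hospital stay covers days 0 through
    ``hospital_days`` and the postpartum period runs from the following day
    to the horizon.  Outcomes are evaluated at 1, 3 and 6 months.
    """

    month_length: float = 30.4375
    horizon_months: float = 6.0
    hospital_days: int = 2
    eval_months: tuple[float, ...] = (1.0, 3.0, 6.0)

    @property
    def horizon_day(self) -> int:
        return int(round(self.horizon_months * self.month_length))

    @property
    def first_postpartum_day(self) -> int:
        return self.hospital_days + 1

    @property
    def eval_days(self) -> tuple[int, ...]:
        days = tuple(int(round(m * self.month_length))
                     for m in self.eval_months)
        if len(set(days)) != len(days):
            raise ValueError("evaluation months collapse onto the same day")
        return days

    def day_of_month(self, months: float) -> int:
        return int(np.ceil(months * self.month_length))


def monthly_to_per_step(p_month: float, month_length: float = 30.4375) -> float:
    """Convert a monthly transition proportion to a per-day probability.

    Uses ``1 - (1 - p_month)**(1/month_length)`` so that compounding over
    one month recovers ``p_month`` exactly.
    """
    if not 0.0 <= p_month <= 1.0:
        raise ValueError(f"monthly proportion {p_month} outside [0, 1]")
    if p_month == 1.0:
        warnings.warn("monthly proportion 1.0 is degenerate: per-step "
                      "probability is 1", stacklevel=2)
        return 1.0
    return 1.0 - (1.0 - p_month) ** (1.0 / month_length)


@dataclass
class SimulationResult:
    """Trajectories of one cohort run."""

    ids: np.ndarray
    intent: np.ndarray
    initiated: np.ndarray
    #: Feeding status (0/1/2) per woman: columns are ``status_days``.
    statuses: np.ndarray
    status_days: tuple[int, ...]
    clock: SimClock

    def status_at_day(self, day: int) -> np.ndarray:
        try:
            j = self.status_days.index(day)
        except ValueError:
            raise KeyError(f"day {day} was not recorded") from None
        return self.statuses[:, j]

    def outcome_rates(self) -> dict[str, float]:
        """The eight outcome rates, in percent of the whole cohort."""
        out = {
            "intent": 100.0 * float(np.mean(self.intent)),
            "initiation": 100.0 * float(np.mean(self.initiated)),
        }
        for m, d in zip(self.clock.eval_months, self.clock.eval_days):
            s = self.status_at_day(d)
            label = f"{m:g}m"
            out[f"any_bf_{label}"] = 100.0 * float(np.mean(s >= _PART))
            out[f"excl_bf_{label}"] = 100.0 * float(np.mean(s == _EXCL))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Per-agent export: intent, initiation, status at each instant."""
        df = pd.DataFrame({"id": self.ids,
                           "intent": self.intent.astype(np.int8),
                           "initiated": self.initiated.astype(np.int8)})
        for d in self.clock.eval_days:
            df[f"status_day{d}"] = self.status_at_day(d)
        return df


def _require_complete(cohort: pd.DataFrame) -> None:
    core = ["id", "age", "education", "ethnicity", "income", "knowledge",
            "bfhi", "counseling", "partner", "workplace"]
    missing = [c for c in core if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing columns: {missing}")
    if cohort[core].isna().any().any():
        bad = cohort[core].isna().any()
        raise ValueError("cohort has missing values in "
                         f"{list(bad.index[bad])}; complete records are "
                         "required before simulation")


def _barrier_arrays(cohort: pd.DataFrame, clock: SimClock,
                    zero_support_drop: int, rtw_unsupported_drop: int
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Event days (-1 = none) and step-down depths for both barriers."""
    n = len(cohort)
    first, last = clock.first_postpartum_day, clock.horizon_day

    def event_day(times_months: np.ndarray) -> np.ndarray:
        day = np.full(n, -1, dtype=np.int64)
        has = np.isfinite(times_months)
        d = np.ceil(times_months[has] * clock.month_length).astype(np.int64)
        d = np.clip(d, first, None)
        d[d > last] = -1
        day[has] = d
        return day

    lact_day = event_day(cohort["lactation_problem_time"].to_numpy(float))
    rtw_day = event_day(cohort["return_to_work_time"].to_numpy(float))

    couns = cohort["counseling"].to_numpy(bool)
    part = cohort["partner"].to_numpy(bool)
    n_support = couns.astype(np.int8) + part.astype(np.int8)
    lact_drop = np.where(n_support == 2, 0,
                         np.where(n_support == 1, 1, zero_support_drop)
                         ).astype(np.int8)
    rtw_drop = np.where(cohort["workplace"].to_numpy(bool), 0,
                        rtw_unsupported_drop).astype(np.int8)
    return lact_day, lact_drop, rtw_day, rtw_drop


def _postpartum_loop(status0: np.ndarray, lact_day: np.ndarray,
                     lact_drop: np.ndarray, rtw_day: np.ndarray,
                     rtw_drop: np.ndarray, u_daily: np.ndarray,
                     rates: TransitionRates, clock: SimClock,
                     record_days: tuple[int, ...]) -> np.ndarray:
    """Advance statuses day by day; returns statuses at ``record_days``.

    On a day with both a scheduled barrier and a residual draw, the
    lactation-problem tree is resolved first, then return to work, then the
    residual hazard, so outcomes are reproducible.
    """
    p_ef = monthly_to_per_step(rates.excl_to_formula, clock.month_length)
    p_pf = monthly_to_per_step(rates.partial_to_formula, clock.month_length)
    p_ep = monthly_to_per_step(rates.excl_to_partial, clock.month_length)

    out = np.empty((len(status0), len(record_days)), dtype=np.int8)
    _loop_kernel(status0, lact_day.astype(np.int64),
                 lact_drop.astype(np.int8), rtw_day.astype(np.int64),
                 rtw_drop.astype(np.int8),
                 np.ascontiguousarray(u_daily), p_ep, p_ef, p_pf,
                 clock.first_postpartum_day, clock.horizon_day,
                 np.asarray(record_days, dtype=np.int64), out)
    return out


def _uniform_matrix(ids: np.ndarray, n_cols: int,
                    seed) -> np.ndarray:
    """Uniforms with rows assigned by agent-id rank (order invariant)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    gen = np.random.default_rng(ss)
    n = len(ids)
    u_by_rank = gen.random((n, n_cols))
    rank = np.empty(n, dtype=np.int64)
    rank[np.argsort(ids, kind="stable")] = np.arange(n)
    return u_by_rank[rank]


def run_cohort(cohort: pd.DataFrame,
               intent_model: IntentModel | None = None,
               initiation_model: InitiationModel | None = None,
               rates: TransitionRates | None = None,
               exclusive_share: float = 0.5,
               clock: SimClock | None = None,
               seed: int | np.random.SeedSequence = 0,
               network: PeerNetwork | None = None,
               record: str = "eval",
               zero_support_drop: int = 1,
               rtw_unsupported_drop: int = 1) -> SimulationResult:
    """Simulate every woman in the cohort over the 6-month horizon.

    Intent is drawn once during pregnancy, initiation at childbirth (with
    ``exclusive_share`` of initiators starting exclusive), and the feeding
    status then evolves daily.  Deterministic given ``seed``; per-agent
    draws are keyed to agent id so permuting the cohort rows leaves every
    woman's trajectory unchanged.

    ``record`` is ``"eval"`` (statuses at 1/3/6 months, the default) or
    ``"daily"`` (full daily trajectories).
    """
    _require_complete(cohort)
    intent_model = intent_model or IntentModel()
    initiation_model = initiation_model or InitiationModel()
    rates = rates or TransitionRates()
    clock = clock or SimClock()
    if not 0.0 <= exclusive_share <= 1.0:
        raise ValueError("exclusive_share must lie in [0, 1]")
    if record not in ("eval", "daily"):
        raise ValueError("record must be 'eval' or 'daily'")

    ids = cohort["id"].to_numpy()
    n = len(cohort)
    n_days = clock.horizon_day - clock.first_postpartum_day + 1
    u = _uniform_matrix(ids, 3 + n_days, seed)

    # Intent: with peer influence on, a provisional peer-blind pass supplies
    # the neighbor intents that feed the final pass; both passes reuse the
    # same uniform so peer_weight = 0 is bitwise identical to no network.
    if network is not None and intent_model.peer_weight != 0.0:
        p_prov = intent_probability(intent_model.with_(peer_weight=0.0),
                                    cohort)
        prov = (u[:, 0] < p_prov).astype(float)
        fracs = peer_intent_fractions(network, ids, prov)
        p_intent = intent_probability(intent_model, cohort, fracs)
    else:
        p_intent = intent_probability(intent_model, cohort, 0.0)
    intent = u[:, 0] < p_intent

    p_init = initiation_probability(initiation_model,
                                    intent.astype(float),
                                    cohort["bfhi"].to_numpy(float))
    initiated = u[:, 1] < p_init
    status0 = np.where(initiated,
                       np.where(u[:, 2] < exclusive_share, _EXCL, _PART),
                       _FORM).astype(np.int8)

    lact_day, lact_drop, rtw_day, rtw_drop = _barrier_arrays(
        cohort, clock, zero_support_drop, rtw_unsupported_drop)

    if record == "daily":
        record_days = tuple(range(clock.horizon_day + 1))
    else:
        record_days = clock.eval_days
    # Days before the first postpartum day keep the initial status.
    loop_days = tuple(d for d in record_days
                      if d >= clock.first_postpartum_day)
    statuses = np.empty((n, len(record_days)), dtype=np.int8)
    pre = [j for j, d in enumerate(record_days)
           if d < clock.first_postpartum_day]
    for j in pre:
        statuses[:, j] = status0
    looped = _postpartum_loop(status0, lact_day, lact_drop, rtw_day,
                              rtw_drop, u[:, 3:], rates, clock, loop_days)
    keep = [j for j, d in enumerate(record_days)
            if d >= clock.first_postpartum_day]
    statuses[:, keep] = looped

    return SimulationResult(ids=ids, intent=intent, initiated=initiated,
                            statuses=statuses, status_days=record_days,
                            clock=clock)


def run_one_agent(woman: pd.Series | pd.DataFrame, **kwargs
                  ) -> SimulationResult:
    """Simulate a single woman (full daily trajectory by default)."""
    if isinstance(woman, pd.Series):
        woman = woman.to_frame().T
        woman = woman.astype({"id": np.int64})
    kwargs.setdefault("record", "daily")
    return run_cohort(woman, **kwargs)
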