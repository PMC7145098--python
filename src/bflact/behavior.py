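"""Individual decision models.

Three stages of the behavioral process are modeled here:

* prenatal **intent** to breastfeed — a logistic model in the woman's
  knowledge score, optional sociodemographic indicators, and the fraction
  of her peers who intend to breastfeed;
* **initiation** at childbirth — a logistic model in prenatal intent and
  delivery at a Baby-Friendly facility;
* postpartum **barrier decisions** — small deterministic decision trees
  resolving what happens to the current feeding status when a lactation
  problem arises or the woman returns to work.

Feeding status is strictly path dependent: once a woman steps down from
exclusive to partial breastfeeding, or stops entirely, she never steps back
up.  Formula feeding is absorbing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "FeedingStatus",
    "IntentModel",
    "InitiationModel",
    "intent_probability",
    "initiation_probability",
    "lactation_problem_decision",
    "return_to_work_decision",
    "calibrate_intercepts",
    "CalibrationError",
]


class FeedingStatus(IntEnum):
    """Infant feeding status; the integer order is the step-down order."""

    FORMULA = 0
    PARTIAL = 1
    EXCLUSIVE = 2
    #: Pre-initiation placeholder (pregnancy / hospital stay only).
    NOT_STARTED = 3


@dataclass(frozen=True)
class IntentModel:
    """Logistic model for prenatal intent to breastfeed.

    ``P(intent) = expit(intercept + beta_knowledge * knowledge
    + sociodem terms + peer_weight * peer_intent_fraction)``.

    The knowledge coefficient default (1.17) is the published estimate for
    the effect of breastfeeding education on intention; sociodemographic
    coefficients default to zero and the peer term is off unless a network
    is supplied.
    """

    intercept: float = 0.0
    beta_knowledge: float = 1.17
    #: Log-odds per indicator for (education, ethnicity, income) and per
    #: year of age, in that order; all default 0.
    sociodem_betas: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    peer_weight: float = 0.0

    def with_(self, **kwargs) -> "IntentModel":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class InitiationModel:
    """Logistic model for breastfeeding initiation at childbirth.

    The BFHI coefficient default (0.155) is the published estimate for the
    effect of Baby-Friendly Hospital Initiative practices on initiation.
    The intent coefficient is not identifiable from published marginals and
    defaults to 2.0; the intercept is calibrated.
    """

    intercept: float = 0.0
    beta_intent: float = 2.0
    beta_bfhi: float = 0.155

    def with_(self, **kwargs) -> "InitiationModel":
        return replace(self, **kwargs)


def _linear_predictor(model: IntentModel, women: pd.DataFrame,
                      peer_intent_fraction) -> np.ndarray:
    be, bh, bi, ba = model.sociodem_betas
    lp = (model.intercept
          + model.beta_knowledge * women["knowledge"].to_numpy(float)
          + be * women["education"].to_numpy(float)
          + bh * women["ethnicity"].to_numpy(float)
          + bi * women["income"].to_numpy(float)
          + ba * women["age"].to_numpy(float)
          + model.peer_weight * np.asarray(peer_intent_fraction, float))
    return lp


def intent_probability(model: IntentModel, women: pd.DataFrame,
                       peer_intent_fraction=0.0) -> np.ndarray:
    """Per-woman probability of prenatal intent to breastfeed."""
    k = women["knowledge"].to_numpy(float)
    if np.any((k < 0) | (k > 1)):
        raise ValueError("knowledge scores must lie in [0, 1]")
    p = np.asarray(peer_intent_fraction, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("peer intent fractions must lie in [0, 1]")
    return expit(_linear_predictor(model, women, peer_intent_fraction))


def initiation_probability(model: InitiationModel, intent, bfhi) -> np.ndarray:
    """Probability of initiating breastfeeding, given intent and BFHI birth."""
    intent = np.asarray(intent, float)
    bfhi = np.asarray(bfhi, float)
    return expit(model.intercept + model.beta_intent * intent
                 + model.beta_bfhi * bfhi)


def _step_down(status: FeedingStatus, levels: int) -> FeedingStatus:
    return FeedingStatus(max(int(status) - levels, int(FeedingStatus.FORMULA)))


def lactation_problem_decision(status: FeedingStatus, counseling: bool,
                               partner: bool,
                               zero_support_drop: int = 1) -> FeedingStatus:
    """Resolve a lactation problem.

    Support from both a lactation consultant and the partner lets the woman
    continue as she has been; exactly one source of support means one step
    down (exclusive -> partial, partial -> formula).  The no-support branch
    is configurable via ``zero_support_drop`` (default 1, i.e. the same
    single step down; 2 sends exclusive breastfeeders straight to formula).
    """
    status = FeedingStatus(status)
    if status in (FeedingStatus.NOT_STARTED, FeedingStatus.FORMULA):
        warnings.warn(
            f"lactation_problem_decision called with {status.name}; no-op",
            stacklevel=2,
        )
        return status
    n_support = int(bool(counseling)) + int(bool(partner))
    if n_support == 2:
        return status
    if n_support == 1:
        return _step_down(status, 1)
    return _step_down(status, zero_support_drop)


def return_to_work_decision(status: FeedingStatus, workplace_support: bool,
                            unsupported_drop: int = 1) -> FeedingStatus:
    """Resolve a return to work.

    A workplace accommodating nursing mothers (break time, private pumping
    space) leaves the status unchanged; otherwise the woman steps down
    ``unsupported_drop`` levels (default 1).
    """
    status = FeedingStatus(status)
    if status in (FeedingStatus.NOT_STARTED, FeedingStatus.FORMULA):
        warnings.warn(
            f"return_to_work_decision called with {status.name}; no-op",
            stacklevel=2,
        )
        return status
    if workplace_support:
        return status
    return _step_down(status, unsupported_drop)


class CalibrationError(RuntimeError):
    """A calibration target could not be reached within its bracket."""


def _root_find_intercept(expected_rate, target: float,
                         bracket: tuple[float, float] = (-20.0, 20.0)) -> float:
    lo, hi = bracket
    f_lo, f_hi = expected_rate(lo) - target, expected_rate(hi) - target
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"target rate {target} unreachable in intercept bracket "
            f"[{lo}, {hi}]: achievable range "
            f"[{expected_rate(lo):.4f}, {expected_rate(hi):.4f}]"
        )
    return brentq(lambda a: expected_rate(a) - target, lo, hi, xtol=1e-10)


def calibrate_intercepts(
    targets,
    cohort: pd.DataFrame,
    intent_model: IntentModel | None = None,
    initiation_model: InitiationModel | None = None,
) -> tuple[IntentModel, InitiationModel, float]:
    """Calibrate the intent and initiation intercepts to target marginals.

    Each intercept is root-found so that the *expected* population rate over
    the reference cohort equals its target; simulated rates then match the
    targets up to Monte-Carlo noise.  The expected initiation rate averages
    over each woman's Bernoulli intent.  The target exclusive share at
    initiation is passed through unchanged (it is a direct proportion, not
    a logistic intercept; the transition-rate calibration estimates it).

    Parameters
    ----------
    targets
        Object with ``intent``, ``initiation`` (percent) and
        ``exclusive_share_at_initiation`` (proportion) attributes, e.g.
        :class:`bflact.calibration.CalibrationTarget`.
    cohort
        Reference cohort used to average the per-woman probabilities.
    """
    intent_model = intent_model or IntentModel()
    initiation_model = initiation_model or InitiationModel()
    p_intent_target = targets.intent / 100.0
    p_init_target = targets.initiation / 100.0

    # Peer influence is self-referential at the population level; the
    # expectation uses the target prevalence as the peer fraction, which is
    # exact at peer_weight = 0 and a fixed-point approximation otherwise.
    def expected_intent(a: float) -> float:
        m = intent_model.with_(intercept=a)
        return float(np.mean(intent_probability(m, cohort, p_intent_target)))

    a_star = _root_find_intercept(expected_intent, p_intent_target)
    intent_model = intent_model.with_(intercept=a_star)

    p_intent = intent_probability(intent_model, cohort, p_intent_target)
    bfhi = cohort["bfhi"].to_numpy(float)

    def expected_initiation(b: float) -> float:
        m = initiation_model.with_(intercept=b)
        p1 = initiation_probability(m, 1.0, bfhi)
        p0 = initiation_probability(m, 0.0, bfhi)
        return float(np.mean(p_intent * p1 + (1.0 - p_intent) * p0))

    b_star = _root_find_intercept(expected_initiation, p_init_target)
    initiation_model = initiation_model.with_(intercept=b_star)

    share = getattr(targets, "exclusive_share_at_initiation", None)
    if share is None:
        share = float("nan")
    return intent_model, initiation_model, float(share)
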