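"""Synthetic cohorts of primiparous WIC-enrolled women.

The original survey records behind the model are not publicly deposited, so
cohorts are synthesized from the published marginal distributions: age
(truncated normal), three binary sociodemographics, a Beta-distributed
breastfeeding-knowledge score, four binary intervention exposures, and the
two scheduled barriers to breastfeeding maintenance (lactation problems and
return to work).

A cohort is a :class:`pandas.DataFrame` with one row per woman and the
columns listed in :data:`COHORT_COLUMNS`.  Event times are in months
postpartum; an absent event is coded ``NaN`` (empty in CSV).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationParams",
    "COHORT_COLUMNS",
    "SOCIODEM_COLUMNS",
    "beta_shape_from_moments",
    "sample_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
]

#: Canonical cohort column order.  Binary fields are coded 0/1:
#: ``education`` 1 = high-school graduate or above, ``ethnicity`` 1 =
#: Hispanic, ``income`` 1 = at or below 100% of the federal poverty level,
#: and each exposure flag 1 = exposed.  Times are months postpartum.
COHORT_COLUMNS = [
    "id",
    "age",
    "education",
    "ethnicity",
    "income",
    "knowledge",
    "bfhi",
    "counseling",
    "partner",
    "workplace",
    "lactation_problem_time",
    "return_to_work_time",
]

SOCIODEM_COLUMNS = ["age", "education", "ethnicity", "income"]

#: Days per month of simulated time (365.25 / 12).
DAYS_PER_MONTH = 30.4375


@dataclass(frozen=True)
class PopulationParams:
    """Marginal distributions of the baseline cohort.

    Defaults are the published baseline values for the 2014 Los Angeles
    County WIC survey population of primiparous women.
    """

    age_mean: float = 28.1
    age_sd: float = 6.4
    age_min: float = 15.0
    age_max: float = 50.0
    #: P(high-school graduate or above).  The printed marginals
    #: (36.5% / 64.5%) sum to 101%; the complement of the
    #: less-than-high-school figure is used.
    p_hs_or_above: float = 0.635
    p_hispanic: float = 0.85
    #: P(household income at or below 100% of the federal poverty level).
    p_income_le_fpl: float = 0.484
    knowledge_mean: float = 0.67
    knowledge_sd: float = 0.10
    # Baseline coverage of the four binary intervention exposures.
    cov_bfhi: float = 0.114
    cov_counseling: float = 0.7812
    cov_partner: float = 0.6774
    cov_workplace: float = 0.5205
    #: Cumulative incidence of a lactation problem over 0-6 months.
    p_lactation_problem: float = 0.874
    #: Earliest lactation-problem onset, in months (hospital discharge,
    #: day 3).
    lactation_onset_min: float = 3.0 / DAYS_PER_MONTH
    lactation_onset_max: float = 6.0
    #: Onset-time distribution within the window: "exponential" (decaying
    #: from discharge, truncated at 6 months; matches the clinical
    #: clustering of lactation problems in the early weeks) or "uniform".
    lactation_onset_dist: str = "exponential"
    #: Mean of the untruncated exponential onset time, in months past the
    #: window start.  Identifiable from the shape of the baseline
    #: breastfeeding trajectory; refined by calibration.
    lactation_onset_scale: float = 1.0
    #: Return-to-work category probabilities:
    #: (0-2 months, 3-5 months, >= 6 months, not employed).
    p_rtw: tuple[float, float, float, float] = (0.091, 0.144, 0.130, 0.635)
    #: Optional rank-correlation matrix (Gaussian copula) over the nine
    #: sampled fields (age, education, ethnicity, income, knowledge, bfhi,
    #: counseling, partner, workplace).  ``None`` = independent marginals.
    association: np.ndarray | None = field(default=None, compare=False)

    def validate(self) -> None:
        for name in ("p_hs_or_above", "p_hispanic", "p_income_le_fpl",
                     "cov_bfhi", "cov_counseling", "cov_partner",
                     "cov_workplace", "p_lactation_problem"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} is not a probability")
        if abs(sum(self.p_rtw) - 1.0) > 1e-9:
            raise ValueError(
                "return-to-work category probabilities must sum to 1, got "
                f"{self.p_rtw} (sum {sum(self.p_rtw):.4f})"
            )
        if self.lactation_onset_dist not in ("exponential", "uniform"):
            raise ValueError(
                f"unknown lactation_onset_dist "
                f"{self.lactation_onset_dist!r}; choose 'exponential' or "
                "'uniform'")
        if self.lactation_onset_scale <= 0:
            raise ValueError("lactation_onset_scale must be positive")

    def with_(self, **kwargs) -> "PopulationParams":
        return replace(self, **kwargs)


def beta_shape_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters matching a given mean and SD (method of moments).

    For a Beta(a, b) on [0, 1] with mean m and variance v the feasibility
    bound is v < m(1 - m); within it ``nu = m(1-m)/v - 1``, ``a = m*nu``,
    ``b = (1-m)*nu``.

    Raises
    ------
    ValueError
        If ``mean`` is not strictly inside (0, 1) or the variance violates
        the feasibility bound.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must lie strictly in (0, 1), got {mean}")
    var = sd * sd
    bound = mean * (1.0 - mean)
    if not 0.0 < var < bound:
        raise ValueError(
            f"infeasible (mean, sd) = ({mean}, {sd}): a Beta distribution "
            f"requires 0 < sd^2 < mean*(1-mean) = {bound:.6g}"
        )
    nu = bound / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float,
                   lo: float, hi: float) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _copula_uniforms(n: int, corr: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """(n, 9) uniforms with Gaussian-copula rank dependence ``corr``."""
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (9, 9):
        raise ValueError("association matrix must be 9x9 over "
                         "(age, education, ethnicity, income, knowledge, "
                         "bfhi, counseling, partner, workplace)")
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, 9)) @ chol.T
    return stats.norm.cdf(z)


def sample_cohort(n: int, params: PopulationParams | None = None,
                  seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """Draw a synthetic cohort of ``n`` primiparous women.

    All marginals converge to the configured values as ``n`` grows.  Fields
    are drawn independently of one another unless ``params.association``
    supplies a copula correlation matrix.  Fixing ``seed`` makes the draw
    fully reproducible.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    params = params or PopulationParams()
    params.validate()
    rng = np.random.default_rng(seed)

    if params.association is not None:
        u = _copula_uniforms(n, params.association, rng)
    else:
        u = rng.random((n, 9))

    age = _truncnorm_ppf(u[:, 0], params.age_mean, params.age_sd,
                         params.age_min, params.age_max)
    education = (u[:, 1] < params.p_hs_or_above).astype(np.int8)
    ethnicity = (u[:, 2] < params.p_hispanic).astype(np.int8)
    income = (u[:, 3] < params.p_income_le_fpl).astype(np.int8)

    alpha, beta = beta_shape_from_moments(params.knowledge_mean,
                                          params.knowledge_sd)
    knowledge = stats.beta.ppf(u[:, 4], alpha, beta)

    bfhi = (u[:, 5] < params.cov_bfhi).astype(np.int8)
    counseling = (u[:, 6] < params.cov_counseling).astype(np.int8)
    partner = (u[:, 7] < params.cov_partner).astype(np.int8)
    workplace = (u[:, 8] < params.cov_workplace).astype(np.int8)

    # Barriers are drawn outside the copula block: the survey gives no
    # information tying their timing to sociodemographics.
    has_lp = rng.random(n) < params.p_lactation_problem
    lp_time = np.full(n, np.nan)
    u_onset = rng.random(n)[has_lp]  # one draw per woman keeps streams
    lo, hi = params.lactation_onset_min, params.lactation_onset_max
    if params.lactation_onset_dist == "uniform":
        lp_time[has_lp] = lo + u_onset * (hi - lo)
    else:
        # Inverse CDF of an exponential truncated to (lo, hi].
        s = params.lactation_onset_scale
        mass = -np.expm1(-(hi - lo) / s)
        lp_time[has_lp] = lo - s * np.log1p(-u_onset * mass)

    cat = rng.choice(4, size=n, p=params.p_rtw)
    rtw_time = np.full(n, np.nan)
    early = cat == 0
    mid = cat == 1
    rtw_time[early] = rng.uniform(0.0, 2.0, size=int(early.sum()))
    rtw_time[mid] = rng.uniform(3.0, 5.0, size=int(mid.sum()))
    # Category ">= 6 months" falls outside the horizon; recorded as the
    # horizon boundary so the information survives a CSV round trip.
    late = cat == 2
    rtw_time[late] = 6.0

    return pd.DataFrame({
        "id": np.arange(n, dtype=np.int64),
        "age": age,
        "education": education,
        "ethnicity": ethnicity,
        "income": income,
        "knowledge": knowledge,
        "bfhi": bfhi,
        "counseling": counseling,
        "partner": partner,
        "workplace": workplace,
        "lactation_problem_time": lp_time,
        "return_to_work_time": rtw_time,
    })


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to CSV (one row per woman, times in months)."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing required columns: {missing}")
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV.

    Rows with a missing value in any of the four sociodemographic fields
    are dropped with a logged warning, mirroring the exclusion of
    incomplete survey records.  Unknown extra columns are ignored.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing required columns: {missing}")
    df = df[COHORT_COLUMNS]
    bad = df[SOCIODEM_COLUMNS].isna().any(axis=1)
    if bad.any():
        msg = (f"dropping {int(bad.sum())} row(s) with missing "
               f"sociodemographic fields")
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        df = df.loc[~bad].reset_index(drop=True)
    for col in ("id", "education", "ethnicity", "income",
                "bfhi", "counseling", "partner", "workplace"):
        df[col] = df[col].astype(np.int64 if col == "id" else np.int8)
    return df
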