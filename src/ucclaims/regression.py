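"""Multivariable outcome models and group-comparison statistics.

The three time-to-event outcomes (systemic steroid initiation, first
MTD, surgery) are modelled with Cox proportional hazards (partial
likelihood, Efron handling of tied event days — claims data are
day-granular with many ties), reported as hazard ratios with Wald 95%
intervals.  Death, recorded only as an indicator, is modelled with
logistic regression and reported as odds ratios.  Both families are
exposed so either reporting convention can be reproduced.

Group comparisons of categorical rows use the Pearson chi-square
without continuity correction by default (Yates correction available by
flag); Fisher's exact test is also provided for sparse 2×2 tables,
where the two can differ noticeably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .survival import extract_time_to_event

logger = logging.getLogger(__name__)

__all__ = [
    "ModelResult",
    "DegenerateFitError",
    "fit_cox",
    "fit_logistic",
    "fit_outcome_model",
    "chi_square_compare",
    "fisher_exact_2x2",
    "median_iqr",
    "OUTCOME_COVARIATES",
]


class DegenerateFitError(RuntimeError):
    """Zero events or complete separation; names the offending term."""


@dataclass
class ModelResult:
    """Fitted effects on the ratio scale with Wald intervals."""

    outcome: str
    family: str  # "proportional_hazards" | "logistic"
    table: pd.DataFrame  # index: covariate; columns: estimate, ci_low, ci_high, p
    n: int
    n_events: int
    reference: dict = field(default_factory=dict)

    def estimate(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "estimate"])


def _check_events(y: np.ndarray, outcome: str, binary: bool = False) -> None:
    if y.sum() == 0:
        raise DegenerateFitError(f"no events for outcome {outcome!r}")
    if binary and y.sum() == len(y):
        # a fully-censored Cox sample is caught above; an all-event binary
        # outcome has no variation left to model
        raise DegenerateFitError(f"all subjects have the event for outcome {outcome!r}")


def _check_separation(
    X: pd.DataFrame, y: np.ndarray, outcome: str, binary: bool = False
) -> None:
    for col in X.columns:
        x = X[col].to_numpy()
        if np.unique(x).size == 1:
            raise DegenerateFitError(
                f"covariate {col!r} is constant in the {outcome!r} model"
            )
        if np.unique(x).size == 2:
            for level in np.unique(x):
                n_events = y[x == level].sum()
                # a level with no events drives the coefficient to -inf;
                # for a binary outcome an all-event level does the same
                if n_events == 0 or (binary and n_events == (x == level).sum()):
                    raise DegenerateFitError(
                        f"complete separation on covariate {col!r} "
                        f"in the {outcome!r} model"
                    )


def fit_cox(
    df: pd.DataFrame, duration_col: str, event_col: str, covariates: list[str],
    outcome: str = "",
) -> ModelResult:
    """Cox proportional-hazards fit; hazard ratios with Wald 95% CIs."""
    y = df[event_col].to_numpy(dtype=int)
    _check_events(y, outcome or event_col)
    _check_separation(df[covariates], y, outcome or event_col)
    cph = CoxPHFitter()  # Efron tie handling (lifelines default)
    try:
        cph.fit(df[[duration_col, event_col] + covariates],
                duration_col=duration_col, event_col=event_col)
    except ConvergenceError as exc:
        raise DegenerateFitError(
            f"Cox fit failed to converge for outcome {outcome!r}: {exc}"
        ) from exc
    summ = cph.summary
    table = pd.DataFrame(
        {
            "estimate": np.exp(summ["coef"]),
            "ci_low": np.exp(summ["coef lower 95%"]),
            "ci_high": np.exp(summ["coef upper 95%"]),
            "p": summ["p"],
            "se_log": summ["se(coef)"],
        }
    )
    return ModelResult(
        outcome=outcome or event_col,
        family="proportional_hazards",
        table=table,
        n=len(df),
        n_events=int(y.sum()),
    )


def fit_logistic(
    df: pd.DataFrame, y_col: str, covariates: list[str], outcome: str = ""
) -> ModelResult:
    """Logistic fit; odds ratios with Wald 95% CIs."""
    y = df[y_col].to_numpy(dtype=int)
    _check_events(y, outcome or y_col, binary=True)
    _check_separation(df[covariates], y, outcome or y_col, binary=True)
    X = sm.add_constant(df[covariates].astype(float), has_constant="add")
    try:
        res = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:  # perfect separation raises at fit time
        raise DegenerateFitError(
            f"logistic fit failed for outcome {outcome!r}: {exc}"
        ) from exc
    params = res.params.drop("const")
    conf = res.conf_int().drop("const")
    table = pd.DataFrame(
        {
            "estimate": np.exp(params),
            "ci_low": np.exp(conf[0]),
            "ci_high": np.exp(conf[1]),
            "p": res.pvalues.drop("const"),
            "se_log": res.bse.drop("const"),
        }
    )
    return ModelResult(
        outcome=outcome or y_col,
        family="logistic",
        table=table,
        n=len(df),
        n_events=int(y.sum()),
    )


#: covariate sets per outcome (reference levels: male, non-elderly onset,
#: non-academic facility, no steroid, no MTD)
OUTCOME_COVARIATES = {
    "steroid": ["female", "elderly_onset", "academic"],
    "mtd": ["female", "elderly_onset", "academic", "steroid_use"],
    "surgery": ["female", "elderly_onset", "academic", "steroid_use", "mtd_use"],
    "death": ["female", "elderly_onset", "academic", "steroid_use", "mtd_use"],
}

_REFERENCE = {
    "female": "male",
    "elderly_onset": "non-elderly onset",
    "academic": "non-academic",
    "steroid_use": "no systemic steroid",
    "mtd_use": "no MTD",
}


def _design_from_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": cohort["patient_id"],
            "female": (cohort["sex"] == "F").astype(int),
            "elderly_onset": (cohort["onset_group"] == "EO").astype(int),
            "academic": cohort["academic"].astype(int),
            "steroid_use": cohort["steroid_use"].astype(int),
            "mtd_use": cohort["mtd_use"].astype(int),
            "death": cohort["death"].astype(int),
        }
    )


def _adaptive_defaults(
    X: pd.DataFrame, y: np.ndarray, defaults: list[str], binary: bool, outcome: str
) -> list[str]:
    """Filter the default adjustment set down to identifiable covariates.

    Silently dropping a covariate the caller asked for would hide a
    modelling error, so this only applies to the defaults: small cohorts
    may sample e.g. no academic-facility patient (constant covariate) or
    no event in one level of a rare flag (complete separation).
    """
    kept = []
    for c in defaults:
        x = X[c].to_numpy()
        levels = np.unique(x)
        reason = None
        if levels.size == 1:
            reason = "constant"
        elif levels.size == 2:
            for level in levels:
                n_events = y[x == level].sum()
                if n_events == 0 or (binary and n_events == (x == level).sum()):
                    reason = "separated"
                    break
        if reason:
            logger.warning(
                "dropping %s covariate %r from the %r model", reason, c, outcome
            )
        else:
            kept.append(c)
    return kept


def fit_outcome_model(
    cohort: pd.DataFrame,
    outcome: str,
    covariates: list[str] | None = None,
    family: str | None = None,
) -> ModelResult:
    """Fit the multivariable model for one clinical outcome.

    ``outcome`` is ``steroid``, ``mtd``, ``surgery`` (proportional
    hazards on time from onset) or ``death`` (logistic).  ``family``
    can force the other model family where both readings are wanted.
    """
    if outcome not in OUTCOME_COVARIATES:
        raise ValueError(f"unknown outcome {outcome!r}")
    design = _design_from_cohort(cohort)
    family = family or ("logistic" if outcome == "death" else "proportional_hazards")

    if outcome == "death" and family == "logistic":
        if covariates is None:
            covariates = _adaptive_defaults(
                design, design["death"].to_numpy(dtype=int),
                OUTCOME_COVARIATES[outcome], binary=True, outcome="death",
            )
        result = fit_logistic(design, "death", covariates, outcome="death")
    else:
        if outcome == "death":
            # death as time-to-event: follow-up from onset to observation end
            time = (cohort["obs_end"] - cohort["onset_date"]).dt.days
            tte = pd.DataFrame(
                {
                    "patient_id": cohort["patient_id"],
                    "time": time.to_numpy(dtype=int),
                    "event": design["death"].to_numpy(),
                }
            )
        else:
            tte = extract_time_to_event(cohort, outcome)
        df = tte.merge(design, on="patient_id")
        if covariates is None:
            covariates = _adaptive_defaults(
                df, df["event"].to_numpy(dtype=int),
                OUTCOME_COVARIATES[outcome], binary=(family == "logistic"),
                outcome=outcome,
            )
        if family == "logistic":
            df["event"] = df["event"].astype(int)
            result = fit_logistic(df, "event", covariates, outcome=outcome)
        else:
            result = fit_cox(df, "time", "event", covariates, outcome=outcome)
    result.reference = {c: _REFERENCE.get(c, "0") for c in covariates}
    return result


def chi_square_compare(
    table, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on a 2×k contingency table -> ``(stat, p)``.

    No continuity correction by default; set ``correction=True`` for
    the Yates-corrected 2×2 variant.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 2 or arr.shape[1] < 2:
        raise ValueError(f"expected a 2 x k table with k >= 2; got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero-margin row or column")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=correction)
    return float(stat), float(p)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher's exact test on a 2×2 table -> ``(odds ratio, p)``."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("Fisher's exact test needs a 2 x 2 table")
    odds, p = stats.fisher_exact(arr)
    return float(odds), float(p)


def median_iqr(values) -> tuple[float, float, float]:
    """Median and 25th/75th percentiles (linear interpolation)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr needs at least one value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)
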