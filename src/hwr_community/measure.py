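"""The hospital-wide readmission measure: standardized readmission ratios.

For each of five specialty cohorts, a hierarchical logistic regression
with a hospital-specific random intercept and patient covariates (age,
principal-diagnosis category, comorbidity burden) yields, per hospital,

- a *predicted* readmission count: the sum over the hospital's eligible
  index admissions of the predicted probability using the hospital's own
  (shrunken) effect, and
- an *expected* count: the same sum with the hospital effect replaced by
  the average hospital effect in the sample.

Their ratio is the cohort SRR; the hospital-wide value is the
volume-weighted logarithmic mean of the cohort SRRs.  Multiplying by the
national observed rate converts the ratio to a standardized rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from hwr_community.random_intercept import (
    RandomInterceptFit,
    fit_random_intercept_logit,
)
from hwr_community.synthetic import COHORTS, DIAGNOSIS_CATEGORIES

EXCLUSION_FLAGS = (
    "excluded_planned_index",
    "excluded_transfer",
    "excluded_died_hospice_ama",
)


def filter_index_admissions(
    discharges: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop excluded index admissions; report counts removed per reason.

    Excluded are planned index admissions, transfers to another hospital,
    and patients who died, enrolled in hospice, or left against medical
    advice.  A record with several flags is counted under each.
    """
    removed = {flag: int(discharges[flag].sum()) for flag in EXCLUSION_FLAGS}
    keep = ~discharges[list(EXCLUSION_FLAGS)].any(axis=1)
    eligible = discharges[keep].copy()
    if len(eligible) == 0:
        warnings.warn("no eligible discharges remain after exclusions", stacklevel=2)
    return eligible, removed


def _cohort_design(records: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect design: intercept, centered age/comorbidity, dx dummies."""
    X = pd.DataFrame(index=records.index)
    X["const"] = 1.0
    X["age_c"] = records["age_years"].astype(float) - 75.0
    X["comorbidity_c"] = records["comorbidity_count"].astype(float) - 2.0
    for dx in DIAGNOSIS_CATEGORIES[1:]:
        X[f"dx_{dx}"] = (records["diagnosis_category"] == dx).astype(float)
    return X


@dataclass
class CohortFit:
    """Fitted hierarchical model for one specialty cohort."""

    cohort: str
    fit: RandomInterceptFit
    average_effect: float  # value used in the expected-count denominator
    average_effect_rule: str  # "mean_alpha" or "zero"

    @property
    def tau_hat(self) -> float:
        return self.fit.tau

    @property
    def alpha_hat(self) -> pd.Series:
        return self.fit.alpha

    @property
    def coef(self) -> pd.Series:
        return self.fit.coef


def fit_cohort_model(
    records: pd.DataFrame,
    average_effect: str = "mean_alpha",
    n_quad: int = 9,
) -> CohortFit:
    """Fit the hierarchical readmission model for one cohort's records.

    ``average_effect`` selects what stands in for the "average hospital"
    in the expected count: ``"mean_alpha"`` (default) is the unweighted
    arithmetic mean of the shrunken hospital-effect estimates;
    ``"weighted_mean_alpha"`` weights that mean by each hospital's
    eligible-discharge count; ``"zero"`` uses the mean of the
    random-effect distribution.

    Raises
    ------
    ValueError
        Fewer than two hospitals, or no outcome variation.
    RuntimeError
        Optimizer failed to converge.
    """
    cohorts = records["cohort"].unique()
    if len(cohorts) != 1:
        raise ValueError(f"records span {len(cohorts)} cohorts; fit one at a time")
    if average_effect not in ("mean_alpha", "weighted_mean_alpha", "zero"):
        raise ValueError(
            "average_effect must be 'mean_alpha', 'weighted_mean_alpha' or 'zero'"
        )
    X = _cohort_design(records)
    y = records["readmitted_30d_unplanned"].astype(float)
    fit = fit_random_intercept_logit(
        X, y, records["hospital_id"], n_quad=n_quad
    )
    if not fit.converged:
        raise RuntimeError(f"cohort {cohorts[0]!r}: optimizer did not converge")
    if fit.separation_groups:
        warnings.warn(
            f"cohort {cohorts[0]!r}: {len(fit.separation_groups)} hospital(s) with "
            "all events or all non-events; their effects are shrunken toward the mean",
            stacklevel=2,
        )
    if average_effect == "mean_alpha":
        avg = float(fit.alpha.mean())
    elif average_effect == "weighted_mean_alpha":
        vol = records.groupby("hospital_id").size().reindex(fit.alpha.index)
        avg = float(np.average(fit.alpha.to_numpy(), weights=vol.to_numpy(float)))
    else:
        avg = 0.0
    return CohortFit(
        cohort=str(cohorts[0]),
        fit=fit,
        average_effect=avg,
        average_effect_rule=average_effect,
    )


def compute_srr(
    cohort_fit: CohortFit, hospital_records: pd.DataFrame
) -> tuple[float, float, float]:
    """Predicted sum, expected sum, and SRR for one hospital in one cohort.

    The predicted sum uses the hospital's shrunken effect; the expected
    sum replaces it with the cohort's average effect.  Both are sums of
    inverse-logit probabilities, hence strictly positive.
    """
    hospitals = hospital_records["hospital_id"].unique()
    if len(hospitals) != 1:
        raise ValueError("pass the records of exactly one hospital")
    if len(hospital_records) == 0:
        raise ValueError("hospital has no eligible discharges in this cohort")
    alpha_h = float(cohort_fit.alpha_hat.get(hospitals[0], np.nan))
    if np.isnan(alpha_h):
        raise KeyError(f"hospital {hospitals[0]!r} not present in the cohort fit")
    X = _cohort_design(hospital_records)
    xb = X.to_numpy(float) @ cohort_fit.coef.to_numpy(float)
    predicted = float(expit(xb + alpha_h).sum())
    expected = float(expit(xb + cohort_fit.average_effect).sum())
    assert expected > 0.0
    return predicted, expected, predicted / expected


def combine_srrs(
    srrs: np.ndarray | list[float], volumes: np.ndarray | list[float]
) -> tuple[float, float]:
    """Volume-weighted logarithmic mean of cohort SRRs.

    Returns ``(combined_log_srr, combined_srr)`` where
    ``combined_log_srr = Σ v_c ln(srr_c) / Σ v_c`` over cohorts with
    positive volume; ``combined_srr`` is its exponential (the weighted
    geometric mean).
    """
    s = np.asarray(srrs, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if len(s) != len(v):
        raise ValueError("srrs and volumes must align")
    if (v < 0).any():
        raise ValueError("volumes must be nonnegative")
    keep = v > 0
    if not keep.any():
        raise ValueError("at least one cohort must have positive volume")
    if (s[keep] <= 0).any():
        raise ValueError("SRRs must be positive")
    log_srr = float(np.sum(v[keep] * np.log(s[keep])) / np.sum(v[keep]))
    return log_srr, float(np.exp(log_srr))


def standardized_rate(combined_srr: float, national_rate: float) -> float:
    """Convert a combined SRR to a risk-standardized rate in percent."""
    if not 0.0 < national_rate < 1.0:
        raise ValueError("national_rate must be in (0, 1)")
    return combined_srr * national_rate * 100.0


def compute_hospital_srr(
    discharges: pd.DataFrame,
    average_effect: str = "mean_alpha",
    n_quad: int = 9,
    national_rate: float | None = None,
) -> tuple[pd.DataFrame, dict[str, CohortFit]]:
    """End-to-end hospital-wide SRR table from raw discharge records.

    Applies the index-admission exclusions, fits the hierarchical model
    per cohort, computes per-hospital predicted/expected sums and SRRs,
    combines them into the volume-weighted log-mean, and converts to the
    rate scale using ``national_rate`` (default: the observed eligible
    readmission rate).

    Returns the per-hospital table (one row per hospital, per-cohort
    ``pred_*``/``exp_*``/``srr_*``/``vol_*`` columns, ``combined_log_srr``,
    ``combined_srr``, ``standardized_rate_pct``, ``total_volume``) and the
    per-cohort fits.
    """
    eligible, _ = filter_index_admissions(discharges)
    if len(eligible) == 0:
        raise ValueError("no eligible discharges")
    if national_rate is None:
        national_rate = float(eligible["readmitted_30d_unplanned"].mean())

    fits: dict[str, CohortFit] = {}
    pieces: dict[str, pd.DataFrame] = {}
    for cohort in COHORTS:
        sub = eligible[eligible["cohort"] == cohort]
        if len(sub) == 0:
            continue
        cf = fit_cohort_model(sub, average_effect=average_effect, n_quad=n_quad)
        fits[cohort] = cf
        X = _cohort_design(sub)
        xb = X.to_numpy(float) @ cf.coef.to_numpy(float)
        alpha = cf.alpha_hat.reindex(sub["hospital_id"]).to_numpy(float)
        pred = expit(xb + alpha)
        exp_ = expit(xb + cf.average_effect)
        agg = pd.DataFrame(
            {"pred": pred, "exp": exp_}, index=sub["hospital_id"].to_numpy()
        ).groupby(level=0).sum()
        agg["vol"] = sub.groupby("hospital_id").size()
        agg["srr"] = agg["pred"] / agg["exp"]
        pieces[cohort] = agg

    hospitals = sorted(eligible["hospital_id"].unique())
    out = pd.DataFrame(index=pd.Index(hospitals, name="hospital_id"))
    for cohort, agg in pieces.items():
        out[f"pred_{cohort}"] = agg["pred"]
        out[f"exp_{cohort}"] = agg["exp"]
        out[f"srr_{cohort}"] = agg["srr"]
        out[f"vol_{cohort}"] = agg["vol"].reindex(out.index).fillna(0).astype(int)

    srr_cols = [f"srr_{c}" for c in pieces]
    vol_cols = [f"vol_{c}" for c in pieces]
    log_srr = np.zeros(len(out))
    tot = np.zeros(len(out))
    for sc, vc in zip(srr_cols, vol_cols):
        v = out[vc].to_numpy(float)
        s = out[sc].to_numpy(float)
        term = np.where(v > 0, np.log(np.where(v > 0, s, 1.0)) * v, 0.0)
        log_srr += term
        tot += v
    out["total_volume"] = tot.astype(int)
    out["combined_log_srr"] = log_srr / tot
    out["combined_srr"] = np.exp(out["combined_log_srr"])
    out["standardized_rate_pct"] = out["combined_srr"] * national_rate * 100.0
    out.attrs["national_rate"] = national_rate
    return out, fits
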