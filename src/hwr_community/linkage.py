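"""Linking community variables to patients and hospitals.

Community variables are measured at the zip or county level.  Patients
are linked through their 5-digit zip of residence; when only county-level
data exist and a zip spans several counties, the value of the member
county with the greatest population is used.  Hospital-level exposure is
the unweighted mean over the hospital's eligible discharges, and those
means are stratified into quintiles across hospitals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def _major_county(geography: pd.DataFrame) -> pd.Series:
    """zip → greatest-population member county (ties: lowest fips)."""
    g = geography.sort_values(
        ["zip_code", "county_population", "county_fips"],
        ascending=[True, False, True],
        kind="stable",
    )
    return g.drop_duplicates("zip_code").set_index("zip_code")["county_fips"]


def resolve_unit_values(
    geography: pd.DataFrame,
    community_values: pd.DataFrame,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Resolve every variable to a per-zip value.

    Zip-level variables map directly; county-level variables map through
    the zip's greatest-population county.  Missing values stay missing
    (NaN), never zero.

    Returns a zip × variable DataFrame indexed by ``zip_code``.
    """
    zips = np.sort(geography["zip_code"].unique())
    major = _major_county(geography)
    cv = community_values
    if variables is not None:
        cv = cv[cv["variable_name"].isin(variables)]
    out: dict[str, pd.Series] = {}
    for (name, level), sub in cv.groupby(["variable_name", "level"], sort=True):
        lut = sub.set_index("unit_id")["value"]
        if level == "zip":
            out[name] = lut.reindex(zips).to_numpy()
        else:
            out[name] = lut.reindex(major.reindex(zips).to_numpy()).to_numpy()
    order = variables if variables is not None else sorted(out)
    df = pd.DataFrame(out, index=pd.Index(zips, name="zip_code"))
    return df.reindex(columns=list(order))


def resolve_unit_value(
    zip_code: str,
    variable: str,
    geography: pd.DataFrame,
    community_values: pd.DataFrame,
) -> float:
    """Resolved value of one variable for one zip (NaN when missing)."""
    if zip_code not in set(geography["zip_code"]):
        raise KeyError(f"zip {zip_code!r} not in geography")
    resolved = resolve_unit_values(
        geography[geography["zip_code"] == zip_code], community_values, [variable]
    )
    return float(resolved.loc[zip_code, variable])


def hospital_exposure_means(
    discharges: pd.DataFrame, resolved: pd.DataFrame
) -> pd.DataFrame:
    """Mean community exposure per hospital over its discharges.

    Each discharge contributes once (patient-weighted); missing values
    are excluded from the mean, and a hospital whose patients are all
    missing a variable gets NaN for it.

    Parameters
    ----------
    discharges
        Eligible discharges with ``hospital_id`` and ``zip_code``.
    resolved
        Zip × variable values from :func:`resolve_unit_values`.
    """
    per_patient = resolved.reindex(discharges["zip_code"].to_numpy())
    per_patient.index = discharges["hospital_id"].to_numpy()
    means = per_patient.groupby(level=0, sort=True).mean()
    means.index.name = "hospital_id"
    return means


def assign_quintiles(values: pd.Series) -> pd.Series:
    """Rank-based quintile labels (1–5) across hospitals.

    Sorted values are split into five near-equal groups (sizes differ by
    at most one); tied values all receive the lowest quintile label among
    their positions, so labels are reproducible regardless of input
    order.  Constant input collapses to all-Q1 with a warning; fewer than
    five distinct values triggers a collapse warning.  Missing values
    stay missing.
    """
    v = values.astype(float)
    mask = v.notna().to_numpy()
    n = int(mask.sum())
    labels = pd.Series(pd.NA, index=values.index, dtype="Int64")
    if n == 0:
        return labels
    x = v.to_numpy(float)[mask]
    order = np.argsort(x, kind="stable")
    pos_label = (np.arange(n) * 5) // n + 1
    lab = np.empty(n, dtype=np.int64)
    lab[order] = pos_label
    # ties share the lowest label in their value group
    sx = x[order]
    group_start = np.concatenate(([True], sx[1:] != sx[:-1]))
    group_id = np.cumsum(group_start) - 1
    group_min = np.minimum.reduceat(pos_label, np.flatnonzero(group_start))
    lab[order] = group_min[group_id]
    n_distinct = int(group_start.sum())
    if n_distinct == 1:
        warnings.warn(
            f"constant variable {values.name!r}: all hospitals labeled Q1",
            stacklevel=2,
        )
    elif n_distinct < 5:
        warnings.warn(
            f"variable {values.name!r} has only {n_distinct} distinct values; "
            "quintiles collapse",
            stacklevel=2,
        )
    labels.iloc[np.flatnonzero(mask)] = lab
    return labels


def quintile_matrix(means: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`assign_quintiles` column-wise to hospital exposure means."""
    return pd.DataFrame(
        {c: assign_quintiles(means[c]) for c in means.columns}, index=means.index
    )


def quintile_summary(
    quintiles: pd.DataFrame,
    outcome: pd.Series,
    weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-variable, per-quintile weighted mean and SD of the outcome.

    Weights default to 1 (unweighted); pass readmission-denominator
    volumes to match the modeling convention.  The SD uses the weighted
    analogue with an (n-1)/n reliability correction and is missing for
    single-hospital quintiles; empty quintiles are omitted.
    """
    w = pd.Series(1.0, index=outcome.index) if weights is None else weights.astype(float)
    rows = []
    for var in quintiles.columns:
        q = quintiles[var]
        for lev in (1, 2, 3, 4, 5):
            idx = q.index[(q == lev).fillna(False)]
            idx = idx.intersection(outcome.dropna().index)
            if len(idx) == 0:
                continue
            y = outcome.loc[idx].to_numpy(float)
            ww = w.loc[idx].to_numpy(float)
            m = np.average(y, weights=ww)
            if len(idx) > 1:
                var_w = np.average((y - m) ** 2, weights=ww) * len(y) / (len(y) - 1)
                sd = float(np.sqrt(var_w))
            else:
                sd = np.nan
            rows.append(
                {
                    "variable_name": var,
                    "quintile": lev,
                    "mean": float(m),
                    "sd": sd,
                    "n_hospitals": len(idx),
                }
            )
    return pd.DataFrame(rows)
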