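"""Volume-weighted quintile regressions, Wald tests, and collinearity
diagnostics.

All explanatory models are hospital-level weighted least squares on
indicator-coded exposure quintiles (Q1 is the reference), weighted by the
readmission-denominator volume.  For each variable a joint Wald test asks
whether its four non-reference quintile contrasts are simultaneously
zero.  Redundancy among variables is assessed with Belsley
variance-decomposition diagnostics: condition indices of the
column-equilibrated design and the share of each coefficient's variance
carried by each singular component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

QUINTILES = (2, 3, 4, 5)  # non-reference levels


def quintile_design(
    quintiles: pd.DataFrame, variables: list[str]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Indicator-coded design (with intercept) for the given variables.

    Rows with a missing quintile label in any used variable are dropped.
    Returns the design and the variable → column-name mapping.
    """
    sub = quintiles[variables].dropna()
    X = pd.DataFrame(index=sub.index)
    X["const"] = 1.0
    colmap: dict[str, list[str]] = {}
    for var in variables:
        cols = []
        for q in QUINTILES:
            col = f"{var}=Q{q}"
            X[col] = (sub[var] == q).astype(float)
            cols.append(col)
        colmap[var] = cols
    return X, colmap


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns implicated in the null space of a rank-deficient design."""
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    null = vt[s < s.max() * 1e-10]
    if len(null) == 0:
        return []
    mask = (np.abs(null) > 1e-8).any(axis=0)
    return [n for n, m in zip(names, mask) if m]


@dataclass
class ModelFit:
    """A fitted weighted quintile regression."""

    outcome: str
    variables: list[str]
    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    colmap: dict[str, list[str]]
    r2: float
    adjusted_r2: float
    n_hospitals: int
    weights_descriptor: str
    n_dropped_missing: int = 0
    design: pd.DataFrame = field(repr=False, default=None)
    _weights: pd.Series = field(repr=False, default=None)

    def wald_p(self, variable: str, reference: str = "chisq") -> float:
        return wald_joint_test(self, variable, reference)[1]

    def report_frame(self, reference: str = "chisq") -> pd.DataFrame:
        """Per-quintile coefficients (SE) and joint Wald P, one block per
        variable, in the layout of a final-model table (Q1 = ref)."""
        rows = []
        for var in self.variables:
            stat, p, _ = wald_joint_test(self, var, reference)
            rows.append(
                {"variable": var, "quintile": "Q1", "coefficient": 0.0,
                 "se": np.nan, "wald_p": p}
            )
            for q, col in zip(QUINTILES, self.colmap[var]):
                rows.append(
                    {"variable": var, "quintile": f"Q{q}",
                     "coefficient": float(self.params[col]),
                     "se": float(self.bse[col]), "wald_p": p}
                )
        return pd.DataFrame(rows)


def fit_weighted_quintile_model(
    quintiles: pd.DataFrame,
    variables: list[str],
    outcome: pd.Series,
    weights: pd.Series,
) -> ModelFit:
    """Weighted least squares of the outcome on quintile indicators.

    Weighted R² is 1 − SSE_w/SST_w about the weighted mean; the adjusted
    value uses n = hospitals in the fit and p = indicator columns.
    Hospitals missing any used variable or the outcome are dropped (count
    recorded on the fit).

    Raises
    ------
    ValueError
        Too few hospitals for the parameter count, or a rank-deficient
        design (the error names the aliased columns).
    """
    if not variables:
        raise ValueError("no variables to fit")
    X, colmap = quintile_design(quintiles, variables)
    common = X.index.intersection(outcome.dropna().index).intersection(
        weights.dropna().index
    )
    n_dropped = len(quintiles) - len(common)
    X = X.loc[common]
    y = outcome.loc[common].astype(float)
    w = weights.loc[common].astype(float)
    k = len(variables)
    if len(common) < 4 * k + 2:
        raise ValueError(
            f"need at least {4 * k + 2} hospitals for {k} variables, have {len(common)}"
        )
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    Xw = X.to_numpy(float) * np.sqrt(w.to_numpy(float))[:, None]
    if np.linalg.matrix_rank(Xw) < X.shape[1]:
        aliased = _aliased_columns(Xw, list(X.columns))
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")

    res = sm.WLS(y, X, weights=w).fit()
    n = len(common)
    p = X.shape[1] - 1  # indicator columns, excluding the intercept
    r2 = float(res.rsquared)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return ModelFit(
        outcome=str(outcome.name),
        variables=list(variables),
        params=res.params,
        bse=res.bse,
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        colmap=colmap,
        r2=r2,
        adjusted_r2=float(adj),
        n_hospitals=n,
        weights_descriptor=str(weights.name or "weights"),
        n_dropped_missing=n_dropped,
        design=X,
        _weights=w,
    )


def wald_joint_test(
    fit: ModelFit, variable: str, reference: str = "chisq"
) -> tuple[float, float, int]:
    """Joint test that a variable's Q2–Q5 coefficients are all zero.

    The statistic is b′V⁻¹b on 4 degrees of freedom.  ``reference``
    selects the chi-square distribution (default; appropriate at the
    study's hospital counts) or an F with denominator df n − p.

    Returns ``(statistic, p_value, df)``.
    """
    if variable not in fit.colmap:
        raise KeyError(f"variable {variable!r} not in fit")
    cols = fit.colmap[variable]
    b = fit.params[cols].to_numpy(float)
    V = fit.cov.loc[cols, cols].to_numpy(float)
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular covariance block for {variable!r}"
        ) from err
    df = len(b)
    if reference == "chisq":
        p = float(stats.chi2.sf(stat, df))
    elif reference == "f":
        dfd = fit.n_hospitals - len(fit.params)
        p = float(stats.f.sf(stat / df, df, dfd))
    else:
        raise ValueError("reference must be 'chisq' or 'f'")
    return stat, p, df


@dataclass
class CollinearityDiagnostics:
    """Belsley condition indices and variance-decomposition proportions."""

    condition_indices: np.ndarray  # nondecreasing, one per singular component
    proportions: pd.DataFrame  # component × coefficient, columns sum to 1
    flags: list[dict]  # each: component, condition_index, columns involved
    condition_threshold: float
    proportion_threshold: float

    @property
    def condition_number(self) -> float:
        return float(self.condition_indices[-1])

    def flagged_columns(self) -> set[str]:
        out: set[str] = set()
        for f in self.flags:
            out.update(f["columns"])
        return out


def belsley_diagnostics(
    X: pd.DataFrame,
    condition_threshold: float = 20.0,
    proportion_threshold: float = 0.50,
) -> CollinearityDiagnostics:
    """Variance-decomposition collinearity diagnostics of a design matrix.

    Columns (including any intercept, per standard practice) are scaled
    to unit length; singular values s_j give condition indices
    max(s)/s_j, and the proportion of coefficient k's variance carried by
    component j is (v_kj²/s_j²) normalized over components.  A component
    is flagged when its condition index reaches ``condition_threshold``
    and at least two coefficients each load more than
    ``proportion_threshold`` of their variance on it.

    An exactly singular design is reported with an infinite condition
    index and flags, not an exception.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    A = X.to_numpy(float)
    norms = np.linalg.norm(A, axis=0)
    if (norms == 0).any():
        zero = [c for c, nm in zip(X.columns, norms) if nm == 0]
        raise ValueError(f"zero columns in design: {zero}")
    A = A / norms
    _, s, vt = np.linalg.svd(A, full_matrices=False)
    s = np.where(s < s.max() * 1e-13, 0.0, s)  # numerically singular → exact
    # components ordered weakest-last so condition indices are nondecreasing
    with np.errstate(divide="ignore"):
        ci = s.max() / s
    order = np.argsort(ci, kind="stable")
    ci = ci[order]
    v = vt[order].T  # coefficient × component
    with np.errstate(divide="ignore", invalid="ignore"):
        q = v**2 / (s[order] ** 2)[None, :]
    q = np.where(np.isfinite(q), q, np.inf)
    row_tot = q.sum(axis=1)
    props = np.empty_like(q)
    for k in range(q.shape[0]):
        if np.isinf(row_tot[k]):
            inf_mask = np.isinf(q[k])
            props[k] = np.where(inf_mask, 1.0 / inf_mask.sum(), 0.0)
        else:
            props[k] = q[k] / row_tot[k]
    prop_df = pd.DataFrame(
        props.T,
        index=pd.RangeIndex(len(ci), name="component"),
        columns=X.columns,
    )
    flags = []
    for j in range(len(ci)):
        if ci[j] >= condition_threshold:
            if np.isinf(ci[j]):
                # exact singularity: variance proportions are undefined, so
                # flag the columns participating in the null-space direction
                heavy = [
                    c for c, load in zip(X.columns, np.abs(v[:, j]))
                    if load > 1e-8
                ]
            else:
                heavy = [
                    c for c in X.columns if prop_df.loc[j, c] > proportion_threshold
                ]
            if len(heavy) >= 2:
                flags.append(
                    {"component": j, "condition_index": float(ci[j]), "columns": heavy}
                )
    return CollinearityDiagnostics(
        condition_indices=ci,
        proportions=prop_df,
        flags=flags,
        condition_threshold=condition_threshold,
        proportion_threshold=proportion_threshold,
    )
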