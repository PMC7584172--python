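"""Variable selection and the end-to-end pipeline.

The selection procedure mirrors the study design: within each of the six
community domains, start from the variable the forest ranked most
important, then add the remaining domain variables in decreasing
importance order, keeping a candidate when it improves the adjusted R²
by at least a relative 10% (a P-value rule is available as an
alternative).  The union of retained variables is screened for
redundancy with Belsley diagnostics — within a flagged set the variable
with the lowest forest importance is dropped, iterating until no flags
remain — and the survivors enter one final volume-weighted multivariable
model.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hwr_community import forest as forest_mod
from hwr_community import linkage, measure, synthetic
from hwr_community.catalog import catalog_frame, default_catalog
from hwr_community.models import (
    ModelFit,
    belsley_diagnostics,
    fit_weighted_quintile_model,
    quintile_design,
)

logger = logging.getLogger("hwr_community")


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds governing selection and redundancy elimination."""

    rule: str = "relative_r2"  # or "pvalue"
    relative_r2_threshold: float = 0.10
    pvalue_threshold: float = 0.10
    condition_threshold: float = 20.0
    proportion_threshold: float = 0.50

    def __post_init__(self) -> None:
        if self.rule not in ("relative_r2", "pvalue"):
            raise ValueError("rule must be 'relative_r2' or 'pvalue'")
        for name in ("relative_r2_threshold", "pvalue_threshold",
                     "condition_threshold", "proportion_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SelectionTrace:
    """Audit record of one domain's sequential selection."""

    domain: str
    candidates: list[str]  # decreasing importance
    steps: pd.DataFrame  # variable, r2_before, r2_after, relative_gain, wald_p, decision
    retained: list[str]
    rule: str

    def to_frame(self) -> pd.DataFrame:
        out = self.steps.copy()
        out.insert(0, "domain", self.domain)
        return out


def _relative_gain(before: float, after: float) -> float:
    return (after - before) / max(before, 1e-6)


def sequential_domain_selection(
    domain: str,
    importance: pd.Series,
    domain_of: pd.Series,
    quintiles: pd.DataFrame,
    outcome: pd.Series,
    weights: pd.Series,
    config: SelectionConfig = SelectionConfig(),
) -> SelectionTrace:
    """Importance-ordered forward selection within one domain.

    The domain's top-importance variable seeds the model unconditionally.
    Every further candidate is added in turn, the model refit, and the
    candidate kept iff the relative adjusted-R² gain reaches the
    threshold (or, under the P-value rule, its joint Wald P is below the
    threshold).  All candidates are evaluated regardless of intermediate
    rejections; a candidate whose fit fails is recorded as skipped.
    """
    cand = importance[domain_of.reindex(importance.index) == domain]
    cand = cand[cand > 0]
    if cand.empty:
        raise ValueError(f"domain {domain!r} has no candidate with nonzero importance")
    # strictly decreasing importance; ties broken by name for reproducibility
    order = sorted(cand.index, key=lambda v: (-cand[v], v))
    seed_var = order[0]
    retained = [seed_var]
    seed_fit = fit_weighted_quintile_model(quintiles, retained, outcome, weights)
    r2 = seed_fit.adjusted_r2
    rows = [
        {"variable": seed_var, "r2_before": np.nan, "r2_after": r2,
         "relative_gain": np.nan, "wald_p": seed_fit.wald_p(seed_var),
         "decision": "seed"}
    ]
    for var in order[1:]:
        try:
            trial = fit_weighted_quintile_model(
                quintiles, retained + [var], outcome, weights
            )
        except (ValueError, np.linalg.LinAlgError) as err:
            logger.warning("domain %s: skipping %s (%s)", domain, var, err)
            rows.append(
                {"variable": var, "r2_before": r2, "r2_after": np.nan,
                 "relative_gain": np.nan, "wald_p": np.nan, "decision": "skipped"}
            )
            continue
        gain = _relative_gain(r2, trial.adjusted_r2)
        wald_p = trial.wald_p(var)
        if config.rule == "relative_r2":
            keep = gain >= config.relative_r2_threshold
        else:
            keep = wald_p < config.pvalue_threshold
        rows.append(
            {"variable": var, "r2_before": r2, "r2_after": trial.adjusted_r2,
             "relative_gain": gain, "wald_p": wald_p,
             "decision": "kept" if keep else "dropped"}
        )
        if keep:
            retained.append(var)
            r2 = trial.adjusted_r2
    return SelectionTrace(
        domain=domain,
        candidates=order,
        steps=pd.DataFrame(rows),
        retained=retained,
        rule=config.rule,
    )


def eliminate_collinear(
    variables: list[str],
    importance: pd.Series,
    quintiles: pd.DataFrame,
    config: SelectionConfig = SelectionConfig(),
) -> tuple[list[str], list[dict]]:
    """Drop redundant variables flagged by Belsley diagnostics.

    The pooled quintile design of all retained variables is diagnosed;
    while any singular component has a condition index at or above the
    threshold with two or more coefficients loading more than the
    proportion threshold on it, the flagged variable with the lowest
    forest importance is removed and the diagnosis repeated.  Returns
    the surviving variables and an elimination log.
    """
    if not variables:
        raise ValueError("retained set is empty")
    current = list(variables)
    log: list[dict] = []
    while len(current) >= 1:
        X, colmap = quintile_design(quintiles, current)
        diag = belsley_diagnostics(
            X,
            condition_threshold=config.condition_threshold,
            proportion_threshold=config.proportion_threshold,
        )
        flagged_vars: set[str] = set()
        worst = None
        for f in diag.flags:
            involved = {
                v for v, cols in colmap.items() if set(cols) & set(f["columns"])
            }
            if involved:
                flagged_vars |= involved
                if worst is None or f["condition_index"] > worst["condition_index"]:
                    worst = {**f, "variables": sorted(involved)}
        if not flagged_vars:
            break
        # drop the least-important member of the worst flagged set
        pool = worst["variables"] if len(worst["variables"]) >= 2 else sorted(flagged_vars)
        drop = min(pool, key=lambda v: (importance.get(v, 0.0), v))
        log.append(
            {
                "dropped": drop,
                "condition_index": worst["condition_index"],
                "flagged_set": sorted(flagged_vars),
            }
        )
        logger.info(
            "eliminating %s (condition index %.1f, flagged with %s)",
            drop, worst["condition_index"], sorted(flagged_vars),
        )
        current.remove(drop)
        if len(current) == 0:
            break
    return current, log


def fit_final_model(
    variables: list[str],
    quintiles: pd.DataFrame,
    outcome: pd.Series,
    weights: pd.Series,
) -> ModelFit:
    """Final multivariable weighted quintile regression over the retained set."""
    if not variables:
        raise ValueError("final variable set is empty")
    return fit_weighted_quintile_model(quintiles, variables, outcome, weights)


# --------------------------------------------------------------------------
# end-to-end orchestration


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs, from generation to the final model."""

    seed: int = 0
    n_counties: int = 100
    zips_per_county: int = 3
    multi_county_fraction: float = 0.1
    n_hospitals: int = 100
    n_discharges: int = 50_000
    volume_distribution: tuple = ("lognormal", 5.5, 0.5)
    tau: float = 0.3
    mu: float = -1.7113
    beta: dict = field(default_factory=dict)
    gamma: synthetic.PatientEffects = field(
        default_factory=lambda: synthetic.PatientEffects(
            age_per_year=0.02, per_comorbidity=0.15, diagnosis=(0.0, 0.25, -0.2, 0.4)
        )
    )
    within_domain_rho: float = 0.3
    collinear_pairs: tuple = ()
    n_variables_per_domain: int = 5  # 0 means the full 71-variable catalog
    n_trees: int = 500
    vars_per_tree: int = 3
    min_node_size: int = 5
    max_depth: int | None = 3
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    average_effect: str = "mean_alpha"
    outcome_name: str = "combined_log_srr"
    n_quad: int = 9

    def catalog(self):
        from hwr_community.catalog import demo_catalog

        if self.n_variables_per_domain and self.n_variables_per_domain > 0:
            return demo_catalog(self.n_variables_per_domain)
        return default_catalog()


@dataclass
class PipelineResult:
    """All artifacts of one pipeline run."""

    config: PipelineConfig
    geography: pd.DataFrame
    community_values: pd.DataFrame
    hospitals: pd.DataFrame
    discharges: pd.DataFrame
    srr: pd.DataFrame
    cohort_fits: dict
    exposures: pd.DataFrame
    quintiles: pd.DataFrame
    importance: pd.Series
    forest_meta: pd.DataFrame
    traces: dict[str, SelectionTrace]
    retained_union: list[str]
    eliminations: list[dict]
    final_variables: list[str]
    final_fit: ModelFit
    domain_r2: dict[str, float]

    def final_report(self) -> pd.DataFrame:
        return self.final_fit.report_frame()

    def write(self, outdir: str | Path) -> None:
        """Write every intermediate table as delimited text."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        params = synthetic.TrueParams(
            mu=self.config.mu, tau=self.config.tau, gamma=self.config.gamma,
            beta=dict(self.config.beta), seed=self.config.seed,
        )
        synthetic.write_tables(
            out, self.geography, self.community_values, self.hospitals,
            self.discharges, params,
            extra_config={"n_trees": self.config.n_trees,
                          "vars_per_tree": self.config.vars_per_tree,
                          "min_node_size": self.config.min_node_size},
        )
        self.srr.to_csv(out / "srr.csv")
        self.exposures.to_csv(out / "exposures.csv")
        self.quintiles.to_csv(out / "quintiles.csv")
        cat = catalog_frame(self.config.catalog()).set_index("variable_name")
        imp = self.importance.rename("importance").to_frame()
        imp["domain"] = cat["domain"].reindex(imp.index)
        imp["rank"] = np.arange(1, len(imp) + 1)
        imp.to_csv(out / "importance.csv", index_label="variable_name")
        self.forest_meta.to_csv(out / "forest_meta.csv", index=False)
        for dom, trace in self.traces.items():
            trace.to_frame().to_csv(out / f"trace_{dom}.csv", index=False)
        self.final_report().to_csv(out / "model_fit.csv", index=False)
        summary = pd.DataFrame(
            {
                "key": ["r2", "adjusted_r2", "n_hospitals", "final_variables",
                        "eliminated"],
                "value": [
                    self.final_fit.r2, self.final_fit.adjusted_r2,
                    self.final_fit.n_hospitals,
                    "|".join(self.final_variables),
                    "|".join(e["dropped"] for e in self.eliminations) or "none",
                ],
            }
        )
        summary.to_csv(out / "summary.csv", index=False)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage: generate → measure → link → screen → select → fit.

    Deterministic for a fixed config: rerunning with the same seed yields
    an identical final report.  Any stage failure propagates with the
    stage named in the log.
    """
    cat = config.catalog()
    cat_df = catalog_frame(cat)
    logger.info("stage geography/community/hospitals (seed %d)", config.seed)
    geography = synthetic.generate_geography(
        config.n_counties, config.zips_per_county, config.multi_county_fraction,
        seed=config.seed,
    )
    community = synthetic.generate_community_values(
        geography, cat, within_domain_rho=config.within_domain_rho,
        collinear_pairs=tuple(config.collinear_pairs), seed=config.seed,
    )
    hospitals = synthetic.generate_hospitals(
        config.n_hospitals, tau=config.tau,
        volume_distribution=tuple(config.volume_distribution), seed=config.seed,
    )
    params = synthetic.TrueParams(
        mu=config.mu, tau=config.tau, gamma=config.gamma,
        beta=dict(config.beta), seed=config.seed,
    )
    logger.info("stage discharges (n=%d)", config.n_discharges)
    discharges = synthetic.simulate_discharges(
        hospitals, geography, community, params, config.n_discharges
    )

    logger.info("stage hwr measure")
    eligible, removed = measure.filter_index_admissions(discharges)
    logger.info("exclusions: %s", removed)
    srr, cohort_fits = measure.compute_hospital_srr(
        discharges, average_effect=config.average_effect, n_quad=config.n_quad
    )

    logger.info("stage community linkage")
    resolved = linkage.resolve_unit_values(
        geography, community, variables=list(cat_df["variable_name"])
    )
    exposures = linkage.hospital_exposure_means(eligible, resolved)
    exposures = exposures.reindex(srr.index)
    quintiles = linkage.quintile_matrix(exposures)
    outcome = srr[config.outcome_name]
    weights = srr["total_volume"].astype(float).rename("total_volume")

    logger.info("stage forest (%d trees)", config.n_trees)
    fr = forest_mod.build_forest(
        exposures, outcome, n_trees=config.n_trees,
        vars_per_tree=config.vars_per_tree, seed=config.seed,
        min_node_size=config.min_node_size, max_depth=config.max_depth,
    )
    importance = forest_mod.path_importance(fr).importance

    logger.info("stage domain selection")
    domain_of = cat_df.set_index("variable_name")["domain"]
    traces: dict[str, SelectionTrace] = {}
    domain_r2: dict[str, float] = {}
    retained_union: list[str] = []
    for dom in cat_df["domain"].unique():
        try:
            trace = sequential_domain_selection(
                dom, importance, domain_of, quintiles, outcome, weights,
                config.selection,
            )
        except ValueError as err:
            logger.warning("domain %s skipped: %s", dom, err)
            continue
        traces[dom] = trace
        retained_union.extend(v for v in trace.retained if v not in retained_union)
        dom_fit = fit_weighted_quintile_model(
            quintiles, trace.retained, outcome, weights
        )
        domain_r2[dom] = dom_fit.r2

    logger.info("stage collinearity elimination (%d retained)", len(retained_union))
    final_vars, elim = eliminate_collinear(
        retained_union, importance, quintiles, config.selection
    )
    logger.info("stage final model (%d variables)", len(final_vars))
    final_fit = fit_final_model(final_vars, quintiles, outcome, weights)

    result = PipelineResult(
        config=config,
        geography=geography,
        community_values=community,
        hospitals=hospitals,
        discharges=discharges,
        srr=srr,
        cohort_fits=cohort_fits,
        exposures=exposures,
        quintiles=quintiles,
        importance=importance,
        forest_meta=fr.meta_frame(),
        traces=traces,
        retained_union=retained_union,
        eliminations=elim,
        final_variables=final_vars,
        final_fit=final_fit,
        domain_r2=domain_r2,
    )
    if outdir is not None:
        result.write(outdir)
    return result


def config_from_dict(d: dict) -> PipelineConfig:
    """Build a PipelineConfig from a plain (YAML-loaded) mapping."""
    d = dict(d)
    if "gamma" in d and isinstance(d["gamma"], dict):
        d["gamma"] = synthetic.PatientEffects(**d["gamma"])
    if "selection" in d and isinstance(d["selection"], dict):
        d["selection"] = SelectionConfig(**d["selection"])
    if "collinear_pairs" in d:
        d["collinear_pairs"] = tuple(tuple(p) for p in d["collinear_pairs"])
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**d)
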