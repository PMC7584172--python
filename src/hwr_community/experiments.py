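"""Seeded validation experiments for the whole pipeline.

These packaged experiments are how the pipeline is validated in the
absence of restricted claims: null calibration (are the Wald tests the
right size, and does the final model find nothing when there is
nothing?), parameter recovery (does the hierarchical model recover the
between-hospital SD and covariate effects?), and selection operating
characteristics (are true community effects retained with the right
sign?).  Every experiment is reproducible bit-for-bit from its
configuration and seed, and every summary carries a Monte-Carlo SE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hwr_community import measure, synthetic
from hwr_community.catalog import catalog_frame
from hwr_community.models import fit_weighted_quintile_model
from hwr_community.selection import PipelineConfig, run_pipeline


@dataclass
class ExperimentResult:
    """Per-replicate metrics plus recomputable summaries."""

    name: str
    seeds: list[int]
    replicates: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def summarize(self, columns: list[str]) -> dict:
        """Mean and Monte-Carlo SE per metric column."""
        out = {}
        for c in columns:
            x = self.replicates[c].dropna().to_numpy(float)
            out[f"{c}_mean"] = float(x.mean())
            out[f"{c}_mc_se"] = float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan
        return out


def _rep_seeds(seed: int, reps: int) -> list[int]:
    # keep derived seeds well below 2**31
    return [int((seed * 100_003 + 7919 * r) % 2_000_000_011) for r in range(reps)]


def experiment_tau_recovery(
    n_hospitals: int = 300,
    discharges_per_hospital: int = 300,
    tau: float = 0.3,
    n_seeds: int = 5,
    seed: int = 0,
    gamma: synthetic.PatientEffects | None = None,
) -> ExperimentResult:
    """Recovery of the random-intercept SD and covariate effects.

    Generates a single-cohort dataset per replicate (all discharges in
    the medicine cohort so one hierarchical fit sees all the data) and
    records tau_hat and the fixed-effect estimates with their SEs.
    """
    if gamma is None:
        gamma = synthetic.PatientEffects(
            age_per_year=0.02, per_comorbidity=0.15, diagnosis=(0.0, 0.25, -0.2, 0.4)
        )
    seeds = _rep_seeds(seed, n_seeds)
    rows = []
    for s in seeds:
        geo = synthetic.generate_geography(10, 4, 0.0, seed=s)
        hosp = synthetic.generate_hospitals(
            n_hospitals, tau=tau, volume_distribution=("constant", 100), seed=s
        )
        params = synthetic.TrueParams(
            tau=tau, gamma=gamma, cohort_mix=(1.0, 0.0, 0.0, 0.0, 0.0),
            exclusion_rates=(0.0, 0.0, 0.0), seed=s,
        )
        community = pd.DataFrame(
            columns=["unit_id", "level", "variable_name", "value"]
        )
        disc = synthetic.simulate_discharges(
            hosp, geo, community, params, n_hospitals * discharges_per_hospital
        )
        fit = measure.fit_cohort_model(disc)
        rows.append(
            {
                "seed": s,
                "tau_hat": fit.tau_hat,
                "coef_age": fit.coef["age_c"],
                "se_age": fit.fit.coef_se["age_c"],
                "coef_comorbidity": fit.coef["comorbidity_c"],
                "se_comorbidity": fit.fit.coef_se["comorbidity_c"],
                "coef_dx_b": fit.coef["dx_dx_b"],
                "se_dx_b": fit.fit.coef_se["dx_dx_b"],
            }
        )
    reps = pd.DataFrame(rows)
    res = ExperimentResult("tau_recovery", seeds, reps)
    res.summary = res.summarize(["tau_hat", "coef_age", "coef_comorbidity"])
    res.summary.update(
        true_tau=tau, true_age=gamma.age_per_year, true_comorbidity=gamma.per_comorbidity
    )
    return res


def experiment_null_calibration(
    n_hospitals: int = 1000,
    n_discharges: int = 30_000,
    reps: int = 20,
    seed: int = 0,
    n_variables_per_domain: int = 5,
    n_trees: int = 500,
    alpha: float = 0.05,
    tau: float = 0.3,
) -> ExperimentResult:
    """Type-I-error calibration with all community effects zero.

    Per replicate: a full synthetic run (hospital intercepts present,
    every community beta zero), the hospital SRR table, then one
    bivariate weighted quintile model per community variable.  Records
    the fraction of per-variable joint Wald tests rejecting at
    ``alpha``, the final-model R² from the full selection pipeline, and
    the mean tau_hat across cohort fits.

    Hospitals are given equal target volumes so the residual variance of
    the log-SRR is the same for every hospital and the weighted test's
    nominal size is the quantity under study.  (With strongly unequal
    volumes and few discharges per hospital, shrinkage makes the log-SRR
    *more* variable at large hospitals, which volume weighting cannot
    represent; see the methods note.)
    """
    if reps < 2:
        raise ValueError("reps must be at least 2")
    seeds = _rep_seeds(seed, reps)
    rows = []
    for s in seeds:
        cfg = PipelineConfig(
            seed=s, n_hospitals=n_hospitals, n_counties=n_hospitals,
            n_discharges=n_discharges,
            volume_distribution=("constant", max(1, n_discharges // n_hospitals)),
            tau=tau, beta={}, n_variables_per_domain=n_variables_per_domain,
            n_trees=n_trees,
        )
        result = run_pipeline(cfg)
        outcome = result.srr[cfg.outcome_name]
        weights = result.srr["total_volume"].astype(float)
        rejections = []
        for var in result.quintiles.columns:
            try:
                f = fit_weighted_quintile_model(
                    result.quintiles, [var], outcome, weights
                )
            except ValueError:
                continue
            rejections.append(f.wald_p(var) < alpha)
        tau_hats = [cf.tau_hat for cf in result.cohort_fits.values()]
        rows.append(
            {
                "seed": s,
                "rejection_rate": float(np.mean(rejections)),
                "n_tests": len(rejections),
                "final_r2": result.final_fit.r2,
                "final_adjusted_r2": result.final_fit.adjusted_r2,
                "n_final_variables": len(result.final_variables),
                "tau_hat_mean": float(np.mean(tau_hats)),
            }
        )
    reps_df = pd.DataFrame(rows)
    res = ExperimentResult("null_calibration", seeds, reps_df)
    res.summary = res.summarize(["rejection_rate", "final_r2", "tau_hat_mean"])
    res.summary.update(alpha=alpha, true_tau=tau)
    return res


def signal_betas(
    n_variables_per_domain: int = 5, magnitude: float = 0.5
) -> dict[str, float]:
    """One signal variable per domain (the first), alternating sign."""
    from hwr_community.catalog import demo_catalog

    cat = catalog_frame(demo_catalog(n_variables_per_domain))
    betas: dict[str, float] = {}
    sign = 1.0
    for dom in cat["domain"].unique():
        first = cat[cat["domain"] == dom]["variable_name"].iloc[0]
        betas[first] = sign * magnitude
        sign = -sign
    return betas


def _signal_betas(
    n_variables_per_domain: int, magnitude: float
) -> tuple[dict[str, float], dict[str, float]]:
    betas = signal_betas(n_variables_per_domain, magnitude)
    return betas, dict(betas)


def demo_config(seed: int = 0) -> PipelineConfig:
    """The standard demonstration configuration.

    100 hospitals, 50,000 discharges, the 29-variable reduced catalog,
    500 trees, and one true community effect of ±0.5 log-odds per SD in
    each domain — large enough that a correct pipeline should recover
    most of them at this scale.
    """
    return PipelineConfig(seed=seed, beta=signal_betas())


def experiment_effect_recovery(
    effect_grid: tuple[float, ...] = (0.0, 0.25, 0.5),
    reps: int = 10,
    seed: int = 0,
    n_hospitals: int = 300,
    n_discharges: int = 30_000,
    n_variables_per_domain: int = 5,
    n_trees: int = 500,
) -> ExperimentResult:
    """Selection operating characteristics across effect sizes.

    For each generating |beta| (log-odds per SD of exposure, one signal
    variable per domain with alternating signs), runs the full pipeline
    and records: the fraction of signal variables retained in the final
    model, the fraction whose Q5 coefficient sign matches the generating
    sign, and the final R².
    """
    if not effect_grid:
        raise ValueError("effect_grid must be nonempty")
    seeds = _rep_seeds(seed, reps)
    rows = []
    for mag in effect_grid:
        betas, _ = _signal_betas(n_variables_per_domain, mag)
        signal_vars = list(betas) if mag != 0 else []
        for s in seeds:
            cfg = PipelineConfig(
                seed=s, n_hospitals=n_hospitals, n_counties=n_hospitals,
                n_discharges=n_discharges,
                beta=betas if mag != 0 else {},
                n_variables_per_domain=n_variables_per_domain, n_trees=n_trees,
            )
            result = run_pipeline(cfg)
            if signal_vars:
                retained = np.mean([v in result.final_variables for v in signal_vars])
                signs = []
                rep_frame = result.final_report()
                for v in signal_vars:
                    if v not in result.final_variables:
                        continue
                    q5 = rep_frame[
                        (rep_frame["variable"] == v) & (rep_frame["quintile"] == "Q5")
                    ]["coefficient"].iloc[0]
                    signs.append(np.sign(q5) == np.sign(betas[v]))
                sign_agree = float(np.mean(signs)) if signs else np.nan
            else:
                retained = np.mean(
                    [v in result.final_variables for v in result.quintiles.columns]
                )
                sign_agree = np.nan
            rows.append(
                {
                    "beta_magnitude": mag,
                    "seed": s,
                    "retention": float(retained),
                    "q5_sign_agreement": sign_agree,
                    "final_r2": result.final_fit.r2,
                    "n_final_variables": len(result.final_variables),
                }
            )
    reps_df = pd.DataFrame(rows)
    res = ExperimentResult("effect_recovery", seeds, reps_df)
    by_mag = reps_df.groupby("beta_magnitude")
    res.summary = {
        "retention_by_beta": by_mag["retention"].mean().to_dict(),
        "final_r2_by_beta": by_mag["final_r2"].mean().to_dict(),
        "retention_mc_se_by_beta": (
            by_mag["retention"].std() / np.sqrt(by_mag["retention"].count())
        ).to_dict(),
    }
    return res


_EXPERIMENTS = {
    "tau_recovery": experiment_tau_recovery,
    "null_calibration": experiment_null_calibration,
    "effect_recovery": experiment_effect_recovery,
}


def run_experiment_config(config_path: str | Path, outdir: str | Path) -> ExperimentResult:
    """Run one experiment from a YAML config; write per-replicate and
    summary tables.

    The config must contain an ``experiment`` key naming one of
    ``tau_recovery``, ``null_calibration`` or ``effect_recovery``; all
    other keys are passed to that experiment as keyword arguments.
    """
    with open(config_path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    name = cfg.pop("experiment", None)
    if name not in _EXPERIMENTS:
        raise ValueError(
            f"config must set experiment to one of {sorted(_EXPERIMENTS)}, got {name!r}"
        )
    if "effect_grid" in cfg:
        cfg["effect_grid"] = tuple(cfg["effect_grid"])
    result = _EXPERIMENTS[name](**cfg)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.replicates.to_csv(out / f"{result.name}_replicates.csv", index=False)
    with open(out / f"{result.name}_summary.json", "w", encoding="utf-8") as fh:
        json.dump(result.summary, fh, indent=2, default=float)
    return result
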