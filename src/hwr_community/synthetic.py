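"""Synthetic claims-like data with known ground truth.

Restricted Medicare claims cannot be redistributed, so this module
generates the four tables the pipeline consumes — geography (zip→county),
community variables, hospitals, and patient-level discharges — from a
generative model whose parameters are known exactly:

.. math::

    \\mathrm{logit}\\, P(\\text{readmit}_i) = \\mu + \\alpha_{h(i)}
        + \\gamma' x_i + \\beta' z_{\\mathrm{zip}(i)}

with hospital random intercepts :math:`\\alpha_h \\sim N(0, \\tau^2)`,
patient covariates :math:`x_i` (age, comorbidity burden, diagnosis
category), and community exposures :math:`z` resolved at the patient's
zip of residence and standardized to unit variance before the effects
:math:`\\beta` are applied.  Every stage draws from a named substream of
one global seed, so identical configuration yields byte-identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from hwr_community._rng import substream
from hwr_community.linkage import resolve_unit_values

#: The five specialty cohorts of the hospital-wide readmission measure.
COHORTS = (
    "medicine",
    "surgery_gynecology",
    "cardiorespiratory",
    "cardiovascular",
    "neurology",
)

#: Diagnosis-category labels used by the generator (coarse case-mix strata).
DIAGNOSIS_CATEGORIES = ("dx_a", "dx_b", "dx_c", "dx_d")

_DX_MIX = (0.4, 0.3, 0.2, 0.1)


@dataclass(frozen=True)
class PatientEffects:
    """Patient-level covariate effects on the log-odds of readmission."""

    age_per_year: float = 0.0
    per_comorbidity: float = 0.0
    diagnosis: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.diagnosis) != len(DIAGNOSIS_CATEGORIES):
            raise ValueError(
                f"diagnosis effects must have {len(DIAGNOSIS_CATEGORIES)} entries"
            )


@dataclass(frozen=True)
class TrueParams:
    """Ground-truth generative parameters.

    Parameters
    ----------
    mu
        Baseline log-odds of 30-day unplanned readmission for the
        reference patient.  The default is logit(0.153), matching a
        marginal readmission rate of 15.3% when all effects are zero.
    tau
        Standard deviation of hospital random intercepts (log-odds).
    gamma
        Patient covariate effects (log-odds per unit).
    beta
        Community-variable effects, log-odds per standard deviation of
        exposure, keyed by catalog variable name.  Variables not listed
        have no effect.
    cohort_mix
        Proportions of discharges in the five specialty cohorts.
    exclusion_rates
        Marginal probabilities of the three exclusion flags
        (planned index admission, transfer out, died/hospice/AMA).
    catchment_leak
        Probability that a patient's zip is drawn from the whole map
        instead of the hospital's home county; keeps hospital exposure
        means variable but not perfectly segregated.
    """

    mu: float = -1.7113
    tau: float = 0.3
    gamma: PatientEffects = field(default_factory=PatientEffects)
    beta: dict[str, float] = field(default_factory=dict)
    cohort_mix: tuple[float, ...] = (0.45, 0.20, 0.15, 0.12, 0.08)
    exclusion_rates: tuple[float, float, float] = (0.03, 0.02, 0.05)
    catchment_leak: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")
        mix = np.asarray(self.cohort_mix, dtype=float)
        if len(mix) != len(COHORTS) or (mix < 0).any():
            raise ValueError(f"cohort_mix needs {len(COHORTS)} nonnegative entries")
        if abs(mix.sum() - 1.0) > 1e-12:
            raise ValueError("cohort_mix must sum to 1 within 1e-12")

    @classmethod
    def null(cls, seed: int = 0, tau: float = 0.0, mu: float = -1.7113) -> "TrueParams":
        """All patient and community effects zero; handy for calibration."""
        return cls(mu=mu, tau=tau, seed=seed)

    @classmethod
    def realistic(cls, seed: int = 0, **kwargs) -> "TrueParams":
        """Moderate, plausible patient-covariate effects (community betas off)."""
        gamma = PatientEffects(
            age_per_year=0.02, per_comorbidity=0.15, diagnosis=(0.0, 0.25, -0.2, 0.4)
        )
        return cls(gamma=gamma, seed=seed, **kwargs)


def generate_geography(
    n_counties: int,
    zips_per_county: int,
    multi_county_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a flat zip→county table with county populations.

    A requested fraction of zips is assigned to a second county (with a
    distinct population) to exercise the greatest-population resolution
    rule used when linking county-level variables.  Multi-county zips get
    one row per member county.

    Returns a DataFrame with columns ``zip_code``, ``county_fips``,
    ``county_population``, ``zip_spans_multiple_counties``.
    """
    if n_counties < 2:
        raise ValueError("need at least 2 counties")
    if zips_per_county < 1:
        raise ValueError("zips_per_county must be positive")
    if not 0.0 <= multi_county_fraction <= 1.0:
        raise ValueError("multi_county_fraction must be in [0, 1]")
    rng = substream(seed, "geography")

    pops = np.maximum(rng.lognormal(mean=10.5, sigma=1.0, size=n_counties), 500.0)
    pops = pops.astype(np.int64)
    # distinct populations so the greatest-population rule never ties
    order = np.argsort(pops, kind="stable")
    for i, j in zip(order[:-1], order[1:]):
        if pops[j] <= pops[i]:
            pops[j] = pops[i] + 1
    county_fips = np.array([f"{i + 1:05d}" for i in range(n_counties)])

    n_zips = n_counties * zips_per_county
    zip_codes = np.array([f"{10000 + j:05d}" for j in range(n_zips)])
    primary = np.repeat(np.arange(n_counties), zips_per_county)

    n_multi = int(round(multi_county_fraction * n_zips))
    multi_idx = np.sort(rng.choice(n_zips, size=n_multi, replace=False))
    is_multi = np.zeros(n_zips, dtype=bool)
    is_multi[multi_idx] = True

    rows = {
        "zip_code": list(zip_codes),
        "county_fips": list(county_fips[primary]),
        "county_population": list(pops[primary]),
        "zip_spans_multiple_counties": list(is_multi),
    }
    for j in multi_idx:
        second = (primary[j] + 1) % n_counties
        rows["zip_code"].append(zip_codes[j])
        rows["county_fips"].append(county_fips[second])
        rows["county_population"].append(pops[second])
        rows["zip_spans_multiple_counties"].append(True)

    geo = pd.DataFrame(rows)
    return geo.sort_values(["zip_code", "county_fips"], kind="stable").reset_index(
        drop=True
    )


def _largest_county_by_zip(geography: pd.DataFrame) -> pd.Series:
    """Map each zip to its greatest-population member county (ties: lowest fips)."""
    g = geography.sort_values(
        ["zip_code", "county_population", "county_fips"],
        ascending=[True, False, True],
        kind="stable",
    )
    return g.drop_duplicates("zip_code").set_index("zip_code")["county_fips"]


def generate_community_values(
    geography: pd.DataFrame,
    catalog,
    within_domain_rho: float = 0.3,
    collinear_pairs: tuple[tuple[str, str], ...] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw one value per (geographic unit, variable).

    Variables within a domain share a latent county-level factor, giving
    pairwise correlation ``within_domain_rho`` between any two variables
    of the same domain.  Zip-level variables inherit the factor of the
    zip's greatest-population county, so cross-level correlation within a
    domain is preserved.  Marginal distributions are standard normal.

    ``collinear_pairs`` lists (a, b) name pairs; b is regenerated as a
    near-duplicate of a (sample correlation > 0.99) to exercise the
    collinearity-elimination stage.  Both members must share a
    measurement level.

    Returns a long DataFrame with columns ``unit_id``, ``level``,
    ``variable_name``, ``value``.
    """
    if not 0.0 <= within_domain_rho < 1.0:
        raise ValueError("within_domain_rho must be in [0, 1)")
    entries = list(catalog)
    by_name = {e.variable_name: e for e in entries}
    for a, b in collinear_pairs:
        for name in (a, b):
            if name not in by_name:
                raise ValueError(f"unknown variable in collinear_pairs: {name!r}")
        if by_name[a].level != by_name[b].level:
            raise ValueError(
                f"collinear pair ({a!r}, {b!r}) must share a measurement level"
            )

    rng = substream(seed, "community")
    counties = np.sort(geography["county_fips"].unique())
    zips = np.sort(geography["zip_code"].unique())
    county_pos = {c: i for i, c in enumerate(counties)}
    zip_major = _largest_county_by_zip(geography)
    zip_factor_idx = np.array([county_pos[zip_major[z]] for z in zips])

    domains = sorted({e.domain for e in entries})
    factors = {d: rng.standard_normal(len(counties)) for d in domains}
    r = np.sqrt(within_domain_rho)
    s = np.sqrt(1.0 - within_domain_rho)

    values: dict[str, np.ndarray] = {}
    for e in entries:
        f = factors[e.domain]
        if e.level == "county":
            values[e.variable_name] = r * f + s * rng.standard_normal(len(counties))
        else:
            values[e.variable_name] = r * f[zip_factor_idx] + s * rng.standard_normal(
                len(zips)
            )
    for a, b in collinear_pairs:
        # near-duplicate: corr(a, a + 0.04 e) ≈ 0.9992
        values[b] = values[a] + 0.04 * rng.standard_normal(len(values[a]))

    frames = []
    for e in entries:
        units = counties if e.level == "county" else zips
        frames.append(
            pd.DataFrame(
                {
                    "unit_id": units,
                    "level": e.level,
                    "variable_name": e.variable_name,
                    "value": values[e.variable_name],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_hospitals(
    n_hospitals: int,
    tau: float = 0.3,
    volume_distribution: tuple = ("lognormal", 5.5, 0.5),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate hospitals with true random intercepts and target volumes.

    ``volume_distribution`` is ``("lognormal", mean_log, sigma_log)`` or
    ``("constant", v)``; volumes are positive integers used as sampling
    weights when allocating discharges.
    """
    if n_hospitals < 1:
        raise ValueError("n_hospitals must be positive")
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    rng = substream(seed, "hospitals")
    alpha = rng.normal(0.0, tau, size=n_hospitals) if tau > 0 else np.zeros(n_hospitals)
    kind = volume_distribution[0]
    if kind == "lognormal":
        _, m, sg = volume_distribution
        volume = np.maximum(rng.lognormal(m, sg, size=n_hospitals), 1.0).astype(int)
    elif kind == "constant":
        volume = np.full(n_hospitals, int(volume_distribution[1]))
        if volume[0] < 1:
            raise ValueError("constant volume must be positive")
    else:
        raise ValueError(f"unknown volume_distribution kind {kind!r}")
    return pd.DataFrame(
        {
            "hospital_id": [f"H{i:04d}" for i in range(n_hospitals)],
            "alpha": alpha,
            "volume": volume,
        }
    )


def simulate_discharges(
    hospitals: pd.DataFrame,
    geography: pd.DataFrame,
    community_values: pd.DataFrame,
    params: TrueParams,
    n_discharges: int,
) -> pd.DataFrame:
    """Simulate patient-level index admissions and 30-day outcomes.

    Each hospital is assigned a home county; patient zips are drawn from
    that county's zips with probability ``1 - catchment_leak`` and from
    the whole map otherwise, so hospitals differ in their patients'
    community exposures.  The outcome is Bernoulli with log-odds
    ``mu + alpha_h + gamma·x + beta·z(zip)`` where z is the standardized
    resolved community exposure of the patient's zip.  Exclusion flags
    (planned index admission, transfer, died/hospice/AMA) are independent
    Bernoulli draws at the configured rates.
    """
    if len(hospitals) == 0:
        raise ValueError("hospitals table is empty")
    if len(geography) == 0:
        raise ValueError("geography table is empty")
    rng = substream(params.seed, "discharges")
    crng = substream(params.seed, "catchment")

    counties = np.sort(geography["county_fips"].unique())
    all_zips = np.sort(geography["zip_code"].unique())
    zips_by_county = {
        c: np.sort(sub["zip_code"].unique())
        for c, sub in geography.groupby("county_fips")
    }

    n_h = len(hospitals)
    perm = crng.permutation(len(counties))
    home_county = counties[perm[np.arange(n_h) % len(counties)]]

    probs = hospitals["volume"].to_numpy(float)
    probs = probs / probs.sum()
    counts = rng.multinomial(n_discharges, probs)
    hosp_idx = np.repeat(np.arange(n_h), counts)

    # zips: per hospital from its home county, with a leak to the whole map
    zip_code = np.empty(n_discharges, dtype=object)
    pos = 0
    for i in range(n_h):
        c = counts[i]
        if c == 0:
            continue
        local = zips_by_county[home_county[i]]
        zip_code[pos : pos + c] = local[rng.integers(0, len(local), size=c)]
        pos += c
    if params.catchment_leak > 0:
        leak = rng.random(n_discharges) < params.catchment_leak
        zip_code[leak] = all_zips[rng.integers(0, len(all_zips), size=int(leak.sum()))]

    cohort_idx = rng.choice(len(COHORTS), size=n_discharges, p=list(params.cohort_mix))
    age = 65 + rng.poisson(12.0, size=n_discharges)
    comorb = rng.poisson(2.0, size=n_discharges)
    dx_idx = rng.choice(len(DIAGNOSIS_CATEGORIES), size=n_discharges, p=_DX_MIX)

    g = params.gamma
    eta = (
        params.mu
        + hospitals["alpha"].to_numpy(float)[hosp_idx]
        + g.age_per_year * (age - 75.0)
        + g.per_comorbidity * (comorb - 2.0)
        + np.asarray(g.diagnosis, dtype=float)[dx_idx]
    )

    active = {v: b for v, b in params.beta.items() if b != 0.0}
    if active:
        resolved = resolve_unit_values(
            geography, community_values, variables=sorted(active)
        )
        z = resolved.to_numpy(float)
        z = (z - np.nanmean(z, axis=0)) / np.nanstd(z, axis=0)
        bvec = np.array([active[v] for v in resolved.columns])
        zip_effect = pd.Series(z @ bvec, index=resolved.index)
        eta = eta + zip_effect.reindex(zip_code).to_numpy(float)

    readmit = rng.random(n_discharges) < expit(eta)
    r_pl, r_tr, r_dh = params.exclusion_rates
    excl_planned = rng.random(n_discharges) < r_pl
    excl_transfer = rng.random(n_discharges) < r_tr
    excl_died = rng.random(n_discharges) < r_dh

    return pd.DataFrame(
        {
            "discharge_id": [f"D{i:07d}" for i in range(n_discharges)],
            "hospital_id": hospitals["hospital_id"].to_numpy()[hosp_idx],
            "zip_code": zip_code.astype(str),
            "cohort": np.array(COHORTS)[cohort_idx],
            "age_years": age,
            "comorbidity_count": comorb,
            "diagnosis_category": np.array(DIAGNOSIS_CATEGORIES)[dx_idx],
            "excluded_planned_index": excl_planned,
            "excluded_transfer": excl_transfer,
            "excluded_died_hospice_ama": excl_died,
            "readmitted_30d_unplanned": readmit,
        }
    )


def write_tables(
    outdir: str | Path,
    geography: pd.DataFrame,
    community_values: pd.DataFrame,
    hospitals: pd.DataFrame,
    discharges: pd.DataFrame,
    params: TrueParams,
    extra_config: dict | None = None,
) -> None:
    """Write the four generated tables plus a params.yaml echo of the config."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    geography.to_csv(out / "geography.csv", index=False)
    community_values.to_csv(out / "community.csv", index=False)
    hospitals.to_csv(out / "hospitals.csv", index=False)
    discharges.to_csv(out / "discharges.csv", index=False)
    cfg = dataclasses.asdict(params)
    cfg["gamma"] = dataclasses.asdict(params.gamma)
    if extra_config:
        cfg.update(extra_config)
    with open(out / "params.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
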