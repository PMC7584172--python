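"""The community-variable catalog: 71 variables in 6 domains.

Variables follow the County Health Rankings framework (clinical care,
health behaviors, social & economic environment, physical environment)
extended with demographic and social-capital domains.  Most variables are
measured at the county (FIPS) level; the nursing-home and home-health
quality measures are available at the 5-digit zip level.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Canonical domain keys, in catalog order.
DOMAINS = (
    "demographic",
    "health_behaviors",
    "clinical_care",
    "social_economic",
    "physical_environment",
    "social_capital",
)

#: Human-readable domain labels.
DOMAIN_LABELS = {
    "demographic": "Demographic",
    "health_behaviors": "Health Behaviors",
    "clinical_care": "Clinical Care",
    "social_economic": "Social & Economic Environment",
    "physical_environment": "Physical Environment",
    "social_capital": "Social Capital",
}


@dataclass(frozen=True)
class CommunityCatalogEntry:
    """One community variable: its name, domain, and measurement level."""

    variable_name: str
    domain: str
    level: str  # "zip" or "county"
    source: str = ""

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.level not in ("zip", "county"):
            raise ValueError(f"level must be 'zip' or 'county', got {self.level!r}")


_CHR = "County Health Rankings"
_AHRF = "Area Health Resources File"
_ACS = "American Community Survey"
_SCI = "Social Capital Index"
_NHC = "Nursing Home Compare"
_HHC = "Home Health Compare"

# (name, domain, level, source); county level unless the source reports by zip.
_CATALOG = (
    # Demographic (10)
    ("Population estimate", "demographic", "county", _CHR),
    ("% below 18 years of age", "demographic", "county", _CHR),
    ("% aged 65 years and older", "demographic", "county", _CHR),
    ("% non-Hispanic African American", "demographic", "county", _CHR),
    ("% American Indian or Alaskan Native", "demographic", "county", _CHR),
    ("% Asian", "demographic", "county", _CHR),
    ("% Hawaiian/Pacific Islander", "demographic", "county", _CHR),
    ("% Hispanic", "demographic", "county", _CHR),
    ("% non-Hispanic White", "demographic", "county", _CHR),
    ("% non-English", "demographic", "county", _CHR),
    # Health behaviors (13)
    ("Adult smoking", "health_behaviors", "county", _CHR),
    ("Adult obesity", "health_behaviors", "county", _CHR),
    ("Food environment index", "health_behaviors", "county", _CHR),
    ("Physical inactivity", "health_behaviors", "county", _CHR),
    ("Access to exercise opportunities", "health_behaviors", "county", _CHR),
    ("Excessive drinking", "health_behaviors", "county", _CHR),
    ("Alcohol-impaired driving deaths", "health_behaviors", "county", _CHR),
    ("Sexually transmitted infections", "health_behaviors", "county", _CHR),
    ("Teen births", "health_behaviors", "county", _CHR),
    ("Food insecurity", "health_behaviors", "county", _CHR),
    ("Limited access to healthy foods", "health_behaviors", "county", _CHR),
    ("Motor vehicle crash deaths", "health_behaviors", "county", _CHR),
    ("Drug poisoning deaths", "health_behaviors", "county", _CHR),
    # Clinical care (19)
    ("Uninsured", "clinical_care", "county", _CHR),
    ("Primary care physicians", "clinical_care", "county", _CHR),
    ("Dentists", "clinical_care", "county", _CHR),
    ("Mental health providers", "clinical_care", "county", _CHR),
    ("Diabetic screening", "clinical_care", "county", _CHR),
    ("Mammography screening", "clinical_care", "county", _CHR),
    ("Nursing Home Quality: Vaccines", "clinical_care", "zip", _NHC),
    ("Nursing Home Quality: Pain", "clinical_care", "zip", _NHC),
    ("HHA Quality: Improvement", "clinical_care", "zip", _HHC),
    ("HHA Quality: Pain, bedsores", "clinical_care", "zip", _HHC),
    ("HHA Quality: Vaccines", "clinical_care", "zip", _HHC),
    ("# Nursing Home beds", "clinical_care", "county", _AHRF),
    ("# Hospital Beds", "clinical_care", "county", _AHRF),
    ("GPs/100k", "clinical_care", "county", _AHRF),
    ("Med Specialists/100k", "clinical_care", "county", _AHRF),
    ("Surg Specialists/100k", "clinical_care", "county", _AHRF),
    ("Other Specialists/100k", "clinical_care", "county", _AHRF),
    ("GPs/Specialists", "clinical_care", "county", _AHRF),
    ("# Fed Qual Health Centers", "clinical_care", "county", _AHRF),
    # Social & economic environment (15)
    ("High school graduation", "social_economic", "county", _CHR),
    ("Some college", "social_economic", "county", _CHR),
    ("Unemployment", "social_economic", "county", _CHR),
    ("Children in poverty", "social_economic", "county", _CHR),
    ("Income inequality", "social_economic", "county", _CHR),
    ("Children of single parents", "social_economic", "county", _CHR),
    ("Violent crime", "social_economic", "county", _CHR),
    ("Injury deaths", "social_economic", "county", _CHR),
    ("% Commute car", "social_economic", "county", _ACS),
    ("% Commute bike", "social_economic", "county", _ACS),
    ("% Commute work at home", "social_economic", "county", _ACS),
    ("% Commute public", "social_economic", "county", _ACS),
    ("% Preschool", "social_economic", "county", _ACS),
    ("% Kindergarten", "social_economic", "county", _ACS),
    ("Median Home Value", "social_economic", "county", _ACS),
    # Physical environment (10)
    ("Particulate air pollution", "physical_environment", "county", _CHR),
    ("Drinking water violations", "physical_environment", "county", _CHR),
    ("Severe housing problems", "physical_environment", "county", _CHR),
    ("Driving alone to work", "physical_environment", "county", _CHR),
    ("Long commute - driving alone", "physical_environment", "county", _CHR),
    ("Housing Density", "physical_environment", "county", _AHRF),
    ("Good Air Days", "physical_environment", "county", _AHRF),
    ("Daily Fine Particulate Matter", "physical_environment", "county", _AHRF),
    ("Toxic Sites", "physical_environment", "county", _AHRF),
    ("Housing Units", "physical_environment", "county", _ACS),
    # Social capital (4)
    ("Social Capital: Associations", "social_capital", "county", _SCI),
    ("Social Capital: Voter turnout", "social_capital", "county", _SCI),
    ("Social Capital: Census response", "social_capital", "county", _SCI),
    ("Social Capital: Non-profits", "social_capital", "county", _SCI),
)


def default_catalog() -> list[CommunityCatalogEntry]:
    """Return the full 71-variable catalog.

    Domain sizes are 10 (demographic), 13 (health behaviors),
    19 (clinical care), 15 (social & economic), 10 (physical environment)
    and 4 (social capital).
    """
    return [CommunityCatalogEntry(*row) for row in _CATALOG]


def demo_catalog(n_per_domain: int = 5) -> list[CommunityCatalogEntry]:
    """A reduced catalog with the first ``n_per_domain`` variables per domain.

    Used by desk-scale demonstrations and validation experiments where the
    full 71-variable catalog would be unnecessarily slow.
    """
    out: list[CommunityCatalogEntry] = []
    for dom in DOMAINS:
        picked = [e for e in default_catalog() if e.domain == dom][:n_per_domain]
        out.extend(picked)
    return out


def catalog_frame(catalog: list[CommunityCatalogEntry] | None = None) -> pd.DataFrame:
    """Catalog as a DataFrame with columns variable_name/domain/level/source."""
    entries = default_catalog() if catalog is None else catalog
    return pd.DataFrame(
        {
            "variable_name": [e.variable_name for e in entries],
            "domain": [e.domain for e in entries],
            "level": [e.level for e in entries],
            "source": [e.source for e in entries],
        }
    )
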