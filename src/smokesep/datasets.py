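"""Small built-in reference tables.

``national_smoke_summary`` is a published yearly summary (2007-2018) of fire
smoke impact on the contiguous-U.S. population, stratified by regulatory
monitor coverage (residence within 5 km of a monitor).  It serves as the
worked example for :func:`smokesep.exposure.summarize_years`: averaging the
yearly rows reproduces the published average row for the columns that are
simple means.  Populations are millions of persons; day columns are mean
smoke impact days per person; concentrations are ug/m3.
"""

from __future__ import annotations

import pandas as pd

# year, total pop (M), pop w/o coverage (M), smoke-impacted pop (M),
# smoke-impacted pop w/o coverage (M), impact days covered, impact days
# uncovered, total PM covered, smoke PM covered, total PM uncovered,
# smoke PM uncovered
_YEARLY = [
    (2007, 300.1, 73.6, 299.7, 73.6, 38.2, 54.6, 11.90, 0.96, 9.87, 1.11),
    (2008, 302.6, 74.1, 298.3, 72.6, 21.2, 22.4, 10.42, 0.32, 8.26, 0.38),
    (2009, 305.5, 70.9, 300.3, 69.9, 13.5, 19.4, 11.20, 0.25, 8.45, 0.22),
    (2010, 307.0, 72.0, 285.7, 71.6, 12.8, 22.6, 10.83, 0.57, 9.73, 0.77),
    (2011, 310.0, 72.9, 307.9, 72.7, 16.4, 25.7, 11.43, 0.51, 9.14, 0.73),
    (2012, 299.9, 72.0, 289.0, 71.6, 11.9, 20.3, 10.35, 0.53, 9.28, 0.83),
    (2013, 313.1, 74.0, 308.0, 72.9, 16.7, 19.1, 11.57, 0.61, 9.34, 0.66),
    (2014, 317.3, 74.6, 310.8, 74.3, 16.9, 22.5, 9.40, 0.31, 8.74, 0.40),
    (2015, 319.8, 74.9, 313.2, 74.6, 14.4, 19.2, 9.37, 0.48, 7.91, 0.64),
    (2016, 321.5, 74.9, 319.7, 74.9, 17.6, 25.0, 9.30, 0.31, 7.98, 0.48),
    (2017, 324.1, 74.6, 321.6, 74.5, 26.2, 33.8, 11.22, 0.97, 8.78, 0.92),
    (2018, 325.6, 74.8, 308.9, 73.1, 20.2, 18.5, 10.51, 0.61, 8.95, 0.65),
]

# the published average row (not recomputed; two of its concentration cells
# are not simple means of the yearly values above)
PUBLISHED_AVERAGE = {
    "total_population": 312.2,
    "population_uncovered": 73.6,
    "smoke_impacted_population": 305.3,
    "smoke_impacted_population_uncovered": 73.0,
    "impact_days_covered": 18.8,
    "impact_days_uncovered": 25.2,
    "total_pm_covered": 10.79,
    "smoke_pm_covered": 0.50,
    "total_pm_uncovered": 8.87,
    "smoke_pm_uncovered": 0.65,
}

_COLUMNS = [
    "year", "total_population", "population_uncovered",
    "smoke_impacted_population", "smoke_impacted_population_uncovered",
    "impact_days_covered", "impact_days_uncovered",
    "total_pm_covered", "smoke_pm_covered",
    "total_pm_uncovered", "smoke_pm_uncovered",
]


def national_smoke_summary() -> pd.DataFrame:
    """Yearly national fire-smoke exposure summary, 2007-2018, one row per year."""
    return pd.DataFrame(_YEARLY, columns=_COLUMNS)
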