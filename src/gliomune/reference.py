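"""Reference demographics of the three-cohort study design.

Printed patient counts of the discovery cohort (n=210) and the two
radiogenomic cohorts (n=130 / n=55) that the synthetic generator mirrors.
The percentage helper reproduces the convention the summary tables use
(share of the full cohort, one decimal), so printed percentages can be
recomputed from the counts.
"""

from __future__ import annotations

__all__ = ["COHORT_SIZES", "DEMOGRAPHIC_COUNTS", "percent_of_cohort"]

COHORT_SIZES = {"discovery": 210, "rg1": 130, "rg2": 55}

#: characteristic -> cohort -> count of patients
DEMOGRAPHIC_COUNTS = {
    "male": {"discovery": 117, "rg1": 72},
    "female": {"discovery": 91, "rg1": 58},
    "grade_2": {"discovery": 48, "rg1": 29},
    "grade_3": {"discovery": 22, "rg1": 16},
    "grade_4": {"discovery": 140, "rg1": 85},
    "idh_mutant": {"discovery": 73, "rg1": 51},
    "radiation_therapy": {"discovery": 163, "rg1": 84},
    "chemotherapy": {"discovery": 157, "rg1": 103},
}


def percent_of_cohort(characteristic: str, cohort: str) -> float:
    """Percentage of the cohort with the characteristic, one decimal."""
    count = DEMOGRAPHIC_COUNTS[characteristic][cohort]
    return round(100.0 * count / COHORT_SIZES[cohort], 1)
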