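"""Published per-participant results from a seven-participant hemiparesis
study of simultaneous proportional myoelectric control.

These tables hold the reported best DOF combination per participant with
its intended (RMSE) and unintended (xRMSE) movement errors for the 2-, 3-
and 4-DOF analyses, plus the cohort demographics.  They serve as in-repo
reference data for the functional-control classification: applying the
inclusive 0.45/0.04 criteria reproduces the reported counts of 6, 4 and 2
functional participants (86%, 57%, 29%).
"""

from __future__ import annotations

import pandas as pd

from .metrics import FunctionalCriteria, classify_functional

__all__ = [
    "demographics",
    "best_combinations",
    "functional_counts",
    "functional_percentages",
]

_DEMOGRAPHICS = [
    # participant, age, sex, MAS, injury, years since injury
    (1, 32, "M", 2, "TBI", 10.8),
    (2, 54, "M", 2, "Ischemic Stroke", 6.3),
    (3, 44, "F", 1, "Hemorrhagic Stroke", 3.8),
    (4, 47, "M", 2, "Ischemic Stroke", 1.7),
    (5, 66, "M", 2, "Ischemic Stroke", 1.2),
    (6, 47, "M", 1, "Ischemic Stroke", 1.4),
    (7, 30, "M", 2, "TBI", 6.6),
]

_BEST = {
    2: [
        (1, "HC/WS", 0.36, 0.02),
        (2, "HC/WS", 0.33, 0.0),
        (3, "HC/WP", 0.24, 0.0),
        (4, "TC/WS", 0.33, 0.0),
        (5, "TC/WP", 0.34, 0.0),
        (6, "TC/WE", 0.31, 0.0),
        (7, "HC/WF", 0.48, 0.11),
    ],
    3: [
        (1, "HC/WF/WS", 0.55, 0.13),
        (2, "HC/WF/WS", 0.40, 0.0),
        (3, "HC/WE/WP", 0.39, 0.06),
        (4, "HC/WE/WP", 0.42, 0.0006),
        (5, "TC/WE/WS", 0.43, 0.01),
        (6, "HC/WE/WS", 0.37, 0.04),
        (7, "HC/WF/WS", 0.48, 0.09),
    ],
    4: [
        (1, "HC/TC/WE/WP", 0.55, 0.12),
        (2, "HC/TC/WE/WP", 0.32, 0.11),
        (3, "HC/TC/WF/WP", 0.35, 0.13),
        (4, "HC/TC/WE/WS", 0.42, 0.04),
        (5, "HC/TC/WE/WS", 0.43, 0.01),
        (6, "HC/TC/WE/WS", 0.39, 0.05),
        (7, "HC/TC/WF/WS", 0.63, 0.14),
    ],
}


def demographics() -> pd.DataFrame:
    """Cohort demographics (age, sex, spasticity score, injury, chronicity)."""
    return pd.DataFrame(
        _DEMOGRAPHICS,
        columns=["participant", "age", "sex", "mas", "injury", "years_since_injury"],
    )


def best_combinations(n_dofs: int) -> pd.DataFrame:
    """Reported best combination per participant for the 2/3/4-DOF analyses."""
    if n_dofs not in _BEST:
        raise ValueError(f"n_dofs must be one of {sorted(_BEST)}, got {n_dofs}")
    return pd.DataFrame(
        _BEST[n_dofs], columns=["participant", "combo", "intended", "unintended"]
    )


def functional_counts(
    criteria: FunctionalCriteria = FunctionalCriteria(),
) -> dict[int, int]:
    """Functional participants per DOF level under the inclusive criteria."""
    counts = {}
    for n_dofs in sorted(_BEST):
        df = best_combinations(n_dofs)
        counts[n_dofs] = sum(
            classify_functional(row.intended, row.unintended, criteria)
            for row in df.itertuples()
        )
    return counts


def functional_percentages(
    criteria: FunctionalCriteria = FunctionalCriteria(),
) -> dict[int, int]:
    """Functional percentages per DOF level, rounded to the nearest integer."""
    counts = functional_counts(criteria)
    n = len(_DEMOGRAPHICS)
    return {k: int(round(100.0 * v / n)) for k, v in counts.items()}
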