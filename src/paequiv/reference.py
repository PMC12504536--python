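"""Published UK Biobank equivalence medians, for context and arithmetic checks.

The restricted accelerometry cohort behind these figures is not available
here, so the numbers serve as documentation context — except for the
arithmetic identities among them, which the package reproduces exactly:
the LPA-per-MPA column is the VPA:LPA median divided by the VPA:MPA
median (2-dp rounding), and the cross-outcome medians over the four
non-cancer outcomes round to 6.6 (MPA) and 79.3 (LPA) at 1 dp.
"""

from __future__ import annotations

import pandas as pd

from .equivalence import cross_outcome_median, derive_secondary_ratio

#: Published median minutes equivalent to 1 min of VPA, per outcome:
#: (MPA per VPA, LPA per VPA, LPA per MPA as printed).
PUBLISHED_MEDIANS: dict[str, tuple[float, float, float]] = {
    "all_cause_mortality": (4.09, 52.65, 12.87),
    "cvd_mortality": (7.78, 72.47, 9.31),
    "mace": (5.44, 86.13, 15.83),
    "type2_diabetes": (9.40, 94.03, 10.00),
    "cancer_mortality": (3.47, 156.23, 45.02),
    "cancer_incidence": (1.63, 5.09, 3.12),
}

#: Outcomes pooled in the published cross-outcome medians (the four
#: non-cancer endpoints).
NON_CANCER_OUTCOMES = ("all_cause_mortality", "cvd_mortality", "mace", "type2_diabetes")


def published_table() -> pd.DataFrame:
    rows = [
        {"outcome": k, "mpa_per_vpa": m, "lpa_per_vpa": l, "lpa_per_mpa": s}
        for k, (m, l, s) in PUBLISHED_MEDIANS.items()
    ]
    return pd.DataFrame(rows)


def derived_secondary_ratios() -> dict[str, float]:
    """Recompute the LPA-per-MPA column from the two VPA-anchored columns."""
    return {
        outcome: derive_secondary_ratio(lpa, mpa)
        for outcome, (mpa, lpa, _) in PUBLISHED_MEDIANS.items()
    }


def cross_outcome_summaries() -> dict[str, float]:
    """Median MPA and LPA equivalence across the non-cancer outcomes."""
    mpa = cross_outcome_median([PUBLISHED_MEDIANS[o][0] for o in NON_CANCER_OUTCOMES])
    lpa = cross_outcome_median([PUBLISHED_MEDIANS[o][1] for o in NON_CANCER_OUTCOMES])
    return {"median_mpa_per_vpa": mpa, "median_lpa_per_vpa": lpa}
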