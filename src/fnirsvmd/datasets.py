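"""Small published reference tables shipped for demonstrations and checks.

These are subject-wise classification accuracies (percent) from a published
20-subject fNIRS visual-merchandising experiment — two-class (positive vs
negative display, best feature pair, one column per store category) and
four-class (four stores at one valence).  They exercise the reporting
utilities without re-running a cohort analysis; the synthetic generator is
the source of raw signals everywhere else.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "two_class_subject_accuracies",
    "four_class_subject_accuracies",
    "published_summary_inputs",
]


_TWO_CLASS = {
    "menswear": [75.00, 66.67, 66.67, 42.86, 50.00, 66.67, 50.00, 50.00, 57.14, 60.00,
                 83.33, 66.67, 75.00, 60.00, 83.33, 66.67, 71.43, 50.00, 75.00, 66.67],
    "womenswear": [54.03, 60.00, 50.00, 60.00, 80.00, 40.00, 50.00, 60.00, 50.00, 75.00,
                   66.67, 83.33, 83.33, 50.00, 83.33, 80.00, 66.67, 66.67, 75.00, 75.00],
    "underwear": [66.67, 83.33, 83.33, 66.67, 57.14, 60.00, 66.67, 80.00, 66.67, 83.33,
                  50.00, 75.00, 60.00, 66.67, 57.14, 50.00, 66.67, 75.00, 80.00, 66.67],
    "sportswear": [83.33, 66.67, 75.00, 55.00, 66.67, 83.33, 66.67, 66.67, 60.00, 60.00,
                   57.14, 75.00, 83.33, 57.14, 50.00, 42.74, 50.00, 75.00, 66.67, 60.00],
}

_FOUR_CLASS = {
    "positive": [51.90, 31.67, 51.00, 60.76, 42.38, 38.52, 60.00, 50.00, 54.00, 76.67,
                 40.00, 40.76, 65.95, 64.57, 48.33, 42.00, 46.10, 44.38, 45.57, 59.00],
    "negative": [48.33, 44.67, 51.24, 44.67, 31.33, 54.67, 55.00, 51.00, 62.38, 54.67,
                 66.95, 63.33, 54.67, 50.00, 48.14, 44.33, 42.74, 51.00, 59.55, 42.67],
}

#: Printed aggregate (mean, SD, n, chance %) pairs for the summary t-tests.
#: The two-class underwear mean is kept as printed (67.04) even though its
#: subject column above averages to 68.05; its printed SD does match.
_SUMMARY_INPUTS = {
    ("two-class", "menswear"): (64.15, 11.51, 20, 50.0),
    ("two-class", "womenswear"): (65.45, 13.54, 20, 50.0),
    ("two-class", "underwear"): (67.04, 10.55, 20, 50.0),
    ("two-class", "sportswear"): (65.54, 11.62, 20, 50.0),
    ("four-class", "positive"): (50.68, 11.08, 20, 25.0),
    ("four-class", "negative"): (51.07, 8.37, 20, 25.0),
}


def two_class_subject_accuracies() -> pd.DataFrame:
    """20 × 4 subject-wise two-class accuracies (%), one column per store."""
    return pd.DataFrame(_TWO_CLASS, index=pd.RangeIndex(1, 21, name="subject"))


def four_class_subject_accuracies() -> pd.DataFrame:
    """20 × 2 subject-wise four-class accuracies (%) per display valence."""
    return pd.DataFrame(_FOUR_CLASS, index=pd.RangeIndex(1, 21, name="subject"))


def published_summary_inputs() -> dict:
    """Printed (mean, sd, n, chance) per problem/category for t-vs-chance."""
    return dict(_SUMMARY_INPUTS)
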