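"""Summary statistics for classification accuracies.

Accuracies are aggregated as mean ± sample SD over subjects and tested
against the chance level (100/k % for k classes) with a one-sample t-test:
t = (mean − chance) / (SD/√n), referred to Student t with n − 1 degrees of
freedom.  Significance is marked * (p < 0.05) and ** (p < 0.01); display
rounding is 2 decimals for accuracies and 4 for t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "one_sample_t_from_summary",
    "aggregate_accuracies",
    "chance_level",
    "SummaryRow",
    "summary_table",
    "summary_markdown",
]


def one_sample_t_from_summary(
    mean: float,
    sd: float,
    n: int,
    chance: float,
    tail: Literal["two-sided", "one-sided"] = "two-sided",
) -> tuple[float, float]:
    """One-sample t-test against chance from summary statistics.

    Returns ``(t, p)`` with ``t = (mean − chance)/(sd/√n)`` and ``p`` from a
    Student t with n − 1 dof (two-sided by default).
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    t = (mean - chance) / (sd / math.sqrt(n))
    if tail == "two-sided":
        p = 2.0 * stats.t.sf(abs(t), n - 1)
    elif tail == "one-sided":
        p = float(stats.t.sf(t, n - 1))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float(t), float(p)


def aggregate_accuracies(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n − 1 denominator) of accuracies (%)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    return float(values.mean()), float(values.std(ddof=1))


def chance_level(n_classes: int) -> float:
    """Random-guessing accuracy in percent: 100/k (50% for 2, 25% for 4)."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    return 100.0 / n_classes


def _marks(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class SummaryRow:
    """One row of the accuracy-vs-chance summary table."""

    group: str
    category: str
    subjects: str
    mean: float
    sd: float
    n: int
    chance: float
    t: float
    p: float
    marks: str

    def __post_init__(self) -> None:
        expected = (self.mean - self.chance) / (self.sd / math.sqrt(self.n))
        if not math.isclose(self.t, expected, rel_tol=0, abs_tol=0):
            raise ValueError("t must equal (mean - chance)/(sd/sqrt(n)) exactly")


def summary_row(
    group: str,
    category: str,
    subjects: str,
    values: Sequence[float] | None = None,
    *,
    mean: float | None = None,
    sd: float | None = None,
    n: int | None = None,
    n_classes: int = 2,
    tail: Literal["two-sided", "one-sided"] = "two-sided",
) -> SummaryRow:
    """Build one summary row from raw accuracies or printed summary values."""
    if values is not None:
        mean, sd = aggregate_accuracies(values)
        n = len(values)
    if mean is None or sd is None or n is None:
        raise ValueError("give either raw values or (mean, sd, n)")
    chance = chance_level(n_classes)
    t, p = one_sample_t_from_summary(mean, sd, n, chance, tail)
    return SummaryRow(group, category, subjects, mean, sd, n, chance, t, p, _marks(p))


def summary_table(rows: Sequence[SummaryRow]) -> pd.DataFrame:
    """Tabulate summary rows with the reference display rounding."""
    return pd.DataFrame(
        [
            {
                "Class": r.group,
                "Category": r.category,
                "Subject": r.subjects,
                "Accuracy(mean ± SD)": f"{r.mean:.2f} ± {r.sd:.2f}",
                "t-value": round(r.t, 4),
                "p-value": f"{r.p:.4f}{r.marks}" if r.p >= 0.005 else f"0.00{r.marks}",
            }
            for r in rows
        ]
    )


def summary_markdown(rows: Sequence[SummaryRow]) -> str:
    """Markdown rendering of the summary table (pure: same rows → same text)."""
    df = summary_table(rows)
    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    lines = [header, sep]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"
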