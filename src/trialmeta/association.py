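"""Odds ratios for class membership versus reporting behaviour.

For a binary class-membership indicator Y and a binary reporting indicator
X (results deposited, or at least one outcome listed), the association is
summarised by the cross-product odds ratio of the 2×2 joint distribution,

    OR = (p11 * p00) / (p10 * p01),

identical whether computed from joint probabilities or raw counts. The
confidence interval is the log-odds (Woolf) interval: log OR ± q * SE with
SE = sqrt(1/n11 + 1/n10 + 1/n01 + 1/n00); the quantile q is by default a
two-sided Student-t quantile with n − 1 degrees of freedom, switchable to
the standard normal. Collaborations are excluded from class comparisons by
default because that class overlaps the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from scipy import stats

from .filters import RequirementFlags
from .records import SponsorClass, TrialRecord

__all__ = [
    "ContingencyTable2x2",
    "ORResult",
    "build_table",
    "odds_ratio",
    "odds_ratio_ci",
    "class_or_report",
    "OR_REPORT_CLASSES",
]

#: Classes compared in the standard report (collaborations omitted).
OR_REPORT_CLASSES = (
    SponsorClass.COM,
    SponsorClass.GOV,
    SponsorClass.HOS,
    SponsorClass.EDU,
)

DEFAULT_EXCLUDE = frozenset({SponsorClass.COL, SponsorClass.UNCLASSIFIED})


class DegenerateTableError(ValueError):
    """A margin or cell prevents a finite odds ratio."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Joint counts of (Y, X); ``n11`` is Y=1, X=1 ... ``n00`` is Y=0, X=0."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def joint_probabilities(self) -> dict[str, float]:
        """Empirical joint distribution p_yx = n_yx / n."""
        n = self.n
        return {
            "p11": self.n11 / n,
            "p10": self.n10 / n,
            "p01": self.n01 / n,
            "p00": self.n00 / n,
        }

    def rowswap(self) -> "ContingencyTable2x2":
        """Swap Y=1 and Y=0 rows (inverts the odds ratio)."""
        return ContingencyTable2x2(self.n01, self.n00, self.n11, self.n10)

    def transpose(self) -> "ContingencyTable2x2":
        """Swap the roles of X and Y (leaves the odds ratio unchanged)."""
        return ContingencyTable2x2(self.n11, self.n01, self.n10, self.n00)

    def corrected(self, amount: float = 0.5) -> "_CorrectedTable":
        """Haldane–Anscombe correction: add ``amount`` to every cell."""
        return _CorrectedTable(
            self.n11 + amount, self.n10 + amount, self.n01 + amount, self.n00 + amount, self.n
        )


@dataclass(frozen=True)
class _CorrectedTable:
    """Continuity-corrected cells; keeps the uncorrected n for the t quantile."""

    n11: float
    n10: float
    n01: float
    n00: float
    n_uncorrected: int


@dataclass(frozen=True)
class ORResult:
    """Odds-ratio point estimate with a confidence interval."""

    or_value: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "woolf-t"

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.or_value <= self.ci_high):
            raise ValueError("interval must bracket a positive odds ratio")

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def _check_cells(table, correction: str) -> tuple:
    if correction == "haldane":
        c = table.corrected() if isinstance(table, ContingencyTable2x2) else table
        return c.n11, c.n10, c.n01, c.n00
    if min(table.n11, table.n10, table.n01, table.n00) == 0:
        raise DegenerateTableError(
            "zero cell: odds ratio undefined without a continuity correction"
        )
    return table.n11, table.n10, table.n01, table.n00


def odds_ratio(
    table: ContingencyTable2x2, correction: Literal["none", "haldane"] = "none"
) -> float:
    """Cross-product odds ratio (n11·n00)/(n10·n01).

    Raises :class:`DegenerateTableError` on a zero cell unless the
    Haldane–Anscombe +0.5 correction is requested; never returns infinity.
    """
    n11, n10, n01, n00 = _check_cells(table, correction)
    return (n11 * n00) / (n10 * n01)


def odds_ratio_ci(
    table: ContingencyTable2x2,
    level: float = 0.95,
    method: Literal["t", "normal"] = "t",
    correction: Literal["none", "haldane"] = "none",
) -> ORResult:
    """Log-odds (Woolf) confidence interval around the odds ratio.

    ``method="t"`` (default) uses a two-sided Student-t quantile with
    n − 1 degrees of freedom; ``"normal"`` uses the standard-normal
    quantile. Both converge for large tables.
    """
    n11, n10, n01, n00 = _check_cells(table, correction)
    or_value = (n11 * n00) / (n10 * n01)
    se = math.sqrt(1 / n11 + 1 / n10 + 1 / n01 + 1 / n00)
    alpha = 1 - level
    if method == "t":
        q = stats.t.ppf(1 - alpha / 2, df=table.n - 1)
        label = "woolf-t"
    elif method == "normal":
        q = stats.norm.ppf(1 - alpha / 2)
        label = "woolf-normal"
    else:
        raise ValueError(f"unknown CI method {method!r}")
    log_or = math.log(or_value)
    ci_low = math.exp(log_or - q * se)
    ci_high = math.exp(log_or + q * se)
    if correction == "haldane":
        label += "+haldane"
    return ORResult(or_value, ci_low, ci_high, level=level, method=label)


def build_table(
    corpus: Iterable[TrialRecord],
    assignments: Mapping[str, SponsorClass],
    target_class: SponsorClass,
    indicator: Literal["results", "outcome"] = "results",
    restrained: bool = False,
    flags: Mapping[str, RequirementFlags] | None = None,
    exclude: frozenset[SponsorClass] = DEFAULT_EXCLUDE,
) -> ContingencyTable2x2:
    """Count the 2×2 table of target-class membership against reporting.

    Y = 1 for trials of ``target_class``; X = 1 when the indicator holds
    (results deposited, or at least one outcome listed). Trials of excluded
    classes leave both margins. ``restrained=True`` keeps only trials
    meeting every deposition requirement (``flags`` then required).
    """
    if restrained and flags is None:
        raise ValueError("restrained table requires requirement flags")
    n11 = n10 = n01 = n00 = 0
    pool = 0
    for record in corpus:
        cls = assignments[record.nct_id]
        if cls in exclude:
            continue
        if restrained and not flags[record.nct_id].all_requirements:
            continue
        pool += 1
        y = cls == target_class
        if indicator == "results":
            x = record.has_results
        elif indicator == "outcome":
            x = record.n_outcomes >= 1
        else:
            raise ValueError(f"unknown indicator {indicator!r}")
        if y and x:
            n11 += 1
        elif y:
            n10 += 1
        elif x:
            n01 += 1
        else:
            n00 += 1
    if restrained and pool == 0:
        raise DegenerateTableError("empty restrained pool")
    table = ContingencyTable2x2(n11, n10, n01, n00)
    if n11 + n10 == 0 or n01 + n00 == 0:
        raise DegenerateTableError(
            f"zero class margin for target {target_class.value}"
        )
    if n11 + n01 == 0 or n10 + n00 == 0:
        raise DegenerateTableError("zero indicator margin")
    return table


def class_or_report(
    corpus: Iterable[TrialRecord],
    assignments: Mapping[str, SponsorClass],
    flags: Mapping[str, RequirementFlags] | None = None,
    restrained: bool = False,
    classes: Sequence[SponsorClass] = OR_REPORT_CLASSES,
    indicators: Sequence[str] = ("results", "outcome"),
    level: float = 0.95,
    method: Literal["t", "normal"] = "t",
    correction: Literal["none", "haldane"] = "none",
    exclude: frozenset[SponsorClass] = DEFAULT_EXCLUDE,
) -> pd.DataFrame:
    """Odds ratios with confidence intervals per class × indicator.

    One row per investigated class and indicator, mirroring the
    class-versus-rest comparison: each class in turn is Y=1 against all
    non-excluded others.
    """
    corpus = list(corpus)
    rows = []
    for cls in classes:
        for indicator in indicators:
            table = build_table(
                corpus,
                assignments,
                cls,
                indicator=indicator,
                restrained=restrained,
                flags=flags,
                exclude=exclude,
            )
            result = odds_ratio_ci(table, level=level, method=method, correction=correction)
            rows.append(
                {
                    "class": cls.value,
                    "indicator": indicator,
                    "odds_ratio": result.or_value,
                    "ci_low": result.ci_low,
                    "ci_high": result.ci_high,
                    "level": result.level,
                    "method": result.method,
                    "n": table.n,
                }
            )
    return pd.DataFrame(rows)
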