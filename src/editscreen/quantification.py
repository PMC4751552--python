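"""Editing-level computation and factor-effect testing.

The editing level is the edited-allele fraction in RNA, standardized by
the allele fraction measured on genomic DNA from the same assay (a
per-assay correction factor that is 1 for a clean homozygous DNA
signal), clamped into [0, 1]. Group effects are tested with the
classical two-sided unpaired homoscedastic (pooled-variance) t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .errors import UsageError
from .pileup import AlleleCounts

logger = logging.getLogger(__name__)

MIN_P_VALUE = 1e-300  # underflow-safe floor when pooled variance is zero

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True, slots=True)
class EditingLevelMeasurement:
    """Raw edited/total signals for one sample at one site."""

    sample: str
    site: str
    rna_edited_signal: float
    rna_total_signal: float
    dna_allele_signal: float
    dna_total_signal: float

    def __post_init__(self) -> None:
        for name in (
            "rna_edited_signal",
            "rna_total_signal",
            "dna_allele_signal",
            "dna_total_signal",
        ):
            if getattr(self, name) < 0:
                raise UsageError(f"{name} must be non-negative")


@dataclass(frozen=True, slots=True)
class GroupComparison:
    """Pooled two-sample t-test result with Fig-7-style significance stars."""

    group_a: tuple[float, ...]
    group_b: tuple[float, ...]
    t_statistic: float
    df: int
    p_value: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p_value: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p_value < threshold:
            return stars
    return ""


def editing_fraction(rna_counts: AlleleCounts, edited_allele: str) -> float:
    """Edited-read count over total depth at the site."""
    depth = rna_counts.depth
    if depth == 0:
        raise UsageError("editing_fraction on an empty column")
    return rna_counts.count(edited_allele) / depth


def standardize_level(measurement: EditingLevelMeasurement) -> float:
    """DNA-standardized editing level, clamped into [0, 1].

    level = (rna_edited / rna_total) / (dna_allele / dna_total); the DNA
    term corrects assay-specific amplification bias and equals 1 for a
    perfectly homozygous DNA signal.
    """
    if measurement.rna_total_signal <= 0 or measurement.dna_total_signal <= 0:
        raise UsageError("total signals must be positive")
    if measurement.dna_allele_signal <= 0:
        raise UsageError("DNA allele signal must be positive")
    rna_frac = measurement.rna_edited_signal / measurement.rna_total_signal
    dna_frac = measurement.dna_allele_signal / measurement.dna_total_signal
    level = rna_frac / dna_frac
    if level > 1.0:
        logger.warning(
            "editing level %.4f for %s at %s clamped to 1.0",
            level,
            measurement.sample,
            measurement.site,
        )
        return 1.0
    return level


def pooled_t_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> GroupComparison:
    """Two-sided unpaired homoscedastic Student t-test.

    df = n_a + n_b - 2; the two-sided p comes from the t distribution.
    With zero pooled variance the result degenerates to t=0, p=1 for
    equal means and an underflow-safe minimum p otherwise.
    """
    a = [float(x) for x in group_a]
    b = [float(x) for x in group_b]
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise UsageError("each group needs at least two observations")
    mean_a = sum(a) / n_a
    mean_b = sum(b) / n_b
    ss_a = sum((x - mean_a) ** 2 for x in a)
    ss_b = sum((x - mean_b) ** 2 for x in b)
    df = n_a + n_b - 2
    pooled_var = (ss_a + ss_b) / df
    if pooled_var == 0.0:
        if mean_a == mean_b:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = math.inf if mean_a > mean_b else -math.inf
            p = MIN_P_VALUE
    else:
        se = math.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
        t_stat = (mean_a - mean_b) / se
        p = 2.0 * stats.t.sf(abs(t_stat), df)
        p = max(min(p, 1.0), MIN_P_VALUE)
    return GroupComparison(
        group_a=tuple(a),
        group_b=tuple(b),
        t_statistic=t_stat,
        df=df,
        p_value=p,
    )


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> GroupComparison:
    """Welch's unequal-variance alternative (optional, non-default)."""
    a = [float(x) for x in group_a]
    b = [float(x) for x in group_b]
    if len(a) < 2 or len(b) < 2:
        raise UsageError("each group needs at least two observations")
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        group_a=tuple(a),
        group_b=tuple(b),
        t_statistic=float(res.statistic),
        df=len(a) + len(b) - 2,  # reported df stays the pooled convention
        p_value=float(res.pvalue),
    )


def compare_factor_groups(
    level_table: Iterable[Mapping[str, object]],
    factor: str,
    *,
    welch: bool = False,
) -> list[dict[str, object]]:
    """One pooled t-test per (site, tissue) between the two factor levels.

    ``level_table`` rows need keys: site, tissue, ``factor`` (two
    distinct values) and level. Returns one result row per (site,
    tissue) with the test and Fig-7-style stars.
    """
    grouped: dict[tuple[str, str], dict[str, list[float]]] = {}
    for row in level_table:
        key = (str(row["site"]), str(row["tissue"]))
        grouped.setdefault(key, {}).setdefault(str(row[factor]), []).append(
            float(row["level"])  # type: ignore[arg-type]
        )
    results = []
    test = welch_t_test if welch else pooled_t_test
    for (site, tissue), levels_by_group in sorted(grouped.items()):
        if len(levels_by_group) != 2:
            raise UsageError(
                f"factor {factor!r} must have exactly two levels for "
                f"site {site}/{tissue}, got {sorted(levels_by_group)}"
            )
        (name_a, a), (name_b, b) = sorted(levels_by_group.items())
        comparison = test(a, b)
        results.append(
            {
                "site": site,
                "tissue": tissue,
                "factor": factor,
                "group_a": name_a,
                "group_b": name_b,
                "n_a": len(a),
                "n_b": len(b),
                "t_statistic": comparison.t_statistic,
                "df": comparison.df,
                "p_value": comparison.p_value,
                "stars": comparison.stars,
            }
        )
    return results
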