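"""Per-metabolite univariate chemometrics over storage days.

Two analyses mirror standard postharvest-metabolomics reporting:

* :func:`anova_tukey` — one-way fixed-effects ANOVA of intensity across
  storage-day groups, followed by Tukey's HSD on all day pairs using the
  studentized-range distribution with N-k error degrees of freedom
  (the Tukey-Kramer form when replicate counts differ).
* :func:`volcano` — two-group comparison of an early vs a late storage
  day: log2 fold change of raw group means (early over late, so a
  metabolite depleted late in storage carries a *positive* log2 FC) and
  a two-sided Wilcoxon rank-sum p-value, exact for small untied groups
  and normal-approximated with tie correction otherwise.  A metabolite
  is flagged significant when p < p_thresh and |log2 FC| >= the log2
  fold-change threshold.

No multiplicity correction is applied across metabolites in either
analysis: p-values are reported raw, per-metabolite, matching how such
tables are conventionally printed.  Tukey adjustment applies only within
a metabolite, across its day pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import IntensityMatrix
from .errors import DegenerateDataError

logger = logging.getLogger(__name__)

UP_LATE = "up_late"
DOWN_LATE = "down_late"
NONE = "none"

#: largest per-group n for which the rank-sum test uses the exact
#: distribution (ties force the tie-corrected normal approximation)
EXACT_WILCOXON_MAX_N = 12


@dataclass(frozen=True)
class TukeyPair:
    day_a: int
    day_b: int
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class UnivariateResult:
    metabolite: str
    f_stat: float
    p_value: float
    tukey_pairs: tuple[TukeyPair, ...]
    degenerate: bool = False

    def significant_pairs(self) -> list[TukeyPair]:
        return [p for p in self.tukey_pairs if p.significant]


@dataclass(frozen=True)
class VolcanoRecord:
    metabolite: str
    log2_fc: float
    p_value: float
    significant: bool
    direction: str


def anova_tukey(
    matrix: IntensityMatrix, tissue: str, alpha: float = 0.05
) -> list[UnivariateResult]:
    """One-way ANOVA + Tukey HSD per metabolite; sorted by p ascending.

    Metabolites with zero variance everywhere (all groups constant and
    equal) get F = 0, p = 1 and a degenerate-data flag instead of a NaN.
    """
    groups_by_day = matrix.day_groups(tissue)
    days = sorted(groups_by_day)
    if len(days) < 2:
        raise DegenerateDataError("ANOVA needs >= 2 day groups")
    sizes = {d: len(groups_by_day[d]) for d in days}
    if min(sizes.values()) < 2:
        raise DegenerateDataError("ANOVA needs >= 2 replicates per day")
    if len(set(sizes.values())) > 1:
        logger.info("unequal replicate counts %s: using Tukey-Kramer form", sizes)

    results = []
    for metabolite in matrix.metabolites:
        samples = [groups_by_day[d][metabolite].to_numpy(dtype=float) for d in days]
        flat = np.concatenate(samples)
        if np.ptp(flat) == 0:
            pairs = tuple(
                TukeyPair(b, a, 1.0, False)
                for i, a in enumerate(days)
                for b in days[i + 1 :]
            )
            results.append(UnivariateResult(metabolite, 0.0, 1.0, pairs, degenerate=True))
            continue
        f_stat, p_value = stats.f_oneway(*samples)
        hsd = stats.tukey_hsd(*samples)
        pairs = []
        for i, day_a in enumerate(days):
            for j in range(i + 1, len(days)):
                day_b = days[j]
                p_adj = float(np.clip(hsd.pvalue[i, j], 0.0, 1.0))
                # reported later-day-first to match conventional tables
                pairs.append(TukeyPair(day_b, day_a, p_adj, p_adj < alpha))
        results.append(
            UnivariateResult(metabolite, float(f_stat), float(p_value), tuple(pairs))
        )
    return sorted(results, key=lambda r: r.p_value)


def anova_table(results: list[UnivariateResult]) -> pd.DataFrame:
    """Flatten results to the conventional report layout."""
    rows = []
    for r in results:
        sig = ", ".join(
            f"Day {p.day_a} vs Day {p.day_b}" for p in r.significant_pairs()
        )
        rows.append(
            {
                "metabolite": r.metabolite,
                "p_value": r.p_value,
                "f_stat": r.f_stat,
                "significant_pairs": sig,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows)


def _rank_sum_p(early: np.ndarray, late: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact when both n <= 12 and untied."""
    combined = np.concatenate([early, late])
    has_ties = len(np.unique(combined)) < len(combined)
    small = len(early) <= EXACT_WILCOXON_MAX_N and len(late) <= EXACT_WILCOXON_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(early, late, alternative="two-sided", method=method).pvalue
    )


def volcano(
    matrix: IntensityMatrix,
    tissue: str,
    day_early: int,
    day_late: int,
    p_thresh: float = 0.05,
    fc_thresh_log2: float = 1.0,
) -> list[VolcanoRecord]:
    """Early-vs-late volcano records on raw intensities.

    log2_fc = log2(mean(early) / mean(late)); positive values mark
    metabolites reduced by the late day (direction ``down_late``).
    """
    groups = matrix.day_groups(tissue)
    for day in (day_early, day_late):
        if day not in groups:
            raise DegenerateDataError(f"day {day} absent for tissue {tissue!r}")
        if len(groups[day]) < 2:
            raise DegenerateDataError(f"day {day} has < 2 replicates")
    records = []
    for metabolite in matrix.metabolites:
        early = groups[day_early][metabolite].to_numpy(dtype=float)
        late = groups[day_late][metabolite].to_numpy(dtype=float)
        mean_late = late.mean()
        if mean_late <= 0 or early.mean() <= 0:
            raise ValueError(f"{metabolite}: non-positive group mean")
        log2_fc = float(np.log2(early.mean() / mean_late))
        if np.array_equal(np.sort(early), np.sort(late)):
            p_value = 1.0  # identical groups: no evidence by symmetry
        else:
            p_value = _rank_sum_p(early, late)
        significant = p_value < p_thresh and abs(log2_fc) >= fc_thresh_log2
        if log2_fc > 0:
            direction = DOWN_LATE
        elif log2_fc < 0:
            direction = UP_LATE
        else:
            direction = NONE
        records.append(VolcanoRecord(metabolite, log2_fc, p_value, significant, direction))
    return records


def volcano_table(records: list[VolcanoRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite": r.metabolite,
                "log2_fc": r.log2_fc,
                "p_value": r.p_value,
                "significant": r.significant,
                "direction": r.direction,
            }
            for r in records
        ]
    )


def write_results(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)
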