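"""RANO-LGG best-overall-response classification and exact ORR inference.

Postoperative tumor burden is tracked as the sum of products of perpendicular
lesion diameters (SPD, cm²) on MRI every 56 (±2) days, relative to the
postoperative baseline scan.  Best overall response follows the low-grade
glioma RANO categories on percent SPD change from baseline:

    CR  — disappearance of all lesions (SPD 0), confirmed
    PR  — decrease ≤ −50%, confirmed
    mR  — minor response, decrease ≤ −25% and > −50%, confirmed
    PD  — increase ≥ +25% relative to the nadir (smallest SPD so far,
          baseline included)
    SD  — anything else, including qualifying decreases never confirmed at
          the next scheduled scan

Subjects resected without residual disease are scored SD unless progression
(new measurable disease) occurs.  The objective response rate counts CR, PR
and mR, with an exact (Clopper–Pearson) binomial confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from scipy import stats

__all__ = [
    "ResponseCategory",
    "LesionSeries",
    "BestResponse",
    "OrrResult",
    "best_percent_change",
    "classify_best_response",
    "clopper_pearson",
    "orr",
    "NotEvaluable",
]

# response thresholds, % change from baseline (PD relative to nadir)
PR_THRESHOLD = -50.0
MR_THRESHOLD = -25.0
PD_THRESHOLD = 25.0


class ResponseCategory(str, Enum):
    CR = "CR"
    PR = "PR"
    mR = "mR"
    SD = "SD"
    PD = "PD"
    NE = "NE"


_RESPONDERS = (ResponseCategory.CR, ResponseCategory.PR, ResponseCategory.mR)


class NotEvaluable(ValueError):
    """Raised when a percent change is requested for a non-evaluable series."""


@dataclass(frozen=True)
class LesionSeries:
    """Ordered postoperative SPD series for one subject.

    ``baseline_spd`` of ``None`` means no residual disease after resection.
    Days must be strictly increasing; the baseline precedes all visits.
    """

    subject_id: str
    baseline_spd: float | None
    days: tuple[int, ...]
    spd: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.baseline_spd is not None and self.baseline_spd <= 0:
            raise ValueError("baseline_spd must be positive when present")
        if len(self.days) != len(self.spd):
            raise ValueError("days and spd lengths differ")
        if any(b >= a for a, b in zip(self.days[1:], self.days)):
            raise ValueError("days must be strictly increasing")
        if any(v < 0 for v in self.spd):
            raise ValueError("SPD must be nonnegative")

    @property
    def no_residual_disease(self) -> bool:
        return self.baseline_spd is None


@dataclass(frozen=True)
class BestResponse:
    subject_id: str
    category: ResponseCategory
    best_percent_change: float | None  # absent for no-residual-disease without PD


@dataclass(frozen=True)
class OrrResult:
    responders: int
    n: int
    orr: float      # %
    ci: tuple[float, float]  # %
    level: float


def best_percent_change(series: LesionSeries) -> float:
    """Best (most negative) percent change in SPD from the postoperative baseline."""
    if series.no_residual_disease:
        raise NotEvaluable(f"{series.subject_id}: no residual disease at baseline")
    if not series.spd:
        raise NotEvaluable(f"{series.subject_id}: no post-baseline visits")
    base = series.baseline_spd
    return min(100.0 * (v - base) / base for v in series.spd)


def _percent_changes(series: LesionSeries) -> list[float]:
    base = series.baseline_spd
    return [100.0 * (v - base) / base for v in series.spd]


def _category_of_decrease(change: float, spd: float) -> ResponseCategory | None:
    if spd == 0.0:
        return ResponseCategory.CR
    if change <= PR_THRESHOLD:
        return ResponseCategory.PR
    if change <= MR_THRESHOLD:
        return ResponseCategory.mR
    return None


def classify_best_response(series: LesionSeries) -> BestResponse:
    """Best overall response for one subject under the rules in the module docstring.

    A qualifying decrease (CR/PR/mR) counts only when the *next* scheduled scan
    sustains at least that category (confirmation); an unconfirmed qualifying
    decrease is SD.  The classification is invariant to rescaling the SPD unit.
    """
    if series.no_residual_disease:
        # progression = appearance of new measurable disease
        progressed = any(v > 0 for v in series.spd)
        cat = ResponseCategory.PD if progressed else ResponseCategory.SD
        return BestResponse(series.subject_id, cat, None)
    if not series.spd:
        return BestResponse(series.subject_id, ResponseCategory.NE, None)

    changes = _percent_changes(series)
    best_change = min(changes)
    rank = {ResponseCategory.CR: 5, ResponseCategory.PR: 4, ResponseCategory.mR: 3,
            ResponseCategory.SD: 2, ResponseCategory.PD: 1}

    # per-visit category: PD vs the running nadir beats everything else at
    # that visit; a qualifying decrease needs the next scan to sustain at
    # least the same category, otherwise the visit scores SD
    nadir = series.baseline_spd
    per_visit: list[ResponseCategory] = []
    for i, (chg, spd) in enumerate(zip(changes, series.spd)):
        if nadir > 0 and 100.0 * (spd - nadir) / nadir >= PD_THRESHOLD:
            per_visit.append(ResponseCategory.PD)
        else:
            cat = _category_of_decrease(chg, spd)
            if cat is not None and i + 1 < len(series.spd):
                nxt = _category_of_decrease(changes[i + 1], series.spd[i + 1])
                confirmed = nxt is not None and rank[nxt] >= rank[cat]
            else:
                confirmed = False
            per_visit.append(cat if cat is not None and confirmed
                             else ResponseCategory.SD)
        nadir = min(nadir, spd)

    best = max(per_visit, key=rank.__getitem__)
    return BestResponse(series.subject_id, best, best_change)


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial interval in percent, via Beta quantiles.

    lower = Beta(α/2; x, n−x+1) quantile (0 at x=0);
    upper = Beta(1−α/2; x+1, n−x) quantile (100 at x=n).
    """
    if not (0 <= x <= n) or n < 1:
        raise ValueError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return 100.0 * lower, 100.0 * upper


def _round_half_up(value: float, ndigits: int = 1) -> float:
    factor = 10.0**ndigits
    return math.floor(value * factor + 0.5) / factor


def orr(responses: Sequence[BestResponse], level: float = 0.95) -> OrrResult:
    """Objective response rate: responders are CR, PR or mR; exact binomial CI.

    Percentages round half-up to one decimal, matching clinical reporting.
    """
    if not responses:
        raise ValueError("response list must be nonempty")
    n = len(responses)
    x = sum(1 for r in responses if r.category in _RESPONDERS)
    lower, upper = clopper_pearson(x, n, level)
    return OrrResult(
        responders=x,
        n=n,
        orr=_round_half_up(100.0 * x / n),
        ci=(_round_half_up(lower), _round_half_up(upper)),
        level=level,
    )
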