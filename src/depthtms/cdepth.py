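"""C-DEPTH: a clinical differential predictor between two Deep TMS targets.

The score is the mean of baseline HDRS-21 item scores, each normalized by its
item maximum, over a mood-and-anxiety item cluster; it lies in [0, 1].  The
cluster is refined by greedy leave-one-feature-out (LOFO) elimination, a
decision threshold is selected on a grid, and the resulting above/below
subgroups are characterized by 2x2 contingency statistics (Pearson chi-square
without continuity correction, odds ratios with a Haldane-Anscombe fallback).
An external cohort can be scored against a fixed cluster and threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .datamodel import (
    ARMS,
    ClusterDefinition,
    HDRSVisitRecord,
    PatientOutcome,
    ValidationError,
)

__all__ = [
    "CDepthScore",
    "compute_cdepth",
    "compute_cdepth_scores",
    "correlate_score_outcome",
    "chi_square_2x2",
    "OddsRatioResult",
    "odds_ratio",
    "ContingencyTable2x2",
    "SideAnalysis",
    "SubgroupAnalysis",
    "subgroup_analysis",
    "threshold_search",
    "lofo_optimize",
    "LofoStep",
    "validate_external",
    "ValidationReport",
]


@dataclass(frozen=True)
class CDepthScore:
    patient_id: str
    score: float
    cluster_items: tuple[int, ...]


def compute_cdepth(record: HDRSVisitRecord, cluster: ClusterDefinition) -> CDepthScore:
    """Mean of the cluster items' scores normalized by their item maxima.

    With s_i the item score and m_i the item maximum, the score is
    (1/|C|) * sum_{i in C} s_i / m_i, which lies in [0, 1].
    """
    if not cluster.items:
        raise ValidationError("cluster has no items")
    normalized = []
    for i in cluster.items:
        if not 1 <= i <= len(record.items):
            raise ValidationError(f"cluster item {i} missing from record")
        normalized.append(record.item(i) / cluster.maxima[i])
    return CDepthScore(
        patient_id=record.patient_id,
        score=float(np.mean(normalized)),
        cluster_items=cluster.items,
    )


def compute_cdepth_scores(
    records: Iterable[HDRSVisitRecord],
    cluster: ClusterDefinition,
    visit: str = "BL",
) -> dict[str, float]:
    """Score every patient's ``visit`` record; returns patient_id -> score."""
    scores: dict[str, float] = {}
    for rec in records:
        if rec.visit == visit:
            scores[rec.patient_id] = compute_cdepth(rec, cluster).score
    return scores


def correlate_score_outcome(
    scores: Mapping[str, float],
    outcomes: Sequence[PatientOutcome],
    arm: Optional[str] = None,
) -> tuple[float, float, int]:
    """Pearson correlation of C-DEPTH with percent improvement.

    Returns (r, two-sided p, n).  ``arm`` restricts to one coil group.
    """
    xs, ys = [], []
    for out in outcomes:
        if arm is not None and out.arm != arm:
            continue
        if out.patient_id in scores:
            xs.append(scores[out.patient_id])
            ys.append(out.percent_improvement)
    n = len(xs)
    if n < 4:
        raise ValidationError(f"need at least 4 paired observations, got {n}")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in scores or outcomes")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


# ---------------------------------------------------------------------------
# contingency statistics
# ---------------------------------------------------------------------------

def chi_square_2x2(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-square for a 2x2 table, without Yates correction.

    chi2 = N (ad - bc)^2 / (r1 r2 c1 c2); p from the chi-square(1) tail.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("expected a nonnegative 2x2 table")
    (a, b), (c, d) = t
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = t.sum()
    if min(r1, r2, c1, c2) == 0:
        raise ValidationError("zero marginal row or column")
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), 1, p


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane-Anscombe +0.5 applied
    defined: bool = True


def odds_ratio(table: Sequence[Sequence[float]]) -> OddsRatioResult:
    """Cross-product odds ratio with a Wald log-scale 95% CI.

    Any zero cell triggers the Haldane-Anscombe correction (+0.5 to all
    cells, flagged).  A row or column that is entirely zero leaves the ratio
    undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("expected a nonnegative 2x2 table")
    (a, b), (c, d) = t
    undefined = (a == 0 and b == 0) or (c == 0 and d == 0) \
        or (a == 0 and c == 0) or (b == 0 and d == 0)
    if undefined:
        return OddsRatioResult(math.nan, math.nan, math.nan, False, defined=False)
    corrected = 0.0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    return OddsRatioResult(
        odds_ratio=float(oratio),
        ci_low=float(math.exp(math.log(oratio) - z * se)),
        ci_high=float(math.exp(math.log(oratio) + z * se)),
        corrected=corrected,
    )


@dataclass
class ContingencyTable2x2:
    """Rows are arms (H1, H7); columns are (event, no event)."""

    counts: tuple[tuple[int, int], tuple[int, int]]
    arms: tuple[str, str] = ARMS

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)


@dataclass
class SideAnalysis:
    """Statistics for one side of the threshold (above or below)."""

    side: str
    n: int
    arm_n: dict[str, int]
    response_table: ContingencyTable2x2
    remission_table: ContingencyTable2x2
    response_rates: dict[str, float]
    remission_rates: dict[str, float]
    response_chi2: float
    response_p: float
    remission_chi2: float
    remission_p: float
    response_or: OddsRatioResult
    or_favors: str  # arm in the numerator odds
    defined: bool = True  # False when only one arm is present on this side


@dataclass
class SubgroupAnalysis:
    threshold: float
    above: SideAnalysis
    below: SideAnalysis

    @property
    def n(self) -> int:
        return self.above.n + self.below.n


def _build_table(events: Mapping[str, int], totals: Mapping[str, int]) -> ContingencyTable2x2:
    return ContingencyTable2x2(counts=(
        (events["H1"], totals["H1"] - events["H1"]),
        (events["H7"], totals["H7"] - events["H7"]),
    ))


def _analyze_side(side: str, members: Sequence[PatientOutcome]) -> SideAnalysis:
    totals = {arm: sum(1 for o in members if o.arm == arm) for arm in ARMS}
    responses = {arm: sum(1 for o in members if o.arm == arm and o.response)
                 for arm in ARMS}
    remissions = {arm: sum(1 for o in members if o.arm == arm and o.remission)
                  for arm in ARMS}
    resp_table = _build_table(responses, totals)
    remi_table = _build_table(remissions, totals)
    rates = {arm: responses[arm] / totals[arm] if totals[arm] else math.nan
             for arm in ARMS}
    remrates = {arm: remissions[arm] / totals[arm] if totals[arm] else math.nan
                for arm in ARMS}
    defined = min(totals.values()) > 0
    if defined:
        try:
            chi2_r, _, p_r = chi_square_2x2(resp_table.counts)
        except ValidationError:
            chi2_r, p_r = math.nan, math.nan
        try:
            chi2_m, _, p_m = chi_square_2x2(remi_table.counts)
        except ValidationError:
            chi2_m, p_m = math.nan, math.nan
        # orient the odds ratio toward the arm with the higher response rate
        favors = "H1" if rates["H1"] >= rates["H7"] else "H7"
        arr = resp_table.as_array()
        oriented = arr if favors == "H1" else arr[::-1]
        orres = odds_ratio(oriented)
    else:
        chi2_r = p_r = chi2_m = p_m = math.nan
        favors = ""
        orres = OddsRatioResult(math.nan, math.nan, math.nan, False, defined=False)
    return SideAnalysis(
        side=side, n=len(members), arm_n=totals,
        response_table=resp_table, remission_table=remi_table,
        response_rates=rates, remission_rates=remrates,
        response_chi2=chi2_r, response_p=p_r,
        remission_chi2=chi2_m, remission_p=p_m,
        response_or=orres, or_favors=favors, defined=defined,
    )


def subgroup_analysis(
    scores: Mapping[str, float],
    outcomes: Sequence[PatientOutcome],
    threshold: float,
) -> SubgroupAnalysis:
    """Split patients at ``threshold`` and tabulate response/remission by arm.

    Patients with score > threshold fall on the "above" side; <= threshold on
    the "below" side (the threshold itself belongs to the low-score group).
    """
    scored = [o for o in outcomes if o.patient_id in scores]
    above = [o for o in scored if scores[o.patient_id] > threshold]
    below = [o for o in scored if scores[o.patient_id] <= threshold]
    if not above or not below:
        raise ValidationError("both sides of the threshold must be non-empty")
    return SubgroupAnalysis(
        threshold=threshold,
        above=_analyze_side("above", above),
        below=_analyze_side("below", below),
    )


def threshold_search(
    scores: Mapping[str, float],
    outcomes: Sequence[PatientOutcome],
    grid_step: float = 0.05,
    grid_range: tuple[float, float] = (0.1, 0.9),
    min_side_n: int = 15,
) -> tuple[float, SubgroupAnalysis]:
    """Select the threshold maximizing the weaker per-side response chi-square.

    The objective at each grid point is min(chi2_above, chi2_below) of the
    response tables, subject to both sides holding at least ``min_side_n``
    patients with both arms represented; ties break toward the grid midpoint.
    """
    for arm in ARMS:
        if sum(1 for o in outcomes if o.arm == arm and o.patient_id in scores) < 10:
            raise ValidationError(f"need at least 10 scored patients in arm {arm}")
    lo, hi = grid_range
    n_steps = int(round((hi - lo) / grid_step))
    grid = [lo + k * grid_step for k in range(n_steps + 1)]
    midpoint = (lo + hi) / 2

    best: tuple[float, float, SubgroupAnalysis] | None = None
    for tau in grid:
        try:
            analysis = subgroup_analysis(scores, outcomes, tau)
        except ValidationError:
            continue
        if analysis.above.n < min_side_n or analysis.below.n < min_side_n:
            continue
        if not (analysis.above.defined and analysis.below.defined):
            continue
        objective = min(analysis.above.response_chi2, analysis.below.response_chi2)
        if math.isnan(objective):
            continue
        if best is None:
            best = (objective, tau, analysis)
            continue
        better = objective > best[0] + 1e-12
        tie = abs(objective - best[0]) <= 1e-12
        if better or (tie and abs(tau - midpoint) < abs(best[1] - midpoint)):
            best = (objective, tau, analysis)
    if best is None:
        raise ValidationError(
            "no threshold satisfies the minimum subgroup-size constraint")
    return best[1], best[2]


# ---------------------------------------------------------------------------
# LOFO cluster optimization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LofoStep:
    removed_item: int
    objective_before: float
    objective_after: float
    cluster_after: tuple[int, ...]


def _lofo_objective(
    cluster: ClusterDefinition,
    records: Sequence[HDRSVisitRecord],
    outcomes: Sequence[PatientOutcome],
) -> float:
    """Differential-prediction objective: |r_H1 - r_H7|.

    Per-arm Pearson correlations of the cluster score with percent
    improvement; a larger gap means the score better separates which coil a
    patient benefits from.
    """
    scores = compute_cdepth_scores(records, cluster)
    r_h1, _, _ = correlate_score_outcome(scores, outcomes, arm="H1")
    r_h7, _, _ = correlate_score_outcome(scores, outcomes, arm="H7")
    return abs(r_h1 - r_h7)


def lofo_optimize(
    records: Sequence[HDRSVisitRecord],
    outcomes: Sequence[PatientOutcome],
    initial_cluster: ClusterDefinition,
    min_size: int = 4,
    min_improvement: float = 0.02,
) -> tuple[ClusterDefinition, list[LofoStep]]:
    """Greedy leave-one-feature-out elimination of cluster items.

    At each round every item's omission is scored with the differential
    objective; the removal yielding the largest improvement is committed.
    Stops when no single removal improves the objective by more than
    ``min_improvement`` or the cluster has shrunk to ``min_size`` items.
    The tolerance guards the stepwise loop against chasing sampling noise in
    the correlation gap (leave-out objectives are evaluated on nearly
    identical scores, so chance fluctuations of a few hundredths are
    common at trial-scale n).  Deterministic given the data (ties break
    toward the lowest item index).
    """
    if len(initial_cluster.items) <= min_size:
        return initial_cluster, []
    for arm in ARMS:
        if not any(o.arm == arm for o in outcomes):
            raise ValidationError(f"arm {arm} not represented in outcomes")

    cluster = initial_cluster
    trace: list[LofoStep] = []
    current = _lofo_objective(cluster, records, outcomes)
    while len(cluster.items) > min_size:
        best_item: Optional[int] = None
        best_value = -math.inf
        for item in cluster.items:
            candidate = cluster.drop(item)
            try:
                value = _lofo_objective(candidate, records, outcomes)
            except ValidationError:
                continue
            if value > best_value:
                best_item, best_value = item, value
        if best_item is None or best_value <= current + min_improvement:
            break
        cluster = cluster.drop(best_item)
        trace.append(LofoStep(
            removed_item=best_item,
            objective_before=current,
            objective_after=best_value,
            cluster_after=cluster.items,
        ))
        current = best_value
    return cluster, trace


# ---------------------------------------------------------------------------
# external validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    threshold: float
    n_above: int
    n_below: int
    response_rate_above: float
    response_rate_below: float
    remission_rate_above: float
    remission_rate_below: float
    response_chi2: float
    response_p: float
    chi2_defined: bool
    population_rate: Optional[float]
    above_minus_population: Optional[float]
    below_minus_population: Optional[float]


def validate_external(
    records: Sequence[HDRSVisitRecord],
    outcomes: Sequence[PatientOutcome],
    cluster: ClusterDefinition,
    threshold: float,
    population_rate: Optional[float] = None,
) -> ValidationReport:
    """Score an external single-arm cohort and compare across the threshold.

    Builds the above/below response 2x2 table over threshold sides (not arms)
    and, when supplied, contrasts each side's response rate against a
    population-average rate.
    """
    scores = compute_cdepth_scores(records, cluster)
    scored = [o for o in outcomes if o.patient_id in scores]
    if not scored:
        raise ValidationError("no external patients could be scored")
    above = [o for o in scored if scores[o.patient_id] > threshold]
    below = [o for o in scored if scores[o.patient_id] <= threshold]

    def rate(group: Sequence[PatientOutcome], attr: str) -> float:
        return (sum(1 for o in group if getattr(o, attr)) / len(group)
                if group else math.nan)

    chi2 = p = math.nan
    defined = bool(above and below)
    if defined:
        table = (
            (sum(o.response for o in above), sum(not o.response for o in above)),
            (sum(o.response for o in below), sum(not o.response for o in below)),
        )
        try:
            chi2, _, p = chi_square_2x2(table)
        except ValidationError:
            defined = False
    ra, rb = rate(above, "response"), rate(below, "response")
    return ValidationReport(
        threshold=threshold,
        n_above=len(above), n_below=len(below),
        response_rate_above=ra, response_rate_below=rb,
        remission_rate_above=rate(above, "remission"),
        remission_rate_below=rate(below, "remission"),
        response_chi2=chi2, response_p=p, chi2_defined=defined,
        population_rate=population_rate,
        above_minus_population=(ra - population_rate
                                if population_rate is not None and above else None),
        below_minus_population=(rb - population_rate
                                if population_rate is not None and below else None),
    )
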