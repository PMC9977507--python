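"""Trial-level outcome statistics.

Covers endpoint classification (response = >= 50% HDRS-21 reduction from
baseline, remission = endpoint total < 10), the noninferiority assessment of
the arm difference in change scores against a fixed margin via a one-sided
95% confidence limit from a fixed-effects ANCOVA, and a simplified
cross-lagged path model between the depression (items 1, 7, 8) and anxiety
(items 9-11) subclusters estimated by per-transition least squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    ARMS,
    HDRSVisitRecord,
    PatientOutcome,
    ValidationError,
    VISITS,
)

__all__ = [
    "classify_outcomes",
    "ChangeScore",
    "change_scores",
    "NoninferiorityResult",
    "noninferiority_test",
    "DEPRESSION_ITEMS",
    "ANXIETY_ITEMS",
    "weekly_subcluster_scores",
    "PathEstimate",
    "TransitionFit",
    "CrossLaggedFit",
    "cross_lagged_fit",
]

DEPRESSION_ITEMS = (1, 7, 8)
ANXIETY_ITEMS = (9, 10, 11)

RESPONSE_FRACTION = 0.5
REMISSION_CUTOFF = 10  # endpoint total strictly below


def classify_outcomes(
    records: Sequence[HDRSVisitRecord],
    endpoint_visit: str = "W6",
) -> tuple[list[PatientOutcome], list[str]]:
    """Classify each patient's endpoint status from item-level records.

    Returns (outcomes, non_evaluable): patients lacking a baseline or the
    endpoint visit are flagged non-evaluable and excluded from the
    completer-set outputs.  A patient with both visits gets percent
    improvement, response, and remission flags; completers are labeled
    analysis_set="CO".
    """
    by_patient: dict[str, dict[str, HDRSVisitRecord]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, {})[rec.visit] = rec

    outcomes: list[PatientOutcome] = []
    non_evaluable: list[str] = []
    for pid, visits in by_patient.items():
        baseline = visits.get("BL")
        endpoint = visits.get(endpoint_visit)
        if baseline is None or endpoint is None:
            non_evaluable.append(pid)
            continue
        b, e = baseline.total, endpoint.total
        if b <= 0:
            non_evaluable.append(pid)
            continue
        improvement = (b - e) / b
        outcomes.append(PatientOutcome(
            patient_id=pid,
            arm=baseline.arm,
            site_id=baseline.site_id,
            baseline_total=b,
            endpoint_total=e,
            percent_improvement=improvement,
            response=improvement >= RESPONSE_FRACTION,
            remission=e < REMISSION_CUTOFF,
            analysis_set="CO",
        ))
    return outcomes, sorted(non_evaluable)


@dataclass(frozen=True)
class ChangeScore:
    patient_id: str
    arm: str
    site_id: str
    baseline_total: int
    endpoint_total: int

    @property
    def change(self) -> int:
        """Baseline minus endpoint; positive values are improvement."""
        return self.baseline_total - self.endpoint_total


def change_scores(outcomes: Sequence[PatientOutcome]) -> list[ChangeScore]:
    return [ChangeScore(o.patient_id, o.arm, o.site_id,
                        o.baseline_total, o.endpoint_total) for o in outcomes]


@dataclass
class NoninferiorityResult:
    difference: float       # adjusted H1 - H7 change difference (HDRS points)
    upper_limit: float      # one-sided 95% upper confidence limit
    margin: float
    noninferior: bool
    n: int
    dropped_covariates: list[str] = field(default_factory=list)


def noninferiority_test(
    changes: Sequence[ChangeScore],
    margin: float = 3.0,
    strata: Optional[Mapping[str, str]] = None,
) -> NoninferiorityResult:
    """Noninferiority of the H7 arm via ANCOVA on endpoint change scores.

    Fits change ~ arm + baseline + center (+ strata) by least squares and
    forms the one-sided 95% upper confidence limit of the adjusted H1 - H7
    difference (positive = H1 better).  H7 is noninferior when that limit
    falls below the margin.  Collinear strata columns are dropped with a
    warning and reported.
    """
    import statsmodels.api as sm

    for arm in ARMS:
        if sum(1 for c in changes if c.arm == arm) < 2:
            raise ValidationError(f"need at least 2 patients in arm {arm}")

    frame = pd.DataFrame({
        "change": [c.change for c in changes],
        "h1": [1.0 if c.arm == "H1" else 0.0 for c in changes],
        "baseline": [float(c.baseline_total) for c in changes],
        "site": [c.site_id for c in changes],
        "stratum": [strata.get(c.patient_id, "none") if strata else "none"
                    for c in changes],
    })
    design = pd.DataFrame({"const": 1.0, "h1": frame["h1"],
                           "baseline": frame["baseline"]})
    for col, values in (("site", frame["site"]), ("stratum", frame["stratum"])):
        dummies = pd.get_dummies(values, prefix=col, drop_first=True, dtype=float)
        design = pd.concat([design, dummies], axis=1)

    dropped: list[str] = []
    X = design.to_numpy()
    # prune collinear columns (never the arm indicator) by rank inspection
    keep = [0, 1, 2]
    for j in range(3, X.shape[1]):
        candidate = keep + [j]
        if np.linalg.matrix_rank(X[:, candidate]) == len(candidate):
            keep.append(j)
        else:
            dropped.append(design.columns[j])
    if dropped:
        warnings.warn(f"dropped collinear covariates: {dropped}", stacklevel=2)
    X = X[:, keep]

    model = sm.OLS(frame["change"].to_numpy(), X).fit()
    diff = float(model.params[1])
    se = float(model.bse[1])
    df = int(model.df_resid)
    upper = diff + stats.t.ppf(0.95, df) * se
    return NoninferiorityResult(
        difference=diff,
        upper_limit=float(upper),
        margin=margin,
        noninferior=bool(upper < margin),
        n=len(changes),
        dropped_covariates=dropped,
    )


# ---------------------------------------------------------------------------
# cross-lagged depression <-> anxiety paths
# ---------------------------------------------------------------------------

def weekly_subcluster_scores(records: Sequence[HDRSVisitRecord]) -> pd.DataFrame:
    """Per-patient per-wave depression and anxiety subcluster sums.

    Depression is the sum of items 1, 7, 8; anxiety of items 9-11.  Missing
    waves simply have no row (gaps propagate, never imputed).
    """
    rows = []
    for rec in records:
        rows.append({
            "patient_id": rec.patient_id,
            "arm": rec.arm,
            "visit": rec.visit,
            "depression": sum(rec.item(i) for i in DEPRESSION_ITEMS),
            "anxiety": sum(rec.item(i) for i in ANXIETY_ITEMS),
        })
    frame = pd.DataFrame(rows, columns=["patient_id", "arm", "visit",
                                        "depression", "anxiety"])
    order = {v: k for k, v in enumerate(VISITS)}
    return frame.sort_values(
        ["patient_id", "visit"], key=lambda s: s.map(order) if s.name == "visit" else s
    ).reset_index(drop=True)


@dataclass(frozen=True)
class PathEstimate:
    coefficient: float
    stderr: float
    p_value: float


@dataclass
class TransitionFit:
    """Coefficients for one wave transition (t-1 -> t) in one group."""

    group: str
    wave_from: str
    wave_to: str
    n: int
    dep_auto: PathEstimate       # dep_{t-1} -> dep_t
    anx_auto: PathEstimate       # anx_{t-1} -> anx_t
    dep_to_anx: PathEstimate     # dep_{t-1} -> anx_t (cross-lagged)
    anx_to_dep: PathEstimate     # anx_{t-1} -> dep_t (cross-lagged)
    flagged: bool = False        # singular design (e.g. constant wave)


@dataclass
class CrossLaggedFit:
    waves: tuple[str, ...]
    transitions: list[TransitionFit]

    def cross_paths(self, group: str, direction: str = "dep_to_anx"
                    ) -> list[PathEstimate]:
        return [getattr(t, direction) for t in self.transitions
                if t.group == group and not t.flagged]


def _ols_paths(y: np.ndarray, x_auto: np.ndarray, x_cross: np.ndarray
               ) -> tuple[PathEstimate, PathEstimate, bool]:
    """Least-squares fit y ~ 1 + x_auto + x_cross; returns (auto, cross, flagged)."""
    import statsmodels.api as sm

    X = np.column_stack([np.ones_like(x_auto), x_auto, x_cross])
    if np.linalg.matrix_rank(X) < 3:
        nanest = PathEstimate(math.nan, math.nan, math.nan)
        return nanest, nanest, True
    fit = sm.OLS(y, X).fit()
    auto = PathEstimate(float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1]))
    cross = PathEstimate(float(fit.params[2]), float(fit.bse[2]), float(fit.pvalues[2]))
    return auto, cross, False


def cross_lagged_fit(
    subclusters: pd.DataFrame,
    groups: Optional[Mapping[str, str]] = None,
    waves: Optional[Sequence[str]] = None,
) -> CrossLaggedFit:
    """Per-transition cross-lagged least-squares paths by group.

    For each consecutive wave pair and group, estimates
    dep_t ~ dep_{t-1} + anx_{t-1} and anx_t ~ anx_{t-1} + dep_{t-1} with
    listwise deletion per transition.  For saturated observed-variable path
    models this per-equation fit coincides with the joint path system.
    Requires at least 3 waves and 20 patients per group.
    """
    frame = subclusters.copy()
    if groups is not None:
        frame["arm"] = frame["patient_id"].map(dict(groups))
    if waves is None:
        waves = [v for v in VISITS if v in set(frame["visit"])]
    if len(waves) < 3:
        raise ValidationError("cross-lagged fit needs at least 3 waves")

    wide = frame.pivot_table(index=["patient_id", "arm"], columns="visit",
                             values=["depression", "anxiety"], aggfunc="first")
    transitions: list[TransitionFit] = []
    for group, block in wide.groupby(level="arm"):
        if len(block) < 20:
            raise ValidationError(
                f"group {group}: need at least 20 patients, got {len(block)}")
        for prev, cur in zip(waves[:-1], waves[1:]):
            cols = [("depression", prev), ("anxiety", prev),
                    ("depression", cur), ("anxiety", cur)]
            if any(c not in block.columns for c in cols):
                continue
            sub = block[cols].dropna()
            n = len(sub)
            dep_prev = sub[("depression", prev)].to_numpy(float)
            anx_prev = sub[("anxiety", prev)].to_numpy(float)
            dep_cur = sub[("depression", cur)].to_numpy(float)
            anx_cur = sub[("anxiety", cur)].to_numpy(float)
            if n < 4:
                continue
            dep_auto, anx_to_dep, flag1 = _ols_paths(dep_cur, dep_prev, anx_prev)
            anx_auto, dep_to_anx, flag2 = _ols_paths(anx_cur, anx_prev, dep_prev)
            transitions.append(TransitionFit(
                group=str(group), wave_from=prev, wave_to=cur, n=n,
                dep_auto=dep_auto, anx_auto=anx_auto,
                dep_to_anx=dep_to_anx, anx_to_dep=anx_to_dep,
                flagged=flag1 or flag2,
            ))
    return CrossLaggedFit(waves=tuple(waves), transitions=transitions)
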