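"""E-DEPTH statistics: band metrics vs clinical improvement, per coil group.

Each EEG metric is correlated with percent HDRS-21 improvement within a coil
group, with recording site partialled out (residualization on site indicator
variables) after a single outlier-stabilization pass (observations beyond
3 SD in standardized residual, or with leverage above mean + 3 SD, removed).
Between-group differences in correlation magnitude are assessed with
Fisher's r-to-z test.  The electrodes of interest follow each coil's maximal
induction point: the F3/F4 asymmetry for lateral (H1) stimulation and Fz for
medial (H7) stimulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .datamodel import PatientOutcome, StudyConfig, ValidationError
from .spectral import BandMetrics

__all__ = [
    "CorrelationResult",
    "partial_correlation",
    "StabilizeResult",
    "stabilize",
    "FisherZResult",
    "fisher_z_compare",
    "EOI_METRICS",
    "EoiContrast",
    "EoiReport",
    "eoi_report",
]


@dataclass
class CorrelationResult:
    metric: str
    electrode: str
    group: str
    r: float
    p_value: float
    n: int
    excluded: list[str] = field(default_factory=list)
    covariates: tuple[str, ...] = ("site",)


def _site_design(sites: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + site indicator columns (first site as reference).

    Sites with a single patient contribute no usable indicator; their column
    is dropped (the patient is retained) with a warning.
    """
    sites = [str(s) for s in sites]
    levels = sorted(set(sites))
    singletons = [s for s in levels if sites.count(s) == 1]
    if singletons:
        warnings.warn(
            f"site(s) {singletons} have a single patient; indicator dropped, "
            "patient retained", stacklevel=3)
    used = [s for s in levels[1:] if s not in singletons]
    cols = [np.ones(len(sites))]
    cols += [np.array([1.0 if s == lv else 0.0 for s in sites]) for lv in used]
    return np.column_stack(cols), used


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    sites: Optional[Sequence[str]] = None,
    metric: str = "",
    electrode: str = "",
    group: str = "",
) -> CorrelationResult:
    """Pearson correlation of x and y with site residualized out of both.

    With a single site this reduces exactly to the plain Pearson correlation.
    The p-value uses a t reference with n - 2 - k degrees of freedom, k the
    number of site indicators.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValidationError("x and y must be aligned")
    if sites is None:
        sites = ["0"] * n
    n_sites = len(set(sites))
    if n < n_sites + 4:
        raise ValidationError(f"need at least sites + 4 = {n_sites + 4} "
                              f"observations, got {n}")
    Z, used = _site_design(sites)
    beta_x, *_ = np.linalg.lstsq(Z, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
    rx = x - Z @ beta_x
    ry = y - Z @ beta_y
    if np.allclose(rx.std(), 0) or np.allclose(ry.std(), 0):
        raise ValidationError("zero residual variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - len(used)
    t = r * math.sqrt(df / max(1e-300, 1 - r * r))
    p = float(2 * stats.t.sf(abs(t), df))
    return CorrelationResult(metric=metric, electrode=electrode, group=group,
                             r=r, p_value=p, n=n,
                             covariates=("site",) if used else ())


@dataclass
class StabilizeResult:
    kept: np.ndarray
    removed: np.ndarray
    reasons: dict[int, str]
    high_removal_warning: bool


def stabilize(
    x: Sequence[float],
    y: Sequence[float],
    sites: Optional[Sequence[str]] = None,
    sd_limit: float = 3.0,
) -> StabilizeResult:
    """One-pass outlier removal on the correlation regression.

    Fits y ~ x + site indicators; removes observations with a standardized
    residual beyond ``sd_limit`` SD or leverage above mean + ``sd_limit`` SD
    of the leverages.  A single pass only — iterating the rule can cascade on
    small samples.  Removing more than 20% of observations raises a hard
    warning (suspect data).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 10:
        raise ValidationError(f"stabilization needs n >= 10, got {n}")
    if sites is None:
        sites = ["0"] * n
    Z, _ = _site_design(sites)
    X = np.column_stack([Z, x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    p = np.linalg.matrix_rank(X)
    sigma = math.sqrt(float(resid @ resid) / max(1, n - p))
    std_resid = resid / sigma if sigma > 0 else np.zeros_like(resid)
    hat = np.einsum("ij,ji->i", X, np.linalg.pinv(X))
    lev_cut = hat.mean() + sd_limit * hat.std()

    reasons: dict[int, str] = {}
    for i in range(n):
        if abs(std_resid[i]) > sd_limit:
            reasons[i] = "residual"
        elif hat[i] > lev_cut and hat.std() > 0:
            reasons[i] = "leverage"
    removed = np.array(sorted(reasons), dtype=int)
    kept = np.array([i for i in range(n) if i not in reasons], dtype=int)
    high = len(removed) > 0.2 * n
    if high:
        warnings.warn(
            f"stabilization removed {len(removed)}/{n} observations (>20%): "
            "suspect data", stacklevel=2)
    return StabilizeResult(kept=kept, removed=removed, reasons=reasons,
                           high_removal_warning=high)


@dataclass(frozen=True)
class FisherZResult:
    r1: float
    n1: int
    r2: float
    n2: int
    z: float
    p_value: float


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> FisherZResult:
    """Fisher r-to-z comparison of two independent correlations.

    Z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)) with a two-sided
    normal p.  Antisymmetric under swapping the two groups.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValidationError("|r| must be < 1 for the z transform")
        if n < 4:
            raise ValidationError("each group needs n >= 4")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1 / (n1 - 3) + 1 / (n2 - 3))
    p = float(2 * stats.norm.sf(abs(z)))
    return FisherZResult(r1=r1, n1=n1, r2=r2, n2=n2, z=float(z), p_value=p)


#: The reported metric panel: (metric name, electrode or pair label).
EOI_METRICS: tuple[tuple[str, str], ...] = (
    ("asymmetry", "F3/F4"),   # lateral alpha asymmetry over the H1 EOI
    ("alpha", "FZ"),          # medial absolute/deviated alpha power
    ("gamma", "FZ"),          # medial low-gamma power
    ("ratio", "FZ"),          # medial low-gamma/alpha ratio
)


@dataclass
class EoiContrast:
    metric: str
    electrode: str
    correlations: dict[str, CorrelationResult]
    fisher: Optional[FisherZResult]
    skipped_reason: str = ""


@dataclass
class EoiReport:
    contrasts: list[EoiContrast]

    def get(self, metric: str, electrode: str) -> EoiContrast:
        for c in self.contrasts:
            if c.metric == metric and c.electrode.upper() == electrode.upper():
                return c
        raise KeyError((metric, electrode))


def eoi_report(
    metrics: Mapping[str, BandMetrics],
    outcomes: Sequence[PatientOutcome],
    config: Optional[StudyConfig] = None,
    metric_panel: Sequence[tuple[str, str]] = EOI_METRICS,
    log_transform: bool = False,
    min_group_n: int = 10,
) -> EoiReport:
    """Per-(metric, electrode) group correlations and between-group contrasts.

    For each metric and coil group: a stabilization pass, then the
    site-partialled correlation with percent improvement; the two groups are
    then contrasted with Fisher's z (the z uses post-exclusion n - 3).  A
    group below ``min_group_n`` after the join skips the contrast with a note.
    ``log_transform`` applies log10 to (positive) metric values before
    correlating — an option for ratio-type metrics.
    """
    config = config or StudyConfig()
    outcome_by_pid = {o.patient_id: o for o in outcomes}
    contrasts: list[EoiContrast] = []
    for metric, electrode in metric_panel:
        per_group: dict[str, CorrelationResult] = {}
        skipped = ""
        for group in ("H1", "H7"):
            pids, xs, ys, sites = [], [], [], []
            for pid, bm in metrics.items():
                out = outcome_by_pid.get(pid)
                if out is None or out.arm != group:
                    continue
                try:
                    value = bm.value(metric, electrode)
                except ValidationError:
                    continue
                if log_transform:
                    if value <= 0:
                        continue
                    value = math.log10(value)
                pids.append(pid)
                xs.append(value)
                ys.append(out.percent_improvement)
                sites.append(out.site_id)
            if len(xs) < min_group_n:
                skipped = (f"group {group} has n={len(xs)} < {min_group_n} "
                           f"for {metric}@{electrode}")
                continue
            try:
                stab = stabilize(xs, ys, sites, sd_limit=config.outlier_sd)
                keep = stab.kept
                result = partial_correlation(
                    np.asarray(xs)[keep], np.asarray(ys)[keep],
                    [sites[i] for i in keep],
                    metric=metric, electrode=electrode, group=group)
            except ValidationError as exc:
                skipped = (f"group {group} degenerate for "
                           f"{metric}@{electrode}: {exc}")
                continue
            result.excluded = [pids[i] for i in stab.removed]
            per_group[group] = result
        fisher = None
        if len(per_group) == 2:
            h1, h7 = per_group["H1"], per_group["H7"]
            fisher = fisher_z_compare(h1.r, h1.n, h7.r, h7.n)
        contrasts.append(EoiContrast(
            metric=metric, electrode=electrode,
            correlations=per_group, fisher=fisher, skipped_reason=skipped))
    return EoiReport(contrasts=contrasts)
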