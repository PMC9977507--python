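"""Printed trial summary figures and integer contingency-table reconstruction.

The trial's patient-level data are not public, but the printed subgroup sizes
and response/remission percentages pin down the underlying integer 2x2 tables
uniquely.  This module records those printed figures as inputs and solves for
the integer counts consistent with them, so the headline chi-square and
odds-ratio statistics can be recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MAIN_STUDY",
    "VALIDATION_ITT",
    "VALIDATION_PP",
    "reconstruct_side_table",
    "reconstruct_main_tables",
    "EOI_CORRELATIONS",
]


@dataclass(frozen=True)
class PrintedSubgroups:
    """Printed figures for the completers-within-ITT threshold analysis."""

    n_above: int = 43
    n_below: int = 101
    h1_total: int = 64          # implied by the printed 62.5% completer response
    h7_total: int = 80          # n_above + n_below - h1_total
    # response rates in percent, as printed
    response_above: dict = None  # type: ignore[assignment]
    response_below: dict = None  # type: ignore[assignment]
    remission_above: dict = None  # type: ignore[assignment]
    remission_below: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "response_above", {"H1": 95, "H7": 46})
        object.__setattr__(self, "response_below", {"H1": 49, "H7": 73})
        object.__setattr__(self, "remission_above", {"H1": 58, "H7": 33})
        object.__setattr__(self, "remission_below", {"H1": 40, "H7": 55})


MAIN_STUDY = PrintedSubgroups()

#: External H1-only cohort, intent-to-treat set: sizes and percent rates.
VALIDATION_ITT = {
    "n_above": 18, "rate_above": 83, "n_below": 54, "rate_below": 61,
    "remission_above": 72, "remission_below": 55, "population_rate": 67,
}
#: External H1-only cohort, per-protocol set.
VALIDATION_PP = {
    "n_above": 16, "rate_above": 94, "n_below": 49, "rate_below": 65,
    "remission_above": 81, "remission_below": 59, "population_rate": 67,
}

#: Printed per-coil correlations of treatment-session EEG metrics with
#: percent improvement (r, n after exclusions), by metric.
EOI_CORRELATIONS = {
    "alpha_asymmetry_f3f4": {"H1": (-0.32, 48), "H7": (0.27, 59)},
    "gamma_alpha_ratio_fz": {"H1": (0.0, 48), "H7": (0.51, 58)},
}


def reconstruct_side_table(n_above: int, rate_above: float,
                           n_below: int, rate_below: float) -> list[list[int]]:
    """2x2 (side x event) table from group sizes and percent rates.

    Event counts are the integers nearest rate*n; by construction they round
    back to the printed percentages.
    """
    ea = round(rate_above * n_above / 100)
    eb = round(rate_below * n_below / 100)
    return [[ea, n_above - ea], [eb, n_below - eb]]


def _rounds_to(count: int, total: int, printed_pct: int) -> bool:
    return total > 0 and round(100 * count / total) == printed_pct


def reconstruct_main_tables(spec: PrintedSubgroups = MAIN_STUDY) -> dict:
    """Solve for the integer arm-by-side split consistent with every printed rate.

    Searches the H1 above-threshold count; for each candidate the remaining
    three cell totals follow from the printed side and arm sizes, and event
    counts are the integers nearest rate*n.  A split is admissible only if all
    eight reconstructed rates round back to the printed percentages.  Exactly
    one split survives; the result maps side -> {response, remission} tables
    with rows (H1, H7) and columns (event, no event).
    """
    solutions = []
    for h1_above in range(1, spec.n_above):
        h7_above = spec.n_above - h1_above
        h1_below = spec.h1_total - h1_above
        h7_below = spec.h7_total - h7_above
        if min(h7_above, h1_below, h7_below) <= 0:
            continue
        totals = {
            ("above", "H1"): h1_above, ("above", "H7"): h7_above,
            ("below", "H1"): h1_below, ("below", "H7"): h7_below,
        }
        printed = {
            "response": {"above": spec.response_above, "below": spec.response_below},
            "remission": {"above": spec.remission_above, "below": spec.remission_below},
        }
        events: dict = {}
        ok = True
        for outcome, sides in printed.items():
            for side, rates in sides.items():
                for arm, pct in rates.items():
                    total = totals[(side, arm)]
                    count = round(pct * total / 100)
                    if not _rounds_to(count, total, pct):
                        ok = False
                    events[(outcome, side, arm)] = count
        if ok:
            solutions.append((totals, events))
    if len(solutions) != 1:
        raise ValueError(
            f"printed rates admit {len(solutions)} integer splits, expected 1")
    totals, events = solutions[0]
    out: dict = {}
    for side in ("above", "below"):
        out[side] = {}
        for outcome in ("response", "remission"):
            rows = []
            for arm in ("H1", "H7"):
                e = events[(outcome, side, arm)]
                rows.append([e, totals[(side, arm)] - e])
            out[side][outcome] = rows
        out[side]["arm_n"] = {arm: totals[(side, arm)] for arm in ("H1", "H7")}
    return out
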