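"""C-DEPTH scoring, contingency statistics, LOFO, threshold and validation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency, pearsonr

from depthtms.cdepth import (
    chi_square_2x2,
    compute_cdepth,
    compute_cdepth_scores,
    correlate_score_outcome,
    lofo_optimize,
    odds_ratio,
    subgroup_analysis,
    threshold_search,
    validate_external,
)
from depthtms.datamodel import (
    FULL_CLUSTER,
    OPTIMIZED_CLUSTER,
    ClusterDefinition,
    HDRSVisitRecord,
    PatientOutcome,
    ValidationError,
)
from depthtms.synth import CohortSimParams, default_item_weights, simulate_cohort


def _bl_record(items, pid="P1"):
    return HDRSVisitRecord(patient_id=pid, site_id="S1", arm="H1",
                           visit="BL", items=tuple(items))


def _items(**scores):
    vals = [0] * 21
    for item, s in scores.items():
        vals[int(item[1:]) - 1] = s
    return vals


def _outcome(pid, improvement, arm="H1", site="S1", baseline=40):
    endpoint = int(round(baseline * (1 - improvement)))
    impr = (baseline - endpoint) / baseline
    return PatientOutcome(patient_id=pid, arm=arm, site_id=site,
                          baseline_total=baseline, endpoint_total=endpoint,
                          percent_improvement=impr, response=impr >= 0.5,
                          remission=endpoint < 10)


class TestScore:
    @pytest.mark.parametrize("cluster,items,expected", [
        (OPTIMIZED_CLUSTER, _items(), 0.0),
        (OPTIMIZED_CLUSTER,
         _items(i1=4, i7=4, i8=4, i9=4, i10=4, i11=4), 1.0),
        (OPTIMIZED_CLUSTER, _items(i1=4, i7=4, i8=4), 0.5),
        (FULL_CLUSTER,
         _items(i1=2, i7=2, i8=2, i9=2, i10=2, i11=2, i15=2, i13=1), 0.5),
    ])
    def test_normalized_item_mean(self, cluster, items, expected):
        score = compute_cdepth(_bl_record(items), cluster)
        assert score.score == pytest.approx(expected)

    def test_missing_cluster_item_named(self):
        cluster = ClusterDefinition(items=(1, 7), maxima={1: 4, 7: 4, 25: 4})
        object.__setattr__(cluster, "items", (1, 7, 25))
        with pytest.raises(ValidationError, match="25"):
            compute_cdepth(_bl_record(_items()), cluster)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_monotone_in_cluster_items_invariant_elsewhere(self, data):
        """Raising any cluster item never lowers the score; non-cluster items
        never change it."""
        from depthtms.datamodel import HDRS_ITEM_MAXIMA

        items = [data.draw(st.integers(0, HDRS_ITEM_MAXIMA[i]))
                 for i in range(1, 22)]
        base = compute_cdepth(_bl_record(items), OPTIMIZED_CLUSTER).score
        assert 0.0 <= base <= 1.0
        for i in OPTIMIZED_CLUSTER.items:
            if items[i - 1] < HDRS_ITEM_MAXIMA[i]:
                bumped = list(items)
                bumped[i - 1] += 1
                up = compute_cdepth(_bl_record(bumped), OPTIMIZED_CLUSTER).score
                assert up > base
        for i in (2, 13, 15, 21):
            if items[i - 1] < HDRS_ITEM_MAXIMA[i]:
                bumped = list(items)
                bumped[i - 1] += 1
                same = compute_cdepth(_bl_record(bumped), OPTIMIZED_CLUSTER).score
                assert same == pytest.approx(base)


class TestCorrelate:
    def test_identical_vectors_give_unit_correlation(self):
        outcomes = [_outcome(f"P{i}", 0.1 * i) for i in range(8)]
        scores = {o.patient_id: o.percent_improvement for o in outcomes}
        r, p, n = correlate_score_outcome(scores, outcomes)
        assert r == pytest.approx(1.0)
        assert n == 8

    def test_zero_variance_rejected(self):
        outcomes = [_outcome(f"P{i}", 0.1 * i) for i in range(6)]
        scores = {o.patient_id: 0.5 for o in outcomes}
        with pytest.raises(ValidationError, match="variance"):
            correlate_score_outcome(scores, outcomes)

    def test_too_few_pairs_rejected(self):
        outcomes = [_outcome(f"P{i}", 0.2 * i) for i in range(3)]
        scores = {o.patient_id: 0.1 * i for i, o in enumerate(outcomes)}
        with pytest.raises(ValidationError, match="4"):
            correlate_score_outcome(scores, outcomes)

    def test_planted_correlation_recovered(self):
        """A rho = 0.4 bivariate plant at n = 70 is recovered within +-0.15."""
        rng = np.random.default_rng(42)
        z1 = rng.standard_normal(70)
        z1 = (z1 - z1.mean()) / z1.std()
        eps = rng.standard_normal(70)
        eps = eps - eps.mean() - (eps @ z1) / (z1 @ z1) * z1
        eps /= eps.std()
        z2 = 0.4 * z1 + math.sqrt(1 - 0.16) * eps  # sample corr exactly 0.4
        outcomes = [_outcome(f"P{i}", float(np.clip(0.4 + 0.15 * z1[i], 0, 0.9)))
                    for i in range(70)]
        scores = {f"P{i}": float(0.5 + 0.15 * z2[i]) for i in range(70)}
        r, _, _ = correlate_score_outcome(scores, outcomes)
        assert abs(r - 0.4) < 0.15


class TestChiSquare:
    @pytest.mark.parametrize("table,expected,decimals", [
        ([[15, 3], [33, 21]], 3.0, 10),    # exact by construction
        ([[15, 1], [32, 17]], 4.9, 1),
        ([[7, 3], [7, 3]], 0.0, 10),
    ])
    def test_known_tables(self, table, expected, decimals):
        chi2, df, p = chi_square_2x2(table)
        assert df == 1
        assert round(chi2, decimals) == pytest.approx(expected)

    def test_oracle_equivalence_on_random_tables(self):
        """Matches the scipy Pearson chi-square (no continuity correction)
        on 1,000 random tables to 1e-10."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 1000:
            t = rng.integers(1, 60, size=(2, 2))
            ours, _, p_ours = chi_square_2x2(t)
            ref, p_ref, _, _ = chi2_contingency(t, correction=False)
            assert abs(ours - ref) < 1e-10
            assert abs(p_ours - p_ref) < 1e-10
            checked += 1

    def test_invariant_to_joint_row_and_column_swap(self):
        t = [[18, 1], [11, 13]]
        swapped = [[13, 11], [1, 18]]
        assert chi_square_2x2(t)[0] == pytest.approx(chi_square_2x2(swapped)[0])

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestOddsRatio:
    def test_reconstructed_above_threshold_table(self):
        res = odds_ratio([[18, 1], [11, 13]])
        assert res.odds_ratio == pytest.approx(234 / 11)
        assert round(res.odds_ratio) == 21
        assert not res.corrected

    def test_uniform_table_is_one(self):
        assert odds_ratio([[5, 5], [5, 5]]).odds_ratio == pytest.approx(1.0)

    def test_haldane_anscombe_on_zero_cell(self):
        res = odds_ratio([[2, 0], [1, 1]])
        assert res.corrected
        assert res.odds_ratio == pytest.approx(5.0)

    def test_zero_line_undefined(self):
        res = odds_ratio([[0, 0], [3, 4]])
        assert not res.defined and math.isnan(res.odds_ratio)

    def test_oracle_equivalence_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 50, size=4)
            assert odds_ratio([[a, b], [c, d]]).odds_ratio == \
                pytest.approx((a * d) / (b * c), rel=1e-12)


def _subgroup_inputs(above_counts, below_counts):
    """Build scores/outcomes realizing (responders, nonresponders) per arm."""
    outcomes, scores = [], {}
    i = 0
    for side, counts, score in (("above", above_counts, 0.7),
                                ("below", below_counts, 0.3)):
        for arm, (resp, nonresp) in counts.items():
            for flag, count in ((True, resp), (False, nonresp)):
                for _ in range(count):
                    o = _outcome(f"P{i}", 0.6 if flag else 0.2, arm=arm)
                    outcomes.append(o)
                    scores[o.patient_id] = score
                    i += 1
    return scores, outcomes


class TestSubgroupAnalysis:
    def test_reconstructed_main_study_tables(self):
        scores, outcomes = _subgroup_inputs(
            {"H1": (18, 1), "H7": (11, 13)}, {"H1": (22, 23), "H7": (41, 15)})
        analysis = subgroup_analysis(scores, outcomes, 0.5)
        # the published figure truncates 11.55 to 11.5
        assert analysis.above.response_chi2 == pytest.approx(11.55, abs=0.01)
        assert round(analysis.above.response_or.odds_ratio) == 21
        assert analysis.above.or_favors == "H1"
        assert round(analysis.below.response_chi2, 1) == 6.3
        assert analysis.below.or_favors == "H7"
        assert analysis.below.response_or.odds_ratio == pytest.approx(2.86, abs=0.01)

    def test_uniform_table_null(self):
        scores, outcomes = _subgroup_inputs(
            {"H1": (10, 10), "H7": (10, 10)}, {"H1": (5, 5), "H7": (5, 5)})
        analysis = subgroup_analysis(scores, outcomes, 0.5)
        assert analysis.above.response_chi2 == pytest.approx(0.0)
        assert analysis.above.response_or.odds_ratio == pytest.approx(1.0)

    def test_marginals_reconstruct_inputs(self):
        scores, outcomes = _subgroup_inputs(
            {"H1": (3, 4), "H7": (5, 6)}, {"H1": (7, 8), "H7": (9, 10)})
        analysis = subgroup_analysis(scores, outcomes, 0.5)
        assert analysis.above.arm_n == {"H1": 7, "H7": 11}
        assert analysis.below.arm_n == {"H1": 15, "H7": 19}
        assert analysis.n == len(outcomes)
        table = analysis.above.response_table.as_array()
        assert table.sum() == analysis.above.n

    def test_single_arm_side_flagged_undefined(self):
        scores, outcomes = _subgroup_inputs(
            {"H1": (5, 5)}, {"H1": (4, 4), "H7": (6, 6)})
        analysis = subgroup_analysis(scores, outcomes, 0.5)
        assert not analysis.above.defined
        assert math.isnan(analysis.above.response_chi2)
        assert analysis.below.defined


class TestThresholdSearch:
    def test_recovers_planted_switch_threshold(self):
        """A response interaction flipping at 0.5 is located within one
        grid step, across seeds."""
        for seed in (0, 1, 2):
            params = CohortSimParams(
                n_per_arm=200, seed=seed, dropout_prob=0.0,
                interaction_form="switch",
                beta_c={"H1": 3.0, "H7": -3.0})
            records, outcomes, _ = simulate_cohort(params)
            scores = compute_cdepth_scores(records, OPTIMIZED_CLUSTER)
            tau, _ = threshold_search(scores, outcomes)
            assert abs(tau - 0.5) <= 0.05 + 1e-9

    def test_matches_exhaustive_scan_on_toy_set(self):
        """Grid argmax equals an independent exhaustive evaluation."""
        rng = np.random.default_rng(3)
        outcomes = [_outcome(f"P{i}", float(rng.uniform(0, 0.9)),
                             arm="H1" if i % 2 else "H7") for i in range(60)]
        scores = {o.patient_id: float(rng.uniform(0, 1)) for o in outcomes}
        tau, _ = threshold_search(scores, outcomes, min_side_n=10)

        best = None
        grid = [0.1 + 0.05 * k for k in range(17)]
        for cand in grid:
            above = [o for o in outcomes if scores[o.patient_id] > cand]
            below = [o for o in outcomes if scores[o.patient_id] <= cand]
            if len(above) < 10 or len(below) < 10:
                continue
            chis = []
            ok = True
            for side in (above, below):
                t = [[sum(o.response for o in side if o.arm == a),
                      sum(not o.response for o in side if o.arm == a)]
                     for a in ("H1", "H7")]
                if min(sum(row) for row in t) == 0 or \
                        min(sum(col) for col in zip(*t)) == 0:
                    ok = False
                    break
                n = sum(v for row in t for v in row)
                (a, b), (c, d) = t
                chis.append(n * (a * d - b * c) ** 2
                            / ((a + b) * (c + d) * (a + c) * (b + d)))
            if not ok:
                continue
            obj = min(chis)
            if best is None or obj > best[0] + 1e-12 or \
                    (abs(obj - best[0]) <= 1e-12
                     and abs(cand - 0.5) < abs(best[1] - 0.5)):
                best = (obj, cand)
        assert tau == pytest.approx(best[1])

    def test_constant_scores_rejected(self):
        outcomes = [_outcome(f"P{i}", 0.6 if i % 2 else 0.2,
                             arm="H1" if i < 15 else "H7") for i in range(30)]
        scores = {o.patient_id: 0.5 for o in outcomes}
        with pytest.raises(ValidationError):
            threshold_search(scores, outcomes)


def _lofo_plant_params(seed, n_per_arm=600):
    weights = default_item_weights()
    weights[13] = (1, 0.02, 1)
    weights[15] = (1, 0.02, 0.02, 0.02, 1)
    loadings = {i: 1.5 for i in range(1, 22)}
    loadings[13] = 0.0
    loadings[15] = 0.0
    return CohortSimParams(n_per_arm=n_per_arm, seed=seed, dropout_prob=0.0,
                           item_weights=weights, severity_loading=loadings,
                           beta_c={"H1": 5.0, "H7": -4.0})


class TestLofo:
    def test_removes_planted_noise_items(self):
        """Items 13 and 15 carry no outcome signal; LOFO strips exactly them
        in most seeds."""
        hits = 0
        for seed in range(5):
            records, outcomes, _ = simulate_cohort(_lofo_plant_params(seed))
            cluster, trace = lofo_optimize(records, outcomes, FULL_CLUSTER)
            hits += cluster.items == (1, 7, 8, 9, 10, 11)
        assert hits >= 4

    def test_min_size_guard_returns_unchanged(self, cohort200):
        records, outcomes, _ = cohort200
        cluster, trace = lofo_optimize(records, outcomes, OPTIMIZED_CLUSTER,
                                       min_size=6)
        assert cluster.items == OPTIMIZED_CLUSTER.items
        assert trace == []

    def test_pure_noise_terminates_at_initial_cluster(self):
        """With no outcome signal anywhere, the stopping rule keeps the
        initial cluster in >= 80% of 20 seeds."""
        unchanged = 0
        for seed in range(20):
            params = CohortSimParams(n_per_arm=1500, seed=seed + 100,
                                     dropout_prob=0.0,
                                     beta_c={"H1": 0.0, "H7": 0.0})
            records, outcomes, _ = simulate_cohort(params)
            cluster, trace = lofo_optimize(records, outcomes, FULL_CLUSTER)
            unchanged += len(trace) == 0
        assert unchanged >= 16


class TestValidateExternal:
    def test_planted_effect_gives_higher_above_rate(self):
        params = CohortSimParams(n_per_arm=150, seed=5, dropout_prob=0.0,
                                 beta_c={"H1": 4.0, "H7": 4.0})
        records, outcomes, _ = simulate_cohort(params)
        h1 = [o for o in outcomes if o.arm == "H1"]
        report = validate_external(records, h1, OPTIMIZED_CLUSTER, 0.5,
                                   population_rate=0.67)
        assert report.response_rate_above > report.response_rate_below
        assert report.above_minus_population is not None

    def test_printed_counts_reproduce_chi2(self):
        """15/18 above vs 33/54 below gives the exact chi-square of 3.0."""
        outcomes, records = [], []
        i = 0
        for side_score, resp, total in ((4, 15, 18), (0, 33, 54)):
            for k in range(total):
                pid = f"V{i}"
                items = _items(i1=side_score, i7=side_score, i8=side_score,
                               i9=side_score, i10=side_score, i11=side_score)
                records.append(HDRSVisitRecord(patient_id=pid, site_id="S1",
                                               arm="H1", visit="BL",
                                               items=tuple(items)))
                outcomes.append(_outcome(pid, 0.6 if k < resp else 0.2))
                i += 1
        report = validate_external(records, outcomes, OPTIMIZED_CLUSTER, 0.5)
        assert report.n_above == 18 and report.n_below == 54
        assert report.response_chi2 == pytest.approx(3.0)

    def test_threshold_outside_range_flags_chi2(self):
        records = [_bl_record(_items(i1=1), pid=f"P{i}") for i in range(12)]
        records = [HDRSVisitRecord(r.patient_id, r.site_id, r.arm, r.visit,
                                   r.items) for r in records]
        outcomes = [_outcome(f"P{i}", 0.6) for i in range(12)]
        report = validate_external(records, outcomes, OPTIMIZED_CLUSTER, 0.99)
        assert report.n_above == 0
        assert not report.chi2_defined
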