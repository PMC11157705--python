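import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from herbprox.evaluation import (
    DiscoveryResult,
    EvaluationError,
    GoldStandard,
    UndefinedCorrelationError,
    auprc,
    auroc,
    auroc_vs_count_correlation,
    baseline_precision,
    discover_novel,
    evaluate,
    label_and_orient,
    per_entity_auroc,
    rank_sum_compare,
    roc_points,
    select_reliable_herbs,
    threshold_at_fpr,
)
from herbprox.proximity import Measure, ScoreMatrix
from oracles import pairwise_auroc, scan_threshold, step_auprc


def make_matrix(values: dict[str, dict[str, float]]) -> ScoreMatrix:
    """ScoreMatrix from {herb: {disease: value}} (NaN for missing cells)."""
    frame = pd.DataFrame.from_dict(values, orient="index").sort_index().sort_index(axis=1)
    return ScoreMatrix(
        Measure.WACP,
        frame.astype(float),
        pd.Series(1, index=frame.index, dtype=int),
        pd.Series(1, index=frame.columns, dtype=int),
    )


def random_scores(seed, n, n_pos):
    rng = np.random.default_rng(seed)
    scores = rng.random(n)
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n_pos, replace=False)] = 1
    return scores, labels


class TestLabelAndOrient:
    def test_counts_on_dense_matrix(self):
        values = {f"h{i}": {f"d{k}": float(i + k) for k in range(4)} for i in range(5)}
        gold = GoldStandard(frozenset({("h0", "d0"), ("h1", "d2"), ("h4", "d3")}))
        scores, labels = label_and_orient(make_matrix(values), gold)
        assert scores.size == 20
        assert labels.sum() == 3

    def test_gold_pair_with_unscored_herb_excluded(self, caplog):
        values = {"h0": {"d0": 1.0, "d1": 2.0}}
        gold = GoldStandard(frozenset({("h0", "d0"), ("ghost", "d1")}))
        with caplog.at_level("WARNING"):
            scores, labels = label_and_orient(make_matrix(values), gold)
        assert labels.sum() == 1
        assert "1 of 2 gold pairs" in caplog.text

    def test_undefined_cells_are_not_ranked(self):
        values = {"h0": {"d0": 1.0, "d1": float("nan")}, "h1": {"d0": 2.0, "d1": 3.0}}
        gold = GoldStandard(frozenset({("h0", "d0")}))
        scores, labels = label_and_orient(make_matrix(values), gold)
        assert scores.size == 3

    def test_no_matched_positives_is_an_error(self):
        values = {"h0": {"d0": 1.0}}
        with pytest.raises(EvaluationError):
            label_and_orient(make_matrix(values), GoldStandard(frozenset({("x", "y")})))


class TestAuroc:
    def test_perfect_separation(self):
        scores = np.array([0.5, 0.6, 2.0, 3.0])
        labels = np.array([1, 1, 0, 0])
        assert auroc(scores, labels) == 1.0

    def test_all_ties_give_half(self):
        assert auroc(np.ones(10), np.array([1] * 3 + [0] * 7)) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            auroc(np.array([1.0, 2.0]), np.array([1, 1]))

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_matches_pairwise_counting_oracle(self, seed):
        scores, labels = random_scores(seed, 30, 9)
        scores = np.round(scores, 1)  # force some ties
        assert auroc(scores, labels) == pytest.approx(pairwise_auroc(scores, labels))

    def test_negation_flips_auroc(self):
        scores, labels = random_scores(8, 40, 10)
        assert auroc(-scores, labels) == pytest.approx(1 - auroc(scores, labels))

    @pytest.mark.parametrize(
        "transform", [lambda s: 2 * s + 1, np.exp, lambda s: s**3]
    )
    def test_invariant_under_strictly_monotone_transform(self, transform):
        scores, labels = random_scores(13, 50, 12)
        assert auroc(transform(scores), labels) == pytest.approx(auroc(scores, labels))

    def test_shuffled_labels_concentrate_at_half(self):
        scores, labels = random_scores(0, 200, 50)
        rng = np.random.default_rng(99)
        values = []
        for _ in range(20):
            shuffled = rng.permutation(labels)
            values.append(auroc(scores, shuffled))
        n_pos, n_neg = labels.sum(), (1 - labels).sum()
        se_null = math.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
        assert abs(np.mean(values) - 0.5) <= 3 * se_null / math.sqrt(20)


class TestAuprc:
    def test_perfect_ranking(self):
        scores = np.arange(10, dtype=float)
        labels = np.array([1, 1] + [0] * 8)
        assert auprc(scores, labels) == 1.0

    def test_baseline_precision_is_positive_rate(self):
        assert baseline_precision(3, 12) == pytest.approx(0.25)
        with pytest.raises(ValueError):
            baseline_precision(5, 4)

    @pytest.mark.parametrize("seed", [9, 10, 11])
    def test_matches_step_summation_oracle(self, seed):
        scores, labels = random_scores(seed, 40, 8)
        assert auprc(scores, labels) == pytest.approx(step_auprc(scores, labels))

    def test_no_positives_rejected(self):
        with pytest.raises(EvaluationError):
            auprc(np.array([1.0, 2.0]), np.array([0, 0]))

    def test_beats_baseline_on_planted_signal(self):
        rng = np.random.default_rng(21)
        labels = np.array([1] * 10 + [0] * 90)
        scores = np.where(labels == 1, rng.normal(1, 1, 100), rng.normal(3, 1, 100))
        assert auprc(scores, labels) > baseline_precision(10, 100)


class TestThresholdAtFpr:
    def test_target_one_returns_maximum_score(self):
        scores, labels = random_scores(17, 30, 5)
        result = threshold_at_fpr(roc_points(scores, labels), 1.0)
        assert result.threshold == pytest.approx(scores.max())

    def test_one_negative_in_twenty_at_five_percent(self):
        scores = np.concatenate([[0.5], np.arange(1, 21, dtype=float)])
        labels = np.array([1] + [0] * 20)
        result = threshold_at_fpr(roc_points(scores, labels), 0.05)
        assert result.threshold == pytest.approx(1.0)
        assert result.fpr == pytest.approx(1 / 20)

    @pytest.mark.parametrize("target", [0.01, 0.05, 0.1, 0.25])
    def test_matches_exhaustive_scan(self, target):
        scores, labels = random_scores(17, 200, 40)
        result = threshold_at_fpr(roc_points(scores, labels), target)
        expected_thr, expected_recall = scan_threshold(scores, labels, target)
        assert result.threshold == pytest.approx(expected_thr)
        assert result.recall == pytest.approx(expected_recall)

    @pytest.mark.parametrize("seed", range(6))
    def test_achieved_fpr_never_exceeds_target(self, seed):
        scores, labels = random_scores(seed, 80, 15)
        for target in (0.02, 0.05, 0.2, 0.7):
            result = threshold_at_fpr(roc_points(scores, labels), target)
            neg = scores[labels == 0]
            assert np.mean(neg <= result.threshold) <= target

    @pytest.mark.parametrize("target", [0.0, -0.1, 1.5])
    def test_invalid_target_rejected(self, target):
        scores, labels = random_scores(1, 10, 3)
        with pytest.raises(ValueError):
            threshold_at_fpr(roc_points(scores, labels), target)


class TestPerEntityAuroc:
    def test_known_diseases_ranked_first_give_one(self):
        values = {"h0": {f"d{k}": float(k) for k in range(6)}}
        gold = GoldStandard(frozenset({("h0", "d0"), ("h0", "d1"), ("h0", "d2")}))
        result = per_entity_auroc(make_matrix(values), gold, axis="herb")
        assert result == {"h0": 1.0}

    def test_entity_without_positives_omitted(self):
        values = {
            "h0": {"d0": 1.0, "d1": 2.0},
            "h1": {"d0": 1.0, "d1": 2.0},
        }
        gold = GoldStandard(frozenset({("h0", "d0")}))
        assert set(per_entity_auroc(make_matrix(values), gold, "herb")) == {"h0"}

    def test_entity_without_negatives_omitted(self):
        values = {"h0": {"d0": 1.0, "d1": 2.0}}
        gold = GoldStandard(frozenset({("h0", "d0"), ("h0", "d1")}))
        assert per_entity_auroc(make_matrix(values), gold, "herb") == {}

    def test_consistent_with_global_auroc_on_each_slice(self):
        rng = np.random.default_rng(21)
        values = {
            f"h{i}": {f"d{k}": float(v) for k, v in enumerate(rng.random(10))}
            for i in range(20)
        }
        pairs = {
            (f"h{i}", f"d{k}")
            for i, k in zip(rng.integers(20, size=30), rng.integers(10, size=30))
        }
        gold = GoldStandard(frozenset(pairs))
        matrix = make_matrix(values)
        per_herb = per_entity_auroc(matrix, gold, "herb")
        assert per_herb  # fixture must exercise at least one herb
        for herb, value in per_herb.items():
            row = matrix.values.loc[herb]
            labels = np.array([(herb, d) in gold for d in row.index], dtype=int)
            assert value == pytest.approx(auroc(row.to_numpy(), labels))

    def test_disease_axis_slices_columns(self):
        values = {
            "h0": {"d0": 0.5, "d1": 5.0},
            "h1": {"d0": 4.0, "d1": 1.0},
        }
        gold = GoldStandard(frozenset({("h0", "d0")}))
        assert per_entity_auroc(make_matrix(values), gold, "disease") == {"d0": 1.0}


class TestAurocCountCorrelation:
    def test_zero_variance_is_undefined(self):
        per_entity = {"h0": 0.7, "h1": 0.7, "h2": 0.7}
        gold = GoldStandard(frozenset({("h0", "d0"), ("h1", "d0"), ("h2", "d0")}))
        with pytest.raises(UndefinedCorrelationError):
            auroc_vs_count_correlation(per_entity, gold, "herb")

    def test_perfect_linearity(self):
        per_entity = {"h0": 0.1, "h1": 0.2, "h2": 0.3}
        # gold-partner counts 1, 2, 3 rise linearly with the AUROCs
        pairs = {
            ("h0", "d9"),
            ("h1", "d0"), ("h1", "d1"),
            ("h2", "d0"), ("h2", "d1"), ("h2", "d2"),
        }
        gold = GoldStandard(frozenset(pairs))
        r, p = auroc_vs_count_correlation(per_entity, gold, "herb")
        assert r == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        entities = [f"h{i}" for i in range(50)]
        per_entity = {e: float(v) for e, v in zip(entities, rng.random(50))}
        counts = rng.integers(1, 8, size=50)
        pairs = {
            (e, f"d{j}") for e, c in zip(entities, counts) for j in range(c)
        }
        gold = GoldStandard(frozenset(pairs))
        r, p = auroc_vs_count_correlation(per_entity, gold, "herb")
        x = np.array([per_entity[e] for e in sorted(per_entity)])
        y = np.array([len(gold.diseases_of(e)) for e in sorted(per_entity)], dtype=float)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected_r = cov / (x.std() * y.std())
        assert r == pytest.approx(expected_r)
        t = expected_r * math.sqrt(48 / (1 - expected_r**2))
        expected_p = 2 * stats.t.sf(abs(t), df=48)
        assert p == pytest.approx(expected_p)

    def test_needs_three_entities(self):
        with pytest.raises(EvaluationError):
            auroc_vs_count_correlation({"h0": 0.5, "h1": 0.6}, GoldStandard(frozenset()), "herb")


def _reliability_fixture():
    """15 herbs, exactly two of which satisfy all three selection rules."""
    rng = np.random.default_rng(31)
    diseases = [f"d{k}" for k in range(6)]
    values, gold_pairs, per_herb = {}, set(), {}
    for i in range(15):
        herb = f"h{i:02d}"
        values[herb] = {d: float(v) for d, v in zip(diseases, 2.0 + rng.random(6))}
        per_herb[herb] = 0.5
    for herb, aur, known in [
        ("h00", 0.95, ["d0", "d1", "d2"]),   # qualifies
        ("h01", 0.93, ["d1", "d2", "d3"]),   # qualifies
        ("h02", 0.97, ["d0", "d1"]),         # too few known diseases
        ("h03", 0.85, ["d0", "d1", "d2"]),   # AUROC below the bar
        ("h04", 0.96, ["d0", "d1", "d2"]),   # one known score above threshold
    ]:
        per_herb[herb] = aur
        for d in known:
            gold_pairs.add((herb, d))
            values[herb][d] = 1.0
    values["h04"]["d2"] = 1.9  # above the 1.5 threshold
    return make_matrix(values), GoldStandard(frozenset(gold_pairs)), per_herb


class TestSelectReliableHerbs:
    def test_all_rules_must_hold(self):
        matrix, gold, per_herb = _reliability_fixture()
        selected = select_reliable_herbs(
            per_herb, matrix, gold, auroc_min=0.9, min_known=3, wacp_threshold=1.5
        )
        assert selected == [("h00", 0.95), ("h01", 0.93)]

    def test_sorted_by_auroc_then_id(self):
        matrix, gold, per_herb = _reliability_fixture()
        per_herb["h01"] = 0.95  # tie with h00
        selected = select_reliable_herbs(
            per_herb, matrix, gold, auroc_min=0.9, min_known=3, wacp_threshold=1.5
        )
        assert [h for h, _ in selected] == ["h00", "h01"]

    def test_threshold_is_required(self):
        matrix, gold, per_herb = _reliability_fixture()
        with pytest.raises(ValueError):
            select_reliable_herbs(per_herb, matrix, gold)


class TestDiscoverNovel:
    def test_rule_boundaries(self):
        values = {
            "h0": {"d0": 1.0, "d1": 2.0, "d2": 1.2, "d3": 1.2, "d4": 1.6}
        }
        gold = GoldStandard(frozenset({("h0", "d0"), ("h0", "d1")}))
        per_disease = {"d2": 0.8, "d3": 0.6, "d4": 0.9}
        result = discover_novel(make_matrix(values), gold, per_disease, ["h0"], 0.711)
        # d2: score 1.2 < mean(1.0, 2.0) and AUROC 0.8 > 0.711 -> candidate
        # d3: AUROC 0.6 too low; d4: 1.6 above the known mean
        assert [(h, d) for h, d, _ in result.candidates] == [("h0", "d2")]

    def test_candidates_match_bruteforce_filter(self):
        rng = np.random.default_rng(31)
        herbs = [f"h{i}" for i in range(12)]
        diseases = [f"d{k}" for k in range(8)]
        values = {
            h: {d: float(v) for d, v in zip(diseases, rng.random(8) * 3)}
            for h in herbs
        }
        pairs = {
            (herbs[i], diseases[k])
            for i, k in zip(rng.integers(12, size=15), rng.integers(8, size=15))
        }
        gold = GoldStandard(frozenset(pairs))
        per_disease = {d: float(v) for d, v in zip(diseases, rng.random(8))}
        chosen = sorted({h for h, _ in pairs})[:3]
        result = discover_novel(make_matrix(values), gold, per_disease, chosen, 0.5)
        expected = set()
        for h in chosen:
            known = [values[h][d] for d in diseases if (h, d) in pairs]
            mean_known = np.mean(known)
            for d in diseases:
                if (h, d) in pairs:
                    continue
                if values[h][d] < mean_known and per_disease[d] > 0.5:
                    expected.add((h, d))
        assert {(h, d) for h, d, _ in result.candidates} == expected
        assert all((h, d) not in gold for h, d, _ in result.candidates)

    def test_herb_without_scored_known_disease_rejected(self):
        values = {"h0": {"d0": 1.0}}
        gold = GoldStandard(frozenset({("h0", "dX")}))
        with pytest.raises(EvaluationError):
            discover_novel(make_matrix(values), gold, {}, ["h0"], 0.5)


class TestRankSum:
    def test_identical_samples_not_significant(self):
        statistic, p = rank_sum_compare([1.0, 2.0], [1.0, 2.0])
        assert statistic == pytest.approx(2.0)  # the null mean n1*n2/2
        assert p > 0.9

    def test_fully_separated_four_vs_four_exact(self):
        statistic, p = rank_sum_compare([1, 2, 3, 4], [10, 11, 12, 13])
        assert p == pytest.approx(2 / 70)

    def test_exact_p_matches_rank_enumeration(self):
        known = [1.0, 2.0, 3.0, 4.0]
        other = [10.0, 11.0, 12.0, 13.0]
        _, p = rank_sum_compare(known, other)
        # enumerate all C(8,4) placements of the known sample's ranks
        pooled = sorted(known + other)
        observed = sum(pooled.index(v) + 1 for v in known)
        more_extreme = 0
        assignments = list(itertools.combinations(range(1, 9), 4))
        null_mean = 4 * 9 / 2
        for ranks in assignments:
            if abs(sum(ranks) - null_mean) >= abs(observed - null_mean):
                more_extreme += 1
        assert p == pytest.approx(more_extreme / len(assignments))

    def test_asymptotic_p_agrees_with_permutation(self):
        rng = np.random.default_rng(41)
        known = rng.normal(0.0, 1.0, size=4)
        other = rng.normal(1.2, 1.0, size=100)
        statistic, p = rank_sum_compare(known, other)
        pooled = np.concatenate([known, other])
        ranks = stats.rankdata(pooled)
        observed = ranks[:4].sum()
        null_mean = 4 * (len(pooled) + 1) / 2
        n_perm = 100_000
        perm = np.empty(n_perm)
        for i in range(n_perm):
            perm[i] = rng.permutation(ranks)[:4].sum()
        p_perm = np.mean(np.abs(perm - null_mean) >= abs(observed - null_mean) - 1e-9)
        assert p == pytest.approx(p_perm, abs=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_compare([], [1.0])


class TestEvaluateReport:
    def test_report_is_internally_consistent(self, tmp_path):
        rng = np.random.default_rng(6)
        herbs = [f"h{i}" for i in range(12)]
        diseases = [f"d{k}" for k in range(6)]
        pairs = {(h, diseases[int(rng.integers(6))]) for h in herbs[:6]}
        values = {}
        for h in herbs:
            values[h] = {}
            for d in diseases:
                strong = (h, d) in pairs
                values[h][d] = float(rng.normal(1.0 if strong else 2.5, 0.4))
        matrix = make_matrix(values)
        gold = GoldStandard(frozenset(pairs))
        report = evaluate(matrix, gold, target_fpr=0.1)
        assert report.n_pairs == 72
        assert report.n_positives == len(pairs)
        assert report.baseline_auprc == pytest.approx(len(pairs) / 72)
        assert 0 <= report.auroc <= 1
        assert report.auprc >= report.baseline_auprc  # planted signal
        fprs = [f for f, _, _ in report.roc]
        tprs = [t for _, t, _ in report.roc]
        assert fprs == sorted(fprs)
        assert tprs == sorted(tprs)
        out = tmp_path / "report.json"
        report.to_json(out)
        import json

        payload = json.loads(out.read_text())
        assert payload["auroc"] == pytest.approx(report.auroc)
        assert payload["n_pairs"] == 72
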