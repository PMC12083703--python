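import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mint.evaluation import (
    EvalConfig,
    ParsedResponse,
    avoidance_rate,
    car,
    coverage_rate,
    evaluate,
    hfa,
    match_label,
    parse_ranked_list,
    similarity,
    top1_hit,
    topn_hit,
)
from mint.label_space import LabelEntry, LabelSpace, normalize
from mint.preference import RankedPrediction, render_numbered_list

from _oracles import brute_evaluate, ro_ratio


class TestParseRankedList:
    def test_numbered_disease_block(self):
        text = ("1. Phelan-McDermid syndrome (PHMDS)\n"
                "2. Williams-Beuren syndrome (WBS)")
        resp = parse_ranked_list(text)
        assert resp.parse_ok
        assert resp.names == ["Phelan-McDermid syndrome (PHMDS)",
                              "Williams-Beuren syndrome (WBS)"]

    @pytest.mark.parametrize("marker", ["1. ", "1) ", "1] ", "1: ", "- ", "* "])
    def test_marker_styles(self, marker):
        resp = parse_ranked_list(f"{marker}colon\n")
        assert resp.parse_ok and resp.names == ["colon"]

    def test_empty_text_fails_softly(self):
        resp = parse_ranked_list("")
        assert not resp.parse_ok and resp.names == []

    def test_prose_without_list_fails_softly(self):
        resp = parse_ranked_list("The patient likely has a connective tissue disorder.")
        assert not resp.parse_ok

    def test_truncation_beyond_expected(self):
        text = "\n".join(f"{i + 1}. label {i}" for i in range(8))
        resp = parse_ranked_list(text, expected_len=5)
        assert resp.names == [f"label {i}" for i in range(5)]
        assert resp.truncated

    @settings(max_examples=80, deadline=None)
    @given(st.lists(
        st.text(alphabet="abcdefghij XYZ-,'()", min_size=1, max_size=30)
        .map(str.strip).filter(lambda s: s and not s[0].isdigit()
                               and s[0] not in "-*•"),
        min_size=1, max_size=10))
    def test_round_trip_with_renderer(self, names):
        parsed = parse_ranked_list(render_numbered_list(names))
        assert parsed.parse_ok and parsed.names == names


class TestSimilarity:
    def test_identity(self):
        assert similarity("colon", "colon") == 1.0

    def test_empty(self):
        assert similarity("colon", "") == 0.0

    def test_case_and_period_insensitive(self):
        assert similarity("Kabuki Syndrome.", "kabuki syndrome") == 1.0

    @pytest.mark.parametrize("a,b", [
        ("Simpson-golabi-behmel Syndrome, type 1",
         "Type 1 Simpson-golabi-behmel Syndrome"),
        ("colon", "bile duct"),
        ("Phelan-McDermid syndrome", "Phelan McDermid syndrome"),
        ("Williams-Beuren syndrome", "Williams syndrome"),
        ("CdLS", "Cornelia de Lange Syndrome"),
    ])
    def test_matches_reference_ratcliff_obershelp(self, a, b):
        expected = ro_ratio(normalize(a), normalize(b))
        assert similarity(a, b) == pytest.approx(expected, abs=1e-12)

    def test_reordered_name_variant_above_strict_threshold(self):
        s = similarity("Simpson-golabi-behmel Syndrome, type 1",
                       "Type 1 Simpson-golabi-behmel Syndrome")
        assert s >= 0.8


class TestMatchLabel:
    def test_abbreviation_path(self):
        entry = LabelEntry("Cornelia de Lange Syndrome", "CdLS", 0)
        assert match_label("Cornelia de Lange Syndrome (CdLS)", entry, 0.8)
        assert match_label("CdLS", entry, 0.8)

    def test_exact_canonical(self):
        entry = LabelEntry("Kabuki syndrome", None, 0)
        assert match_label("Kabuki syndrome", entry, 0.8)

    def test_unrelated_below_threshold(self):
        entry = LabelEntry("bile duct", None, 0)
        assert ro_ratio("colon", "bile duct") < 0.8
        assert not match_label("colon", entry, 0.8)

    def test_parenthesized_abbrev_with_unabbreviated_entry(self):
        # response carries "(PHMDS)" but the matched form is the full name
        entry = LabelEntry("Phelan-McDermid syndrome", "PHMDS", 0)
        assert match_label("Phelan-McDermid syndrome (PHMDS)", entry, 0.8)


def resp(names, sid="S0"):
    return ParsedResponse(sid, list(names), parse_ok=bool(names))


class TestHfa:
    def test_verbatim_names_pass(self, tissue_space):
        cfg = EvalConfig(n_top=3, k=2, q=2)
        responses = [resp([n], f"S{i}") for i, n in enumerate(tissue_space.names())]
        rate, flags = hfa(responses, tissue_space, cfg)
        assert rate == 100.0 and all(flags)

    def test_one_gibberish_among_ten(self, tissue_space):
        cfg = EvalConfig(n_top=3, k=2, q=2)
        responses = [resp(["colon"], f"S{i}") for i in range(9)]
        responses.append(resp(["zqxwvkjh pqrst"], "S9"))
        rate, flags = hfa(responses, tissue_space, cfg)
        assert rate == pytest.approx(90.0)
        assert flags == [True] * 9 + [False]

    def test_constructed_corruption_fraction(self, tissue_space):
        """Injecting one corrupted name per flagged sample sets the rate."""
        rng = np.random.default_rng(11)
        cfg = EvalConfig(n_top=3, k=2, q=2)
        names = tissue_space.names()
        responses, flagged = [], 0
        for i in range(40):
            picked = list(rng.choice(names, size=3, replace=False))
            if rng.random() < 0.3:
                picked[int(rng.integers(3))] = "xxqq zz" + str(i)
                flagged += 1
            responses.append(resp(picked, f"S{i}"))
        rate, _ = hfa(responses, tissue_space, cfg)
        assert rate == pytest.approx(100.0 * (1 - flagged / 40))

    def test_empty_set_rejected(self, tissue_space):
        with pytest.raises(ValueError):
            hfa([], tissue_space, EvalConfig())

    def test_parse_failure_fails_hfa(self, tissue_space):
        rate, flags = hfa([resp([])], tissue_space, EvalConfig())
        assert rate == 0.0


class TestTopHits:
    def test_truth_at_position_seven(self, tissue_space):
        truth = tissue_space.lookup("liver")
        names = ["colon", "breast", "kidney", "lung", "bile duct",
                 "colon", "liver", "breast", "kidney", "lung"]
        cfg = EvalConfig(n_top=10)
        assert topn_hit(resp(names), truth, cfg)
        assert not top1_hit(resp(names), truth, cfg)

    def test_truth_first(self, tissue_space):
        truth = tissue_space.lookup("liver")
        cfg = EvalConfig(n_top=10)
        r = resp(["liver", "colon"])
        assert topn_hit(r, truth, cfg) and top1_hit(r, truth, cfg)

    def test_abbreviation_only_truth(self, disease_space):
        truth = disease_space.lookup("Cornelia de Lange Syndrome")
        cfg = EvalConfig(n_top=10)
        r = resp(["CdLS", "Kabuki syndrome"])
        assert topn_hit(r, truth, cfg) and top1_hit(r, truth, cfg)

    def test_outside_window_misses(self, tissue_space):
        truth = tissue_space.lookup("liver")
        cfg = EvalConfig(n_top=3)
        assert not topn_hit(resp(["colon", "breast", "lung", "liver"]), truth, cfg)


class TestCoverageAvoidance:
    def test_full_coverage_no_overlap(self):
        cfg = EvalConfig()
        r = resp(["a1", "a2", "a3"])
        assert coverage_rate(r, ["a1", "a2", "a3", "a4"], cfg) == 1.0
        assert avoidance_rate(r, ["b1", "b2"], cfg) == 1.0

    def test_partial_overlap_arithmetic(self):
        cfg = EvalConfig()
        names = [f"t{i}" for i in range(10)]
        r = resp(names)
        top_k = names[:5] + ["x1", "x2", "x3", "x4", "x5"]
        bottom_q = names[8:] + ["y1", "y2", "y3"]
        assert coverage_rate(r, top_k, cfg) == pytest.approx(0.5)
        assert avoidance_rate(r, bottom_q, cfg) == pytest.approx(0.8)

    def test_disjoint(self):
        cfg = EvalConfig()
        r = resp(["p", "q"])
        assert coverage_rate(r, ["x", "y"], cfg) == 0.0
        assert avoidance_rate(r, ["x", "y"], cfg) == 1.0

    def test_empty_response_zeroes(self):
        cfg = EvalConfig()
        assert coverage_rate(resp([]), ["x"], cfg) == 0.0
        assert avoidance_rate(resp([]), ["x"], cfg) == 0.0

    def test_each_response_name_countable_once(self):
        # three copies of one top-k member still count as a single pair
        cfg = EvalConfig()
        r = resp(["dup", "dup", "dup"])
        assert coverage_rate(r, ["dup", "other"], cfg) == pytest.approx(1 / 3)


class TestCar:
    def test_single_sample_scalar_oracle(self):
        assert car([(0.5, 0.8)], 1.0) == pytest.approx(2 * 0.5 * 0.8 / 1.3)
        assert car([(0.5, 0.8)], 1.0) == pytest.approx(0.6153846153846154)

    def test_equal_rates_harmonic_fixed_point(self):
        for c in (0.2, 0.5, 0.9):
            assert car([(c, c)] * 7, 1.0) == pytest.approx(c)

    def test_zero_coverage_gives_zero(self):
        assert car([(0.0, 0.7), (0.0, 1.0)], 1.0) == 0.0

    def test_zero_denominator_term_is_zero(self):
        assert car([(0.0, 0.0)], 1.0) == 0.0

    def test_symmetry_under_swap_and_lambda_inversion(self):
        """(C,A,lambda) -> (A,C,1/lambda) leaves CAR unchanged."""
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n = int(rng.integers(1, 6))
            pairs = [(float(rng.uniform()), float(rng.uniform())) for _ in range(n)]
            lam = float(rng.uniform(0.05, 20.0))
            swapped = [(a, c) for c, a in pairs]
            assert car(pairs, lam) == pytest.approx(car(swapped, 1.0 / lam), abs=1e-12)

    def test_lambda_limits_recover_components(self):
        pairs = [(0.3, 0.9), (0.6, 0.5)]
        c_mean = sum(c for c, _ in pairs) / 2
        a_mean = sum(a for _, a in pairs) / 2
        assert car(pairs, 1e-8) == pytest.approx(c_mean, abs=1e-6)
        assert car(pairs, 1e8) == pytest.approx(a_mean, abs=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            car([], 1.0)


def _random_instance(rng, n_labels, n_resp):
    labels = [f"name{i}" for i in range(n_labels)]
    probs = rng.dirichlet(np.ones(n_labels))
    truth = labels[int(rng.integers(n_labels))]
    k = int(rng.integers(1, max(2, n_labels // 2)))
    q = int(rng.integers(1, n_labels - k + 1))
    n_top = int(rng.integers(1, 7))
    pool = labels + ["zz gibberish", "made-up disease"]
    names = [str(rng.choice(pool)) for _ in range(n_resp)]
    return labels, probs, truth, k, q, n_top, names


class TestEvaluatePipeline:
    def _setup(self, space, preds, names_by_id):
        responses = [resp(v, k) for k, v in names_by_id.items()]
        truths = {p.sample_id: p.true_label for p in preds}
        return responses, truths, {p.sample_id: p for p in preds}

    def test_oracle_responder_perfect_scores(self, tissue_space):
        """Emitting T_k verbatim, truth first: every rate 100, CAR 1."""
        rng = np.random.default_rng(3)
        names = tissue_space.names()
        preds, names_by_id = [], {}
        from mint.preference import enforce_truth_first, rank_labels
        for i in range(20):
            probs = rng.dirichlet(np.ones(len(names)))
            scores = {n: float(x) for n, x in zip(names, probs)}
            truth = max(scores, key=scores.get)  # keeps T_k, B_q disjoint
            p = RankedPrediction(f"S{i}", scores, truth)
            preds.append(p)
            ranked = rank_labels(p, tissue_space)
            names_by_id[f"S{i}"] = enforce_truth_first(ranked, p.true_label, 3)
        cfg = EvalConfig(n_top=3, k=3, q=3)
        report = evaluate(*self._setup(tissue_space, preds, names_by_id),
                          tissue_space, cfg)
        assert report.hfa_rate == report.topn_rate == report.top1_rate == 100.0
        assert report.car == pytest.approx(1.0)

    def test_bottom_q_responder_zero_scores(self, tissue_space):
        rng = np.random.default_rng(4)
        names = tissue_space.names()
        preds, names_by_id = [], {}
        from mint.preference import rank_labels
        for i in range(20):
            probs = rng.dirichlet(np.ones(len(names)))
            truth = names[int(rng.integers(len(names)))]
            p = RankedPrediction(f"S{i}", {n: float(x) for n, x in zip(names, probs)},
                                 truth)
            ranked = rank_labels(p, tissue_space)
            bottom = [b for b in reversed(ranked[-3:]) if b != truth][:2]
            preds.append(p)
            names_by_id[f"S{i}"] = bottom
        cfg = EvalConfig(n_top=2, k=2, q=3)
        report = evaluate(*self._setup(tissue_space, preds, names_by_id),
                          tissue_space, cfg)
        assert report.top1_rate == 0.0
        assert report.car == pytest.approx(0.0)

    def test_id_mismatch_rejected(self, tissue_space):
        p = RankedPrediction("S0", {n: 1 / 6 for n in tissue_space.names()}, "colon")
        responses = [resp(["colon"], "WRONG")]
        with pytest.raises(KeyError, match="WRONG"):
            evaluate(responses, {"S0": "colon"}, {"S0": p}, tissue_space,
                     EvalConfig(k=2, q=2))

    def test_exact_threshold_matches_brute_force_oracle(self):
        """500 random small instances, threshold 1.0 vs set arithmetic."""
        rng = np.random.default_rng(99)
        for trial in range(500):
            n_labels = int(rng.integers(4, 13))
            n_resp = int(rng.integers(1, 7))
            labels, probs, truth, k, q, n_top, names = _random_instance(
                rng, n_labels, n_resp)
            space = LabelSpace.from_names(labels)
            pred = RankedPrediction(
                "S0", {n: float(p) for n, p in zip(labels, probs)}, truth)
            cfg = EvalConfig(n_top=n_top, k=k, q=q, hfa_threshold=1.0,
                             match_threshold=1.0)
            report = evaluate([resp(names)], {"S0": truth}, {"S0": pred},
                              space, cfg)
            from mint.preference import enforce_truth_first, rank_labels
            ranked = rank_labels(pred, space)
            inst = {
                "names": names, "labels": labels, "truth": truth,
                "n_top": n_top,
                "top_k": enforce_truth_first(ranked, truth, k),
                "bottom_q": list(reversed(ranked[-q:])),
            }
            o_hfa, o_topn, o_top1, o_car = brute_evaluate([inst], 1.0)
            assert report.hfa_rate == pytest.approx(o_hfa), trial
            assert report.topn_rate == pytest.approx(o_topn), trial
            assert report.top1_rate == pytest.approx(o_top1), trial
            assert report.car == pytest.approx(o_car, abs=1e-12), trial

    def test_chain_constraint_many_runs(self, tissue_space):
        """top1 <= topN <= HFA on every randomized evaluation run."""
        rng = np.random.default_rng(7)
        names = tissue_space.names()
        for run in range(30):
            preds, names_by_id = [], {}
            for i in range(15):
                probs = rng.dirichlet(np.ones(len(names)))
                p = RankedPrediction(
                    f"S{i}", {n: float(x) for n, x in zip(names, probs)},
                    names[int(rng.integers(len(names)))])
                preds.append(p)
                pool = names + ["fabricated thing"]
                names_by_id[f"S{i}"] = [str(rng.choice(pool))
                                        for _ in range(int(rng.integers(0, 5)))]
            report = evaluate(*self._setup(tissue_space, preds, names_by_id),
                              tissue_space, EvalConfig(n_top=3, k=2, q=2))
            assert report.top1_rate <= report.topn_rate <= report.hfa_rate

    def test_car_monotone_in_name_substitution(self, tissue_space):
        """Swapping a non-matching name for a bottom-q member never raises CAR."""
        names = tissue_space.names()
        probs = np.linspace(6, 1, 6)
        probs = probs / probs.sum()
        pred = RankedPrediction("S0", {n: float(p) for n, p in zip(names, probs)},
                                names[0])
        from mint.preference import enforce_truth_first, rank_labels
        ranked = rank_labels(pred, tissue_space)
        cfg = EvalConfig(n_top=3, k=2, q=2)
        bottom_q = list(reversed(ranked[-2:]))
        top_k = enforce_truth_first(ranked, names[0], 2)
        base_names = [top_k[0], "fabricated thing", "another fake"]
        base = evaluate([resp(base_names)], {"S0": names[0]}, {"S0": pred},
                        tissue_space, cfg).car
        worse_names = [top_k[0], bottom_q[0], "another fake"]
        worse = evaluate([resp(worse_names)], {"S0": names[0]}, {"S0": pred},
                         tissue_space, cfg).car
        assert worse <= base
        better_names = [top_k[0], top_k[1], "another fake"]
        better = evaluate([resp(better_names)], {"S0": names[0]}, {"S0": pred},
                          tissue_space, cfg)
        assert better.per_sample[0].coverage >= base


def test_evalconfig_threshold_ordering_enforced():
    with pytest.raises(ValueError):
        EvalConfig(hfa_threshold=0.9, match_threshold=0.8)
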