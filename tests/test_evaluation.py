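"""Confusion counts over covered items, error metrics, event aggregation, sweeps."""

import numpy as np
import pandas as pd
import pytest

from trapsift import (
    ConfusionCounts,
    Label,
    ModelProfile,
    SchemeId,
    SchemeResult,
    SyntheticConfig,
    TernaryDecision,
    ThresholdPolicy,
    asymmetric_group_preset,
    compute_confusion,
    compute_metrics,
    coverage,
    evaluate,
    event_decision,
    event_truth,
    generate,
    run_scheme,
    threshold_sweep,
)
from trapsift.metrics import REPORT_COLUMNS, report_frame, write_report

from conftest import SIX_MODELS, make_manifest, six_prob_row

E, A, X = TernaryDecision.EMPTY, TernaryDecision.ANIMAL, TernaryDecision.UNCERTAIN


def result_from_codes(codes):
    codes = np.asarray(codes, dtype=np.int8)
    ids = [f"i{k}" for k in range(len(codes))]
    return SchemeResult(
        scheme=SchemeId.SCHEME_I, delta=0.95, image_ids=ids, event_ids=ids, codes=codes
    )


class TestCoverage:
    def test_worked_example(self):
        # 100 predictions, 80 accepted -> coverage 80%
        assert coverage(result_from_codes([0] * 50 + [1] * 30 + [2] * 20)) == 0.80

    def test_extremes(self):
        assert coverage(result_from_codes([2, 2, 2])) == 0.0
        assert coverage(result_from_codes([0, 1, 1])) == 1.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            coverage(result_from_codes([]))


class TestComputeConfusion:
    def test_direct_tabulation(self):
        result = result_from_codes([1, 0, 0, 2])
        truths = {"i0": Label.ANIMAL, "i1": Label.ANIMAL, "i2": Label.EMPTY, "i3": Label.EMPTY}
        c = compute_confusion(result, truths)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 1, 1)
        assert c.n_uncertain == 1
        assert c.n_empty_total == 2  # abstained empty image still counts in N_e

    def test_perfect_predictor(self):
        result = result_from_codes([1, 1, 0, 0])
        truths = {"i0": Label.ANIMAL, "i1": Label.ANIMAL, "i2": Label.EMPTY, "i3": Label.EMPTY}
        c = compute_confusion(result, truths)
        assert c.fn == 0 and c.fp == 0

    def test_missing_truth_raises(self):
        with pytest.raises(ValueError, match="missing truth"):
            compute_confusion(result_from_codes([1]), {})

    def test_counts_conserve_total_on_random_tables(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 500))
            codes = rng.integers(0, 3, size=n).astype(np.int8)
            truth_animal = rng.random(n) < 0.3
            result = result_from_codes(codes)
            truths = {
                f"i{k}": (Label.ANIMAL if t else Label.EMPTY)
                for k, t in enumerate(truth_animal)
            }
            c = compute_confusion(result, truths)
            # brute-force recount
            tp = fp = fn = tn = unc = 0
            for code, t in zip(codes, truth_animal):
                if code == 2:
                    unc += 1
                elif code == 1:
                    tp, fp = tp + t, fp + (not t)
                else:
                    fn, tn = fn + t, tn + (not t)
            assert (c.tp, c.fp, c.fn, c.tn, c.n_uncertain) == (tp, fp, fn, tn, unc)
            assert c.tp + c.fp + c.fn + c.tn + c.n_uncertain == n
            assert c.n_empty_total == int((~truth_animal).sum())


class TestComputeMetrics:
    def test_hand_arithmetic(self):
        c = ConfusionCounts(tp=90, fp=10, fn=5, tn=95, n_uncertain=0, n_empty_total=120)
        m = compute_metrics(c)
        assert m.e_oa == pytest.approx(5 / 95)
        assert m.e_ce == pytest.approx(5 / 100)
        assert m.e_ov == pytest.approx(15 / 200)
        assert m.e_ca == pytest.approx(10 / 100)
        assert m.r_re == pytest.approx(95 / 120)
        assert m.coverage == 1.0

    def test_no_false_negatives(self):
        c = ConfusionCounts(tp=10, fp=2, fn=0, tn=8, n_uncertain=0, n_empty_total=10)
        m = compute_metrics(c)
        assert m.e_oa == 0.0 and m.e_ce == 0.0

    def test_zero_denominators_are_undefined_not_zero(self):
        c = ConfusionCounts(tp=0, fp=0, fn=0, tn=0, n_uncertain=5, n_empty_total=0)
        m = compute_metrics(c)
        assert m.e_ca is None and m.e_oa is None and m.e_ov is None
        assert m.e_ce is None and m.r_re is None
        assert m.coverage == 0.0

    def test_omission_error_equals_one_minus_recall(self, rng):
        for _ in range(50):
            tp, fp, fn, tn = (int(x) for x in rng.integers(0, 200, size=4))
            c = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn,
                                n_uncertain=int(rng.integers(0, 50)),
                                n_empty_total=fp + tn + int(rng.integers(0, 20)))
            m = compute_metrics(c)
            if tp + fn:
                assert m.e_oa == pytest.approx(1 - tp / (tp + fn))
            else:
                assert m.e_oa is None


class TestEventRules:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            ([Label.EMPTY] * 3, Label.EMPTY),
            ([Label.EMPTY, Label.ANIMAL, Label.EMPTY], Label.ANIMAL),
            ([Label.ANIMAL], Label.ANIMAL),
        ],
    )
    def test_event_truth(self, labels, expected):
        assert event_truth(labels) is expected

    @pytest.mark.parametrize(
        "decisions, expected",
        [
            ([E, E, E], E),
            ([E, A, X], A),
            ([E, X, E], X),  # cannot certify empty with an abstention
            ([A], A),
        ],
    )
    def test_event_decision(self, decisions, expected):
        assert event_decision(decisions) is expected

    def test_empty_event_rejected(self):
        with pytest.raises(ValueError):
            event_truth([])
        with pytest.raises(ValueError):
            event_decision([])


def perfect_config(n_events=150, seed=0):
    """All models always right and essentially always confident."""
    profiles = {
        m: ModelProfile(
            accuracy_on_empty=1.0,
            accuracy_on_animal=1.0,
            confidence_when_correct=(1000.0, 1.0),
        )
        for m in SIX_MODELS
    }
    return SyntheticConfig(n_events=n_events, model_profiles=profiles,
                           correlation=0.0, seed=seed)


class TestEvaluate:
    def test_perfect_manifest_all_schemes_zero_error(self):
        m = generate(perfect_config())
        for scheme in SchemeId:
            for level in ("image", "event"):
                report, counts = evaluate(m, scheme, ThresholdPolicy(0.95), level)
                assert report.e_oa == 0.0 and report.e_ca == 0.0
                assert report.e_ov == 0.0 and report.e_ce == 0.0
                assert report.r_re == 1.0
                assert report.coverage == 1.0
                assert counts.fn == 0 and counts.fp == 0

    def test_group2_abstaining_gives_scheme_ii_zero_coverage(self):
        rows = [
            six_prob_row(f"i{k}", f"e{k}", (0.99, 0.99, 0.99, 0.6, 0.6, 0.6),
                         truth="animal")
            for k in range(4)
        ]
        m = make_manifest(rows)
        report, counts = evaluate(m, SchemeId.SCHEME_II, ThresholdPolicy(0.95))
        assert report.coverage == 0.0
        assert counts.n_uncertain == 4

    def test_event_level_empty_requires_all_images_empty(self):
        # one event: two empty-decided images + one abstention => event uncertain
        rows = [
            six_prob_row("i1", "ev", [0.01] * 6, truth="empty"),
            six_prob_row("i2", "ev", [0.01] * 6, truth="empty"),
            six_prob_row("i3", "ev", [0.60] * 6, truth="empty"),
        ]
        m = make_manifest(rows)
        report, counts = evaluate(m, SchemeId.SCHEME_I, ThresholdPolicy(0.95), "event")
        assert counts.n_uncertain == 1 and counts.tn == 0
        assert report.coverage == 0.0

    def test_event_level_matches_per_event_recount(self):
        m = generate(asymmetric_group_preset(n_events=200, seed=9))
        scheme, policy = SchemeId.SCHEME_III, ThresholdPolicy(0.95)
        _, counts = evaluate(m, scheme, policy, "event")
        # oracle: recount by looping over events with the scalar rules
        result = run_scheme(m, scheme, policy)
        decisions = result.decisions
        truths = m.truths()
        per_event = {}
        for _, row in m.frame.iterrows():
            per_event.setdefault(row["event_id"], []).append(row["image_id"])
        tp = fp = fn = tn = unc = ne = 0
        for imgs in per_event.values():
            t = event_truth([truths[i] for i in imgs])
            d = event_decision([decisions[i] for i in imgs])
            ne += t is Label.EMPTY
            if d is X:
                unc += 1
            elif d is A:
                tp, fp = tp + (t is Label.ANIMAL), fp + (t is Label.EMPTY)
            else:
                fn, tn = fn + (t is Label.ANIMAL), tn + (t is Label.EMPTY)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (tp, fp, fn, tn)
        assert counts.n_uncertain == unc and counts.n_empty_total == ne

    def test_removal_rate_and_fn_orderings(self):
        for seed in (0, 1, 2):
            m = generate(asymmetric_group_preset(n_events=250, seed=seed))
            reports = {}
            counts = {}
            for s in (SchemeId.SCHEME_I, SchemeId.SCHEME_II, SchemeId.SCHEME_III):
                reports[s], counts[s] = evaluate(m, s, ThresholdPolicy(0.95))
            for other in (SchemeId.SCHEME_II, SchemeId.SCHEME_III):
                assert counts[SchemeId.SCHEME_I].fn <= counts[other].fn
                assert reports[SchemeId.SCHEME_I].r_re <= reports[other].r_re

    def test_bad_level_rejected(self, preset_manifest):
        with pytest.raises(ValueError, match="level"):
            evaluate(preset_manifest, SchemeId.SCHEME_I, level="site")


class TestThresholdSweep:
    def test_grid_shape_and_columns(self, preset_manifest):
        deltas = [0.5, 0.9, 0.95, 0.9725]
        table = threshold_sweep(preset_manifest, list(SchemeId), deltas)
        assert list(table.columns) == REPORT_COLUMNS
        assert len(table) == len(SchemeId) * len(deltas)

    def test_coverage_non_increasing_in_delta(self, preset_manifest):
        deltas = [0.5, 0.9, 0.95, 0.9725]
        table = threshold_sweep(preset_manifest, list(SchemeId), deltas)
        for _, grp in table.groupby("scheme"):
            cov = grp.sort_values("delta")["coverage"].to_numpy(dtype=float)
            assert (np.diff(cov) <= 1e-12).all()

    def test_half_threshold_abstains_only_on_double_disagreement(self, preset_manifest):
        """At delta = 0.5 no base model abstains, so the complementary rule is
        uncertain exactly on images where both trios disagree internally."""
        m = preset_manifest
        result = run_scheme(m, SchemeId.SCHEME_III, ThresholdPolicy(0.5))
        votes = m.frame[m.model_ids].to_numpy() >= 0.5
        trio1_split = votes[:, :3].any(axis=1) & ~votes[:, :3].all(axis=1)
        trio2_split = votes[:, 3:].any(axis=1) & ~votes[:, 3:].all(axis=1)
        np.testing.assert_array_equal(result.codes == 2, trio1_split & trio2_split)
        # scheme IV then covers everything at any threshold
        table = threshold_sweep(m, [SchemeId.SCHEME_IV], [0.5, 0.95])
        assert (table["coverage"] == 1.0).all()

    def test_single_image_manifest(self):
        m = make_manifest([six_prob_row("i1", "e1", [0.9] * 6, truth="animal")])
        table = threshold_sweep(m, list(SchemeId), [0.5, 0.95])
        assert len(table) == 8

    def test_invalid_delta_rejected(self, preset_manifest):
        with pytest.raises(ValueError):
            threshold_sweep(preset_manifest, [SchemeId.SCHEME_I], [0.4])


class TestReportOutput:
    def test_percent_rendering_and_na(self, tmp_path):
        c = ConfusionCounts(tp=0, fp=0, fn=0, tn=0, n_uncertain=3, n_empty_total=0)
        frame = report_frame(SchemeId.SCHEME_I, "image", 0.95, compute_metrics(c), c)
        out = tmp_path / "report.csv"
        write_report(frame, out)
        df = pd.read_csv(out, dtype=str, keep_default_na=False)
        assert df.loc[0, "e_oa_pct"] == "NA"
        assert df.loc[0, "coverage_pct"] == "0.00"
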