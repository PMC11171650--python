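"""Grouping schemes, comparative statistics, ROC and the decision rule."""

import numpy as np
import pytest

from dermfractal import (
    FULL_CLASS_COUNTS,
    InsufficientDataError,
    LesionRecord,
    VocabularyError,
    assign_groups,
    compare_groups,
    decide,
    get_scheme,
    group_counts,
    median_ci,
    roc_curve,
    screen_cohort,
)


def records_from_counts(counts: dict[str, int], fd: float = 1.7):
    return [
        LesionRecord(f"{d}-{i}", d, fd)
        for d, n in counts.items()
        for i in range(n)
    ]


def make_records(fds_by_dx: dict[str, list[float]]):
    return [
        LesionRecord(f"{d}-{i}", d, fd)
        for d, fds in fds_by_dx.items()
        for i, fd in enumerate(fds)
    ]


class TestSchemes:
    def test_nevus_is_benign_and_breslow_is_melanoma(self):
        bm = get_scheme("benign_malignant")
        assert bm.group_of("nevus") == "benign"
        mnm = get_scheme("melanoma_nonmelanoma")
        for d in ("Breslow 1", "Breslow 2", "Breslow 3", "metastatic melanoma"):
            assert mnm.group_of(d) == "melanoma"

    def test_unknown_diagnosis_raises_and_names_label(self):
        bm = get_scheme("benign_malignant")
        with pytest.raises(VocabularyError, match="unknown-lesion"):
            assign_groups([LesionRecord("x", "unknown-lesion", 1.7)], bm)

    def test_published_cohort_counts_reproduce_all_group_totals(self):
        records = records_from_counts(FULL_CLASS_COUNTS)
        bm = group_counts(records, get_scheme("benign_malignant"))
        assert bm["benign"] == 29050
        assert bm["malignant"] == 10220
        mnm = group_counts(records, get_scheme("melanoma_nonmelanoma"))
        assert mnm["melanoma"] == 6035
        assert mnm["non-melanoma"] == 33235
        melanoma_only = [
            r for r in records
            if get_scheme("melanoma_nonmelanoma").group_of(r.diagnosis) == "melanoma"
        ]
        mm = group_counts(melanoma_only, get_scheme("metastatic_nonmetastatic"))
        assert mm["metastatic"] == 4
        assert mm["non-metastatic"] == 6031

    def test_scc_override_moves_it_out_of_malignant(self):
        records = records_from_counts(FULL_CLASS_COUNTS)
        bm = group_counts(records, get_scheme("benign_malignant", scc_malignant=False))
        assert bm["malignant"] == 10220 - 687

    def test_group_totals_partition_the_cohort(self, two_class_cohort):
        for name in ("benign_malignant", "melanoma_nonmelanoma"):
            counts = group_counts(two_class_cohort, get_scheme(name))
            assert counts.sum() == len(two_class_cohort)

    def test_empty_record_list_gives_empty_table(self):
        assert len(group_counts([], get_scheme("benign_malignant"))) == 0


class TestCompareGroups:
    def test_extreme_separation_gives_tiny_p(self):
        rng = np.random.default_rng(0)
        recs = make_records(
            {
                "nevus": list(1.2 + 0.01 * rng.random(50)),
                "non-metastatic melanoma": list(1.9 + 0.01 * rng.random(50)),
            }
        )
        res = compare_groups(recs, get_scheme("melanoma_nonmelanoma"))
        assert res.test_name == "Mann-Whitney U"
        assert res.pvalue < 1e-6

    def test_single_group_or_tiny_group_raises(self):
        recs = make_records({"nevus": [1.6, 1.7]})
        with pytest.raises(InsufficientDataError):
            compare_groups(recs, get_scheme("benign_malignant"))
        recs2 = make_records({"nevus": [1.6, 1.7], "Breslow 3": [1.9]})
        with pytest.raises(InsufficientDataError):
            compare_groups(recs2, get_scheme("benign_malignant"))

    def test_three_groups_run_kruskal_with_dunn_pairwise(self):
        rng = np.random.default_rng(1)
        recs = make_records(
            {
                "nevus": list(1.60 + 0.05 * rng.random(40)),
                "non-metastatic melanoma": list(1.75 + 0.05 * rng.random(40)),
                "basal cell carcinoma": list(1.68 + 0.05 * rng.random(40)),
            }
        )
        # raw diagnoses: use an identity-like scheme by comparing on diagnosis
        from dermfractal import GroupingScheme

        scheme = GroupingScheme("identity", {d: d for d in set(r.diagnosis for r in recs)})
        res = compare_groups(recs, scheme, reference="non-metastatic melanoma")
        assert res.test_name == "Kruskal-Wallis"
        assert res.pairwise is not None and len(res.pairwise) == 2
        assert (res.pairwise["p_adj"] >= res.pairwise["p_raw"] - 1e-15).all()

    def test_dunn_z_matches_direct_formula_on_small_instance(self):
        from dermfractal import GroupingScheme
        from scipy import stats

        recs = make_records(
            {
                "nevus": [1.60, 1.62, 1.64, 1.66],
                "basal cell carcinoma": [1.63, 1.65, 1.67, 1.70],
                "Breslow 3": [1.80, 1.85, 1.90, 1.95],
            }
        )
        scheme = GroupingScheme("identity", {d: d for d in {r.diagnosis for r in recs}})
        res = compare_groups(recs, scheme, reference="nevus")
        # independent oracle: direct rank computation (no ties here)
        fds = {d: [r.fd for r in recs if r.diagnosis == d] for d in scheme.mapping}
        pooled = np.concatenate([fds[d] for d in sorted(fds)])
        ranks = stats.rankdata(pooled)
        groups = {}
        off = 0
        for d in sorted(fds):
            groups[d] = ranks[off : off + len(fds[d])].mean()
            off += len(fds[d])
        n = len(pooled)
        se = np.sqrt(n * (n + 1) / 12 * (1 / 4 + 1 / 4))
        for row in res.pairwise.itertuples(index=False):
            other = row.comparison.split(" vs ")[0]
            z_expected = (groups[other] - groups["nevus"]) / se
            assert row.z == pytest.approx(z_expected, abs=1e-12)

    def test_median_ci_contains_median_and_is_ordered(self):
        rng = np.random.default_rng(2)
        x = rng.normal(1.7, 0.08, 501)
        lo, hi = median_ci(x)
        assert lo <= np.median(x) <= hi


class TestRocCurve:
    def test_perfect_separation_auc_one(self):
        recs = make_records(
            {"nevus": [1.2, 1.3, 1.4], "non-metastatic melanoma": [1.6, 1.7, 1.9]}
        )
        roc = roc_curve(recs, get_scheme("melanoma_nonmelanoma"), "melanoma")
        assert roc.auc == pytest.approx(1.0, abs=1e-12)

    def test_brute_force_concordant_pair_counting(self):
        # positives 1.4,1.5,1.9 vs negatives 1.2,1.6,1.7 -> AUC = 5/9
        recs = make_records(
            {"nevus": [1.2, 1.6, 1.7], "non-metastatic melanoma": [1.4, 1.5, 1.9]}
        )
        roc = roc_curve(recs, get_scheme("melanoma_nonmelanoma"), "melanoma")
        assert roc.auc == pytest.approx(5 / 9, abs=1e-12)

    def test_auc_equals_mann_whitney_identity_with_ties(self):
        rng = np.random.default_rng(4)
        recs = make_records(
            {
                "nevus": list(np.round(rng.normal(1.65, 0.08, 300), 2)),
                "non-metastatic melanoma": list(np.round(rng.normal(1.75, 0.08, 200), 2)),
            }
        )
        recs = [r for r in recs if 1.0 < r.fd < 2.0]
        roc = roc_curve(recs, get_scheme("melanoma_nonmelanoma"), "melanoma")
        assert roc.auc == pytest.approx(roc.auc_u, abs=1e-9)

    def test_sensitivity_non_increasing_in_threshold(self, two_class_cohort):
        roc = roc_curve(two_class_cohort, get_scheme("melanoma_nonmelanoma"), "melanoma")
        assert (np.diff(roc.points["sensitivity"].to_numpy()) <= 1e-15).all()

    def test_single_class_input_rejected(self):
        recs = make_records({"nevus": [1.6, 1.7]})
        with pytest.raises(ValueError):
            roc_curve(recs, get_scheme("melanoma_nonmelanoma"), "melanoma")


class TestDecide:
    def test_two_stage_rule_and_strict_boundary(self):
        d = decide(1.90, t_malignant=1.70)
        assert (d.stage1, d.stage2) == ("malignant", "melanoma")
        d = decide(1.755, t_malignant=1.70)  # exactly at the melanoma cutoff
        assert (d.stage1, d.stage2) == ("malignant", "non-melanoma")
        d = decide(1.60, t_malignant=1.70)
        assert (d.stage1, d.stage2) == ("benign", None)

    def test_out_of_range_fd_rejected(self):
        with pytest.raises(ValueError):
            decide(2.5)

    def test_monotone_in_fd(self):
        order = {"benign": 0, "malignant": 1}
        stage2_order = {None: 0, "non-melanoma": 1, "melanoma": 2}
        prev = (-1, -1)
        for fd in np.linspace(1.01, 2.09, 200):
            d = decide(float(fd))
            cur = (order[d.stage1], stage2_order[d.stage2])
            assert cur >= prev
            prev = cur


class TestScreenCohort:
    def test_perfectly_separated_cohort_scores_perfectly(self):
        recs = make_records(
            {"nevus": [1.3, 1.4, 1.5], "basal cell carcinoma": [1.8, 1.85, 1.9]}
        )
        rep = screen_cohort(recs, t_malignant=1.6)
        assert rep.stage1.sensitivity == 1.0
        assert rep.stage1.specificity == 1.0

    def test_matches_brute_force_counting_oracle(self, two_class_cohort):
        t1, t2 = 1.70, 1.755
        rep = screen_cohort(two_class_cohort, t1, t2)
        bm = get_scheme("benign_malignant")
        mal = [r for r in two_class_cohort if bm.group_of(r.diagnosis) == "malignant"]
        ben = [r for r in two_class_cohort if bm.group_of(r.diagnosis) == "benign"]
        sens = sum(r.fd > t1 for r in mal) / len(mal)
        spec = sum(r.fd <= t1 for r in ben) / len(ben)
        assert rep.stage1.sensitivity == pytest.approx(sens, abs=0)
        assert rep.stage1.specificity == pytest.approx(spec, abs=0)

    def test_empty_cohort_raises(self):
        with pytest.raises(InsufficientDataError):
            screen_cohort([])
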