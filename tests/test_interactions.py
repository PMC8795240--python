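"""Stratified contingency statistics: chi-squared screen, Woolf IH, joint
risk, posterior risk, and the pair-selection pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import binary_matrix, sample_joint_columns

from ehrpairs import (
    StratifiedPair,
    build_contingency,
    expected_count,
    fit_nbc,
    joint_risk,
    pair_stats,
    pearson_chi2,
    posterior_risk,
    rank_report,
    sample_equal_cohorts,
    select_pairs,
    woolf_ih,
)
from ehrpairs.cohort import STRUCTURED, UNSTRUCTURED
from ehrpairs.worked_examples import example_pair

cell_counts = st.tuples(
    st.integers(1, 500), st.integers(1, 500), st.integers(1, 500), st.integers(1, 500)
)


class TestStratifiedPair:
    def test_margin_reconstruction_matches_published_row(self):
        # case margins |A|=2356, |B|=3741, a=1003 at n=23,566
        pair = example_pair("drug_abuse_x_suicide_attempts")
        assert pair.case == (1003, 1353, 2738, 18472)
        assert pair.noncase == (53, 95, 510, 22908)
        assert pair.n("case") == pair.n("noncase") == 23_566

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            StratifiedPair("a", "b", (1, -1, 2, 3), (1, 1, 1, 1))


class TestBuildContingency:
    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(0)
        n = 500
        xa, xb = sample_joint_columns(0.3, 0.2, 4.0, n, rng)
        xa2 = (rng.random(n) < 0.1).astype(int)
        X = np.column_stack([xa, xa2, xb])
        kinds = [STRUCTURED, STRUCTURED, UNSTRUCTURED]
        fids = ["A", "A2", "B|positive"]
        case_m = binary_matrix(X, np.ones(n), kinds, fids, tag="c")
        noncase_m = binary_matrix(X[::-1], np.zeros(n), kinds, fids, tag="n")
        pair = build_contingency(case_m, noncase_m, "A", "B|positive")
        a = int(((xa == 1) & (xb == 1)).sum())
        b = int(((xa == 1) & (xb == 0)).sum())
        c = int(((xa == 0) & (xb == 1)).sum())
        d = n - a - b - c
        assert pair.case == (a, b, c, d)
        assert pair.noncase == (a, b, c, d)  # reversed rows, same counts

    def test_degenerate_extremes(self):
        n = 10
        X = np.column_stack([np.ones(n), np.zeros(n)])
        m1 = binary_matrix(X, np.ones(n), [STRUCTURED, UNSTRUCTURED], ["A", "B|positive"])
        m0 = binary_matrix(X, np.zeros(n), [STRUCTURED, UNSTRUCTURED], ["A", "B|positive"])
        pair = build_contingency(m1, m0, "A", "B|positive")
        assert pair.case == (0, n, 0, 0)

    def test_unknown_feature_named_in_error(self):
        n = 4
        X = np.ones((n, 2))
        m = binary_matrix(X, np.ones(n), [STRUCTURED, UNSTRUCTURED], ["A", "B|positive"])
        with pytest.raises(KeyError, match="nope"):
            build_contingency(m, m, "nope", "B|positive")


class TestExpectedCountAndChi2:
    def test_published_noncase_expected_count(self):
        pair = example_pair("drug_abuse_x_suicide_attempts")
        e = expected_count(pair, "noncase")
        assert e == pytest.approx(148 * 563 / 23_566)
        assert f"{e:.2f}" == "3.54"

    def test_independent_table_expected_equals_actual(self):
        pair = StratifiedPair("a", "b", (6, 4, 9, 6), (6, 4, 9, 6))
        assert expected_count(pair, "case") == pytest.approx(6.0)
        t, p = pearson_chi2(pair, "case")
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_chi2(self):
        pair = StratifiedPair("a", "b", (30, 20, 20, 30), (25, 25, 25, 25))
        t, p = pearson_chi2(pair, "case")
        assert t == pytest.approx(4.0, rel=1e-12)
        t0, p0 = pearson_chi2(pair, "noncase")
        assert t0 == pytest.approx(0.0, abs=1e-12)

    def test_published_case_table_is_overwhelmingly_significant(self):
        pair = example_pair("drug_abuse_x_suicide_attempts")
        t, p = pearson_chi2(pair, "case")
        assert t > 100
        assert p < 1e-10

    @given(case=cell_counts)
    @settings(max_examples=1000)
    def test_equals_shortcut_formula(self, case):
        # oracle: T = n (ad - bc)^2 / (r1 r2 c1 c2)
        a, b, c, d = case
        pair = StratifiedPair("a", "b", case, case)
        n = a + b + c + d
        shortcut = (
            n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        )
        t, _ = pearson_chi2(pair, "case")
        assert t == pytest.approx(shortcut, rel=1e-9, abs=1e-9)

    def test_zero_margin_raises(self):
        pair = StratifiedPair("a", "b", (0, 0, 5, 5), (1, 1, 1, 1))
        with pytest.raises(ValueError, match="margin"):
            pearson_chi2(pair, "case")


class TestWoolfIH:
    def test_identical_strata_have_zero_heterogeneity(self):
        pair = StratifiedPair("a", "b", (30, 20, 10, 40), (30, 20, 10, 40))
        ih, p = woolf_ih(pair)
        assert ih == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "name,published",
        [
            ("drug_abuse_x_suicide_attempts", 77.55),
            ("suicidal_ideation_x_section_xii", 54.69),
            ("suicidal_ideation_x_schizoaffective", 52.75),
        ],
    )
    def test_published_worked_examples_within_one_percent(self, name, published):
        ih, p = woolf_ih(example_pair(name))
        assert ih == pytest.approx(published, rel=0.01)
        assert p < 1e-10

    @given(cells=cell_counts, lam=st.integers(2, 20))
    @settings(max_examples=200)
    def test_stratum_scaling_identity(self, cells, lam):
        # scaling one stratum's cells by lam scales w by lam, log OR unchanged
        from ehrpairs.interactions import _log_or_and_weight

        l1, w1 = _log_or_and_weight(*cells)
        l2, w2 = _log_or_and_weight(*(lam * x for x in cells))
        assert l2 == pytest.approx(l1, abs=1e-12)
        assert w2 == pytest.approx(lam * w1, rel=1e-12)

    def test_zero_cell_handled_by_haldane_correction(self):
        pair = StratifiedPair("a", "b", (0, 20, 10, 40), (5, 20, 10, 40))
        ih, p = woolf_ih(pair)
        assert np.isfinite(ih) and ih >= 0

    def test_empty_stratum_raises(self):
        pair = StratifiedPair("a", "b", (1, 1, 1, 1), (0, 0, 0, 0))
        with pytest.raises(ValueError, match="non-empty"):
            woolf_ih(pair)


class TestJointRisk:
    def test_equal_expectations_give_zero(self):
        pair = StratifiedPair("a", "b", (10, 10, 10, 10), (10, 10, 10, 10))
        assert joint_risk(pair) == pytest.approx(0.0)

    def test_one_decade_ratio_gives_one(self):
        # E scales with (a+c)(a+b)/n; same n, case margins sqrt(10)x larger
        pair = StratifiedPair.from_margins(
            "a", "b", case=(1000, 1000, 10), noncase=(100, 100, 1), n=10_000
        )
        assert joint_risk(pair) == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "name,published",
        [
            ("drug_abuse_x_suicide_attempts", 2.02),
            ("suicidal_ideation_x_section_xii", 2.03),
        ],
    )
    def test_published_joint_risk_to_two_decimals(self, name, published):
        assert round(joint_risk(example_pair(name)), 2) == published

    @given(case=cell_counts, noncase=cell_counts)
    @settings(max_examples=200)
    def test_swapping_strata_negates(self, case, noncase):
        p = StratifiedPair("a", "b", case, noncase)
        q = StratifiedPair("a", "b", noncase, case)
        assert joint_risk(p) == pytest.approx(-joint_risk(q), abs=1e-12)


class TestPosterior:
    def test_balanced_scaled_cells_give_half(self):
        # a1 * scale == a0
        pair = StratifiedPair("a", "b", (500, 100, 10, 10), (5, 100, 10, 10))
        assert posterior_risk(pair, case_scale=1 / 100) == pytest.approx(0.5)

    def test_identical_strata_unscaled_give_half(self):
        pair = StratifiedPair("a", "b", (7, 3, 2, 8), (7, 3, 2, 8))
        assert posterior_risk(pair, case_scale=1.0) == pytest.approx(0.5)

    def test_published_pair_posterior(self):
        pair = example_pair("drug_abuse_x_suicide_attempts")
        assert posterior_risk(pair) == pytest.approx(10.03 / 63.03, abs=1e-9)

    @given(case=cell_counts, noncase=cell_counts)
    @settings(max_examples=500)
    def test_full_bayes_chain_agrees_with_simplification(self, case, noncase):
        # independent oracle: evaluate the three-factor chain explicitly
        pair = StratifiedPair("a", "b", case, noncase)
        scale = 1 / 100
        a1, b1 = case[0] * scale, case[1] * scale
        a0, b0 = noncase[0], noncase[1]
        chain = (
            (a1 / (a1 + b1))
            * ((a1 + b1) / (a0 + b0 + a1 + b1))
            / ((a1 + a0) / (a1 + b1 + a0 + b0))
        )
        assert posterior_risk(pair, scale) == pytest.approx(chain, abs=1e-12)

    def test_no_joint_carrier_raises(self):
        pair = StratifiedPair("a", "b", (0, 5, 5, 5), (0, 5, 5, 5))
        with pytest.raises(ValueError, match="both A and B"):
            posterior_risk(pair)


class TestSampleEqualCohorts:
    @pytest.fixture
    def matrix(self):
        rng = np.random.default_rng(0)
        X = (rng.random((1100, 3)) < 0.2).astype(int)
        y = np.zeros(1100, int)
        y[:100] = 1
        return binary_matrix(
            X, y, [STRUCTURED, STRUCTURED, UNSTRUCTURED],
            ["A", "A2", "B|positive"],
        )

    def test_label_pure_equal_sizes(self, matrix):
        cases, noncases = sample_equal_cohorts(matrix, cohort_size=100, seed=0)
        assert cases.n_subjects == noncases.n_subjects == 100
        assert cases.labels.sum() == 100
        assert noncases.labels.sum() == 0
        assert len(set(cases.subject_ids)) == 100  # without replacement

    def test_default_size_is_minimum_class_count(self, matrix):
        cases, noncases = sample_equal_cohorts(matrix, seed=0)
        assert cases.n_subjects == noncases.n_subjects == 100

    def test_deterministic_under_seed(self, matrix):
        a, _ = sample_equal_cohorts(matrix, seed=3)
        b, _ = sample_equal_cohorts(matrix, seed=3)
        assert list(a.subject_ids) == list(b.subject_ids)

    def test_oversized_request_reports_maximum(self, matrix):
        with pytest.raises(ValueError, match="maximum"):
            sample_equal_cohorts(matrix, cohort_size=500)


def _screening_fixture(seed=0, n=2000):
    """Cohorts with one heterogeneous pair, one homogeneous-association
    pair, one independent pair, and a heterogeneous pair hidden behind a
    negated mention."""
    rng = np.random.default_rng(seed)
    fids = [
        "A_het", "A_hom", "A_null",
        "B_het|positive", "B_hom|positive", "B_null|positive", "B_neg|NEG",
    ]
    kinds = [STRUCTURED] * 3 + [UNSTRUCTURED] * 4

    def cohort(or_het, or_hom, tag, label):
        a_het, b_het = sample_joint_columns(0.25, 0.25, or_het, n, rng)
        a_hom, b_hom = sample_joint_columns(0.25, 0.25, or_hom, n, rng)
        a_null = (rng.random(n) < 0.25).astype(int)
        b_null = (rng.random(n) < 0.25).astype(int)
        _, b_neg = sample_joint_columns(0.25, 0.25, or_het, n, rng)
        X = np.column_stack([a_het, a_hom, a_null, b_het, b_hom, b_null, b_neg])
        return binary_matrix(X, np.full(n, label), kinds, fids, tag=tag)

    case_m = cohort(or_het=12.0, or_hom=4.0, tag="c", label=1)
    noncase_m = cohort(or_het=3.0, or_hom=4.0, tag="n", label=0)
    # a model whose scores keep every feature inside any top-k
    combined_X = np.vstack(
        [np.asarray(case_m.counts.todense()), np.asarray(noncase_m.counts.todense())]
    )
    combined = binary_matrix(
        combined_X, np.concatenate([case_m.labels, noncase_m.labels]), kinds, fids
    )
    model = fit_nbc(combined)
    return case_m, noncase_m, model


class TestSelectPairs:
    def test_only_heterogeneous_pair_survives_all_filters(self):
        case_m, noncase_m, model = _screening_fixture()
        selected, survival = select_pairs(
            case_m, noncase_m, model, top_k=10, min_joint=5
        )
        assert list(zip(selected["A"], selected["B"])) == [
            ("A_het", "B_het|positive")
        ]
        # survival counts shrink monotonically through the pipeline
        assert survival["universe"] == 12
        assert survival["mention"] == 9  # B_neg|NEG pairs removed
        assert survival["top_k"] <= survival["mention"]
        assert survival["chi2"] >= survival["ih"] >= survival["min_joint"]

    def test_homogeneous_pair_passes_chi2_but_fails_ih(self):
        case_m, noncase_m, model = _screening_fixture()
        _, survival = select_pairs(case_m, noncase_m, model, top_k=None)
        chi2_only, _ = select_pairs(
            case_m, noncase_m, model, top_k=None, alpha_ih=None, min_joint=0
        )
        pairs = set(zip(chi2_only["A"], chi2_only["B"]))
        assert ("A_hom", "B_hom|positive") in pairs
        assert survival["ih"] < survival["chi2"]

    def test_disabled_thresholds_return_mention_filtered_universe(self):
        case_m, noncase_m, model = _screening_fixture()
        selected, _ = select_pairs(
            case_m,
            noncase_m,
            model,
            top_k=None,
            alpha_chi2=None,
            alpha_ih=None,
            min_joint=0,
        )
        assert len(selected) == 9
        assert not any(selected["B"].str.endswith("|NEG"))

    def test_min_joint_excludes_sparse_pairs(self):
        # nine joint carriers in each stratum fails a threshold of ten
        n = 200
        xa = np.zeros(n, int)
        xb = np.zeros(n, int)
        xa[:40] = 1
        xb[:9] = 1
        xb[40:71] = 1  # some B-only subjects
        X = np.column_stack([xa, xb])
        case_m = binary_matrix(
            X, np.ones(n), [STRUCTURED, UNSTRUCTURED], ["A", "B|positive"], tag="c"
        )
        noncase_m = binary_matrix(
            X, np.zeros(n), [STRUCTURED, UNSTRUCTURED], ["A", "B|positive"], tag="n"
        )
        combined = binary_matrix(
            np.vstack([X, X]),
            np.concatenate([np.ones(n), np.zeros(n)]),
            [STRUCTURED, UNSTRUCTURED],
            ["A", "B|positive"],
        )
        model = fit_nbc(combined)
        kwargs = dict(top_k=None, alpha_chi2=None, alpha_ih=None)
        with_filter, _ = select_pairs(
            case_m, noncase_m, model, min_joint=10, **kwargs
        )
        without, _ = select_pairs(case_m, noncase_m, model, min_joint=9, **kwargs)
        assert len(with_filter) == 0
        assert len(without) == 1

    def test_sorted_by_ih_descending(self):
        case_m, noncase_m, model = _screening_fixture()
        selected, _ = select_pairs(
            case_m, noncase_m, model, top_k=None, alpha_chi2=None,
            alpha_ih=None, min_joint=0,
        )
        assert list(selected["ih"]) == sorted(selected["ih"], reverse=True)

    def test_row_statistics_match_per_pair_operations(self):
        case_m, noncase_m, model = _screening_fixture()
        selected, _ = select_pairs(case_m, noncase_m, model, top_k=10, min_joint=5)
        row = selected.iloc[0]
        pair = build_contingency(case_m, noncase_m, row["A"], row["B"])
        stats = pair_stats(pair)
        for key in ("E_case", "T_case", "T_noncase", "ih", "joint_risk", "posterior"):
            assert row[key] == pytest.approx(stats[key], rel=1e-9)


class TestRankReport:
    def test_direction_partitions_by_sign_of_structured_score(self):
        case_m, noncase_m, model = _screening_fixture()
        selected, _ = select_pairs(
            case_m, noncase_m, model, top_k=None, alpha_chi2=None,
            alpha_ih=None, min_joint=0,
        )
        risk_detail, risk_summary = rank_report(selected, "risk")
        prot_detail, _ = rank_report(selected, "protective")
        assert (selected["score_A"].loc[selected["A"].isin(risk_detail["A"])] > 0).all()
        assert len(risk_detail) + len(prot_detail) <= len(selected)
        # zero scores fall in neither report
        zeroed = selected.copy()
        zeroed["score_A"] = 0.0
        d, s = rank_report(zeroed, "risk")
        assert d.empty and s.empty

    def test_report_row_reproduces_fixture_statistics(self):
        pair = example_pair("drug_abuse_x_suicide_attempts")
        stats = pair_stats(pair)
        import pandas as pd

        frame = pd.DataFrame([{**stats,
                               "a_case": pair.case[0], "b_case": pair.case[1],
                               "c_case": pair.case[2], "d_case": pair.case[3],
                               "a_noncase": pair.noncase[0], "b_noncase": pair.noncase[1],
                               "c_noncase": pair.noncase[2], "d_noncase": pair.noncase[3],
                               "score_A": 1.0, "score_B": 1.0}])
        detail, summary = rank_report(frame, "risk")
        row = detail.iloc[0]
        assert row["nA_case"] == 2356
        assert row["nB_case"] == 3741
        assert row["E_case"] == pytest.approx(expected_count(pair, "case"))
        assert row["a_case"] == 1003
        assert summary.iloc[0]["joint_risk"] == pytest.approx(joint_risk(pair))
        assert row["ih"] == pytest.approx(woolf_ih(pair)[0])
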