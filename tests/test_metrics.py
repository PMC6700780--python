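"""Concordance and diagnostic-accuracy computations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import beta, binom

from crcside.metrics import (
    AlignmentError,
    CrossTab,
    TwoByTwo,
    accuracy,
    binomial_ci,
    cohens_kappa,
    cross_tabulate,
    observed_agreement,
    per_side_2x2,
    restricted_concordance,
    stratified_validate,
    validate,
)

#: Frozen 2x2 tables of the reconstructed validation sample
#: (tp, fp, fn, tn), derived by integer search from the published
#: margins and rounding windows before the implementation was written.
EXPECTED_2X2 = {
    "LEFT": (62, 8, 37, 93),
    "RIGHT": (33, 3, 34, 130),
    "TRANSVERSE": (7, 4, 5, 184),
    "RIGHT_OR_TRANSVERSE": (41, 5, 38, 116),
}


def _table(cells: dict[tuple[str, str], int]) -> CrossTab:
    rows = sorted({r for r, _ in cells})
    cols = ["LEFT", "RIGHT", "TRANSVERSE", "UNSPECIFIED"]
    counts = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for (r, c), v in cells.items():
        counts.loc[r, c] = v
    return CrossTab(counts=counts)


class TestCrossTabulate:
    def test_fixture_margins(self, fixture_crosstab):
        assert fixture_crosstab.row_margins().tolist() == [70, 35, 10, 76, 8, 1]
        assert fixture_crosstab.col_margins().tolist() == [99, 67, 12, 22]
        assert fixture_crosstab.n == 200

    def test_single_patient_diagonal(self):
        ct = cross_tabulate({"a": "LEFT"}, {"a": "LEFT"})
        assert ct.n == 1
        assert int(ct.counts.loc["LEFT", "LEFT"]) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(AlignmentError):
            cross_tabulate({}, {})

    def test_id_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            cross_tabulate({"a": "LEFT"}, {"b": "LEFT"})

    def test_duplicate_ids_rejected(self):
        with pytest.raises(AlignmentError):
            cross_tabulate([("a", "LEFT"), ("a", "RIGHT")], {"a": "LEFT"})

    def test_out_of_vocabulary_gold_rejected(self):
        with pytest.raises(AlignmentError):
            cross_tabulate({"a": "LEFT"}, {"a": "RECTUM"})


class TestPerSide2x2:
    @pytest.mark.parametrize("side", sorted(EXPECTED_2X2))
    def test_fixture_tables(self, fixture_crosstab, side):
        t = per_side_2x2(fixture_crosstab, side)
        assert (t.tp, t.fp, t.fn, t.tn) == EXPECTED_2X2[side]

    def test_multiple_counts_for_each_component(self):
        ct = _table({("MULTIPLE[RIGHT+TRANSVERSE]", "RIGHT"): 1})
        assert per_side_2x2(ct, "RIGHT").tp == 1
        assert per_side_2x2(ct, "TRANSVERSE").fp == 1
        assert per_side_2x2(ct, "LEFT").fn == 0

    def test_abstracted_unspecified_is_gold_negative(self):
        ct = _table({("LEFT", "UNSPECIFIED"): 3})
        t = per_side_2x2(ct, "LEFT")
        assert (t.tp, t.fp, t.fn, t.tn) == (0, 3, 0, 0)

    def test_unknown_side_rejected(self):
        ct = _table({("LEFT", "LEFT"): 1})
        with pytest.raises(KeyError):
            per_side_2x2(ct, "SIGMOID")

    def test_margin_conservation(self, fixture_crosstab):
        for side, sides_cols in [
            ("LEFT", ["LEFT"]),
            ("RIGHT", ["RIGHT"]),
            ("TRANSVERSE", ["TRANSVERSE"]),
            ("RIGHT_OR_TRANSVERSE", ["RIGHT", "TRANSVERSE"]),
        ]:
            t = per_side_2x2(fixture_crosstab, side)
            gold_margin = int(fixture_crosstab.col_margins()[sides_cols].sum())
            assert t.tp + t.fn == gold_margin
            assert t.n == fixture_crosstab.n


class TestAccuracy:
    def test_left_display_percents(self):
        acc = accuracy(TwoByTwo(62, 8, 37, 93))
        assert acc.sensitivity.display_percent() == 63
        assert acc.specificity.display_percent() == 92
        assert acc.ppv.display_percent() == 89
        assert acc.npv.display_percent() == 72

    def test_transverse_display_percents(self):
        acc = accuracy(TwoByTwo(7, 4, 5, 184))
        assert acc.sensitivity.display_percent() == 58
        assert acc.specificity.display_percent() == 98
        assert acc.ppv.display_percent() == 64
        assert acc.npv.display_percent() == 97

    def test_zero_denominator_is_undefined_not_zero(self):
        acc = accuracy(TwoByTwo(0, 0, 4, 20))
        assert acc.sensitivity.point == 0.0
        assert not acc.ppv.defined
        assert acc.ppv.display_percent() is None

    def test_ci_brackets_point(self):
        acc = accuracy(TwoByTwo(62, 8, 37, 93))
        for m in (acc.sensitivity, acc.specificity, acc.ppv, acc.npv):
            assert m.ci_low <= m.point <= m.ci_high

    @given(
        st.integers(1, 50), st.integers(1, 50), st.integers(1, 50), st.integers(1, 50)
    )
    @settings(max_examples=100, deadline=None)
    def test_bayes_ppv_identity(self, tp, fp, fn, tn):
        acc = accuracy(TwoByTwo(tp, fp, fn, tn))
        sens = acc.sensitivity.point
        spec = acc.specificity.point
        prev = (tp + fn) / (tp + fp + fn + tn)
        expected = sens * prev / (sens * prev + (1 - spec) * (1 - prev))
        assert abs(acc.ppv.point - expected) < 1e-12


class TestBinomialCI:
    def test_clopper_pearson_matches_beta_quantiles(self):
        low, high = binomial_ci(62, 99, "clopper_pearson")
        assert low == pytest.approx(beta.ppf(0.025, 62, 38), abs=1e-12)
        assert high == pytest.approx(beta.ppf(0.975, 63, 37), abs=1e-12)

    def test_boundaries(self):
        assert binomial_ci(0, 25, "clopper_pearson")[0] == 0.0
        assert binomial_ci(25, 25, "clopper_pearson")[1] == 1.0

    def test_wald_matches_normal_formula(self):
        low, high = binomial_ci(30, 100, "wald")
        p = 0.3
        half = 1.959963984540054 * (p * (1 - p) / 100) ** 0.5
        assert low == pytest.approx(p - half, abs=1e-9)
        assert high == pytest.approx(p + half, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_ci(5, 3)
        with pytest.raises(KeyError):
            binomial_ci(1, 2, method="jeffreys-ish")

    def test_clopper_pearson_coverage(self):
        # nominal 95% exact intervals must cover at >= 93% empirically
        rng = np.random.default_rng(2026)
        for p in (0.1, 0.5, 0.9):
            for n in (12, 99):
                x = rng.binomial(n, p, size=2000)
                low = np.where(x > 0, beta.ppf(0.025, x, n - x + 1), 0.0)
                high = np.where(x < n, beta.ppf(0.975, x + 1, n - x), 1.0)
                covered = np.mean((low <= p) & (p <= high))
                assert covered >= 0.93
                # spot-check our interval against the vectorized oracle
                lo, hi = binomial_ci(int(x[0]), n, "clopper_pearson")
                assert lo == pytest.approx(low[0], abs=1e-12)
                assert hi == pytest.approx(high[0], abs=1e-12)


class TestConcordance:
    def test_fixture_observed_agreement(self, fixture_crosstab):
        assert observed_agreement(fixture_crosstab) == pytest.approx(115 / 200)

    def test_perfect_diagonal(self):
        ct = _table({("LEFT", "LEFT"): 5, ("RIGHT", "RIGHT"): 5})
        assert observed_agreement(ct) == 1.0
        assert cohens_kappa(ct).kappa == 1.0

    def test_empty_diagonal(self):
        ct = _table({("LEFT", "RIGHT"): 4, ("RECTUM", "LEFT"): 4})
        assert observed_agreement(ct) == 0.0

    def test_fixture_kappa(self, fixture_crosstab):
        result = cohens_kappa(fixture_crosstab)
        assert result.expected_agreement == pytest.approx(0.276675)
        assert result.kappa == pytest.approx((0.575 - 0.276675) / (1 - 0.276675))
        po, kappa = result.display(2)
        assert (po, kappa) == (0.58, 0.41)

    def test_matches_sklearn(self, fixture_crosstab):
        from sklearn.metrics import cohen_kappa_score

        y_assigned, y_gold = [], []
        for r, row in fixture_crosstab.counts.iterrows():
            for c, v in row.items():
                y_assigned.extend([str(r)] * int(v))
                y_gold.extend([str(c)] * int(v))
        assert cohens_kappa(fixture_crosstab).kappa == pytest.approx(
            cohen_kappa_score(y_assigned, y_gold), abs=1e-12
        )

    def test_independence_gives_zero(self):
        # rows proportional to the column margins
        ct = _table(
            {
                ("LEFT", "LEFT"): 6,
                ("LEFT", "RIGHT"): 2,
                ("RIGHT", "LEFT"): 3,
                ("RIGHT", "RIGHT"): 1,
            }
        )
        assert cohens_kappa(ct).kappa == pytest.approx(0.0, abs=1e-15)

    def test_relabeling_invariance(self, fixture_crosstab):
        base = cohens_kappa(fixture_crosstab)
        mapping = {
            "LEFT": "RIGHT",
            "RIGHT": "TRANSVERSE",
            "TRANSVERSE": "UNSPECIFIED",
            "UNSPECIFIED": "LEFT",
        }
        counts = fixture_crosstab.counts.rename(
            index=lambda r: mapping.get(str(r), str(r)),
            columns=lambda c: mapping[str(c)],
        )
        counts = counts.reindex(columns=["LEFT", "RIGHT", "TRANSVERSE", "UNSPECIFIED"])
        permuted = cohens_kappa(CrossTab(counts=counts))
        assert permuted.observed_agreement == pytest.approx(base.observed_agreement)
        assert permuted.kappa == pytest.approx(base.kappa)

    def test_degenerate_expected_agreement(self):
        ct = _table({("LEFT", "LEFT"): 7})
        result = cohens_kappa(ct)
        assert result.expected_agreement == 1.0
        assert result.kappa is None


class TestRestrictedConcordance:
    def test_fixture_side_specific_subset(self, fixture_crosstab):
        result = restricted_concordance(fixture_crosstab, {"UNSPECIFIED", "RECTUM"})
        assert result.n == 116
        assert result.observed_agreement == pytest.approx(102 / 116)

    def test_excluding_nothing_is_identity(self, fixture_crosstab):
        full = cohens_kappa(fixture_crosstab)
        result = restricted_concordance(fixture_crosstab, set())
        assert result.kappa == pytest.approx(full.kappa)
        assert result.n == full.n

    def test_single_matching_row_left(self):
        ct = _table({("LEFT", "LEFT"): 4, ("RIGHT", "LEFT"): 9})
        result = restricted_concordance(ct, {"RIGHT"})
        assert result.observed_agreement == 1.0

    def test_empty_remainder_rejected(self):
        ct = _table({("LEFT", "LEFT"): 4})
        with pytest.raises(ValueError):
            restricted_concordance(ct, {"LEFT"})

    def test_unknown_category_rejected(self, fixture_crosstab):
        with pytest.raises(KeyError):
            restricted_concordance(fixture_crosstab, {"SIGMOID"})


class TestStratifiedValidate:
    def test_fixture_stage_strata_sizes(self, fixture_dataset, fixture_assigned):
        demo = fixture_dataset.demographics
        strata = dict(zip(demo["patient_id"], demo["stage_group"]))
        reports = stratified_validate(fixture_assigned, fixture_dataset.abstraction, strata)
        sizes = {k: v.crosstab.n for k, v in reports.items() if k != "pooled"}
        assert sizes == {"I-III": 78, "IV": 107, "Not documented": 15}
        assert reports["pooled"].crosstab.n == 200

    def test_single_stratum_equals_pooled(self, fixture_dataset, fixture_assigned):
        strata = {pid: "all" for pid in fixture_assigned}
        reports = stratified_validate(fixture_assigned, fixture_dataset.abstraction, strata)
        assert reports["all"].concordance.kappa == pytest.approx(
            reports["pooled"].concordance.kappa
        )

    def test_missing_stratum_variable_rejected(self, fixture_dataset, fixture_assigned):
        with pytest.raises(AlignmentError):
            stratified_validate(fixture_assigned, fixture_dataset.abstraction, {})

    def test_zero_gold_positive_stratum_flags_undefined(self):
        assigned = {"a": "LEFT", "b": "LEFT"}
        gold = {"a": "LEFT", "b": "LEFT"}
        report = validate(assigned, gold)
        t, acc = report.per_side["RIGHT"]
        assert t.tp + t.fn == 0
        assert not acc.sensitivity.defined
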