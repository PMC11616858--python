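"""Score aggregation, banding, comparison and the exclusion identity."""

from __future__ import annotations

import itertools
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from mogsa import band, compare, compute_score, star_area_fraction
from mogsa.scoring import load_result, save_result
from conftest import make_results


def brute_score(points: list[int]) -> float:
    """Independent re-summation oracle: exact fraction, then half-up rounding."""
    frac = Fraction(100) * Fraction(sum(points), 3 * len(points))
    return float(
        (Decimal(frac.numerator) / Decimal(frac.denominator)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


class TestScoreFormula:
    def test_all_three_points_scores_hundred(self):
        assert compute_score(make_results([3] * 12)).score == 100.00

    def test_all_one_point_scores_one_third(self):
        assert compute_score(make_results([1] * 12)).score == 33.33

    def test_case_study_vector_unacceptable(self):
        pts = [3, 2, 1, None, 1, 2, 1, 1, 1, 1, None, 1]  # P4, P11 excluded
        res = compute_score(make_results(pts))
        assert (res.score, res.band, res.n_applicable) == (46.67, "unacceptable", 10)

    def test_case_study_vector_moderate(self):
        pts = [2, 2, 2, None, 1, 2, 1, 1, 2, 1, None, 1]
        res = compute_score(make_results(pts))
        assert (res.score, res.band) == (50.00, "acceptable")

    def test_case_study_vector_excellent(self):
        pts = [3, 3, 2, None, 2, 3, 2, 2, 3, 2, None, 2]
        res = compute_score(make_results(pts))
        assert (res.score, res.band) == (80.00, "excellent")

    def test_rejects_wrong_cardinality_and_duplicates(self):
        results = make_results([3] * 12)
        with pytest.raises(ValueError):
            compute_score(results[:11])
        with pytest.raises(ValueError):
            compute_score(results[:11] + [results[0]])

    def test_zero_applicable_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            compute_score(make_results([None] * 12))

    @settings(derandomize=True, max_examples=200)
    @given(
        pts=st.lists(st.one_of(st.none(), st.integers(1, 3)), min_size=12, max_size=12)
    )
    def test_score_bounds_and_oracle_agreement(self, pts):
        applicable = [p for p in pts if p is not None]
        if not applicable:
            return
        res = compute_score(make_results(pts))
        assert 33.33 <= res.score <= 100.00
        assert res.score == brute_score(applicable)

    def test_permutation_invariance(self):
        pts = [3, 2, 1, None, 1, 2, 1, 1, 1, 1, None, 1]
        results = make_results(pts)
        for perm in (results[::-1], results[6:] + results[:6]):
            assert compute_score(perm).score == compute_score(results).score

    def test_strict_monotonicity_in_any_principle(self):
        base = [2] * 12
        base_score = Fraction(sum(base), 36)
        for i in range(12):
            raised = list(base)
            raised[i] = 3
            assert Fraction(sum(raised), 36) > base_score
            assert compute_score(make_results(raised)).score > compute_score(
                make_results(base)
            ).score

    def test_exclusion_renormalization_matches_brute_force(self):
        """Dropping principle p re-normalizes to 100(sum-p_p)/(3(n-1))."""
        for n in (2, 3, 4, 5):
            for vec in itertools.product((1, 2, 3), repeat=n):
                full = list(vec) + [None] * (12 - n)
                assert compute_score(make_results(full)).score == brute_score(list(vec))
                for drop in range(n):
                    kept = [v for i, v in enumerate(vec) if i != drop]
                    reduced = [
                        None if i == drop else v for i, v in enumerate(full)
                    ]
                    assert compute_score(make_results(reduced)).score == brute_score(kept)


class TestBand:
    @pytest.mark.parametrize(
        ("score", "expected"),
        [(46.67, "unacceptable"), (49.99, "unacceptable"), (50.0, "acceptable"),
         (74.99, "acceptable"), (75.0, "excellent"), (80.0, "excellent"),
         (33.33, "unacceptable"), (100.0, "excellent")],
    )
    def test_thresholds(self, score, expected):
        assert band(score) == expected

    def test_out_of_range_rejected(self):
        for bad in (-0.01, 100.01, float("nan")):
            with pytest.raises(ValueError):
                band(bad)

    def test_custom_thresholds(self):
        assert band(60, thresholds=(40, 65)) == "acceptable"
        with pytest.raises(ValueError):
            band(60, thresholds=(65, 40))


class TestCompare:
    def _result(self, pts, title):
        return compute_score(make_results(pts), title=title)

    def test_descending_by_score(self):
        lo = self._result([3, 2, 1, None, 1, 2, 1, 1, 1, 1, None, 1], "low")     # 46.67
        mid = self._result([2, 2, 2, None, 1, 2, 1, 1, 2, 1, None, 1], "mid")    # 50.00
        hi = self._result([3, 3, 2, None, 2, 3, 2, 2, 3, 2, None, 2], "high")    # 80.00
        assert [r.score for r in compare([lo, hi, mid])] == [80.00, 50.00, 46.67]

    def test_stable_on_exact_ties(self):
        a = self._result([2] * 12, "first")
        b = self._result([2] * 12, "second")
        assert [r.title for r in compare([a, b])] == ["first", "second"]

    def test_tie_broken_by_number_of_applicable_principles(self):
        few = self._result([2] * 6 + [None] * 6, "six")
        many = self._result([2] * 12, "twelve")
        assert [r.title for r in compare([few, many])] == ["twelve", "six"]

    def test_single_input_rejected(self):
        with pytest.raises(ValueError):
            compare([self._result([2] * 12, "only")])


class TestSecondaryAreaStatistic:
    def test_full_star_has_unit_area_fraction(self):
        assert star_area_fraction(compute_score(make_results([3] * 12))) == pytest.approx(1.0)

    def test_area_shrinks_quadratically_for_uniform_points(self):
        res = compute_score(make_results([1] * 12))
        assert star_area_fraction(res) == pytest.approx((1 / 3) ** 2)


class TestReportIO:
    def test_save_load_save_is_byte_identical(self, tmp_path):
        res = compute_score(
            make_results([3, 2, 1, None, 1, 2, 1, 1, 1, 1, None, 1]), title="t"
        )
        p1, p2 = tmp_path / "r1.json", tmp_path / "r2.json"
        save_result(res, p1)
        save_result(load_result(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_report_carries_twelve_principles_and_fills(self, tmp_path):
        import json

        res = compute_score(make_results([3, 2, 1, None] + [3] * 8))
        save_result(res, tmp_path / "r.json")
        doc = json.loads((tmp_path / "r.json").read_text())
        assert len(doc["principles"]) == 12
        fills = {p["principle"]: p["fill"] for p in doc["principles"]}
        assert fills["P1"] == "green" and fills["P2"] == "half-green-half-red"
        assert fills["P3"] == "red" and fills["P4"] == "yellow"
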