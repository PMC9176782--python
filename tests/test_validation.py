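import math
import random

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

import casefinder as cf
from casefinder.registry_model import ReviewForm
from casefinder.validation import landis_koch_label

from .oracles import kappa_oracle


def form(m, l, n, o, rid="R1", rater="a"):
    return ReviewForm(rid, rater, m, l, n, o)


class TestConfirmCase:
    @pytest.mark.parametrize(
        "levels, expected",
        [
            (("yes", "yes", "yes", "yes"), True),
            (("yes", "yes", "yes", "maybe"), True),
            (("yes", "yes", "maybe", "yes"), False),
            (("yes", "maybe", "yes", "yes"), False),
            (("maybe", "yes", "yes", "yes"), False),
            (("yes", "yes", "yes", "no"), False),
            (("no", "yes", "yes", "yes"), False),
        ],
    )
    def test_rule(self, levels, expected):
        assert cf.confirm_case(form(*levels)) is expected


class TestAdjudicate:
    def test_agreement_ignores_referee(self):
        a = form("yes", "yes", "no", "maybe")
        b = form("yes", "yes", "no", "maybe")
        referee = form("no", "no", "yes", "yes")
        assert cf.adjudicate(a, b, referee).items() == a.items()

    def test_referee_resolves_only_disagreements(self):
        a = form("yes", "yes", "yes", "yes")
        b = form("no", "yes", "maybe", "yes")
        referee = form("yes", "no", "no", "no")
        resolved = cf.adjudicate(a, b, referee)
        assert resolved.items() == ("yes", "yes", "no", "yes")

    def test_mismatched_record_ids_rejected(self):
        with pytest.raises(ValueError, match="same record"):
            cf.adjudicate(form("yes", "yes", "yes", "yes", rid="R1"),
                          form("yes", "yes", "yes", "yes", rid="R2"),
                          form("yes", "yes", "yes", "yes", rid="R1"))


class TestProportions:
    @pytest.mark.parametrize(
        "num, den, pct",
        [(1496, 2003, 74.7), (186, 200, 93.0), (0, 50, 0.0)],
    )
    def test_ppv_point_estimates(self, num, den, pct):
        estimate = cf.ppv(num, den)
        assert estimate.percent == pct
        assert math.isclose(estimate.estimate, num / den)

    @pytest.mark.parametrize(
        "num, den, pct", [(373, 469, 79.5), (10, 10, 100.0), (0, 7, 0.0)]
    )
    def test_se_indicator_point_estimates(self, num, den, pct):
        assert cf.se_indicator(num, den).percent == pct

    def test_wilson_ci_brackets_estimate(self):
        for num, den in [(1496, 2003), (1, 2), (186, 200), (0, 50), (50, 50)]:
            est = cf.ppv(num, den)
            assert est.ci_low <= est.estimate <= est.ci_high
            assert est.method == "wilson"

    @pytest.mark.parametrize("func", [cf.ppv, cf.se_indicator])
    def test_zero_denominator_rejected(self, func):
        with pytest.raises(ValueError):
            func(0, 0)


class TestIndirectSE:
    def test_perfect_capture(self):
        inputs = cf.IncidenceInputs(0.001, 0.00125, 0.8)  # P == Pi
        assert cf.indirect_se(1.0, inputs).estimate == pytest.approx(1.0)

    def test_confusion_matrix_identity(self):
        # PPV * P / Pi must equal TP / (TP + FN) whenever all three derive
        # from one consistent population.
        rng = random.Random(5)
        for _ in range(25):
            n = rng.randint(1_000, 1_000_000)
            tp = rng.randint(1, n // 4)
            fp = rng.randint(0, n // 4)
            fn = rng.randint(1, n // 4)
            p = (tp + fp) / n
            ppv_est = tp / (tp + fp)
            pi = (tp + fn) / n
            inputs = cf.IncidenceInputs(p, pi / 0.85, 0.85)
            se = cf.indirect_se(ppv_est, inputs)
            assert se.estimate == pytest.approx(tp / (tp + fn), rel=1e-12)

    def test_inconsistent_inputs_capped_with_warning(self):
        inputs = cf.IncidenceInputs(0.01, 0.005, 0.9)  # P >> Pi
        with pytest.warns(UserWarning, match="capping"):
            assert cf.indirect_se(1.0, inputs).estimate == 1.0

    def test_population_ci_brackets_estimate(self):
        inputs = cf.IncidenceInputs(0.0005, 0.00125, 0.8)
        est = cf.indirect_se(0.93, inputs, population=3_700_000)
        assert est.ci_low < est.estimate < est.ci_high


class TestSERangeByYear:
    POP = {y: 3_700_000 for y in range(2009, 2012)}

    def test_min_max_ratio_is_eight_ninths(self):
        ranges = cf.se_range_by_year(
            0.93, {2009: 1200, 2010: 1500, 2011: 1800}, self.POP, 0.00125
        )
        for r in ranges:
            assert r.se_min.estimate / r.se_max.estimate == pytest.approx(8 / 9)

    def test_linearity_in_counts(self):
        single = cf.se_range_by_year(0.9, {2009: 600}, self.POP, 0.00125)[0]
        double = cf.se_range_by_year(0.9, {2009: 1200}, self.POP, 0.00125)[0]
        assert double.se_max.estimate == pytest.approx(2 * single.se_max.estimate)
        assert double.se_min.estimate == pytest.approx(2 * single.se_min.estimate)

    def test_zero_cases_gives_zero_range(self):
        r = cf.se_range_by_year(0.9, {2009: 0}, self.POP, 0.00125)[0]
        assert r.se_min.estimate == r.se_max.estimate == 0.0

    def test_missing_population_names_year(self):
        with pytest.raises(ValueError, match="2012"):
            cf.se_range_by_year(0.9, {2012: 10}, self.POP, 0.00125)


class TestCohensKappa:
    def test_identical_non_constant_ratings(self):
        result = cf.cohens_kappa(["yes", "no", "maybe", "yes"], ["yes", "no", "maybe", "yes"])
        assert result.kappa == pytest.approx(1.0)
        assert result.label == "almost perfect"

    def test_constant_equal_ratings_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            result = cf.cohens_kappa(["yes"] * 5, ["yes"] * 5)
        assert result.kappa is None and result.label == "undefined"

    def test_matches_bruteforce_and_sklearn(self):
        rng = random.Random(11)
        for _ in range(40):
            n = rng.randint(2, 60)
            a = [rng.choice(["yes", "no", "maybe"]) for _ in range(n)]
            b = [rng.choice(["yes", "no", "maybe"]) for _ in range(n)]
            expected = kappa_oracle(a, b)
            result = cf.cohens_kappa(a, b)
            if expected is None:
                assert result.kappa is None
                continue
            assert result.kappa == pytest.approx(expected)
            assert result.kappa == pytest.approx(cohen_kappa_score(a, b))

    def test_symmetry_and_relabeling_invariance(self):
        rng = random.Random(13)
        a = [rng.choice(["yes", "no", "maybe"]) for _ in range(50)]
        b = [rng.choice(["yes", "no", "maybe"]) for _ in range(50)]
        k_ab = cf.cohens_kappa(a, b).kappa
        assert cf.cohens_kappa(b, a).kappa == pytest.approx(k_ab)
        relabel = {"yes": "1", "no": "2", "maybe": "3"}
        assert cf.cohens_kappa(
            [relabel[x] for x in a], [relabel[x] for x in b]
        ).kappa == pytest.approx(k_ab)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            cf.cohens_kappa(["yes"], ["yes", "no"])

    @pytest.mark.parametrize(
        "kappa, label",
        [
            (0.1350, "slight"),
            (0.3128, "fair"),
            (0.4307, "moderate"),
            (0.7617, "substantial"),
            (-0.2, "poor"),
            (0.95, "almost perfect"),
            (None, "undefined"),
        ],
    )
    def test_landis_koch_bands(self, kappa, label):
        assert landis_koch_label(kappa) == label
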