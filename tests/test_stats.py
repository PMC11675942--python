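"""Disproportionality statistics against closed forms, printed values and
independent numerical oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate
from scipy.stats import beta as beta_dist

from glp1gi import (
    BatePriors,
    ContingencyTable,
    build_2x2_from_fixture,
    chi_square,
    evaluate_signal,
    ic_bate,
    ic_noren,
    prr,
    ror,
    verify_fixture,
)
from glp1gi.stats import _bate_posteriors


def T(a, b, c, d):
    return ContingencyTable("drug", "event", a, b, c, d)


class TestROR:
    @pytest.mark.parametrize(
        "cells,est,lo,hi",
        [
            ((1174, 3227, 1668, 10499), 2.290, 2.104, 2.492),
            ((56, 4345, 50, 12117), 3.123, 2.130, 4.581),
        ],
    )
    def test_published_values(self, cells, est, lo, hi):
        r = ror(T(*cells))
        assert round(r.estimate, 3) == est
        assert round(r.ci_low, 3) == lo
        assert round(r.ci_high, 3) == hi

    def test_proportional_rows_are_null(self):
        r = ror(T(10, 20, 30, 60))
        assert r.estimate == pytest.approx(1.0)
        assert r.ci_low < 1 < r.ci_high

    def test_zero_cell_continuity_corrected(self):
        r = ror(T(0, 10, 5, 85))
        assert r.corrected and r.estimable
        assert r.estimate == pytest.approx(0.5 * 85.5 / (10.5 * 5.5))

    def test_degenerate_margin_non_estimable(self):
        r = ror(T(0, 0, 5, 85))
        assert not r.estimable

    @given(st.lists(st.integers(1, 500), min_size=4, max_size=4))
    def test_inversion_symmetry(self, cells):
        a, b, c, d = cells
        fwd = ror(T(a, b, c, d))
        rev = ror(T(c, d, a, b))
        assert rev.estimate == pytest.approx(1.0 / fwd.estimate)
        assert rev.ci_low == pytest.approx(1.0 / fwd.ci_high)
        assert rev.ci_high == pytest.approx(1.0 / fwd.ci_low)


class TestPRR:
    @pytest.mark.parametrize(
        "cells,est",
        [((1174, 3227, 1668, 10499), 1.946), ((568, 3398, 867, 11735), 2.082)],
    )
    def test_published_values(self, cells, est):
        assert round(prr(T(*cells)).estimate, 3) == est

    def test_symmetric_table_is_null(self):
        assert prr(T(7, 13, 7, 13)).estimate == pytest.approx(1.0)

    def test_close_to_ror_for_rare_events(self, fixture):
        """For events rare in both arms the odds ratio and proportion ratio
        agree (the classical rare-outcome approximation needs rarity in the
        comparator arm too)."""
        checked = 0
        for event in fixture.event_names:
            if not fixture.is_complete(event):
                continue
            for drug in fixture.drugs:
                t = build_2x2_from_fixture(fixture, drug, event)
                if t.has_zero_cell or max(
                    t.a / (t.a + t.b), t.c / (t.c + t.d)
                ) >= 0.1:
                    continue
                checked += 1
                delta = abs(
                    math.log(ror(t).estimate) - math.log(prr(t).estimate)
                )
                assert delta < 0.05
        assert checked >= 40


class TestChiSquare:
    def test_proportional_table_is_zero(self):
        assert chi_square(T(10, 20, 30, 60), yates=False) == pytest.approx(0.0)
        assert chi_square(T(10, 10, 10, 10), yates=False) == pytest.approx(0.0)

    @pytest.mark.parametrize("yates", [False, True])
    def test_matches_textbook_formula(self, yates):
        """Independent oracle: the Pearson formula written out directly."""
        a, b, c, d = 20, 10, 10, 40
        n = a + b + c + d
        num = abs(a * d - b * c) - (n / 2 if yates else 0)
        oracle = n * num**2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi_square(T(a, b, c, d), yates=yates) == pytest.approx(
            oracle, abs=1e-6
        )

    def test_degenerate_margin_is_nan(self):
        assert math.isnan(chi_square(T(0, 0, 5, 85)))


class TestICNoren:
    def test_zero_at_independence(self):
        # a equals its expectation: (a+b)(a+c)/N = 100 when all cells 100
        t = T(100, 100, 100, 100)
        assert ic_noren(t).ic == pytest.approx(0.0)

    def test_credibility_bound_below_point(self):
        for cells in [(3, 7, 5, 85), (56, 4345, 50, 12117), (1, 1, 1, 1)]:
            r = ic_noren(T(*cells))
            assert r.ic025 < r.ic

    def test_matches_direct_formula(self):
        """Independent evaluation of the published closed form."""
        a, b, c, d = 56, 4345, 50, 12117
        n = a + b + c + d
        e = (a + b) * (a + c) / n
        ic = math.log((a + 0.5) / (e + 0.5), 2)
        ic025 = ic - 3.3 / math.sqrt(a + 0.5) - 2.0 / (a + 0.5) ** 1.5
        r = ic_noren(T(a, b, c, d))
        assert r.ic == pytest.approx(ic, abs=1e-12)
        assert r.ic025 == pytest.approx(ic025, abs=1e-12)
        assert r.expected_count == pytest.approx(e)


class TestICBate:
    def test_asymptotically_zero_at_independence(self):
        n = 10**6
        t = T(n // 100, n // 10 - n // 100, n // 10 - n // 100,
              n - 2 * (n // 10) + n // 100)
        # cell proportions exactly independent: a/N = (a+b)/N * (a+c)/N
        assert abs(ic_bate(t).ic) < 1e-3

    def test_shrinks_sparse_cells_toward_zero(self):
        t = T(1, 9, 1, 989)
        raw = math.log(t.a * t.n / ((t.a + t.b) * (t.a + t.c)), 2)
        assert abs(ic_bate(t).ic) < abs(raw)

    def test_posterior_moments_match_quadrature(self):
        """Oracle: numerical integration of E[log2 p] and Var[log2 p] under
        each Beta posterior of the two-layer prior model."""
        t = T(3, 7, 5, 85)
        post = _bate_posteriors(t, BatePriors())
        mean, var = 0.0, 0.0
        for name, sign in (("joint", 1), ("drug", -1), ("event", -1)):
            u, v = post[name]
            m1, _ = integrate.quad(
                lambda x: math.log2(x) * beta_dist.pdf(x, u, v), 0, 1,
                epsabs=1e-12, limit=200,
            )
            m2, _ = integrate.quad(
                lambda x: math.log2(x) ** 2 * beta_dist.pdf(x, u, v), 0, 1,
                epsabs=1e-12, limit=200,
            )
            mean += sign * m1
            var += m2 - m1**2
        r = ic_bate(t)
        assert r.ic == pytest.approx(mean, abs=1e-6)
        assert r.ic025 == pytest.approx(mean - 1.96 * math.sqrt(var), abs=1e-6)

    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            BatePriors(alpha1=-1.0)
        with pytest.raises(ValueError):
            BatePriors(alpha1=2.0, alpha=2.0)


class TestMonotonicity:
    def test_all_statistics_nondecreasing_in_a(self):
        b, c, d = 50, 30, 500
        grids = [
            [ror(T(a, b, c, d)).estimate for a in range(1, 40)],
            [prr(T(a, b, c, d)).estimate for a in range(1, 40)],
            [ic_noren(T(a, b, c, d)).ic for a in range(1, 40)],
            [ic_bate(T(a, b, c, d)).ic for a in range(1, 40)],
        ]
        for grid in grids:
            assert all(x2 >= x1 for x1, x2 in zip(grid, grid[1:]))


class TestExactReproduction:
    def test_all_verified_cells_match_printed(self, fixture):
        """Every printed ROR/PRR cell that the packaging audit verified as
        arithmetically consistent reproduces to 0.0005 at 3 decimals."""
        report = verify_fixture(fixture)
        assert report.ok
        summary = report.summary
        assert summary["tolerance_fail"] == 0
        assert summary["match"] >= 190  # the verified-consistent cells

    def test_discrepant_cells_stay_visible(self, fixture):
        report = verify_fixture(fixture)
        excluded = report.rows[report.rows["status"] == "excluded_known_discrepancy"]
        assert len(excluded) > 0
        assert set(excluded["note"]) - {""}


class TestEvaluateSignal:
    def test_cholecystitis_flags_ror_and_prr(self, fixture):
        t = build_2x2_from_fixture(fixture, "exenatide", "cholecystitis")
        res = evaluate_signal(t)
        assert res.flags["ror"] and res.flags["prr"]
        assert res.n_methods_positive == sum(res.flags.values())

    def test_inverse_association_flags_nothing(self, fixture):
        t = build_2x2_from_fixture(fixture, "semaglutide", "pancreatitis")
        res = evaluate_signal(t)
        assert not res.flags["ror"] and not res.flags["prr"] and not res.flags["ic"]

    def test_zero_cases_yield_reason_codes(self):
        res = evaluate_signal(T(0, 100, 50, 850))
        assert not any(res.flags.values())
        assert res.reasons["ror"] == "min_cases"
        assert res.reasons["mlr"] == "not_fitted"

    def test_mlr_flag_uses_beta_and_p(self):
        t = T(30, 70, 10, 90)
        assert evaluate_signal(t, beta=0.5, beta_p=0.01).flags["mlr"]
        assert not evaluate_signal(t, beta=0.5, beta_p=0.2).flags["mlr"]
        assert not evaluate_signal(t, beta=-0.5, beta_p=0.01).flags["mlr"]
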