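"""Cosinor, dichotomy index, R24, aggregation, standardization, tertiles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from rarpipe import (
    DEFAULT_TERTILE_BOUNDS,
    acrophase_tertiles,
    aggregate_rar,
    autocorr_24h,
    circadian_quotient,
    circular_mean_hours,
    dichotomy_index_day,
    fit_cosinor_day,
    standardize_outcomes,
)
from rarpipe.simulate import cosinor_curve

HOURS = (np.arange(1440) + 0.5) / 60.0


def _grid_search_cosinor(y, hours=HOURS):
    """Independent oracle: profile least squares over the acrophase.

    For each candidate phase the best (M, A) follow by linear regression
    on cos(w(t - phi)); the phase minimising the residual sum of squares
    is refined by bounded scalar optimisation.
    """
    w = 2 * np.pi / 24.0

    def rss(phi):
        c = np.cos(w * (hours - phi))
        X = np.column_stack([np.ones_like(hours), c])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        pred = X @ beta
        return float(((y - pred) ** 2).sum())

    grid = np.arange(0, 24, 0.01)
    vals = [rss(p) for p in grid]
    p0 = grid[int(np.argmin(vals))]
    opt = minimize_scalar(rss, bounds=(p0 - 0.02, p0 + 0.02), method="bounded", options={"xatol": 1e-10})
    phi = float(opt.x % 24)
    c = np.cos(w * (hours - phi))
    X = np.column_stack([np.ones_like(hours), c])
    (m, a), *_ = np.linalg.lstsq(X, y, rcond=None)
    if a < 0:
        a, phi = -a, (phi + 12) % 24
    return float(m), float(a), phi


class TestCosinor:
    def test_noiseless_day_recovered_exactly(self):
        y = cosinor_curve(HOURS, 3.7, 0.6, 14.2)
        fit = fit_cosinor_day(y)
        assert fit.mesor == pytest.approx(3.7, abs=1e-9)
        assert fit.amplitude == pytest.approx(0.6, abs=1e-9)
        assert fit.acrophase == pytest.approx(14.2, abs=1e-9)
        assert fit.cq == pytest.approx(0.6 / 3.7, abs=1e-9)

    def test_constant_series_flat_with_undefined_acrophase(self):
        fit = fit_cosinor_day(np.full(1440, 3.7))
        assert fit.mesor == pytest.approx(3.7)
        assert fit.amplitude == 0.0
        assert not fit.acrophase_defined

    def test_noisy_fit_matches_grid_search_oracle(self, rng):
        y = cosinor_curve(HOURS, 3.7, 0.6, 14.2) * np.exp(rng.normal(-0.045, 0.3, 1440))
        fit = fit_cosinor_day(y)
        m, a, phi = _grid_search_cosinor(y)
        assert fit.mesor == pytest.approx(m, abs=1e-6)
        assert fit.amplitude == pytest.approx(a, abs=1e-6)
        assert fit.acrophase == pytest.approx(phi, abs=1e-6)

    def test_recovery_bias_small_over_many_noisy_days(self, rng):
        """MC: bias < 1% for M and A, < 2 min circular bias for phi."""
        ms, amps, phis = [], [], []
        for _ in range(200):
            y = cosinor_curve(HOURS, 3.7, 0.6, 14.2) * np.exp(rng.normal(-0.045, 0.3, 1440))
            fit = fit_cosinor_day(y)
            ms.append(fit.mesor)
            amps.append(fit.amplitude)
            phis.append(fit.acrophase)
        assert abs(np.mean(ms) - 3.7) < 0.037
        assert abs(np.mean(amps) - 0.6) < 0.006
        assert abs(circular_mean_hours(phis) - 14.2) < 2 / 60
    def test_scale_equivariance(self, rng):
        y = cosinor_curve(HOURS, 3.7, 0.6, 14.2) * np.exp(rng.normal(0, 0.2, 1440))
        f1, f2 = fit_cosinor_day(y), fit_cosinor_day(3.0 * y)
        assert f2.mesor == pytest.approx(3 * f1.mesor)
        assert f2.amplitude == pytest.approx(3 * f1.amplitude)
        assert f2.acrophase == pytest.approx(f1.acrophase)
        assert f2.cq == pytest.approx(f1.cq)

    def test_time_shift_equivariance(self, rng):
        y = cosinor_curve(HOURS, 3.7, 0.6, 14.2) * np.exp(rng.normal(0, 0.2, 1440))
        shift_min = 150  # 2.5 h
        f1, f2 = fit_cosinor_day(y), fit_cosinor_day(np.roll(y, shift_min))
        assert f2.acrophase == pytest.approx((f1.acrophase + 2.5) % 24, abs=1e-6)
        assert f2.mesor == pytest.approx(f1.mesor)
        assert f2.amplitude == pytest.approx(f1.amplitude, abs=1e-6)


class TestCircadianQuotient:
    @pytest.mark.parametrize(
        "a, m, expected",
        [(0.6, 3.7, 0.6 / 3.7), (0.0, 3.7, 0.0), (3.7, 3.7, 1.0)],
    )
    def test_ratio(self, a, m, expected):
        assert circadian_quotient(a, m) == pytest.approx(expected)

    def test_nonpositive_mesor_undefined(self):
        assert np.isnan(circadian_quotient(0.5, 0.0))
        assert np.isnan(circadian_quotient(0.5, -1.0))


class TestDichotomyIndex:
    def test_toy_example(self):
        # in-bed {1, 2, 9}; out-of-bed median 5 -> 2 of 3 below
        counts = np.array([1.0, 2.0, 9.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        in_bed = np.array([1, 1, 1, 0, 0, 0, 0, 0], bool)
        assert np.median(counts[~in_bed]) == 5.0
        assert dichotomy_index_day(counts, in_bed) == pytest.approx(2 / 3)

    def test_ties_do_not_count_as_below(self):
        counts = np.array([5.0, 1.0, 4.0, 5.0, 6.0])
        in_bed = np.array([1, 1, 0, 0, 0], bool)
        # out median 5; in-bed {5, 1}: only the 1 is strictly below
        assert dichotomy_index_day(counts, in_bed) == pytest.approx(0.5)

    def test_brute_force_oracle_on_random_series(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 40))
            counts = rng.exponential(2.0, n)
            in_bed = rng.random(n) < 0.4
            if in_bed.all() or not in_bed.any():
                continue
            med = np.median(counts[~in_bed])
            expected = sum(1 for c in counts[in_bed] if c < med) / in_bed.sum()
            assert dichotomy_index_day(counts, in_bed) == pytest.approx(expected)

    def test_empty_side_undefined(self):
        assert np.isnan(dichotomy_index_day(np.ones(5), np.zeros(5, bool)))
        assert np.isnan(dichotomy_index_day(np.ones(5), np.ones(5, bool)))

    def test_same_distribution_gives_half_on_average(self, rng):
        vals = []
        for _ in range(60):
            counts = rng.exponential(1.0, 1440)
            in_bed = np.zeros(1440, bool)
            in_bed[:480] = True
            vals.append(dichotomy_index_day(counts, in_bed))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.02)


class TestR24:
    def test_repeated_day_is_one(self, rng):
        day = rng.exponential(1.0, 1440)
        assert autocorr_24h(np.tile(day, 7)) == pytest.approx(1.0, abs=1e-12)

    def test_iid_noise_is_near_zero(self, rng):
        x = rng.normal(0, 1, 7 * 1440)
        assert abs(autocorr_24h(x)) < 3 / np.sqrt(6 * 1440)

    def test_day_inverted_alternating_pattern_is_minus_one(self, rng):
        day = rng.uniform(0, 4, 1440)
        K = 5.0
        week = np.concatenate([day if d % 2 == 0 else K - day for d in range(7)])
        got = autocorr_24h(week)
        # direct-correlation oracle
        a, b = week[:-1440], week[1440:]
        oracle = float(np.corrcoef(a, b)[0, 1])
        assert got == pytest.approx(oracle, abs=1e-12)
        assert got == pytest.approx(-1.0, abs=1e-9)

    def test_undefined_without_seven_valid_days(self, rng):
        x = rng.normal(5, 1, 7 * 1440)
        valid = [True] * 7
        valid[3] = False
        assert np.isnan(autocorr_24h(x, valid))
        assert np.isnan(autocorr_24h(rng.normal(5, 1, 6 * 1440)))

    def test_pairwise_mode_matches_mean_of_pair_correlations(self, rng):
        x = rng.normal(5, 1, 7 * 1440)
        rs = [
            np.corrcoef(x[d * 1440 : (d + 1) * 1440], x[(d + 1) * 1440 : (d + 2) * 1440])[0, 1]
            for d in range(6)
        ]
        assert autocorr_24h(x, mode="pairwise") == pytest.approx(np.mean(rs))


class TestAggregation:
    def _daily(self, n=7, **over):
        base = {
            "mesor": 3.7,
            "amplitude": 0.6,
            "acrophase": 14.2,
            "cq": 0.6 / 3.7,
            "dichotomy_index": 0.85,
        }
        base.update(over)
        return pd.DataFrame([base] * n)

    def test_identical_rows_aggregate_to_the_row(self):
        agg = aggregate_rar(self._daily(), r24=0.2)
        assert agg["mesor"] == pytest.approx(3.7)
        assert agg["acrophase"] == pytest.approx(14.2)
        assert agg["r24"] == pytest.approx(0.2)

    def test_circular_mean_handles_midnight_wrap(self):
        daily = self._daily(n=2)
        daily.loc[0, "acrophase"] = 23.5
        daily.loc[1, "acrophase"] = 0.5
        agg = aggregate_rar(daily)
        circ_dist = min(agg["acrophase"] % 24, 24 - agg["acrophase"] % 24)
        assert circ_dist == pytest.approx(0.0, abs=1e-9)
        assert not np.isclose(agg["acrophase"], 12.0)  # naive mean would say 12

    def test_means_match_independent_recomputation(self, rng):
        daily = self._daily(n=6)
        for col in ("mesor", "amplitude", "cq", "dichotomy_index"):
            daily[col] = rng.uniform(0.1, 5, 6)
        daily["acrophase"] = rng.uniform(12, 16, 6)
        agg = aggregate_rar(daily, r24=np.nan)
        for col in ("mesor", "amplitude", "cq", "dichotomy_index"):
            assert agg[col] == pytest.approx(daily[col].mean())
        ang = daily["acrophase"] * 2 * np.pi / 24
        expect = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) * 24 / (2 * np.pi) % 24
        assert agg["acrophase"] == pytest.approx(expect)

    def test_empty_daily_rejected(self):
        with pytest.raises(ValueError):
            aggregate_rar(pd.DataFrame())


class TestStandardization:
    def _panel(self, per_visit_sds, n_per_visit=20, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for v, sd in enumerate(per_visit_sds):
            vals = rng.normal(3.7, sd, n_per_visit)
            vals = (vals - vals.mean()) / vals.std(ddof=1) * sd + 3.7  # exact SD
            rows.append(pd.DataFrame({"visit": f"v{v}", "mesor": vals}))
        return pd.concat(rows, ignore_index=True)

    def test_divisor_is_mean_of_per_visit_sds(self):
        panel = self._panel([0.1, 0.15, 0.2, 0.2, 0.2])
        out, div = standardize_outcomes(panel, columns=("mesor",))
        assert div["mesor"] == pytest.approx(0.17)
        # a raw difference of 0.10 becomes 0.10/0.17 = 0.588 SD units
        assert 0.10 / div["mesor"] == pytest.approx(0.588, abs=5e-4)
        assert np.allclose(out["mesor_std"], out["mesor"] / 0.17)

    def test_unit_sds_give_identity_transform(self):
        panel = self._panel([1.0] * 5)
        out, div = standardize_outcomes(panel, columns=("mesor",))
        assert div["mesor"] == pytest.approx(1.0)
        assert np.allclose(out["mesor_std"], out["mesor"])

    def test_degenerate_equal_values_raise(self):
        panel = pd.DataFrame({"visit": ["a"] * 3 + ["b"] * 3, "mesor": 3.7})
        with pytest.raises(ValueError, match="divisor 0"):
            standardize_outcomes(panel, columns=("mesor",))

    def test_small_visit_excluded_with_warning(self):
        panel = self._panel([0.1, 0.2])
        panel = pd.concat(
            [panel, pd.DataFrame({"visit": ["tiny"], "mesor": [3.7]})], ignore_index=True
        )
        with pytest.warns(UserWarning, match="tiny"):
            _, div = standardize_outcomes(panel, columns=("mesor",))
        assert div["mesor"] == pytest.approx(0.15)


class TestTertiles:
    def test_reference_boundary_assignment(self):
        phi = np.array(
            [
                13 + 17 / 60 + 50 / 3600,  # early-group median
                14 + 17 / 60 + 11 / 3600,  # mid-group median
                15 + 13 / 60 + 50 / 3600,  # late-group median
                13 + 51 / 60 + 24 / 3600,  # inside the printed gap -> lower
                np.nan,
            ]
        )
        labels, _ = acrophase_tertiles(phi, DEFAULT_TERTILE_BOUNDS)
        assert list(labels) == [1, 2, 3, 1, 0]

    def test_three_distinct_values_spread_over_tertiles(self):
        labels, bounds = acrophase_tertiles(np.array([12.0, 14.0, 15.5]))
        assert sorted(labels) == [1, 2, 3]
        assert len(bounds) == 3

    def test_empirical_boundaries_balance_a_sample(self, rng):
        phi = rng.normal(14.2, 1.0, 900) % 24
        labels, _ = acrophase_tertiles(phi)
        counts = np.bincount(labels)[1:]
        assert counts.min() >= 280  # near-equal thirds
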