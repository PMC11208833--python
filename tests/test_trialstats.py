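import math

import numpy as np
import pytest
from scipy import integrate, stats

from somnohrv.trialstats import (
    bonferroni_adjust,
    build_tables,
    games_howell,
    one_way_anova,
    pearson_r,
    t_test_two_tailed,
)


class TestTTest:
    def test_identical_samples_give_t0_p1(self):
        x = [1.0, 2.0, 3.0]
        res = t_test_two_tailed(x, x)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_large_shift_tiny_variance_is_overwhelming(self):
        x = [1.0, 2.0, 3.0]
        y = [101.0, 102.0002, 103.0001]
        assert t_test_two_tailed(x, y).p < 1e-6

    def test_welch_statistic_matches_hand_computation(self):
        x = np.array([3.1, 2.7, 3.3, 2.9, 3.0])
        y = np.array([2.2, 2.8, 2.4, 2.6, 2.0])
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        se = math.sqrt(vx / 5 + vy / 5)
        t_hand = (x.mean() - y.mean()) / se
        df_hand = (vx / 5 + vy / 5) ** 2 / ((vx / 5) ** 2 / 4 + (vy / 5) ** 2 / 4)
        res = t_test_two_tailed(x, y)
        assert res.statistic == pytest.approx(t_hand, abs=1e-10)
        assert res.df == pytest.approx(df_hand, abs=1e-10)
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t_hand), df_hand), abs=1e-12)

    def test_degenerate_inputs(self):
        assert t_test_two_tailed([5.0, 5.0], [5.0, 5.0]).p == 1.0
        with pytest.raises(ValueError):
            t_test_two_tailed([1.0], [1.0, 2.0])


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 1).effect == pytest.approx(1.0)
        assert pearson_r(x, -x).effect == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=9), rng.normal(size=9)
        r_hand = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        res = pearson_r(x, y)
        assert res.effect == pytest.approx(r_hand, abs=1e-10)
        t_hand = r_hand * math.sqrt(7 / (1 - r_hand**2))
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t_hand), 7), abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAnova:
    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 10)
        f = one_way_anova([x, y]).statistic
        t = t_test_two_tailed(x, y, variant="student").statistic
        assert f == pytest.approx(t * t, abs=1e-9)

    def test_matches_sums_of_squares_hand_computation(self):
        groups = [
            np.array([4.0, 5.0, 6.0, 5.5, 4.5]),
            np.array([6.0, 7.0, 8.0, 7.5, 6.5]),
            np.array([5.0, 5.5, 6.5, 6.0, 5.0]),
        ]
        allv = np.concatenate(groups)
        ssb = sum(len(g) * (g.mean() - allv.mean()) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_hand = (ssb / 2) / (ssw / 12)
        res = one_way_anova(groups)
        assert res.statistic == pytest.approx(f_hand, abs=1e-10)
        assert (res.df, res.df2) == (2.0, 12.0)

    def test_constant_data_is_an_error(self):
        with pytest.raises(ValueError, match="identical"):
            one_way_anova([[1.0, 1.0], [1.0, 1.0]])


def srange_sf_quadrature(q, k, nu):
    """Independent studentized-range tail probability by double quadrature."""

    def inner(s):
        def f(z):
            return stats.norm.pdf(z) * (
                stats.norm.cdf(z) - stats.norm.cdf(z - q * s)
            ) ** (k - 1)

        val, _ = integrate.quad(f, -8, 8, limit=200)
        return k * val

    def outer(s):
        log_dens = (
            (nu / 2) * math.log(nu)
            - math.lgamma(nu / 2)
            - (nu / 2 - 1) * math.log(2)
            + (nu - 1) * math.log(s)
            - nu * s * s / 2
        )
        return math.exp(log_dens) * inner(s)

    cdf, _ = integrate.quad(outer, 1e-6, 6, limit=200)
    return 1.0 - cdf


class TestGamesHowell:
    def test_reduces_to_welch_t_at_two_groups(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(0, 1, 9), rng.normal(0.8, 2, 7)
        gh = games_howell([x, y])[0]
        tt = t_test_two_tailed(x, y)
        assert gh.p == pytest.approx(tt.p, abs=1e-3)
        assert gh.statistic == pytest.approx(abs(tt.statistic) * math.sqrt(2), rel=1e-9)
        assert gh.df == pytest.approx(tt.df, rel=1e-9)

    def test_identical_groups_have_p_one(self):
        g = [5.0, 5.0, 5.0]
        for res in games_howell([g, g, g]):
            assert res.p >= 0.999

    def test_p_matches_range_cdf_quadrature(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(10, 2, 9), rng.normal(12, 4, 7), rng.normal(11, 1, 8)]
        for res in games_howell(groups):
            assert res.p == pytest.approx(
                srange_sf_quadrature(res.statistic, 3, res.df), abs=1e-4
            )

    def test_agrees_with_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(23)
        sizes, mus, sds = (9, 9, 9), (10.0, 11.0, 14.0), (1.0, 3.0, 2.0)
        groups = [rng.normal(m, s, n) for n, m, s in zip(sizes, mus, sds)]
        df = pd.DataFrame(
            {
                "v": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], sizes),
            }
        )
        ref = pg.pairwise_gameshowell(data=df, dv="v", between="g")
        ours = games_howell(groups, labels=["a", "b", "c"])
        for res, (_, row) in zip(ours, ref.iterrows()):
            assert res.label == f"{row.A} vs {row.B}"
            assert res.p == pytest.approx(row.pval, abs=1e-6)


class TestBonferroni:
    def test_uncapped_value_can_exceed_one(self):
        assert bonferroni_adjust(0.996, 3) == pytest.approx(2.988)

    def test_zero_stays_zero_and_cap_works(self):
        assert bonferroni_adjust(0.0, 7) == 0.0
        assert bonferroni_adjust(0.05, 3, cap=True) == pytest.approx(0.15)
        assert bonferroni_adjust(0.6, 3, cap=True) == 1.0

    def test_monotone_and_linear(self):
        for p in (0.0, 0.01, 0.4, 1.0):
            assert bonferroni_adjust(p, 3) == pytest.approx(3 * p)
            assert bonferroni_adjust(p, 4) >= bonferroni_adjust(p, 3)
            assert bonferroni_adjust(p, 1) == p
        with pytest.raises(ValueError):
            bonferroni_adjust(0.5, 0)
        with pytest.raises(ValueError):
            bonferroni_adjust(1.5, 2)


class TestBuildTables:
    @staticmethod
    def _summaries(rng, effect=0.0):
        rows = []
        for g in ("Mi", "nMi"):
            for subj in range(9):
                for day in (1, 5, 9):
                    shift = -effect * {1: 0.0, 5: 1.0, 9: 2.0}[day] if g == "Mi" else 0.0
                    rows.append(
                        {
                            "group": g,
                            "subject": subj,
                            "day": day,
                            "total": rng.normal(330, 40),
                            "S": rng.normal(130, 20),
                            "PS_shallow": rng.normal(60, 15),
                            "PS_deep": rng.normal(140, 20),
                            "LF": rng.normal(15 + shift, 1.5),
                            "HF": rng.normal(18, 1.5),
                            "LF_HF": rng.normal(1.0, 0.2),
                        }
                    )
        import pandas as pd

        return pd.DataFrame(rows)

    def test_shapes_and_columns(self, rng):
        tables = build_tables(self._summaries(rng))
        t1, t2, t3 = (
            tables["group_means"],
            tables["stage_contrasts"],
            tables["day_contrasts"],
        )
        assert len(t1) == 3 * 7  # days x measures
        assert len(t2) == 2 * 3 * 6  # groups x days x duration pairs
        assert len(t3) == 2 * 3 * 3  # groups x spectral measures x day pairs
        assert not t1.isna().any().any()
        assert (t3["bonferroni"] >= t3["p"] - 1e-15).all()

    def test_missing_cells_reported(self, rng):
        df = self._summaries(rng)
        df = df[~((df.group == "nMi") & (df.day == 9))]
        with pytest.raises(ValueError, match=r"missing \(group, day\) cells"):
            build_tables(df)

    def test_single_subject_rejected(self, rng):
        df = self._summaries(rng)
        df = df.groupby(["group", "day"], as_index=False).head(1)
        with pytest.raises(ValueError):
            build_tables(df)

    def test_strong_day_effect_detected(self, rng):
        tables = build_tables(self._summaries(rng, effect=5.0))
        t3 = tables["day_contrasts"]
        hit = t3.query("group == 'Mi' and measure == 'LF' and contrast == 'day 1 vs day 9'")
        assert (hit["p"] < 0.05).all()
        flat = t3.query("group == 'nMi' and measure == 'LF'")
        assert (flat["p"] > 0.05).mean() >= 2 / 3
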