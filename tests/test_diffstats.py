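"""Differential screening, VIP scoring, BH adjustment, enrichment, ΔΔCt."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from camptomine import diffstats
from camptomine.diffstats import (COUNTED_LISTS, DISCRIMINATING,
                                  ScreenThresholds, bh_adjust, ddct,
                                  deg_screen, enrich, fold_change,
                                  metabolite_screen, plsda_vip, screen,
                                  welch_t)


def _matrix(rows, samples=("a1", "a2", "b1", "b2")):
    return pd.DataFrame(rows, columns=list(samples),
                        index=[f"f{i}" for i in range(len(rows))])


COND = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}


class TestFoldChange:
    def test_doubling_gives_fc_two(self):
        m = _matrix([[4, 4, 2, 2]])
        fc = fold_change(m, COND, "A", "B")
        assert fc.fc.iloc[0] == pytest.approx(2.0)
        assert fc.log2fc.iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_quarter_gives_fc_quarter(self):
        m = _matrix([[1, 1, 4, 4]])
        assert fold_change(m, COND, "A", "B").fc.iloc[0] == pytest.approx(0.25)

    def test_zero_denominator_stays_finite(self):
        m = _matrix([[3, 3, 0, 0]])
        fc = fold_change(m, COND, "A", "B").fc.iloc[0]
        assert math.isfinite(fc) and fc == pytest.approx(3.0 / 1e-9, rel=1e-6)

    def test_absent_condition_raises(self):
        with pytest.raises(ValueError, match="Z"):
            fold_change(_matrix([[1, 1, 1, 1]]), COND, "A", "Z")


def _welch_oracle(x, y):
    """Textbook Welch statistic with Welch–Satterthwaite df."""
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    t = (np.mean(x) - np.mean(y)) / math.sqrt(vx / nx + vy / ny)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return 2.0 * sps.t.sf(abs(t), df)


class TestWelch:
    def test_identical_groups_give_p_one(self):
        m = _matrix([[5, 5, 5, 5]])
        with pytest.warns(UserWarning, match="constant"):
            assert welch_t(m, COND, "A", "B").iloc[0] == 1.0

    def test_separated_groups_give_small_p(self):
        m = _matrix([[1, 2, 3, 11, 12, 13]],
                    samples=["a1", "a2", "a3", "b1", "b2", "b3"])
        cond = {s: s[0].upper() for s in m.columns}
        p = welch_t(m, cond, "A", "B", log_transform=False).iloc[0]
        assert p < 0.01

    def test_matches_textbook_formula_on_random_draws(self):
        rng = np.random.default_rng(3)
        rows = rng.lognormal(3, 0.5, (20, 6))
        m = _matrix(rows, samples=["a1", "a2", "a3", "b1", "b2", "b3"])
        cond = {s: s[0].upper() for s in m.columns}
        p = welch_t(m, cond, "A", "B")
        for i in range(20):
            x = np.log1p(rows[i, :3])
            y = np.log1p(rows[i, 3:])
            assert p.iloc[i] == pytest.approx(_welch_oracle(x, y), rel=1e-9)


class TestVip:
    def _random_fit(self, seed=0, n_feat=12, n_samp=16):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.lognormal(2, 0.4, (n_feat, n_samp)),
                         columns=[f"s{i}" for i in range(n_samp)])
        labels = {f"s{i}": ("x" if i < n_samp // 2 else "y")
                  for i in range(n_samp)}
        return plsda_vip(m, labels)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mean_squared_vip_is_one(self, seed):
        vip = self._random_fit(seed)
        assert (vip ** 2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_informative_feature_has_max_vip(self):
        rng = np.random.default_rng(5)
        n = 10
        noise = rng.normal(0, 1, (9, 2 * n))
        signal = np.concatenate([rng.normal(0, 1, n),
                                 rng.normal(3, 1, n)])  # 3 SD separation
        m = pd.DataFrame(np.vstack([signal, noise]) + 10.0,
                         columns=[f"s{i}" for i in range(2 * n)])
        labels = {f"s{i}": ("x" if i < n else "y") for i in range(2 * n)}
        vip = plsda_vip(m, labels)
        assert vip.idxmax() == 0

    def test_single_feature_single_component_vip_is_one(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(5, 1, (1, 10)),
                         columns=[f"s{i}" for i in range(10)])
        labels = {f"s{i}": ("x" if i < 5 else "y") for i in range(10)}
        assert plsda_vip(m, labels, n_components=1).iloc[0] == \
            pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_feature_reported_as_zero(self):
        rng = np.random.default_rng(9)
        rows = rng.normal(5, 1, (4, 10))
        rows[2] = 7.0
        m = pd.DataFrame(rows, columns=[f"s{i}" for i in range(10)])
        labels = {f"s{i}": ("x" if i < 5 else "y") for i in range(10)}
        with pytest.warns(UserWarning, match="zero-variance"):
            vip = plsda_vip(m, labels)
        assert vip.iloc[2] == 0.0


class TestScreen:
    def _stats(self, rows):
        return pd.DataFrame(rows, columns=["fc", "vip", "p_value"])

    def test_strong_feature_is_up(self):
        out = screen(self._stats([[3.0, 2.5, 0.01]]))
        assert out.direction.iloc[0] == "up"

    def test_vip_threshold_separates_presets(self):
        stats = self._stats([[3.0, 1.5, 0.01]])
        assert screen(stats, DISCRIMINATING).direction.iloc[0] == "ns"
        assert screen(stats, COUNTED_LISTS).direction.iloc[0] == "up"

    def test_counts_match_hand_enumeration(self):
        rows = [
            [3.0, 2.5, 0.01],   # up
            [0.4, 2.5, 0.01],   # down
            [3.0, 1.5, 0.01],   # ns (vip)
            [3.0, 2.5, 0.10],   # ns (p)
            [1.5, 2.5, 0.01],   # ns (fc)
            [0.5, 2.1, 0.04],   # down (boundary fc_low inclusive)
            [2.0, 2.1, 0.04],   # up (boundary fc_high inclusive)
            [9.0, 9.0, 0.05],   # ns (p not strictly below)
            [0.9, 9.0, 0.001],  # ns (fc)
            [4.0, 2.01, 0.049],  # up
        ]
        out = screen(self._stats(rows))
        assert list(out.direction) == ["up", "down", "ns", "ns", "ns",
                                       "down", "up", "ns", "ns", "up"]
        counts = out.direction.value_counts()
        assert counts.sum() == len(rows)

    def test_direction_partition_property(self):
        rng = np.random.default_rng(12)
        stats = self._stats(np.column_stack([
            rng.lognormal(0, 1, 50), rng.uniform(0, 4, 50),
            rng.uniform(0, 1, 50)]))
        out = screen(stats)
        assert set(out.direction) <= {"up", "down", "ns"}
        assert len(out) == 50


class TestBH:
    def test_step_up_hand_example(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_equal_ps_stay_equal(self):
        got = bh_adjust([0.2] * 6)
        assert np.allclose(got, 0.2)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 40)
        perm = rng.permutation(40)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDegScreen:
    def test_threshold_rule(self):
        rng = np.random.default_rng(21)
        samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
        cond = {s: s[0].upper() for s in samples}
        rows = np.vstack([
            rng.lognormal(5, 0.05, 6) * [2, 2, 2, 1, 1, 1],  # clear up
            np.full(6, 150.0),                                # flat null
        ])
        out = deg_screen(pd.DataFrame(rows, columns=samples), cond, "A", "B")
        assert out.direction.iloc[0] == "up"
        assert out.direction.iloc[1] == "ns"

    def test_recovers_planted_two_fold_genes(self):
        # 50 two-fold genes among 300, six replicates per group
        from camptomine.synth import ExpressionTruth, gen_expression

        effects = tuple((f"bg_g{k:05d}", (("MeJa", 1.0),)) for k in range(50))
        truth = ExpressionTruth(n_genes=300, module_sizes=(),
                                gene_effects=effects)
        gen = gen_expression(truth, n_samples_per_condition=6, seed=2)
        deg = deg_screen(gen.expr, gen.conditions, "MeJa", "CK")
        planted = [f"bg_g{k:05d}" for k in range(50)]
        recall = (deg.loc[planted, "direction"] == "up").mean()
        assert recall >= 0.9


class TestEnrich:
    def test_ratio_pass_when_overrepresented(self):
        bg = [f"m{i}" for i in range(100)]
        out = enrich(bg[:10], bg, {"P": bg[:5] + bg[50:55]})
        row = out.iloc[0]
        assert row.N_MPDM == 5 and row.N_DM == 10
        assert row.N_MPBM == 10 and row.N_BM == 100
        assert bool(row.ratio_pass) is True

    def test_ratio_fails_when_underrepresented(self):
        bg = [f"m{i}" for i in range(100)]
        out = enrich(bg[:10], bg, {"P": bg[9:19]})  # overlap 1 of 10
        assert bool(out.iloc[0].ratio_pass) is False

    def test_hypergeometric_matches_enumeration(self):
        # N=20, K=5 in pathway, n=5 differential, observed overlap 3
        bg = [f"m{i}" for i in range(20)]
        out = enrich(bg[:5], bg, {"P": bg[2:7]})  # overlap = 3
        k, N, K, n = 3, 20, 5, 5
        p_oracle = sum(
            math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
            for x in range(k, min(K, n) + 1))
        assert out.iloc[0].p_value == pytest.approx(p_oracle, rel=1e-12)

    def test_count_invariants_hold(self):
        rng = np.random.default_rng(6)
        bg = [f"m{i}" for i in range(30)]
        diff = list(rng.choice(bg, 8, replace=False))
        sets = {f"P{j}": list(rng.choice(bg, 10, replace=False))
                for j in range(5)}
        out = enrich(diff, bg, sets)
        for _, r in out.iterrows():
            assert r.N_MPDM <= min(r.N_DM, r.N_MPBM)
            assert r.N_MPBM <= r.N_BM

    def test_differential_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            enrich(["x"], ["a", "b"], {"P": ["a"]})


class TestDdct:
    @pytest.mark.parametrize(
        "args,expected",
        [((20, 15, 20, 15), 1.0),     # ΔΔCt = 0
         ((19, 15, 20, 15), 2.0),     # ΔΔCt = -1
         ((25, 15, 27, 15), 4.0)],    # ΔΔCt = -2
    )
    def test_relative_expression(self, args, expected):
        assert ddct(*args) == pytest.approx(expected)


class TestEndToEndScreen:
    def test_metabolite_screen_on_planted_table(self):
        from camptomine.synth import gen_metabolites

        m, cond, truth = gen_metabolites(200, 20, 20, effect_log2=1.5,
                                         n_per_group=6, seed=1)
        out = metabolite_screen(m, cond, "treated", "control",
                                thresholds=COUNTED_LISTS)
        hits = (((out.direction == "up") & (truth == "up"))
                | ((out.direction == "down") & (truth == "down"))).sum()
        assert hits / 40 >= 0.8
        assert (out.direction != "ns").sum() <= 60  # few false calls
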