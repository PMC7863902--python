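"""Reporter normalization, efficiency, qPCR, JC-1, decay fits and t-tests."""

import math

import numpy as np
import pytest
from scipy import stats

from scrkit import (
    ReporterPlate,
    estimate_half_life,
    fold_change_ddct,
    gfp_efficiency,
    jc1_ratio,
    normalized_activity,
    readthrough_efficiency,
    welch_t_test,
)
from scrkit.errors import (
    DegenerateReplicateError,
    InsufficientDataError,
    InvalidControlError,
)
from scrkit.simulate import sim_decay, sim_reporter


class TestNormalizedActivity:
    def test_equal_ratios_zero_se(self):
        mean, se = normalized_activity(ReporterPlate("c", ((10, 2), (20, 4))))
        assert mean == 5.0
        assert se == 0.0

    def test_single_replicate(self):
        mean, se = normalized_activity(ReporterPlate("c", ((10, 2),)))
        assert (mean, se) == (5.0, 0.0)

    def test_direct_formula_oracle(self):
        rng = np.random.default_rng(16)
        reps = tuple((float(f), float(r)) for f, r in rng.uniform(1, 100, size=(6, 2)))
        mean, se = normalized_activity(ReporterPlate("c", reps))
        ratios = [f / r for f, r in reps]
        assert mean == pytest.approx(np.mean(ratios))
        assert se == pytest.approx(np.std(ratios, ddof=1) / math.sqrt(6))

    def test_zero_control_errors(self):
        with pytest.raises(DegenerateReplicateError):
            normalized_activity(ReporterPlate("c", ((10, 0),)))


class TestReadthroughEfficiency:
    def test_identical_plates_100_percent(self):
        plate = ReporterPlate("t", ((10, 2), (12, 3)))
        est = readthrough_efficiency(plate, plate)
        assert est.percent == pytest.approx(100.0)

    def test_zero_test_signal_0_percent(self):
        test = ReporterPlate("t", ((0, 2), (0, 3)))
        nostop = ReporterPlate("n", ((10, 2),))
        assert readthrough_efficiency(test, nostop).percent == 0.0

    def test_scale_invariance(self):
        test = ReporterPlate("t", ((10, 2), (12, 3)))
        nostop = ReporterPlate("n", ((30, 2), (29, 3)))
        base = readthrough_efficiency(test, nostop).percent
        scaled = readthrough_efficiency(
            ReporterPlate("t", tuple((f * 7, r * 7) for f, r in test.replicates)),
            ReporterPlate("n", tuple((f * 7, r * 7) for f, r in nostop.replicates)),
        ).percent
        assert scaled == pytest.approx(base)

    def test_background_subtraction_changes_estimate(self):
        test = ReporterPlate("t", ((6, 1),))
        nostop = ReporterPlate("n", ((11, 1),))
        negative = ReporterPlate("b", ((1, 1),))
        raw = readthrough_efficiency(test, nostop)
        sub = readthrough_efficiency(test, nostop, negative, subtract_background=True)
        assert raw.percent == pytest.approx(100 * 6 / 11)
        assert sub.percent == pytest.approx(100 * 5 / 10)
        assert sub.background_subtracted

    def test_invalid_control(self):
        test = ReporterPlate("t", ((1, 1),))
        nostop = ReporterPlate("n", ((1, 1),))
        negative = ReporterPlate("b", ((5, 1),))
        with pytest.raises(InvalidControlError):
            readthrough_efficiency(test, nostop, negative, subtract_background=True)

    def test_noise_free_simulation_exact(self):
        test, nostop, negative = sim_reporter(1, true_percent=59.0, cv=0.0)
        est = readthrough_efficiency(test, nostop, negative)
        assert est.percent == pytest.approx(59.0)
        assert est.se == 0.0

    def test_planted_59_percent_recovered(self):
        """Mean estimate over 500 seeded plates within 2% absolute of planted."""
        vals = []
        for seed in range(500):
            test, nostop, _ = sim_reporter(seed, true_percent=59.0, cv=0.05)
            vals.append(readthrough_efficiency(test, nostop).percent)
        assert abs(float(np.mean(vals)) - 59.0) < 2.0


class TestGfpEfficiency:
    def test_equal_means_100(self):
        est = gfp_efficiency([1.0, 1.2], [1.2, 1.0])
        assert est.percent == pytest.approx(100.0)

    def test_planted_11_5_recovered(self):
        vals = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            sigma = math.sqrt(math.log(1 + 0.05**2))
            noise = lambda n: rng.lognormal(-sigma**2 / 2, sigma, n)
            vals.append(gfp_efficiency(0.115 * noise(3), 1.0 * noise(3)).percent)
        assert abs(float(np.mean(vals)) - 11.5) < 0.5

    def test_empty_replicates_error(self):
        with pytest.raises(InsufficientDataError):
            gfp_efficiency([], [1.0])


class TestDdct:
    def test_zero_ddct_fold_one(self):
        fold = fold_change_ddct({"a": [20.0], "b": [20.0]}, {"a": [15.0], "b": [15.0]}, "a")
        assert fold == {"a": 1.0, "b": 1.0}

    def test_one_ddct_halves(self):
        fold = fold_change_ddct({"a": [20.0], "b": [21.0]}, {"a": [15.0], "b": [15.0]}, "a")
        assert fold["b"] == pytest.approx(0.5)

    def test_random_tables_match_direct_formula(self):
        rng = np.random.default_rng(17)
        conds = ["ctrl", "c1", "c2"]
        target = {c: rng.uniform(18, 30, 3).tolist() for c in conds}
        ref = {c: rng.uniform(12, 20, 3).tolist() for c in conds}
        fold = fold_change_ddct(target, ref, "ctrl")
        for c in conds:
            dct = np.mean(target[c]) - np.mean(ref[c])
            dct0 = np.mean(target["ctrl"]) - np.mean(ref["ctrl"])
            assert fold[c] == pytest.approx(2 ** -(dct - dct0))

    def test_missing_condition_errors(self):
        with pytest.raises(InsufficientDataError):
            fold_change_ddct({"a": [20.0]}, {"a": [15.0], "b": [15.0]}, "a")


class TestJc1:
    def test_exact_points(self):
        assert jc1_ratio([(538, 1.0), (594, 2.0)]) == 2.0

    def test_flat_spectrum(self):
        spectrum = [(w, 3.0) for w in range(510, 621, 2)]
        assert jc1_ratio(spectrum) == pytest.approx(1.0)

    def test_interpolation(self):
        # 537 -> 1.0, 539 -> 2.0 gives 1.5 at 538; 593 -> 4, 595 -> 6 gives 5 at 594
        spectrum = [(537, 1.0), (539, 2.0), (593, 4.0), (595, 6.0)]
        assert jc1_ratio(spectrum) == pytest.approx(5.0 / 1.5)

    def test_zero_green_errors(self):
        with pytest.raises(DegenerateReplicateError):
            jc1_ratio([(538, 0.0), (594, 2.0)])


class TestHalfLife:
    def test_exact_halving(self):
        fit = estimate_half_life([0, 1, 2, 3], [8, 4, 2, 1])
        assert fit.half_life == pytest.approx(1.0)
        assert not fit.censored

    def test_constant_censored(self):
        fit = estimate_half_life([0, 12, 24, 36], [5, 5, 5, 5], t_max=36)
        assert fit.censored
        assert str(fit) == "t1/2 > 36"

    def test_nonpositive_excluded_and_insufficient(self):
        with pytest.raises(InsufficientDataError):
            estimate_half_life([0, 1, 2], [1.0, 0.0, -1.0])

    def test_planted_half_life_recovered(self):
        """Median recovered t1/2 within 20% of planted 0.5 h at 10% noise."""
        times = [0, 0.25, 0.5, 1, 2, 4]
        recovered = []
        for seed in range(50):
            pts = sim_decay(seed, t_half=0.5, times=times, noise_cv=0.10)
            fit = estimate_half_life([t for t, _ in pts], [i for _, i in pts])
            assert not fit.censored
            recovered.append(fit.half_life)
        assert abs(float(np.median(recovered)) - 0.5) < 0.1

    def test_stable_protein_censors(self):
        pts = sim_decay(3, t_half=math.inf, times=[0, 1, 2, 4], noise_cv=0.0)
        fit = estimate_half_life([t for t, _ in pts], [i for _, i in pts])
        assert fit.censored


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_zero_variance_identical(self):
        t, df, p = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_student_equals_welch_for_equal_var_n(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        tw, dfw, _ = welch_t_test(a, b, welch=True)
        ts, dfs, _ = welch_t_test(a, b, welch=False)
        assert tw == pytest.approx(ts)
        assert dfw == pytest.approx(dfs)

    def test_textbook_formula_oracle_to_6_decimals(self):
        rng = np.random.default_rng(18)
        for _ in range(20):
            a = rng.normal(0, 1, int(rng.integers(3, 10)))
            b = rng.normal(0.5, 2, int(rng.integers(3, 10)))
            for welch in (True, False):
                t, df, p = welch_t_test(a, b, welch=welch)
                # independent oracle: textbook formulas evaluated directly
                na, nb = len(a), len(b)
                ma, mb = sum(a) / na, sum(b) / nb
                va = sum((x - ma) ** 2 for x in a) / (na - 1)
                vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
                if welch:
                    t_exp = (ma - mb) / math.sqrt(va / na + vb / nb)
                    df_exp = (va / na + vb / nb) ** 2 / (
                        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
                    )
                else:
                    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
                    t_exp = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
                    df_exp = na + nb - 2
                p_exp = 2 * stats.t.sf(abs(t_exp), df_exp)
                assert t == pytest.approx(t_exp, abs=1e-6)
                assert df == pytest.approx(df_exp, abs=1e-6)
                assert p == pytest.approx(p_exp, abs=1e-6)

    def test_matches_scipy(self):
        rng = np.random.default_rng(19)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 3, 6)
        for welch in (True, False):
            t, _, p = welch_t_test(a, b, welch=welch)
            ref = stats.ttest_ind(a, b, equal_var=not welch)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_small_sample_errors(self):
        with pytest.raises(InsufficientDataError):
            welch_t_test([1.0], [1.0, 2.0])
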