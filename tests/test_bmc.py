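import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from seazit.bmc import (
    BMCResult,
    DEFAULT_GRID,
    anchor_to_baseline,
    bmc_at,
    monotonize,
    pooled_variance,
    scan_thresholds,
    select_bmr,
)
from seazit.endpoints import MORTALITY_120, ConcentrationResponse
from seazit.simdata import hill_prob


def make_cr(responses, conc=None, n=None, substance="S01", rep="P1"):
    responses = np.asarray(responses, dtype=float)
    if conc is None:
        conc = -6.0 + np.arange(len(responses))
    if n is None:
        n = np.full(len(responses), 11)
    return ConcentrationResponse(MORTALITY_120, substance, rep, conc, responses, n)


def isotonic_oracle(y, w):
    """Brute-force weighted least-squares isotonic fit by exhaustive search
    over consecutive-block partitions (block value = weighted mean)."""
    n = len(y)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    best, best_sse = None, np.inf
    for cuts in itertools.product([0, 1], repeat=n - 1):
        blocks, start = [], 0
        for i, c in enumerate(cuts, start=1):
            if c:
                blocks.append((start, i))
                start = i
        blocks.append((start, n))
        means = [np.average(y[a:b], weights=w[a:b]) for a, b in blocks]
        if any(m2 < m1 - 1e-12 for m1, m2 in zip(means, means[1:])):
            continue
        fitted = np.concatenate([np.full(b - a, m) for (a, b), m in zip(blocks, means)])
        sse = float(np.sum(w * (y - fitted) ** 2))
        if sse < best_sse - 1e-12:
            best, best_sse = fitted, sse
    return best


class TestMonotonize:
    def test_worked_example(self):
        out = monotonize(make_cr([0, 10, 5, 20]))
        np.testing.assert_allclose(out.response_corrected, [0, 7.5, 7.5, 20])

    def test_already_monotone_unchanged(self):
        out = monotonize(make_cr([0, 10, 20, 90]))
        np.testing.assert_allclose(out.response_corrected, [0, 10, 20, 90])

    def test_constant_unchanged(self):
        out = monotonize(make_cr([30, 30, 30]))
        np.testing.assert_allclose(out.response_corrected, [30, 30, 30])

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            monotonize(make_cr([10.0], conc=np.array([-5.0])))

    @given(
        y=st.lists(st.floats(0, 100), min_size=2, max_size=6),
        w=st.lists(st.integers(1, 20), min_size=6, max_size=6),
    )
    def test_matches_bruteforce_oracle(self, y, w):
        """The pool-adjacent-violators fit equals an exhaustive level-set
        least-squares search on every input of length <= 6."""
        w = w[: len(y)]
        out = monotonize(make_cr(y, n=np.array(w)))
        np.testing.assert_allclose(
            out.response_corrected, isotonic_oracle(y, w), atol=1e-8
        )


class TestBmcAt:
    def test_interpolation_in_log_concentration(self):
        curve = monotonize(make_cr([0, 0, 20, 40], conc=np.array([-6.0, -5.0, -4.0, -3.0])))
        res = bmc_at(curve, 30.0)
        assert res.active
        assert res.bmc_log10M == pytest.approx(-3.5)

    def test_inactive_censors_at_highest_tested(self):
        curve = monotonize(make_cr([0, 5, 15], conc=np.array([-5.0, -4.0, -3.0])))
        res = bmc_at(curve, 30.0)
        assert not res.active
        assert res.bmc_log10M is None
        assert res.censored_at_max
        assert res.potency_value == pytest.approx(-3.0)

    def test_exact_hit_at_tested_concentration(self):
        curve = monotonize(make_cr([0, 30, 60], conc=np.array([-6.0, -5.0, -4.0])))
        res = bmc_at(curve, 30.0)
        assert res.bmc_log10M == pytest.approx(-5.0)

    def test_first_concentration_already_above_bmr_censored_low(self):
        curve = monotonize(make_cr([50, 60, 70], conc=np.array([-6.0, -5.0, -4.0])))
        res = bmc_at(curve, 30.0)
        assert res.active and res.censored_low
        assert res.bmc_log10M == pytest.approx(-6.0)

    def test_flat_segment_at_bmr_reports_lowest_concentration(self):
        curve = monotonize(make_cr([0, 30, 30, 60], conc=np.array([-7.0, -6.0, -5.0, -4.0])))
        res = bmc_at(curve, 30.0)
        assert res.bmc_log10M == pytest.approx(-6.0)

    @given(st.lists(st.floats(0, 100), min_size=3, max_size=7))
    def test_raising_bmr_never_lowers_bmc(self, y):
        """A higher benchmark response can only move the BMC to higher
        (less potent) concentrations."""
        curve = monotonize(make_cr(y))
        prev = -np.inf
        for bmr in (10.0, 30.0, 50.0, 70.0):
            res = bmc_at(curve, bmr)
            val = res.potency_value
            assert val >= prev - 1e-9
            prev = val

    def test_bmr_bounds(self):
        curve = monotonize(make_cr([0, 50]))
        for bad in (0.0, 100.0, -5.0):
            with pytest.raises(ValueError):
                bmc_at(curve, bad)


def res(sub, rep, bmc, active=True, max_conc=-4.0):
    return BMCResult(
        endpoint="Mortality@120",
        substance_id=sub,
        replicate_key=rep,
        bmr_used=30.0,
        active=active,
        bmc_log10M=bmc,
        max_conc_log10M=max_conc,
        censored_at_max=not active,
    )


class TestPooledVariance:
    def test_single_substance_sample_variance(self):
        results = [res("A", f"P{i}", b) for i, b in enumerate([-4.0, -4.2, -4.1])]
        assert pooled_variance(results) == pytest.approx(0.01)

    def test_two_substances_pooled(self):
        # var 0.01 (n=3) and 0.04 (n=3) -> (2*0.01 + 2*0.04)/4 = 0.025
        a = [res("A", f"P{i}", b) for i, b in enumerate([-4.1, -4.0, -4.2])]
        b = [res("B", f"P{i}", v) for i, v in enumerate([-5.2, -5.0, -4.8])]
        assert pooled_variance(a + b) == pytest.approx(0.025)

    def test_inactive_contributes_censored_max_concentration(self):
        # inactive at max conc 100 µM contributes -4.0
        results = [
            res("A", "P1", -4.0),
            res("A", "P2", None, active=False, max_conc=-4.0),
        ]
        assert pooled_variance(results) == pytest.approx(0.0)

    def test_no_replicated_substance_errors(self):
        with pytest.raises(ValueError):
            pooled_variance([res("A", "P1", -4.0), res("B", "P1", -5.0)])


class TestScanAndSelect:
    def test_identical_replicates_zero_variance_everywhere(self):
        curves = [
            make_cr([0, 20, 50, 90], substance="A", rep=f"P{i}") for i in range(3)
        ]
        grid, profile = scan_thresholds(curves, np.array([10.0, 30.0, 60.0]))
        np.testing.assert_allclose(profile, 0.0)

    def test_grid_of_length_one(self):
        curves = [
            make_cr([0, 20, 50, 90], substance="A", rep=f"P{i}") for i in range(2)
        ]
        grid, profile = scan_thresholds(curves, np.array([30.0]))
        assert len(profile) == 1

    def test_low_noise_profile_decays_to_plateau(self):
        """With Hill-shaped curves plus small binomial noise the pooled
        variance is highest at sub-noise thresholds and then flattens."""
        rng = np.random.default_rng(7)
        conc_uM = 100.0 / 10.0 ** np.arange(6, -1, -1) * 10  # 1e-4..100
        curves = []
        for s in range(12):
            ac50 = 10.0 ** rng.uniform(-0.5, 1.5)
            for rep in range(3):
                p = hill_prob(conc_uM, ac50, 3.0, 0.03, 1.0)
                k = rng.binomial(11, p)
                curves.append(
                    make_cr(
                        100.0 * k / 11,
                        conc=np.log10(conc_uM * 1e-6),
                        substance=f"S{s}",
                        rep=f"P{rep}",
                    )
                )
        grid, profile = scan_thresholds(curves, DEFAULT_GRID)
        # early (noise-dominated) region is more variable than the plateau
        assert profile[:2].mean() >= profile[6:12].mean()

    def test_synthetic_exponential_profile_selects_first_stable_threshold(self):
        grid = np.arange(5.0, 100.0, 5.0)
        v = 0.5 * np.exp(-0.3 * grid) + 0.02
        sel = select_bmr(grid, v)
        # 0.5*exp(-0.3 t) <= 0.025 from t ~ 9.986; first grid point is 10
        assert sel.converged
        assert sel.bmr == pytest.approx(10.0)
        assert sel.plateau_value == pytest.approx(0.02, abs=1e-3)

    def test_flat_profile_selects_lowest_threshold(self):
        grid = np.array([5.0, 10.0, 15.0])
        sel = select_bmr(grid, np.full(3, 0.04))
        assert sel.converged and sel.bmr == 5.0

    def test_rising_profile_does_not_converge(self):
        grid = np.array([5.0, 10.0, 15.0, 20.0])
        with pytest.warns(UserWarning):
            sel = select_bmr(grid, np.array([0.01, 0.02, 0.03, 0.04]))
        assert not sel.converged
        assert sel.bmr == 20.0

    def test_noise_floor_monotone_in_binomial_noise(self):
        """Halving the per-concentration embryo count (doubling binomial
        noise) never lowers the selected BMR, over several seeds."""
        conc_uM = 100.0 / 10.0 ** np.arange(6, -1, -1)

        def run(n_embryos, seed):
            rng = np.random.default_rng(seed)
            curves = []
            for s in range(15):
                ac50 = 10.0 ** rng.uniform(-0.5, 1.5)
                for rep in range(3):
                    p = hill_prob(conc_uM, ac50, 3.0, 0.05, 1.0)
                    k = rng.binomial(n_embryos, p)
                    curves.append(
                        make_cr(
                            100.0 * k / n_embryos,
                            conc=np.log10(conc_uM * 1e-6),
                            substance=f"S{s}",
                            rep=f"P{rep}",
                        )
                    )
            grid, profile = scan_thresholds(curves, DEFAULT_GRID)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return select_bmr(grid, profile).bmr

        for seed in range(10):
            assert run(5, seed) >= run(22, seed) - 1e-9


class TestAnchoring:
    def test_baseline_subtracted_and_floored(self):
        cr = make_cr([5, 2, 40])
        out = anchor_to_baseline(cr, 10.0)
        np.testing.assert_allclose(out.response_pct, [0.0, 0.0, 30.0])
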