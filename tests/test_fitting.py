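"""Model fitting, branch partitioning and replicate statistics."""

import numpy as np
import pytest

from hdokin.errors import InputError
from hdokin.fitting import (
    fit_single_exponential,
    fit_stopped_flow,
    fit_total_products,
    normalize_trace,
    partition_branch_rates,
    replicate_stats,
    FitResult,
)
from hdokin.models import RiseDecayParams, SingleExpParams, eval_single_exp
from hdokin.schemes import TimeCourse
from hdokin.synthetic import (
    GeneratorConfig,
    LVAL_BRANCH_RATES,
    SINGLE_TURNOVER_TIMES_MIN,
    branching_scheme_lval,
    gen_single_turnover,
    gen_stopped_flow,
)

GRID = SINGLE_TURNOVER_TIMES_MIN


def make_tc(params, times=GRID, noise=0.0, rng=None, name="P"):
    y = eval_single_exp(params, times)
    if noise:
        y = y + rng.normal(0.0, noise, size=y.shape)
    return TimeCourse(times, "min", {name: y})


class TestSingleExponentialFit:
    def test_noiseless_inversion_desaturation_rate(self):
        """Recovers the generating rate constant of a clean product curve."""
        truth = SingleExpParams(a0=48.0, a=48.0, k=0.23)
        fit = fit_single_exponential(make_tc(truth), "P")
        assert fit.converged
        assert fit.params["k"] == pytest.approx(0.23, rel=1e-6)
        assert fit.params["a0"] == pytest.approx(48.0, rel=1e-6)

    def test_constant_series_flagged_not_raised(self):
        tc = TimeCourse(GRID, "min", {"P": np.full(len(GRID), 5.0)})
        fit = fit_single_exponential(tc, "P")
        assert not fit.converged

    def test_too_few_points_rejected(self):
        tc = TimeCourse(np.array([0.1, 0.2, 0.3]), "min",
                        {"P": np.array([1.0, 2.0, 3.0])})
        with pytest.raises(InputError):
            fit_single_exponential(tc, "P")

    def test_monte_carlo_recovery_dehydro_conversion_rate(self):
        """Triplicates with 5% noise: mean fitted k within 10% of the
        generating 1.2 min^-1 over 100 seeds."""
        truth = SingleExpParams(a0=100.0, a=100.0, k=1.2)
        ks = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fits = [
                fit_single_exponential(
                    make_tc(truth, noise=0.05 * truth.a0, rng=rng), "P")
                for _ in range(3)
            ]
            ks.extend(f.params["k"] for f in fits if f.converged)
        assert np.mean(ks) == pytest.approx(1.2, rel=0.10)


class TestTotalProductsFit:
    def test_single_product_reduces_to_plain_fit(self):
        truth = SingleExpParams(a0=20.0, a=20.0, k=0.5)
        tc = make_tc(truth)
        total = fit_total_products(tc, ["P"])
        single = fit_single_exponential(tc, "P")
        assert total.params["k"] == pytest.approx(single.params["k"], rel=1e-12)

    def test_total_rate_is_sum_of_branch_rates(self, noiseless_cfg):
        tc = gen_single_turnover(branching_scheme_lval(), noiseless_cfg)[0]
        fit = fit_total_products(tc, list(LVAL_BRANCH_RATES))
        assert fit.params["k"] == pytest.approx(0.556, rel=1e-6)

    def test_product_order_irrelevant(self, noiseless_cfg):
        tc = gen_single_turnover(branching_scheme_lval(), noiseless_cfg)[0]
        names = list(LVAL_BRANCH_RATES)
        a = fit_total_products(tc, names)
        b = fit_total_products(tc, names[::-1])
        assert a.params["k"] == pytest.approx(b.params["k"], rel=1e-12)

    def test_missing_product_rejected(self, noiseless_cfg):
        tc = gen_single_turnover(branching_scheme_lval(), noiseless_cfg)[0]
        with pytest.raises(InputError):
            fit_total_products(tc, ["nope"])


class TestBranchPartition:
    def test_single_product_gets_total(self):
        assert partition_branch_rates(0.556, {"P": 3.0}) == {"P": 0.556}

    def test_reported_fractions_give_reported_constants(self):
        """The reported amplitude fractions re-partition the total rate into
        the four printed branch constants."""
        rates = partition_branch_rates(
            0.556, {"dh": 0.414, "azi": 0.270, "oh4": 0.252, "oh3": 0.065}
        )
        assert rates["dh"] == pytest.approx(0.230, abs=1e-3)
        assert rates["azi"] == pytest.approx(0.150, abs=1e-3)
        assert rates["oh4"] == pytest.approx(0.140, abs=1e-3)
        assert rates["oh3"] == pytest.approx(0.036, abs=1e-3)

    def test_partition_sums_to_total(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            amps = {f"p{i}": rng.uniform(0.0, 5.0) for i in range(4)}
            if sum(amps.values()) == 0:
                continue
            rates = partition_branch_rates(1.7, amps)
            assert sum(rates.values()) == pytest.approx(1.7, rel=1e-12)

    def test_all_zero_amplitudes_rejected(self):
        with pytest.raises(InputError):
            partition_branch_rates(1.0, {"a": 0.0, "b": 0.0})


class TestStoppedFlowFit:
    def test_noiseless_inversion(self, sf_truth, noiseless_cfg):
        trace = gen_stopped_flow(sf_truth, noiseless_cfg)
        fit = fit_stopped_flow(trace)
        assert fit.converged
        for name, truth_val in (
            ("a0", sf_truth.a0), ("da", sf_truth.da), ("da2", sf_truth.da2),
            ("k1", sf_truth.k1), ("k1p", sf_truth.k1p), ("k2", sf_truth.k2),
        ):
            assert fit.params[name] == pytest.approx(truth_val, rel=1e-4)

    def test_absent_second_channel_detected(self, noiseless_cfg):
        truth = RiseDecayParams(a0=0.01, da=0.4, da2=0.0, k1=0.3, k1p=0.05,
                                k2=0.01)
        rng = np.random.default_rng(3)
        trace = gen_stopped_flow(truth, GeneratorConfig(seed=3, noise_sd=0.01))
        fit = fit_stopped_flow(trace)
        # second amplitude statistically consistent with zero
        assert abs(fit.params["da2"]) <= 2.0 * max(fit.param_sd["da2"], 1e-12)

    def test_monte_carlo_decay_rate_recovery(self, sf_truth):
        """100 replicates at 1% peak noise: median k2 within 5% of truth."""
        k2s = []
        for seed in range(100):
            trace = gen_stopped_flow(
                sf_truth, GeneratorConfig(seed=seed, noise_sd=0.01))
            fit = fit_stopped_flow(trace)
            if fit.converged:
                k2s.append(fit.params["k2"])
        assert np.median(k2s) == pytest.approx(sf_truth.k2, rel=0.05)

    def test_too_few_points_rejected(self):
        t = np.linspace(1.0, 10.0, 10)
        tc = TimeCourse(t, "s", {"absorbance": np.sin(t)})
        with pytest.raises(InputError):
            fit_stopped_flow(tc)

    def test_monotone_trace_flagged(self):
        t = np.geomspace(0.01, 100.0, 50)
        tc = TimeCourse(t, "s", {"absorbance": 1.0 - np.exp(-0.1 * t)})
        fit = fit_stopped_flow(tc)
        assert any("monotone" in w for w in fit.warnings)


class TestNormalizeTrace:
    def test_unit_max_unchanged(self, sf_truth, noiseless_cfg):
        trace = gen_stopped_flow(sf_truth, noiseless_cfg)
        once = normalize_trace(trace)
        twice = normalize_trace(once)
        assert np.max(once.observables["absorbance"]) == pytest.approx(1.0)
        assert np.allclose(once.observables["absorbance"],
                           twice.observables["absorbance"])

    def test_scale_invariance(self, sf_truth, noiseless_cfg):
        trace = gen_stopped_flow(sf_truth, noiseless_cfg)
        scaled = TimeCourse(trace.times, trace.unit,
                            {"absorbance": 10.0 * trace.observables["absorbance"]})
        a = normalize_trace(trace).observables["absorbance"]
        b = normalize_trace(scaled).observables["absorbance"]
        assert np.allclose(a, b)

    def test_rate_constants_survive_normalization(self, sf_truth, noiseless_cfg):
        trace = gen_stopped_flow(sf_truth, noiseless_cfg)
        raw = fit_stopped_flow(trace)
        norm = fit_stopped_flow(normalize_trace(trace))
        for name in ("k1", "k1p", "k2"):
            assert norm.params[name] == pytest.approx(raw.params[name], rel=1e-3)

    def test_nonpositive_maximum_rejected(self):
        t = np.linspace(0.0, 1.0, 5)
        tc = TimeCourse(t, "s", {"absorbance": -np.ones(5)})
        with pytest.raises(InputError):
            normalize_trace(tc)


class TestReplicateStats:
    @staticmethod
    def _fit(k, model="single_exp"):
        return FitResult(model, {"k": k}, {"k": 0.01}, 0.0, True, 8)

    def test_identical_fits_zero_sd(self):
        stats = replicate_stats([self._fit(1.0)] * 3)
        assert stats.sd["k"] == 0.0

    def test_hand_arithmetic(self):
        stats = replicate_stats([self._fit(1.0), self._fit(2.0), self._fit(3.0)])
        assert stats.mean["k"] == pytest.approx(2.0)
        assert stats.sd["k"] == pytest.approx(1.0)
        assert stats.n == 3

    def test_mixed_models_rejected(self):
        with pytest.raises(InputError):
            replicate_stats([self._fit(1.0), self._fit(2.0, model="other")])

    def test_replicate_sd_tracks_fit_uncertainty(self):
        """Across noisy triplicates the replicate SD of k lands within a
        factor of 3 of the covariance-based standard error, on average."""
        truth = SingleExpParams(a0=100.0, a=100.0, k=0.556)
        ratios = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            fits = [
                fit_single_exponential(
                    make_tc(truth, noise=0.05 * truth.a0, rng=rng), "P")
                for _ in range(3)
            ]
            fits = [f for f in fits if f.converged]
            if len(fits) < 3:
                continue
            stats = replicate_stats(fits)
            se = np.mean([f.param_sd["k"] for f in fits])
            if stats.sd["k"] > 0 and np.isfinite(se):
                ratios.append(stats.sd["k"] / se)
        assert 1 / 3 < np.median(ratios) < 3
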