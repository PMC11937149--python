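"""Net-benefit framework and CEACs: exact formula checks, boundary limits
of the acceptability curve, and bootstrap reproducibility."""

import numpy as np
import pandas as pd
import pytest

import trialcea as tc
from trialcea.cea import (CEACResult, classify_dominance, inb_regression,
                          monte_carlo_ceac, net_benefit, parametric_ceac,
                          two_stage_bootstrap)
from trialcea.estimation import IncrementalEstimate, ModelSpec


def _fake_inb(delta, se):
    return IncrementalEstimate(delta=delta, se=se, ci_low=delta - 2 * se,
                               ci_high=delta + 2 * se, p=0.5,
                               mean_intervention=0, mean_intervention_ci=(0, 0),
                               mean_control=0, mean_control_ci=(0, 0), n=100)


class TestNetBenefit:
    def test_zero_threshold_is_negative_cost(self):
        assert net_benefit(0.25, 1000.0, 0.0) == -1000.0

    def test_worked_example(self):
        assert net_benefit(0.25, 1000.0, 20_000.0) == pytest.approx(4000.0)

    def test_zero_cost_zero_effect_is_zero_everywhere(self):
        for lam in (0, 20_000, 45_000, 1e6):
            assert net_benefit(0.0, 0.0, lam) == 0.0

    def test_exact_linearity_in_threshold(self):
        e, c = 0.31, 2345.0
        l1, l2, w = 10_000.0, 50_000.0, 0.3
        lhs = net_benefit(e, c, w * l1 + (1 - w) * l2)
        rhs = w * net_benefit(e, c, l1) + (1 - w) * net_benefit(e, c, l2)
        assert lhs == pytest.approx(rhs)


@pytest.fixture(scope="module")
def clustered_frame():
    """Equal-size clusters so exchangeable weighting matches raw means."""
    rng = np.random.default_rng(10)
    k, m = 12, 8
    df = pd.DataFrame({
        "cluster_id": np.repeat(np.arange(2 * k), m),
        "arm_int": np.repeat([0, 1] * k, m),
    })
    df["total_cost_followup"] = rng.gamma(1.0, 3000, len(df)) - 500 * df["arm_int"]
    df["qalys"] = rng.normal(0.24, 0.1, len(df)) + 0.01 * df["arm_int"]
    return df


class TestInbRegression:
    def test_zero_threshold_arm_only_equals_minus_cost_difference(
            self, clustered_frame):
        est = inb_regression(clustered_frame, 0.0)
        raw = clustered_frame.groupby("arm_int")["total_cost_followup"].mean()
        assert est.delta == pytest.approx(-(raw[1] - raw[0]))

    def test_affine_in_threshold_for_singleton_clusters(self):
        rng = np.random.default_rng(11)
        n = 100
        df = pd.DataFrame({
            "cluster_id": np.arange(n),
            "arm_int": np.tile([0, 1], n // 2),
            "total_cost_followup": rng.gamma(1.0, 2000, n),
            "qalys": rng.normal(0.2, 0.08, n),
        })
        e0 = inb_regression(df, 0.0).delta
        e20 = inb_regression(df, 20_000.0).delta
        e45 = inb_regression(df, 45_000.0).delta
        dq = (e45 - e0) / 45_000.0
        assert e20 == pytest.approx(e0 + dq * 20_000.0)

    def test_inb_approaches_generator_truth_with_sample_size(self):
        lam = 30_000.0
        errs = []
        for k, m in ((15, 8), (60, 16)):
            rng = np.random.default_rng(12)
            df = pd.DataFrame({
                "cluster_id": np.repeat(np.arange(2 * k), m),
                "arm_int": np.repeat([0, 1] * k, m),
            })
            df["total_cost_followup"] = (rng.normal(3000, 800, len(df))
                                         - 400 * df["arm_int"])
            df["qalys"] = (rng.normal(0.24, 0.08, len(df))
                           + 0.014 * df["arm_int"])
            truth = 0.014 * lam + 400.0
            errs.append(abs(inb_regression(df, lam).delta - truth))
        assert errs[1] < errs[0]


class TestParametricCeac:
    def test_null_inb_gives_half(self):
        res = parametric_ceac({20_000.0: _fake_inb(0.0, 100.0)})
        assert res.probabilities[0] == pytest.approx(0.5)

    def test_1_96_standard_errors_give_0975(self):
        res = parametric_ceac({0.0: _fake_inb(1.96 * 50.0, 50.0)})
        assert res.probabilities[0] == pytest.approx(0.975, abs=1e-3)

    def test_monotone_in_inb_at_fixed_se(self):
        grid = {float(l): _fake_inb(l / 10.0 - 500.0, 200.0)
                for l in (0, 10_000, 20_000)}
        res = parametric_ceac(grid)
        assert (np.diff(res.probabilities) > 0).all()

    def test_zero_se_degenerates_by_sign(self):
        assert parametric_ceac({0.0: _fake_inb(5.0, 0.0)}).probabilities[0] == 1.0
        assert parametric_ceac({0.0: _fake_inb(-5.0, 0.0)}).probabilities[0] == 0.0


class TestMonteCarloCeac:
    def test_point_mass_dominant_everywhere(self):
        res = monte_carlo_ceac(-500.0, 0.0, 0.02, 0.0, n_sims=100, seed=1)
        assert (res.probabilities == 1.0).all()

    def test_null_estimates_give_half_at_positive_thresholds(self):
        res = monte_carlo_ceac(0.0, 300.0, 0.0, 0.01,
                               lambda_grid=(10_000, 45_000, 100_000),
                               n_sims=2000, seed=2)
        # symmetry of the normal: binomial noise only
        assert np.all(np.abs(res.probabilities - 0.5)
                      < 3 * np.sqrt(0.25 / 2000))

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_ceac(0, 1, 0, 1, correlation=1.5)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_ceac(0, -1, 0, 1)


class TestDominance:
    def test_cheaper_and_more_effective_is_dominant(self):
        assert classify_dominance(-401.27, 0.014).status == "dominant"

    def test_icer_division(self):
        d = classify_dominance(500.0, 0.05)
        assert d.status == "icer"
        assert d.icer == pytest.approx(10_000.0)

    def test_zero_effect_difference_undefined(self):
        assert classify_dominance(0.0, 0.0).status == "undefined"

    def test_dearer_and_less_effective_is_dominated(self):
        assert classify_dominance(100.0, -0.01).status == "dominated"


def _arm_only_specs():
    return (ModelSpec(outcome="total_cost_followup", covariates=("arm_int",)),
            ModelSpec(outcome="qalys", covariates=("arm_int",)))


@pytest.fixture(scope="module")
def draws(clustered_frame):
    cost_spec, qaly_spec = _arm_only_specs()
    return two_stage_bootstrap(clustered_frame, cost_spec, qaly_spec,
                               lambda_grid=(0.0, 20_000.0, 1e9),
                               b=200, seed=5)


class TestTwoStageBootstrap:
    def test_probability_at_zero_is_fraction_of_cost_saving_draws(self, draws):
        assert draws.probability_at(0.0) == pytest.approx(
            (draws.delta_cost_draws < 0).mean())

    def test_limit_at_large_threshold_is_fraction_of_qaly_gain_draws(self, draws):
        assert draws.probability_at(1e9) == pytest.approx(
            (draws.delta_qaly_draws > 0).mean())

    def test_probabilities_bounded(self, draws):
        assert ((draws.probabilities >= 0) & (draws.probabilities <= 1)).all()

    def test_reproducible_under_seed(self, clustered_frame):
        cost_spec, qaly_spec = _arm_only_specs()
        kw = dict(lambda_grid=(0.0, 20_000.0), b=60, seed=9)
        a = two_stage_bootstrap(clustered_frame, cost_spec, qaly_spec, **kw)
        b = two_stage_bootstrap(clustered_frame, cost_spec, qaly_spec, **kw)
        assert np.array_equal(a.delta_cost_draws, b.delta_cost_draws)
        assert np.array_equal(a.probabilities, b.probabilities)

    def test_uniform_dominance_gives_probability_one(self):
        rng = np.random.default_rng(13)
        k, m = 6, 5
        df = pd.DataFrame({
            "cluster_id": np.repeat(np.arange(2 * k), m),
            "arm_int": np.repeat([0, 1] * k, m),
        })
        # every intervention participant cheaper and healthier than every control
        df["total_cost_followup"] = np.where(df["arm_int"] == 1,
                                             rng.uniform(100, 200, len(df)),
                                             rng.uniform(1000, 2000, len(df)))
        df["qalys"] = np.where(df["arm_int"] == 1,
                               rng.uniform(0.4, 0.5, len(df)),
                               rng.uniform(0.1, 0.2, len(df)))
        cost_spec, qaly_spec = _arm_only_specs()
        res = two_stage_bootstrap(df, cost_spec, qaly_spec,
                                  lambda_grid=(0.0, 20_000.0, 45_000.0),
                                  b=100, seed=3)
        assert (res.probabilities == 1.0).all()

    def test_resample_variant_matches_raw_mean_difference_logic(
            self, clustered_frame):
        cost_spec, qaly_spec = _arm_only_specs()
        res = two_stage_bootstrap(clustered_frame, cost_spec, qaly_spec,
                                  lambda_grid=(0.0,), b=50, seed=4,
                                  variant="resample", shrinkage=False)
        assert len(res.delta_cost_draws) == 50
        assert np.isfinite(res.delta_cost_draws).all()

    def test_replicates_split_across_imputations(self, clustered_frame):
        from trialcea.imputation import ImputationSpec, MICollection
        mi = MICollection(datasets=[clustered_frame.copy() for _ in range(3)],
                          spec=ImputationSpec(targets=["qalys"], m=3))
        cost_spec, qaly_spec = _arm_only_specs()
        res = two_stage_bootstrap(mi, cost_spec, qaly_spec,
                                  lambda_grid=(0.0, 20_000.0), b=31, seed=6)
        assert len(res.delta_cost_draws) == 31


class TestCeacResultContracts:
    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            CEACResult(method="m", grid=[0.0, 0.0], probabilities=[0.5, 0.5],
                       n_draws=10)

    def test_probabilities_must_be_in_unit_interval(self):
        with pytest.raises(ValueError):
            CEACResult(method="m", grid=[0.0, 1.0], probabilities=[0.5, 1.2],
                       n_draws=10)

    def test_tidy_frame_layout(self):
        res = CEACResult(method="m", grid=[0.0, 20_000.0],
                         probabilities=[0.4, 0.6], n_draws=10)
        frame = res.to_frame()
        assert list(frame.columns) == ["method", "lambda", "probability"]
        assert len(frame) == 2
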