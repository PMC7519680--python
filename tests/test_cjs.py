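import numpy as np
import pytest
from scipy.special import logit

import transientcmr as tc
from transientcmr.cjs import (ConvergenceError, FitResult, IdentifiabilityError,
                              ModelSpec, aic_table, anodev, fit,
                              neg_log_likelihood, tau_from_fit)
from transientcmr.encounter import EncounterDataset, Individual, build_marray

from conftest import exhaustive_history_nll


def _random_dataset(rng, K, n):
    inds = []
    for i in range(n):
        det = rng.integers(0, 2, K)
        if det.sum() == 0:
            det[rng.integers(K)] = 1
        inds.append(Individual(f"i{i}", "3", tuple(int(d) for d in det)))
    return EncounterDataset(tuple(map(str, range(K))), inds)


class TestLikelihood:
    def test_marray_likelihood_equals_exhaustive_oracle(self):
        """Property sweep: for all small datasets the cohort-multinomial
        likelihood equals brute-force enumeration of individual latent
        fates."""
        rng = np.random.default_rng(0)
        for _ in range(150):
            K = int(rng.integers(2, 5))
            n = int(rng.integers(1, 7))
            data = _random_dataset(rng, K, n)
            ma = build_marray(data)
            phi = rng.uniform(0.2, 0.95, K - 1)
            p = rng.uniform(0.2, 0.95, K - 1)
            tau = float(rng.uniform(0.01, 0.8))
            theta = np.concatenate([logit(phi), logit(p), [logit(tau)]])
            spec = ModelSpec(phi="time", p="time", tau="const")
            nll = neg_log_likelihood(theta, ma, spec)
            oracle = exhaustive_history_nll(data.individuals, phi, p, tau)
            assert nll == pytest.approx(oracle, abs=1e-10 * max(1, abs(oracle)))

    def test_tau_zero_reduces_to_plain_cjs(self):
        """With tau pinned at 0 the transient likelihood equals an
        independently coded standard CJS m-array likelihood."""

        def plain_cjs_nll(marray, phi, p):
            K = marray.n_occasions
            ll = 0.0
            for g in range(len(marray.groups)):
                for c in range(2):
                    for t in range(K - 1):
                        R = marray.released[g, c, t]
                        if R == 0:
                            continue
                        probs = []
                        for j in range(t + 1, K):
                            pr = 1.0
                            for i in range(t, j):
                                pr *= phi[i]
                            for o in range(t + 1, j):
                                pr *= 1 - p[o - 1]
                            pr *= p[j - 1]
                            probs.append(pr)
                            ll += marray.m[g, c, t, j] * np.log(pr)
                        never = R - marray.m[g, c, t].sum()
                        ll += never * np.log(1 - sum(probs))
            return -ll

        rng = np.random.default_rng(3)
        data = _random_dataset(rng, 5, 40)
        ma = build_marray(data)
        phi = rng.uniform(0.4, 0.9, 4)
        p = rng.uniform(0.3, 0.9, 4)
        theta = np.concatenate([logit(phi), logit(p), [-40.0]])  # tau ~ 0
        spec = ModelSpec(phi="time", p="time", tau="const")
        assert neg_log_likelihood(theta, ma, spec) == pytest.approx(
            plain_cjs_nll(ma, phi, p), rel=1e-10
        )

    def test_saturated_boundary_has_zero_log_mass(self):
        """One cohort, two occasions, everyone re-seen, phi*p -> 1."""
        inds = [Individual(f"i{k}", "3", (1, 1)) for k in range(4)]
        ma = build_marray(EncounterDataset(("1", "2"), inds))
        theta = np.array([20.0, 20.0, -20.0])  # phi, p -> 1, tau -> 0
        nll = neg_log_likelihood(theta, ma, ModelSpec(tau="const"))
        assert nll == pytest.approx(0.0, abs=1e-6)

    def test_non_finite_theta_rejected(self):
        inds = [Individual("a", "3", (1, 1, 0))]
        ma = build_marray(EncounterDataset(("1", "2", "3"), inds))
        with pytest.raises(ValueError):
            neg_log_likelihood(np.array([np.nan, 0.0, 0.0]), ma,
                               ModelSpec(tau="const"))


class TestFit:
    def test_group_tau_recovery(self):
        """Estimated group-specific transient probabilities cover the truth."""
        cfg = tc.SimulationConfig(
            n_occasions=20, releases=150, phi_resident=0.92, p_detect=0.6,
            tau=np.array([[0.05, 0.15, 0.25, 0.45, 0.65]] * 20),
            groups=tc.AGE_GROUPS, seed=31,
        )
        data, truth = tc.simulate(cfg)
        f = fit(build_marray(data), ModelSpec(tau="group"), n_restarts=1)
        est = tau_from_fit(f)
        hits = 0
        for gi, g in enumerate(tc.AGE_GROUPS):
            row = est.by_group(g).iloc[0]
            hits += row.lo <= truth.tau[0, gi] <= row.hi
        assert hits >= 4
        assert f.phi_estimates[0] == pytest.approx(0.92, abs=0.02)

    def test_aic_prefers_no_transience_when_tau_is_zero(self):
        wins = 0
        n_rep = 50
        for s in range(n_rep):
            cfg = tc.SimulationConfig(n_occasions=10, releases=150,
                                      phi_resident=0.9, p_detect=0.6, tau=0.0,
                                      groups=("g",), seed=300 + s)
            data, _ = tc.simulate(cfg)
            ma = build_marray(data)
            f0 = fit(ma, ModelSpec(tau="none"), n_restarts=0, compute_vcov=False)
            f1 = fit(ma, ModelSpec(tau="const"), n_restarts=0, compute_vcov=False)
            wins += f0.aic < f1.aic
        assert wins / n_rep >= 0.8

    def test_degenerate_two_occasions_raise(self):
        inds = [Individual(f"i{k}", "3", (1, k % 2)) for k in range(10)]
        ma = build_marray(EncounterDataset(("1", "2"), inds))
        with pytest.raises(IdentifiabilityError):
            fit(ma, ModelSpec(tau="const"))

    def test_estimator_bias_shrinks_with_sample_size(self):
        errs = []
        for n in (100, 1000, 5000):
            rel = np.zeros((8, 1), dtype=int)
            rel[:4, 0] = n // 4
            cfg = tc.SimulationConfig(n_occasions=8, releases=rel,
                                      phi_resident=0.9, p_detect=0.6, tau=0.3,
                                      groups=("g",), seed=50 + n)
            data, _ = tc.simulate(cfg)
            f = fit(build_marray(data), ModelSpec(tau="const"),
                    n_restarts=0, compute_vcov=False)
            tau_hat = float(tau_from_fit(f).table.tau.iloc[0])
            errs.append(abs(tau_hat - 0.3))
        assert errs[2] < errs[0]

    def test_group_relabeling_permutes_estimates(self):
        cfg = tc.SimulationConfig(
            n_occasions=10, releases=100, phi_resident=0.9, p_detect=0.6,
            tau=np.array([[0.1, 0.5]] * 10), groups=("a", "b"), seed=8,
        )
        data, _ = tc.simulate(cfg)
        ma = build_marray(data)
        f1 = fit(ma, ModelSpec(tau="group"), n_restarts=0, compute_vcov=False)
        swapped = EncounterDataset(
            data.occasions,
            [Individual(i.id, {"a": "b", "b": "a"}[i.group], i.detections)
             for i in data.individuals],
            groups=("b", "a"),
        )
        # same animals, groups relabeled and group order swapped: identical
        # data -> identical estimates under the corresponding permutation
        f2 = fit(build_marray(swapped), ModelSpec(tau="group"),
                 n_restarts=0, compute_vcov=False)
        t1 = tau_from_fit(f1).table
        t2 = tau_from_fit(f2).table
        assert float(t1[t1.group == "a"].tau.iloc[0]) == pytest.approx(
            float(t2[t2.group == "b"].tau.iloc[0]), abs=1e-6)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)

    def test_direct_and_twoclass_parameterizations_agree(self):
        """The direct-tau and two-class-survival forms are reparameterizations:
        identical maximized likelihoods."""
        cfg = tc.SimulationConfig(n_occasions=10, releases=120, phi_resident=0.9,
                                  p_detect=0.6, tau=0.35, groups=("g",), seed=12)
        data, _ = tc.simulate(cfg)
        ma = build_marray(data)
        f_direct = fit(ma, ModelSpec(tau="const"), n_restarts=1,
                       compute_vcov=False)
        f_two = fit(ma, ModelSpec(tau="const", parameterization="twoclass"),
                    n_restarts=1)
        assert f_direct.loglik == pytest.approx(f_two.loglik, abs=1e-4)
        tau_two = float(tau_from_fit(f_two).table.tau.iloc[0])
        tau_dir = float(tau_from_fit(f_direct).table.tau.iloc[0])
        assert tau_two == pytest.approx(tau_dir, abs=1e-3)


class TestTauFromFit:
    def test_equal_survivals_give_zero(self):
        # two-class arithmetic: phi_new = phi_resident -> tau = 0
        assert 1 - 0.86 / 0.86 == pytest.approx(0.0)

    def test_half_survival_gives_half(self):
        assert 1 - 0.43 / 0.86 == pytest.approx(0.5)


def _fake_fit(deviance, n_params, loglik=-100.0, n=1000, K=10):
    return FitResult(
        spec=ModelSpec(tau="const"), groups=("g",), n_occasions=K,
        theta=np.zeros(n_params), labels=[f"b{i}" for i in range(n_params)],
        vcov=np.eye(n_params), loglik=loglik, deviance=deviance,
        n_params=n_params, aic=2 * n_params - 2 * loglik, converged=True,
        grad_norm=0.0, boundary=False, n_released_total=n,
    )


class TestAnodev:
    def test_upper_bound_when_covariate_matches_time(self):
        F, pct, p = anodev(_fake_fit(120.0, 3), _fake_fit(80.0, 4),
                           _fake_fit(80.0, 10))
        assert pct == pytest.approx(1.0)

    def test_lower_bound_when_covariate_adds_nothing(self):
        F, pct, p = anodev(_fake_fit(120.0, 3), _fake_fit(120.0, 4),
                           _fake_fit(80.0, 10))
        assert pct == pytest.approx(0.0)

    def test_non_nested_counts_rejected(self):
        with pytest.raises(ValueError):
            anodev(_fake_fit(120.0, 5), _fake_fit(100.0, 4), _fake_fit(80.0, 10))

    def test_strong_covariate_signal_recovered(self):
        """When logit(tau) is generated linear in x_t, the covariate model
        explains most of the temporal deviance."""
        pcts = []
        for s in range(5):
            x = tc.make_covariate(15, "ar1", seed=s)
            cfg = tc.SimulationConfig(
                n_occasions=15, releases=120, phi_resident=0.9, p_detect=0.6,
                alpha=[-0.5], beta=1.2, covariate=x, groups=("g",),
                seed=400 + s,
            )
            data, _ = tc.simulate(cfg)
            ma = build_marray(data)
            cov = tuple(x)
            f_c = fit(ma, ModelSpec(tau="const"), n_restarts=0, compute_vcov=False)
            f_x = fit(ma, ModelSpec(tau="cov", covariate=cov), n_restarts=0,
                      compute_vcov=False)
            f_t = fit(ma, ModelSpec(tau="time"), n_restarts=0, compute_vcov=False)
            _, pct, _ = anodev(f_c, f_x, f_t)
            pcts.append(pct)
        assert np.median(pcts) > 0.5


class TestAicTable:
    def test_single_fit(self):
        df = aic_table([_fake_fit(100.0, 3)])
        assert df.delta_aic.iloc[0] == 0.0
        assert df.weight.iloc[0] == 1.0

    def test_weight_ratio_for_delta_two(self):
        df = aic_table([_fake_fit(100.0, 3, loglik=-50.0),
                        _fake_fit(100.0, 4, loglik=-50.0)])
        w = df.weight.to_numpy()
        assert w[0] / w[1] == pytest.approx(np.e, rel=1e-9)

    def test_weights_sum_to_one(self):
        df = aic_table([_fake_fit(100.0, 3, loglik=-50),
                        _fake_fit(90.0, 5, loglik=-45),
                        _fake_fit(85.0, 8, loglik=-44)])
        assert df.weight.sum() == pytest.approx(1.0)

    def test_mixed_datasets_refused(self):
        with pytest.raises(ValueError):
            aic_table([_fake_fit(100.0, 3, n=1000), _fake_fit(90.0, 3, n=500)])
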