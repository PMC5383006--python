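import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trastecon import nma
from trastecon.trial_network import TrialArm, ValidationError, build_networks


def make_arm(trial, node, events, py, n=1000, **kw):
    base = dict(
        trial_id=trial,
        node_label=node,
        duration_class="zero" if node.startswith("zero") else "short",
        endpoint_type="DDFS",
        randomisation_timing="at_start",
        proxy_events=events,
        os_events=events,
        cardiac_events=events,
        sample_size=n,
        followup_years=10.0,
        person_years=py,
    )
    base.update(kw)
    return TrialArm(**base)


def two_arm_network(d_a, e_a, d_b, e_b):
    arms = [
        make_arm("T", "a-ddfs", d_a, e_a),
        make_arm("T", "zero-ddfs", d_b, e_b),
    ]
    (net,) = build_networks(arms)
    return net


class TestBuildContrasts:
    def test_finher_os_closed_form(self, cea_network):
        contrasts = nma.build_contrasts(cea_network, "os")
        fin = next(c for c in contrasts if c.trial_id == "FinHer")
        assert fin.log_rate_ratio == pytest.approx(np.log((3 / 279) / (10 / 299.7)))
        assert fin.log_rate_ratio == pytest.approx(-1.1324, abs=5e-4)
        assert fin.variance == pytest.approx(1 / 3 + 1 / 10)

    def test_equal_rates_give_zero_log_ratio(self):
        net = two_arm_network(10, 100.0, 20, 200.0)
        (c,) = nma.build_contrasts(net, "proxy_survival")
        assert c.log_rate_ratio == pytest.approx(0.0)

    def test_three_arm_trial_shares_baseline_covariance(self, networks):
        four = next(net for net in networks if len(net.nodes) == 4)
        contrasts = nma.build_contrasts(four, "proxy_survival")
        bcirg = [c for c in contrasts if c.trial_id == "BCIRG006"]
        assert len(bcirg) == 2
        assert all(c.node_b == "zero-ddfs" for c in bcirg)
        assert all(c.baseline_variance == pytest.approx(1 / 257) for c in bcirg)
        block = np.array(
            [
                [bcirg[0].variance, bcirg[0].baseline_variance],
                [bcirg[1].baseline_variance, bcirg[1].variance],
            ]
        )
        assert np.all(np.linalg.eigvalsh(block) > 0)

    def test_continuity_correction_applies_below_one(self, cea_network):
        contrasts = nma.build_contrasts(cea_network, "cardiac")
        fin = next(c for c in contrasts if c.trial_id == "FinHer")
        # 0.5 zero-arm events corrected to 1.0; the 9-week count of 1 is not
        assert fin.continuity_applied
        assert fin.variance == pytest.approx(1 / 1 + 1 / 1)

    def test_zero_person_years_rejected(self):
        with pytest.raises(ValidationError):
            make_arm("T", "a-ddfs", 5, 0.0)


class TestFitConsistency:
    def test_single_trial_passes_through(self):
        net = two_arm_network(8, 120.0, 15, 130.0)
        (c,) = nma.build_contrasts(net, "proxy_survival")
        fit = nma.fit_consistency([c])
        assert fit.basic_parameters[0] == pytest.approx(c.log_rate_ratio)
        assert fit.covariance_matrix[0, 0] == pytest.approx(c.variance)

    def test_two_trials_pool_by_inverse_variance(self):
        arms = [
            make_arm("T1", "a-ddfs", 8, 120.0),
            make_arm("T1", "zero-ddfs", 15, 130.0),
            make_arm("T2", "a-ddfs", 30, 500.0),
            make_arm("T2", "zero-ddfs", 22, 480.0),
        ]
        (net,) = build_networks(arms)
        contrasts = nma.build_contrasts(net, "proxy_survival")
        fit = nma.fit_consistency(contrasts)
        # brute-force inverse-variance oracle
        w = np.array([1.0 / c.variance for c in contrasts])
        y = np.array([c.log_rate_ratio for c in contrasts])
        assert fit.basic_parameters[0] == pytest.approx((w @ y) / w.sum(), abs=1e-12)
        assert fit.covariance_matrix[0, 0] == pytest.approx(1.0 / w.sum(), abs=1e-14)

    def test_gls_matches_independent_wls_oracle(self, cea_network):
        """On the OS network every trial is two-arm, so GLS must equal an
        independently coded weighted least squares solve to 1e-10."""
        contrasts = nma.build_contrasts(cea_network, "os")
        fit = nma.fit_consistency(contrasts)
        nodes = fit.nodes
        X = np.zeros((len(contrasts), len(nodes)))
        y = np.zeros(len(contrasts))
        W = np.zeros((len(contrasts), len(contrasts)))
        for i, c in enumerate(contrasts):
            if c.node_a in nodes:
                X[i, nodes.index(c.node_a)] = 1
            if c.node_b in nodes:
                X[i, nodes.index(c.node_b)] = -1
            y[i] = c.log_rate_ratio
            W[i, i] = 1.0 / c.variance
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        np.testing.assert_allclose(fit.basic_parameters, beta, atol=1e-10)

    def test_consistency_closure_is_exact(self, phare_network):
        """Fitted indirect effects are differences of basic parameters, so
        the A-C contrast equals (A-B) + (B-C) identically."""
        contrasts = nma.build_contrasts(phare_network, "cardiac")
        fit = nma.fit_consistency(contrasts)
        est = dict(zip(fit.nodes, fit.basic_parameters))
        est[fit.reference] = 0.0
        d_6m_vs_9w = est["6m-ddfs"] - est["9w-ddfs"]
        via_12m = (est["6m-ddfs"] - est["12m-ddfs"]) + (
            est["12m-ddfs"] - est["9w-ddfs"]
        )
        assert d_6m_vs_9w == pytest.approx(via_12m, abs=1e-14)

    def test_disconnected_network_names_components(self):
        c1 = nma.Contrast("T1", "a", "b", 0.1, 0.2, 0.1)
        c2 = nma.Contrast("T2", "c", "d", 0.1, 0.2, 0.1)
        with pytest.raises(nma.EstimationError, match="disconnected"):
            nma.fit_consistency([c1, c2])

    def test_random_effects_reduce_to_fixed_when_homogeneous(self):
        net = two_arm_network(8, 120.0, 15, 130.0)
        contrasts = nma.build_contrasts(net, "proxy_survival")
        fit = nma.fit_consistency(contrasts, model="random")
        assert fit.tau2 == 0.0


class TestSucra:
    def test_null_effect_splits_prob_best(self):
        fit = nma.NmaFit(
            outcome="os", reference="zero", nodes=("a",),
            basic_parameters=np.array([0.0]),
            covariance_matrix=np.array([[0.5]]),
            model="fixed", tau2=0.0, n_contrasts=1,
        )
        tab = nma.sucra(fit, n_draws=100_000, seed=3)
        mc_se = np.sqrt(0.25 / 100_000)
        assert abs(tab.prob_best[0] - 0.5) < 3 * mc_se

    def test_large_separation_is_decisive(self):
        fit = nma.NmaFit(
            outcome="os", reference="zero", nodes=("a",),
            basic_parameters=np.array([-3.0]),
            covariance_matrix=np.array([[0.01]]),
            model="fixed", tau2=0.0, n_contrasts=1,
        )
        tab = nma.sucra(fit, n_draws=10_000, seed=3)
        better = tab.nodes.index("a")
        assert tab.prob_best[better] == pytest.approx(1.0)
        assert tab.sucra[better] == pytest.approx(1.0)

    def test_rank_probabilities_doubly_stochastic(self, cea_network):
        tab = nma.rank_arms(cea_network, "proxy_survival", n_draws=50_000, seed=11)
        np.testing.assert_allclose(tab.rank_probabilities.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(tab.rank_probabilities.sum(axis=0), 1.0, atol=1e-12)

    def test_seeded_determinism(self, cea_network):
        t1 = nma.rank_arms(cea_network, "os", n_draws=20_000, seed=5)
        t2 = nma.rank_arms(cea_network, "os", n_draws=20_000, seed=5)
        np.testing.assert_array_equal(t1.rank_probabilities, t2.rank_probabilities)

    def test_too_few_draws_rejected(self, cea_network):
        contrasts = nma.build_contrasts(cea_network, "os")
        fit = nma.fit_consistency(contrasts)
        with pytest.raises(ValueError, match="1000"):
            nma.sucra(fit, n_draws=10)


def test_transitivity_probe_flags_phare_reordering(cea_network, phare_network):
    report = nma.check_transitivity_effect(
        phare_network, cea_network, outcome="cardiac", n_draws=50_000, seed=2
    )
    assert report["ordering_with"][0] == "6m-ddfs"
    assert report["added_node_ranked_first"]
    # without the late-randomising trial, zero and 9 weeks are near-tied best
    assert set(report["ordering_without"][:2]) == {"zero-ddfs", "9w-ddfs"}
    assert abs(
        report["prob_best_without"]["zero-ddfs"]
        - report["prob_best_without"]["9w-ddfs"]
    ) < 0.05
    # adding the trial collapses the zero arm's probability of being safest
    assert report["max_prob_best_shift_on_shared"] > 0.3


@given(st.integers(0, 2**31 - 1))
def test_identical_networks_identical_report(cea_network, seed):
    r = nma.check_transitivity_effect(
        cea_network, cea_network, outcome="os", n_draws=2_000, seed=seed
    )
    assert r["ordering_with"] == r["ordering_without"]
    assert r["prob_best_with"] == r["prob_best_without"]
    assert not r["ordering_changed_on_shared"]
    assert r["max_prob_best_shift_on_shared"] == 0.0
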