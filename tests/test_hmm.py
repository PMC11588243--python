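"""Model specification, likelihood, fitting and decoding.

The independent oracle for the forward likelihood and Viterbi is exhaustive
path enumeration (log-sum-exp / max over all K^T state paths), kept free of
the recursion code it checks.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

import ethostate as es
from ethostate.hmm import (
    PROB_CLAMP,
    BehaviourHMM,
    FittedParams,
    emission_logprob_matrix,
)
from ethostate.states import StateLabel


# ---------------------------------------------------------------------------
# enumeration oracles


def enumerate_loglik(log_b, tpm, delta):
    T, K = log_b.shape
    with np.errstate(divide="ignore"):
        log_tpm = np.log(tpm)
        log_delta = np.log(delta)
    terms = []
    for path in itertools.product(range(K), repeat=T):
        lp = log_delta[path[0]] + log_b[0, path[0]]
        for t in range(1, T):
            lp += log_tpm[path[t - 1], path[t]] + log_b[t, path[t]]
        terms.append(lp)
    return logsumexp(terms)


def enumerate_best_path(log_b, tpm, delta):
    T, K = log_b.shape
    with np.errstate(divide="ignore"):
        log_tpm = np.log(tpm)
        log_delta = np.log(delta)
    best, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=T):
        lp = log_delta[path[0]] + log_b[0, path[0]]
        for t in range(1, T):
            lp += log_tpm[path[t - 1], path[t]] + log_b[t, path[t]]
        if lp > best:  # first-found (lexicographically smallest) wins ties
            best, best_path = lp, path
    return best, np.array(best_path)


def random_instance(rng, K, T, structural_zeros=False):
    log_b = rng.normal(-2.0, 1.5, size=(T, K))
    tpm = rng.dirichlet(np.ones(K) * 1.5, size=K)
    if structural_zeros and K >= 2:
        n_zero = rng.integers(1, K)
        for _ in range(n_zero):
            i = int(rng.integers(K))
            offdiag = [j for j in range(K) if j != i and tpm[i, j] > 0]
            if len(offdiag) > 1:
                tpm[i, rng.choice(offdiag)] = 0.0
        tpm = tpm / tpm.sum(axis=1, keepdims=True)
    delta = rng.dirichlet(np.ones(K))
    return log_b, tpm, delta


# ---------------------------------------------------------------------------
# default specification


class TestDefaultSpec:
    def test_starting_values(self):
        em, _ = es.make_default_spec()
        frame = em.to_frame()
        assert frame.loc["InactiveWater", "odba_mean"] == -2.0
        assert frame.loc["InactiveWater", "odba_sd"] == 0.5
        assert frame.loc["ActiveLand", "immersion_prob"] == pytest.approx(1e-12)
        assert frame.loc["Nesting", "varpitch_mean"] == pytest.approx(0.2)
        np.testing.assert_allclose(em.varpitch_mean, [-0.5, -0.5, -6, -6, 0.2])
        np.testing.assert_allclose(em.varpitch_sd, [3, 2, 3, 2, 1])
        np.testing.assert_allclose(em.odba_mean, [-1, -0.5, -2, -2, -0.5])
        np.testing.assert_allclose(em.odba_sd, [0.8, 1, 0.5, 0.5, 0.2])

    def test_forbidden_set(self):
        _, st = es.make_default_spec()
        L = StateLabel
        expected = {
            (L.InactiveWater, L.Nesting), (L.Nesting, L.InactiveWater),
            (L.Nesting, L.ActiveWater), (L.InactiveWater, L.ActiveLand),
            (L.InactiveWater, L.InactiveLand), (L.ActiveWater, L.Nesting),
            (L.ActiveWater, L.InactiveLand),
        }
        assert st.forbidden == {(int(a) - 1, int(b) - 1) for a, b in expected}

    def test_starting_tpm_rows_normalised_with_forbidden_zero(self):
        em, st = es.make_default_spec()
        model = BehaviourHMM(_tiny_windows(), em, st)
        params = model._params_at(model._packer.pack_start(em))
        tpm = params.tpm
        np.testing.assert_allclose(tpm.sum(axis=1), 1.0, atol=1e-12)
        for i, j in st.forbidden:
            assert tpm[i, j] == 0.0
        assert np.all(tpm[tpm > 0] > 0.0)


def _tiny_windows(n=8, gravid=True, individual="A", seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "individual_id": individual,
            "burst_id": f"{individual}_b0",
            "gravid": gravid,
            "window_index": np.arange(n),
            "var_pitch_log10": rng.normal(-3, 2, n),
            "mean_odba_log10": rng.normal(-1.5, 0.7, n),
            "immersed": rng.integers(0, 2, n),
        }
    )


# ---------------------------------------------------------------------------
# emission log-likelihood


class TestEmissionLoglik:
    def test_closed_form_at_state_means(self):
        em, _ = es.make_default_spec()
        k = 2  # InactiveWater
        feats = {
            "var_pitch_log10": em.varpitch_mean[k],
            "mean_odba_log10": em.odba_mean[k],
            "immersed": 1,
        }
        expected = (
            -np.log(em.varpitch_sd[k] * np.sqrt(2 * np.pi))
            - np.log(em.odba_sd[k] * np.sqrt(2 * np.pi))
            + np.log(1 - 1e-12)
        )
        assert es.emission_loglik(feats, em, k) == pytest.approx(expected, abs=1e-10)

    def test_impossible_immersion_costs_log_clamp(self):
        em, _ = es.make_default_spec()
        k = 1  # ActiveLand, P(immersed) = 1e-12
        dry = {"var_pitch_log10": -0.5, "mean_odba_log10": -0.5, "immersed": 0}
        wet = dict(dry, immersed=1)
        diff = es.emission_loglik(wet, em, k) - es.emission_loglik(dry, em, k)
        assert diff == pytest.approx(np.log(1e-12) - np.log(1 - 1e-12), rel=1e-6)
        assert np.log(PROB_CLAMP) == pytest.approx(-27.631, abs=1e-3)

    def test_batch_matches_scalar_oracle(self):
        em, _ = es.make_default_spec()
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "var_pitch_log10": rng.normal(-2, 2, 100),
                "mean_odba_log10": rng.normal(-1, 1, 100),
                "immersed": rng.integers(0, 2, 100),
            }
        )
        mat = emission_logprob_matrix(
            df["var_pitch_log10"].to_numpy(),
            df["mean_odba_log10"].to_numpy(),
            df["immersed"].to_numpy(),
            em,
        )
        from scipy.stats import norm

        for k in range(5):
            p = np.clip(em.immersion_prob[k], 1e-12, 1 - 1e-12)
            oracle = (
                norm.logpdf(df["var_pitch_log10"], em.varpitch_mean[k], em.varpitch_sd[k])
                + norm.logpdf(df["mean_odba_log10"], em.odba_mean[k], em.odba_sd[k])
                + np.where(df["immersed"] == 1, np.log(p), np.log(1 - p))
            )
            np.testing.assert_allclose(mat[:, k], oracle, atol=1e-10)
            np.testing.assert_allclose(es.emission_loglik(df, em, k), oracle, atol=1e-10)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            es.EmissionParams(
                varpitch_mean=[0.0], varpitch_sd=[0.0],
                odba_mean=[0.0], odba_sd=[1.0], immersion_prob=[0.5],
            )


# ---------------------------------------------------------------------------
# forward likelihood & Viterbi vs enumeration


class TestForwardViterbi:
    def test_single_window_closed_form(self):
        from ethostate._kernels import forward_loglik_kernel

        rng = np.random.default_rng(0)
        log_b, tpm, delta = random_instance(rng, K=3, T=1)
        expected = np.log(np.sum(delta * np.exp(log_b[0])))
        got = forward_loglik_kernel(log_b, tpm, delta)
        assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("structural_zeros", [False, True])
    def test_forward_matches_enumeration_fuzz(self, structural_zeros):
        from ethostate._kernels import forward_loglik_kernel

        rng = np.random.default_rng(99 if structural_zeros else 98)
        for _ in range(30):
            K = int(rng.integers(2, 6))
            T = int(rng.integers(2, 9))
            log_b, tpm, delta = random_instance(rng, K, T, structural_zeros)
            oracle = enumerate_loglik(log_b, tpm, delta)
            got = forward_loglik_kernel(log_b, tpm, delta)
            assert got == pytest.approx(oracle, abs=1e-8)

    @pytest.mark.parametrize("structural_zeros", [False, True])
    def test_viterbi_matches_enumeration_fuzz(self, structural_zeros):
        from ethostate._kernels import viterbi_kernel

        rng = np.random.default_rng(7 if structural_zeros else 6)
        for _ in range(30):
            K = int(rng.integers(2, 6))
            T = int(rng.integers(2, 9))
            log_b, tpm, delta = random_instance(rng, K, T, structural_zeros)
            best, path = enumerate_best_path(log_b, tpm, delta)
            with np.errstate(divide="ignore"):
                got = viterbi_kernel(log_b, np.log(tpm), np.log(delta))
            np.testing.assert_array_equal(got, path)

    def test_forbidden_paths_carry_zero_probability(self):
        # enumeration restricted to allowed paths equals full enumeration
        rng = np.random.default_rng(11)
        log_b, tpm, delta = random_instance(rng, K=4, T=5, structural_zeros=True)
        full = enumerate_loglik(log_b, tpm, delta)
        allowed_terms = []
        for path in itertools.product(range(4), repeat=5):
            if any(tpm[a, b] == 0 for a, b in zip(path[:-1], path[1:])):
                continue
            lp = np.log(delta[path[0]]) + log_b[0, path[0]]
            for t in range(1, 5):
                lp += np.log(tpm[path[t - 1], path[t]]) + log_b[t, path[t]]
            allowed_terms.append(lp)
        assert logsumexp(allowed_terms) == pytest.approx(full, abs=1e-10)

    def test_unambiguous_emissions_force_the_path(self):
        # tight, far-apart state distributions: every window is plausible
        # under exactly one state, so Viterbi must return that labelling
        em = es.EmissionParams(
            varpitch_mean=[-20.0, 0.0, 20.0], varpitch_sd=[0.1, 0.1, 0.1],
            odba_mean=[-20.0, 0.0, 20.0], odba_sd=[0.1, 0.1, 0.1],
            immersion_prob=[0.5, 0.5, 0.5],
        )
        st = es.TransitionStructure(n_states=3, forbidden=frozenset(), masked_state=None)
        seq = [0, 0, 2, 1, 1, 0, 2, 2]
        df = pd.DataFrame(
            {
                "individual_id": "G",
                "burst_id": "G_b0",
                "gravid": True,
                "window_index": np.arange(len(seq)),
                "var_pitch_log10": [(-20.0, 0.0, 20.0)[k] for k in seq],
                "mean_odba_log10": [(-20.0, 0.0, 20.0)[k] for k in seq],
                "immersed": 1,
            }
        )
        model = BehaviourHMM(df, em, st)
        params = model._params_at(model._packer.pack_start(em))
        decoded = es.viterbi(params, df)
        np.testing.assert_array_equal(decoded["state"].to_numpy(), np.array(seq) + 1)

    def test_nongravid_track_never_decodes_nesting(self):
        em, st = es.make_default_spec()
        rng = np.random.default_rng(3)
        # features near the Nesting centroid, but the track is non-gravid
        df = pd.DataFrame(
            {
                "individual_id": "M",
                "burst_id": "M_b0",
                "gravid": False,
                "window_index": np.arange(50),
                "var_pitch_log10": rng.normal(0.2, 0.3, 50),
                "mean_odba_log10": rng.normal(-0.5, 0.1, 50),
                "immersed": 0,
            }
        )
        model = BehaviourHMM(df, em, st)
        params = model._params_at(model._packer.pack_start(em))
        decoded = es.viterbi(params, df)
        assert (decoded["state"] != int(StateLabel.Nesting)).all()

    def test_forward_loglik_public_api_matches_kernel(self):
        em, st = es.make_default_spec()
        df = _tiny_windows(n=6, gravid=True)
        model = BehaviourHMM(df, em, st)
        x0 = model._packer.pack_start(em)
        params = model._params_at(x0)
        assert es.forward_loglik(df, params) == pytest.approx(model.loglike(x0))

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError, match="no tracks|zero windows"):
            BehaviourHMM(_tiny_windows(n=0))


# ---------------------------------------------------------------------------
# fitting


class TestFit:
    def test_degenerate_single_state_mle_closed_form(self):
        rng = np.random.default_rng(12)
        n = 400
        df = pd.DataFrame(
            {
                "individual_id": "A",
                "burst_id": "A_b0",
                "gravid": True,
                "window_index": np.arange(n),
                "var_pitch_log10": rng.normal(-2.0, 1.3, n),
                "mean_odba_log10": rng.normal(-1.0, 0.5, n),
                "immersed": (rng.random(n) < 0.7).astype(int),
            }
        )
        em = es.EmissionParams(
            varpitch_mean=[0.0], varpitch_sd=[1.0],
            odba_mean=[0.0], odba_sd=[1.0], immersion_prob=[0.5],
        )
        st = es.TransitionStructure(n_states=1, forbidden=frozenset(), masked_state=None)
        res = BehaviourHMM(df, em, st).fit(seed=0)
        vp = df["var_pitch_log10"].to_numpy()
        od = df["mean_odba_log10"].to_numpy()
        assert res.emission.varpitch_mean[0] == pytest.approx(vp.mean(), abs=1e-4)
        assert res.emission.varpitch_sd[0] == pytest.approx(vp.std(), rel=1e-3)  # ML (n) sd
        assert res.emission.odba_mean[0] == pytest.approx(od.mean(), abs=1e-4)
        assert res.emission.odba_sd[0] == pytest.approx(od.std(), rel=1e-3)
        assert res.emission.immersion_prob[0] == pytest.approx(df["immersed"].mean(), abs=1e-3)

    def test_loglik_never_below_start(self, small_feature_study):
        windows, _ = small_feature_study
        res = es.fit_hmm(windows, seed=0, max_iter=60)
        assert res.llf >= res.start_llf

    def test_refit_from_optimum_is_fixed_point(self, small_feature_study):
        from scipy.optimize import minimize

        windows, _ = small_feature_study
        sub = windows[windows.individual_id.isin(["SYN_001", "SYN_003"])]
        res = es.fit_hmm(sub, seed=0, max_iter=4000, tol=1e-12)
        model = res.model

        def obj(x):
            ll, g = model.loglike_and_grad(x)
            return -ll, -g

        res2 = minimize(
            obj, res.working_params, jac=True, method="L-BFGS-B",
            bounds=model._packer.bounds(), options={"maxiter": 1000, "ftol": 1e-12},
        )
        # restarting at the optimum changes the log-likelihood by < tol
        assert abs(-res2.fun - res.llf) / abs(res.llf) < 1e-8

    def test_analytic_gradient_matches_finite_differences(self):
        from scipy.optimize import approx_fprime

        df = pd.concat(
            [
                _tiny_windows(n=30, gravid=True, individual="A", seed=1),
                _tiny_windows(n=25, gravid=False, individual="B", seed=2),
            ],
            ignore_index=True,
        )
        model = BehaviourHMM(df)
        rng = np.random.default_rng(5)
        x = model._packer.pack_start(model.start_emission)
        x = x + rng.normal(0, 0.2, x.shape)
        x[20:25] = np.clip(x[20:25], -8, 8)  # keep immersion logits interior
        ll, grad = model.loglike_and_grad(x)
        assert ll == pytest.approx(model.loglike(x), abs=1e-9)
        fd = approx_fprime(x, model.loglike, 1e-6)
        np.testing.assert_allclose(grad, fd, rtol=2e-4, atol=2e-4)

    def test_nonfinite_start_names_the_track(self):
        df = _tiny_windows(n=6)
        df.loc[3, "var_pitch_log10"] = np.nan
        with pytest.raises(ValueError, match="A/A_b0|non-finite"):
            BehaviourHMM(df)


# ---------------------------------------------------------------------------
# stationary distribution


class TestStationary:
    def test_symmetric_two_state(self):
        pi = es.stationary_distribution(np.array([[0.9, 0.1], [0.1, 0.9]]))
        np.testing.assert_allclose(pi, [0.5, 0.5], atol=1e-12)

    def test_defining_property_random_constrained(self):
        rng = np.random.default_rng(21)
        _, st = es.make_default_spec()
        mask = st.mask()
        for _ in range(10):
            tpm = rng.dirichlet(np.ones(5), size=5)
            tpm[mask] = 0.0
            tpm = tpm / tpm.sum(axis=1, keepdims=True)
            pi = es.stationary_distribution(tpm)
            assert np.max(np.abs(pi @ tpm - pi)) < 1e-12
            assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(30)
        tpm = rng.dirichlet(np.ones(5) * 2, size=5)
        pi = es.stationary_distribution(tpm)
        p = np.full(5, 0.2)
        for _ in range(10000):
            p = p @ tpm
        np.testing.assert_allclose(pi, p, atol=1e-10)

    def test_reducible_chain_warns(self):
        tpm = np.array([[1.0, 0.0], [0.5, 0.5]])  # state 1 transient
        with pytest.warns(UserWarning):
            pi = es.stationary_distribution(tpm)
        np.testing.assert_allclose(pi, [1.0, 0.0], atol=1e-9)


# ---------------------------------------------------------------------------
# serialization


def test_params_round_trip_json_yaml(tmp_path):
    em, st = es.make_default_spec()
    model = BehaviourHMM(_tiny_windows(n=10))
    params = model._params_at(model._packer.pack_start(em))
    for name in ("p.json", "p.yaml"):
        path = tmp_path / name
        params.save(path)
        back = FittedParams.load(path)
        np.testing.assert_allclose(back.tpm, params.tpm)
        np.testing.assert_allclose(back.emission.varpitch_mean, em.varpitch_mean)
        assert back.structure.forbidden == params.structure.forbidden
        np.testing.assert_allclose(back.initials["A"], params.initials["A"])
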