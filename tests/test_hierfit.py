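"""Hierarchical DE-MCMC machinery: diagnostics, BPIC, contrasts, contracts."""

import numpy as np
import pandas as pd
import pytest

import selstop.hierfit as hf
from selstop.hierfit import (
    Hyperprior,
    ParameterSpace,
    PosteriorSamples,
    SamplerConfig,
    VARIANTS,
    bpic,
    convergence_diagnostics,
    fit_hierarchical,
    model_comparison,
    posterior_contrasts,
    subject_loglik,
    prepare_subject,
)
from selstop.synth import DesignConfig, default_group_truth, generate_behaviour, sample_group

from conftest import make_params


def make_fake_samples(theta, loglik=None, variant=1):
    """PosteriorSamples wrapper around given draws (chains, draws, S, k)."""
    space = ParameterSpace(VARIANTS[variant], Hyperprior())
    C, R, S, k = theta.shape
    assert k == space.k
    return PosteriorSamples(
        variant=VARIANTS[variant], param_names=list(space.names),
        subject_ids=list(range(S)), theta=theta,
        phi_loc=theta.mean(axis=2), phi_scale=np.abs(theta.std(axis=2)) + 1.0,
        loglik=loglik if loglik is not None else np.zeros((C, R)),
        seed=0, config=SamplerConfig(), priors=Hyperprior(),
        burnin_iterations=0, space=space,
        prepared={i: None for i in range(S)},
    )


def white_noise_theta(rng, C=4, R=500, S=2, variant=1, base=None):
    space = ParameterSpace(VARIANTS[variant], Hyperprior())
    mid = np.clip(0.5 * (space.lo + space.hi), space.lo + 2, 500.0)
    if base is None:
        base = mid
    return base + rng.standard_normal((C, R, S, space.k))


class TestVariants:
    def test_variant_parameter_counts(self):
        priors = Hyperprior()
        assert ParameterSpace(VARIANTS[1], priors).k == 24
        assert ParameterSpace(VARIANTS[3], priors).k == 21
        assert ParameterSpace(VARIANTS[4], priors).k == 18
        assert ParameterSpace(VARIANTS[5], priors).k == 27

    def test_shared_runner_maps_to_same_columns(self):
        space = ParameterSpace(VARIANTS[1], Hyperprior())
        assert space.runner_cols[("dual_stop", "reactive")] == \
            space.runner_cols[("dual_stop", "proactive")]
        assert space.runner_cols[("dual_go", "reactive")] != \
            space.runner_cols[("dual_go", "proactive")]

    def test_vector_round_trip_to_sis_params(self):
        space = ParameterSpace(VARIANTS[1], Hyperprior())
        rng = np.random.default_rng(0)
        vec = np.clip(space.loc_mean + rng.standard_normal(space.k),
                      space.lo + 1, space.hi - 1)
        params = space.to_sis_params(vec)
        i, j, l = space.runner_cols[("dual_go", "reactive")]
        assert params.dual_go["reactive"].mu == vec[i]
        assert 0 < params.tf < 1


class TestLikelihoodConsistency:
    def test_matches_trial_loglik(self, small_study):
        from selstop.sis import trial_loglik

        obs = small_study["observed"]
        df = obs[obs["participant"] == 0]
        df = df[["participant", "condition", "trial", "stimulus", "ssd_ms",
                 "response", "rt_ms"]]
        space = ParameterSpace(VARIANTS[5], Hyperprior())
        prepared = prepare_subject(df)
        params = small_study["cohort"][0]
        # assemble the matching parameter vector
        vec = np.empty(space.k)
        for (runner, cond), (i, j, l) in space.runner_cols.items():
            rp = getattr(params, runner)[cond]
            vec[i], vec[j], vec[l] = rp.mu, rp.sigma, rp.tau
        from scipy.special import ndtri
        for p, name in (("gf", "gf"), ("tf", "tf"), ("eps_wrong", "eps_wrong")):
            vec[space.probit_idx[name]] = ndtri(getattr(params, p))
        fast = float(subject_loglik(space, vec[None, :], prepared)[0])
        slow = sum(
            trial_loglik(params, r.condition, r.stimulus, r.response,
                         None if pd.isna(r.rt_ms) else r.rt_ms,
                         None if pd.isna(r.ssd_ms) else r.ssd_ms)
            for r in df.itertuples()
        )
        assert fast == pytest.approx(slow, abs=0.1)


class TestDiagnostics:
    def test_white_noise_passes(self, rng):
        s = make_fake_samples(white_noise_theta(rng))
        diag = convergence_diagnostics(s)
        sub = diag[diag["parameter"].str.startswith("subject")]
        assert (sub["rhat"] < 1.01).all()
        assert (sub["ess"] > 200).all()
        assert sub["pass"].all()

    def test_offset_chain_fails(self, rng):
        theta = white_noise_theta(rng)
        theta[0] += 10.0
        diag = convergence_diagnostics(make_fake_samples(theta))
        sub = diag[diag["parameter"].str.startswith("subject")]
        assert (sub["rhat"] > 1.1).all()
        assert not sub["pass"].any()

    def test_constant_chains_reported_as_failure(self, rng):
        theta = np.ones((4, 500, 2, 24)) * 300.0
        diag = convergence_diagnostics(make_fake_samples(theta))
        assert not diag["pass"].any()
        assert (diag["reason"].str.contains("variance") | diag["rhat"].isna()).any()

    def test_too_few_draws_rejected(self, rng):
        s = make_fake_samples(white_noise_theta(rng, R=20))
        with pytest.raises(ValueError, match="50"):
            convergence_diagnostics(s)


class TestBPIC:
    def test_arithmetic_from_definition(self, rng, monkeypatch):
        # Dbar = 100 from stored deviances; D(theta_bar) = 90 via stub
        s = make_fake_samples(white_noise_theta(rng, R=100),
                              loglik=np.full((4, 100), -50.0))
        monkeypatch.setattr(hf, "subject_loglik",
                            lambda space, th, prep: np.array([-22.5]))
        # two subjects: D(theta_bar) = -2 * (-22.5 - 22.5) = 90
        assert bpic(s) == pytest.approx(100 + 2 * (100 - 90))

    def test_point_mass_posterior_has_zero_pd(self, rng, monkeypatch):
        s = make_fake_samples(white_noise_theta(rng, R=100),
                              loglik=np.full((4, 100), -45.0))
        monkeypatch.setattr(hf, "subject_loglik",
                            lambda space, th, prep: np.array([-22.5]))
        assert bpic(s) == pytest.approx(90.0)  # pD = 0 -> BPIC = Dbar

    def test_negative_pd_warns(self, rng, monkeypatch):
        s = make_fake_samples(white_noise_theta(rng, R=100),
                              loglik=np.full((4, 100), -40.0))
        monkeypatch.setattr(hf, "subject_loglik",
                            lambda space, th, prep: np.array([-22.5]))
        with pytest.warns(RuntimeWarning, match="pD"):
            val = bpic(s)
        assert np.isfinite(val)

    def test_model_comparison_table(self, rng, monkeypatch):
        monkeypatch.setattr(hf, "subject_loglik",
                            lambda space, th, prep: np.array([-22.5]))
        fits = {
            "m1": make_fake_samples(white_noise_theta(rng, R=100),
                                    loglik=np.full((4, 100), -50.0)),
            "m5": make_fake_samples(white_noise_theta(rng, R=100, variant=5),
                                    loglik=np.full((4, 100), -55.0), variant=5),
        }
        table = model_comparison(fits)
        assert list(table["model"]) == ["m1", "m5"]
        assert table["delta_bpic"].iloc[0] == 0.0


class TestContrasts:
    def test_identical_conditions_give_zero(self, rng):
        theta = white_noise_theta(rng, variant=5)
        space = ParameterSpace(VARIANTS[5], Hyperprior())
        ia = space.runner_cols[("dual_go", "proactive")]
        ib = space.runner_cols[("dual_go", "reactive")]
        theta[..., list(ia)] = theta[..., list(ib)]
        s = make_fake_samples(theta, variant=5)
        res = posterior_contrasts(s, [("dual_go", "proactive", 1),
                                      ("dual_go", "reactive", -1)])
        assert res["median"] == 0.0
        assert res["ci95"] == (0.0, 0.0)

    def test_self_contrast_is_identically_zero(self, rng):
        s = make_fake_samples(white_noise_theta(rng))
        res = posterior_contrasts(s, [("dual_go", "reactive", 1),
                                      ("dual_go", "reactive", -1)])
        assert np.all(res["draws"] == 0.0)

    def test_shared_runner_contrast_rejected(self, rng):
        s = make_fake_samples(white_noise_theta(rng))  # variant 1
        with pytest.raises(ValueError, match="variant 1"):
            posterior_contrasts(s, [("dual_stop", "proactive", 1),
                                    ("dual_stop", "reactive", -1)])


def tiny_config(**kw):
    base = dict(individual_iterations=8, max_iterations=20,
                retained_iterations=8, check_every=5, rhat_window=5,
                rhat_max=50.0, funnel_reps=1, migration_prob=0.0)
    base.update(kw)
    return SamplerConfig(**base)


@pytest.fixture(scope="module")
def tiny_data():
    cohort = sample_group(default_group_truth(), 2, seed=21)
    obs, _, _ = generate_behaviour(
        cohort, DesignConfig(n_trials_per_condition=36), seed=22)
    return obs[["participant", "condition", "trial", "stimulus", "ssd_ms",
                "response", "rt_ms"]]


class TestFitContracts:
    def test_deterministic_given_seed(self, tiny_data):
        a = fit_hierarchical(tiny_data, 1, config=tiny_config(), seed=42)
        b = fit_hierarchical(tiny_data, 1, config=tiny_config(), seed=42)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.loglik, b.loglik)
        c = fit_hierarchical(tiny_data, 1, config=tiny_config(), seed=43)
        assert not np.array_equal(a.theta, c.theta)

    def test_single_participant_rejected(self, tiny_data):
        solo = tiny_data[tiny_data["participant"] == 0]
        with pytest.raises(ValueError, match="2 participants"):
            fit_hierarchical(solo, 1, config=tiny_config(), seed=0)

    def test_participant_without_stop_trials_rejected(self, tiny_data):
        df = tiny_data.copy()
        mask = (df["participant"] == 1) & df["stimulus"].isin(("LS", "RS"))
        df = df[~mask]
        with pytest.raises(ValueError, match="stop trials"):
            fit_hierarchical(df, 1, config=tiny_config(), seed=0)

    def test_too_few_chains_rejected(self, tiny_data):
        with pytest.raises(ValueError, match="chains"):
            fit_hierarchical(tiny_data, 1, config=tiny_config(chains=10), seed=0)

    def test_nonconvergence_raises_with_diagnostics(self, tiny_data):
        cfg = tiny_config(rhat_max=1.0000001, max_iterations=12,
                          check_every=5, rhat_window=5)
        with pytest.raises(hf.ConvergenceError) as err:
            fit_hierarchical(tiny_data, 1, config=cfg, seed=0)
        assert err.value.diagnostics is not None
        assert "rhat" in err.value.diagnostics.columns
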