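"""SIS race model: simulation, likelihood, stop-win probability, censoring."""

import collections

import numpy as np
import pytest
from scipy.stats import ks_2samp

from selstop.exgauss import RunnerParams, exg_sample
from selstop.sis import (
    CensoringWindow,
    censoring_bias_sim,
    category_probabilities,
    detectability_margin_ms,
    simulate_trial,
    simulate_trials,
    staircase_stop_run,
    stop_win_probability,
    trial_loglik,
)
from selstop.task_design import TrialSpec

from conftest import make_params


def near_deterministic(go, stop, sel, **kw):
    """Point-mass-like runners force the race outcome."""
    eps = 1e-6
    return make_params(go=(go, eps, eps), stop=(stop, eps, eps),
                       sel=(sel, eps, eps), **kw)


class TestRaceRule:
    def test_successful_stop_timing(self, rng):
        # stop finishes at 250+100=350 < go 400: unimanual press at 250+290
        p = near_deterministic(400, 100, 290)
        trial = TrialSpec(0, "reactive", "none", "LS", 600.0)
        out = simulate_trial(p, trial, ssd=250.0, rng=rng)
        assert out.response == "LR"
        assert out.stop_success
        assert out.rt_ms == pytest.approx(540.0, abs=0.1)
        assert out.margin_ms == pytest.approx(50.0, abs=0.1)

    def test_failed_stop_timing(self, rng):
        # stop would finish at 250+200=450 > go 400: bimanual press escapes
        p = near_deterministic(400, 200, 290)
        trial = TrialSpec(0, "reactive", "none", "RS", 600.0)
        out = simulate_trial(p, trial, ssd=250.0, rng=rng)
        assert out.response == "DR"
        assert not out.stop_success
        assert out.rt_ms == pytest.approx(400.0, abs=0.1)

    def test_nothing_launched_is_no_response(self, rng):
        p = make_params(gf=1.0, tf=1.0)
        trial = TrialSpec(0, "reactive", "none", "LS", 600.0)
        out = simulate_trial(p, trial, ssd=200.0, rng=rng)
        assert out.response == "NR"
        assert not out.go_launched and not out.stop_launched

    def test_deadline_pushes_response_to_nr(self, rng):
        p = near_deterministic(1200, 2000, 290)
        trial = TrialSpec(0, "reactive", "none", "DS", 600.0)
        out = simulate_trial(p, trial, ssd=None, rng=rng)
        assert out.response == "NR"

    def test_failed_stop_rts_faster_than_go_rts(self, study_params, rng):
        go = simulate_trials(study_params, "reactive", "DS", 0.0, 4000, rng)
        stop = simulate_trials(study_params, "reactive", "LS", 250.0, 4000, rng)
        go_rt = go["rt"][go["response"] == "DR"]
        failed_rt = stop["rt"][stop["response"] == "DR"]
        assert np.nanmean(failed_rt) < np.nanmean(go_rt)

    def test_successful_stop_rt_minus_ssd_is_selective_runner(self, study_params, rng):
        sim = simulate_trials(study_params, "reactive", "LS", 250.0, 20_000, rng)
        ok = (sim["response"] == "LR") & sim["stop_success"]
        rel = sim["rt"][ok] - 250.0
        ref = exg_sample(study_params.sel_left["reactive"], 10_000, rng)
        ref = ref[250.0 + ref <= 1100.0]
        assert ks_2samp(rel, ref).pvalue > 0.01


class TestLikelihood:
    @pytest.mark.parametrize("cond,stim,ssd", [
        ("reactive", "DS", None),
        ("reactive", "LS", 250.0),
        ("proactive", "RS", 150.0),
    ])
    def test_category_probabilities_sum_to_one(self, study_params, cond, stim, ssd):
        probs = category_probabilities(study_params, cond, stim, ssd)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-4)

    def test_matches_simulation_frequencies(self, study_params, rng):
        n = 50_000
        sim = simulate_trials(study_params, "reactive", "LS", 250.0, n, rng)
        freq = collections.Counter(sim["response"])
        probs = category_probabilities(study_params, "reactive", "LS", 250.0)
        for cat, p in probs.items():
            mc = freq[cat] / n
            se = np.sqrt(max(p * (1 - p), 1e-8) / n)
            assert abs(p - mc) <= 3 * se, (cat, p, mc)

    def test_loglik_matches_category_probability_for_nr(self, study_params):
        ll = trial_loglik(study_params, "reactive", "LS", "NR", ssd_ms=250.0)
        p_nr = category_probabilities(study_params, "reactive", "LS", 250.0)["NR"]
        assert ll == pytest.approx(np.log(p_nr))

    def test_no_omission_limit_hits_floor(self):
        # S_G(1100) < p_floor when the go runner is fast and light-tailed
        p = make_params(go=(300.0, 30.0, 30.0))
        ll = trial_loglik(p, "reactive", "DS", "NR")
        assert ll == pytest.approx(np.log(p.p_floor))

    def test_large_ssd_limit_recovers_go_density(self, study_params):
        import selstop.exgauss as xg

        g = study_params.dual_go["reactive"]
        ll = trial_loglik(study_params, "reactive", "LS", "DR", rt_ms=420.0,
                         ssd_ms=1050.0)
        expected = np.log((1 - study_params.gf)) + xg.logpdf(420.0, g.mu, g.sigma, g.tau)
        assert ll == pytest.approx(float(expected), abs=1e-6)

    def test_rt_outside_window_rejected(self, study_params):
        with pytest.raises(ValueError, match="NR"):
            trial_loglik(study_params, "reactive", "DS", "DR", rt_ms=1200.0)
        with pytest.raises(ValueError, match="NR"):
            trial_loglik(study_params, "reactive", "DS", "DR", rt_ms=-5.0)

    def test_loglik_order_invariant_sum(self, study_params, rng):
        trials = [("DS", "DR", 430.0, None), ("LS", "LR", 560.0, 250.0),
                  ("LS", "DR", 400.0, 250.0), ("RS", "NR", None, 300.0)]
        lls = [trial_loglik(study_params, "reactive", s, r, rt, d)
               for s, r, rt, d in trials]
        total = sum(lls)
        rng.shuffle(trials)
        total2 = sum(trial_loglik(study_params, "reactive", s, r, rt, d)
                     for s, r, rt, d in trials)
        assert total == pytest.approx(total2)


class TestStopWinProbability:
    go = RunnerParams(450, 50, 50)
    stop = RunnerParams(150, 30, 30)

    def test_dominance_limit(self):
        assert stop_win_probability(self.go, self.stop, 0.0) > 0.999

    def test_monotone_in_ssd(self):
        ds = np.linspace(0, 600, 13)
        ps = [stop_win_probability(self.go, self.stop, d) for d in ds]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("ssd", [0.0, 150.0, 250.0, 400.0])
    def test_exact_equals_quadrature(self, ssd):
        e = stop_win_probability(self.go, self.stop, ssd)
        q = stop_win_probability(self.go, self.stop, ssd, method="quad")
        assert e == pytest.approx(q, abs=1e-5)

    def test_matches_monte_carlo(self, rng):
        n = 1_000_000
        tg = exg_sample(self.go, n, rng)
        ts = exg_sample(self.stop, n, rng)
        mc = np.mean(250.0 + ts < tg)
        se = np.sqrt(mc * (1 - mc) / n)
        assert stop_win_probability(self.go, self.stop, 250.0) == pytest.approx(
            mc, abs=3 * se)


class TestCensoring:
    def test_threshold_arithmetic(self):
        assert detectability_margin_ms() == 90.0
        assert detectability_margin_ms(50, 20, 20) == 90.0

    def test_window_validation(self):
        with pytest.raises(ValueError):
            CensoringWindow(115, 90)

    def test_unbounded_window_has_no_bias(self, study_params, rng):
        wide = CensoringWindow(1e-9, 1e9)
        res = censoring_bias_sim(study_params, wide, 20_000, rng)
        for cond in res.values():
            assert cond["censored_fraction"] > 0.99
            assert abs(cond["bias_ms"]) < 1.0

    def test_point_mass_margins_all_or_nothing(self, rng):
        p = near_deterministic(450, 150, 290)
        run = staircase_stop_run(p, "reactive", 2000, rng)
        margins = run["margin"][run["success"]]
        # margins live on the SSD lattice: per unique margin the censored
        # membership is all-or-nothing
        uniq = np.unique(np.round(margins, 6))
        w = CensoringWindow()
        for m in uniq:
            inside = w.contains(margins[np.isclose(margins, m)])
            assert inside.all() or not inside.any()

    def test_empty_censored_subset_raises(self, rng):
        p = near_deterministic(450, 150, 290)  # margins on lattice miss [2,3]
        with pytest.raises(RuntimeError, match="censored subset empty"):
            censoring_bias_sim(p, CensoringWindow(2.0, 3.0), 400, rng)

    def test_staircase_tracks_half(self, study_params, rng):
        run = staircase_stop_run(study_params, "reactive", 6000, rng)
        assert run["success"][1000:].mean() == pytest.approx(0.5, abs=0.03)
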