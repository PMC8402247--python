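"""Decay fitting, posterior machinery and the two Bayesian estimators."""

import numpy as np
import pytest

from cuffsim.collapse import CollapseParams
from cuffsim.features import Envelope, lower_envelope
from cuffsim.inference import (EnvelopeForward, LikelihoodSpec, analytic_tau,
                               detect_decay_onset, equilibrium_pressure,
                               fit_exponential, hdi_95, infer_collapse,
                               log_likelihood_envelope, mcmc_infer_circuit,
                               _adaptive_metropolis)
from cuffsim.simulate import (CircuitParams, CuffProfile, SystemicWave,
                              generate_cuff_ramp, generate_systemic_wave,
                              simulate)
from cuffsim.timing import simulated_timing_table


class TestAnalytic:
    def test_series_combination_value(self):
        cp = CircuitParams(Ca=0.03, Cv=0.9, Rs=106.0)
        assert analytic_tau(cp) == pytest.approx(3.0774, abs=1e-3)

    def test_large_cv_limit(self):
        cp = CircuitParams(Ca=0.03, Cv=1e6, Rs=106.0)
        assert analytic_tau(cp) == pytest.approx(106.0 * 0.03, rel=1e-4)

    def test_symmetric_in_compliances(self):
        a = analytic_tau(CircuitParams(Ca=0.05, Cv=0.7, Rs=90.0))
        b = analytic_tau(CircuitParams(Ca=0.7, Cv=0.05, Rs=90.0))
        assert a == pytest.approx(b, rel=1e-12)

    def test_equilibrium_trivial_cases(self):
        cp = CircuitParams(Ca=0.03, Cv=0.9, Rs=106.0)
        assert equilibrium_pressure(40.0, 40.0, cp) == pytest.approx(40.0)
        eq = CircuitParams(Ca=0.5, Cv=0.5, Rs=106.0)
        assert equilibrium_pressure(60.0, 20.0, eq) == pytest.approx(40.0)

    def test_equilibrium_matches_simulated_asymptote(self, preset, preset_inputs):
        """Long-horizon oracle: a 40 s hold lets the decay reach its asymptote."""
        wave_obj = preset.wave
        cuff_prof = CuffProfile(t_start=5.0, ramp_duration=25.0, p_max=150.0,
                                hold_duration=45.0)
        dur = cuff_prof.t_end
        wave = generate_systemic_wave(wave_obj, dur)
        cuff = generate_cuff_ramp(cuff_prof, dur)
        res = simulate(preset.circuit, preset.collapse, wave, cuff, 1e-3)
        t_on = detect_decay_onset(res, wave_obj)
        i_on = int(t_on / 1e-3)
        peq = equilibrium_pressure(res.p_art_distal[i_on], res.p_ven_distal[i_on],
                                   preset.circuit)
        assert abs(res.p_art_distal[-1] - peq) < 0.5


class TestExpFit:
    @pytest.mark.parametrize("tau,peq,p0", [(3.08, 23.0, 30.0), (1.5, 10.0, 80.0),
                                            (8.0, 35.0, 60.0)])
    def test_exact_on_noiseless_exponential(self, tau, peq, p0):
        t = np.arange(0.0, 6.0, 1e-3)
        y = peq + (p0 - peq) * np.exp(-t / tau)
        fit = fit_exponential(y, t)
        assert fit.tau == pytest.approx(tau, rel=1e-6)
        assert fit.p_equilibrium == pytest.approx(peq, rel=1e-6)
        assert fit.residual_rms < 1e-8

    def test_short_window_rejected(self):
        t = np.arange(0.0, 1.0, 1e-3)
        with pytest.raises(ValueError):
            fit_exponential(np.exp(-t), t)

    def test_fit_matches_formula_deep_in_decay(self, preset, preset_sim):
        """One second past collapse the fitted tau agrees with the closed form."""
        t_on = detect_decay_onset(preset_sim, preset.wave) + 1.0
        i0 = int(t_on / preset.dt)
        i1 = i0 + int(12.0 / preset.dt)
        fit = fit_exponential(preset_sim.p_art_distal[i0:i1], preset_sim.t[i0:i1])
        assert fit.tau == pytest.approx(analytic_tau(preset.circuit), rel=0.05)


class TestHdi:
    def test_standard_normal(self):
        rng = np.random.default_rng(0)
        lo, hi = hdi_95(rng.standard_normal(200_000))
        assert lo == pytest.approx(-1.96, abs=0.04)
        assert hi == pytest.approx(1.96, abs=0.04)

    def test_constant_samples(self):
        lo, hi = hdi_95(np.full(5000, 3.3))
        assert lo == hi == 3.3

    def test_uniform_width(self):
        rng = np.random.default_rng(1)
        lo, hi = hdi_95(rng.uniform(0, 1, 100_000))
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_agrees_with_arviz_on_skewed_sample(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        x = rng.gamma(2.0, 1.0, 50_000)
        ours = hdi_95(x)
        theirs = arviz.hdi(x, hdi_prob=0.95)
        assert np.allclose(ours, theirs, atol=0.02)


class TestSampler:
    @staticmethod
    def gauss2d(mu, sd):
        def lp(x):
            return -0.5 * np.sum(((x - mu) / sd) ** 2)
        return lp

    def test_recovers_gaussian_moments(self):
        mu = np.array([1.0, -2.0])
        sd = np.array([0.5, 1.5])
        samples, acc = _adaptive_metropolis(self.gauss2d(mu, sd), np.zeros(2),
                                            40_000, seed=0)
        assert 0.1 < acc < 0.7
        assert np.allclose(np.mean(samples, axis=0), mu, atol=0.1)
        assert np.allclose(np.std(samples, axis=0), sd, rtol=0.15)

    def test_agrees_with_emcee(self):
        emcee = pytest.importorskip("emcee")
        mu = np.array([0.5, 1.5])
        sd = np.array([0.3, 0.8])
        ours, _ = _adaptive_metropolis(self.gauss2d(mu, sd), np.zeros(2),
                                       30_000, seed=1)
        np.random.seed(7)  # emcee draws from the global numpy state
        sampler = emcee.EnsembleSampler(8, 2, self.gauss2d(mu, sd))
        rng = np.random.default_rng(1)
        sampler.run_mcmc(rng.normal(0, 0.1, (8, 2)), 3000)
        theirs = sampler.get_chain(discard=500, flat=True)
        assert np.allclose(np.median(ours, axis=0), np.median(theirs, axis=0), atol=0.08)

    def test_bad_start_rejected(self):
        def lp(x):
            return -np.inf
        with pytest.raises(ValueError):
            _adaptive_metropolis(lp, np.zeros(2), 1000, seed=0)


class TestInferCollapse:
    def test_too_few_points(self, preset):
        with pytest.raises(ValueError):
            infer_collapse(np.arange(5.0), np.zeros(5), preset.wave, preset.collapse)

    def test_samples_respect_prior_support(self, preset, ramp_beats):
        post = infer_collapse(ramp_beats.cuff_at_beat.to_numpy(),
                              ramp_beats.dpat.to_numpy(), preset.wave,
                              preset.collapse, p_beat=ramp_beats.p_dia.to_numpy(),
                              mode="full", n_iter=4000, seed=0)
        assert np.all(post.samples > 0.0)
        for j in range(2):
            assert post.hdi95[j, 0] <= post.central[j] <= post.hdi95[j, 1]

    def test_truncated_coverage_over_seeds(self, preset, ramp_beats):
        """True (a, c) falls inside the 95% HDI for most noisy replicates."""
        pc = ramp_beats.cuff_at_beat.to_numpy()
        base = ramp_beats.dpat.to_numpy()
        pb = ramp_beats.p_dia.to_numpy()
        hits_a = hits_c = 0
        n_rep = 10
        for k in range(n_rep):
            rng = np.random.default_rng(100 + k)
            noisy = base + rng.normal(0.0, 0.001, base.shape)
            post = infer_collapse(pc, noisy, preset.wave, preset.collapse,
                                  p_beat=pb, mode="truncate_at_pdia",
                                  n_iter=15_000, seed=k)
            if post.hdi95[0, 0] <= 0.03 <= post.hdi95[0, 1]:
                hits_a += 1
            if post.hdi95[1, 0] <= 0.1 <= post.hdi95[1, 1]:
                hits_c += 1
        assert hits_a >= int(0.8 * n_rep)
        assert hits_c >= int(0.8 * n_rep)


class TestEnvelopeLikelihood:
    @staticmethod
    def identity_forward(env):
        return lambda theta: env

    def test_perfect_match_value(self):
        env = Envelope(cuff_grid=np.arange(10.0), bp_env=np.full(10, 60.0))
        spec = LikelihoodSpec(sigma=2.0)
        val = log_likelihood_envelope((1, 1, 1), env, spec, self.identity_forward(env))
        assert val == pytest.approx(10 * np.log(1.0 / np.sqrt(2 * np.pi * 4.0)))

    def test_constant_offset_penalty(self):
        n = 8
        env = Envelope(cuff_grid=np.arange(float(n)), bp_env=np.full(n, 60.0))
        shifted = Envelope(cuff_grid=env.cuff_grid, bp_env=env.bp_env + 4.0)
        spec = LikelihoodSpec(sigma=2.0)
        base = log_likelihood_envelope(None, env, spec, self.identity_forward(env))
        off = log_likelihood_envelope(None, shifted, spec, self.identity_forward(env))
        assert base - off == pytest.approx(2.0 * n)

    def test_truth_beats_perturbation(self, preset, preset_inputs, preset_sim):
        wave_s, cuff_s = preset_inputs
        env = lower_envelope(preset_sim.p_art_distal, preset_sim.p_cuff, 1000.0,
                             preset.wave.heart_rate)
        fwd = EnvelopeForward(preset.wave, wave_s, cuff_s, 1e-3,
                              preset.collapse, preset.circuit)
        spec = LikelihoodSpec()
        cp = preset.circuit
        ll_true = log_likelihood_envelope((cp.Ca, cp.Rs, cp.Cv), env, spec, fwd)
        ll_off = log_likelihood_envelope((cp.Ca, cp.Rs * 1.5, cp.Cv), env, spec, fwd)
        assert ll_true > ll_off

    def test_forward_failure_is_rejected(self):
        env = Envelope(cuff_grid=np.arange(5.0), bp_env=np.full(5, 60.0))

        def broken(theta):
            raise ValueError("no")

        assert log_likelihood_envelope((1, 1, 1), env, LikelihoodSpec(), broken) == -np.inf


class TestCircuitMcmc:
    def test_seed_stability_and_recovery(self, preset, preset_inputs, preset_sim):
        wave_s, cuff_s = preset_inputs
        env = lower_envelope(preset_sim.p_art_distal, preset_sim.p_cuff, 1000.0,
                             preset.wave.heart_rate)
        fwd = EnvelopeForward(preset.wave, wave_s, cuff_s, 1e-3,
                              preset.collapse, preset.circuit)
        posts = [mcmc_infer_circuit(env, fwd, n_iter=2500, seed=s) for s in (0, 1)]
        for p in posts:
            assert np.all(p.samples > 0.0)
        widths = posts[0].hdi95[:, 1] - posts[0].hdi95[:, 0]
        assert np.all(np.abs(posts[0].central - posts[1].central) < widths)

    def test_recovery_across_noisy_replicates(self, preset, preset_sim):
        """Median relative error of the posterior centres stays below 15%
        across seeded noisy envelopes (2 mmHg measurement noise)."""
        # coarser grid keeps the many forward solves cheap
        dt = 2e-3
        dur = preset.duration
        wave_s = generate_systemic_wave(preset.wave, dur, sample_rate=1 / dt)
        cuff_s = generate_cuff_ramp(preset.cuff, dur, sample_rate=1 / dt)
        res = simulate(preset.circuit, preset.collapse, wave_s, cuff_s, dt)
        env0 = lower_envelope(res.p_art_distal, res.p_cuff, 1 / dt,
                              preset.wave.heart_rate)
        fwd = EnvelopeForward(preset.wave, wave_s, cuff_s, dt,
                              preset.collapse, preset.circuit)
        truth = np.array([preset.circuit.Ca, preset.circuit.Rs, preset.circuit.Cv])
        rel_err = []
        for k in range(8):
            rng = np.random.default_rng(200 + k)
            env = Envelope(cuff_grid=env0.cuff_grid,
                           bp_env=env0.bp_env + rng.normal(0, 2.0, env0.bp_env.shape))
            post = mcmc_infer_circuit(env, fwd, n_iter=1500, seed=k)
            rel_err.append(np.abs(post.central - truth) / truth)
        med = np.median(np.array(rel_err), axis=0)
        assert np.all(med < 0.15)


class TestDecayWindow:
    def test_onset_requires_collapse(self, preset):
        wave = generate_systemic_wave(preset.wave, 20.0)
        res = simulate(preset.circuit, preset.collapse, wave,
                       np.zeros_like(wave), 1e-3)
        with pytest.raises(ValueError):
            detect_decay_onset(res, preset.wave)
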