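"""Maturation-corrected synthesis-rate inference and Hill fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ringosc as ro
from ringosc.synth import _forward_recursion


def _trace_from_syn(syn, dil=0.15, dt=8.0, mat=None):
    mat = ro.transfer.maturation_rate_from_time(29.0) if mat is None else mat
    Pd, Pf = _forward_recursion(np.asarray(syn, float), dil, dt, mat)
    return ro.FluorescenceTrace(times=np.arange(Pf.size) * dt, Pf=Pf,
                                dil=dil, dt=dt, mat=mat), Pd


class TestInversion:
    def test_steady_state_dark_pool(self):
        """Constant fluorescence P* implies P_d = dil * P* / (mat dt)."""
        dil, dt, mat = 0.2, 10.0, 0.03
        Pstar = 40.0
        trace = ro.FluorescenceTrace(times=np.arange(5) * dt, Pf=np.full(5, Pstar),
                                     dil=dil, dt=dt, mat=mat)
        Pd = ro.infer_dark_protein(trace)
        np.testing.assert_allclose(Pd, dil * Pstar / (mat * dt))

    def test_zero_trace_zero_dark(self):
        trace = ro.FluorescenceTrace(times=np.arange(6) * 8.0, Pf=np.zeros(6),
                                     dil=0.15, dt=8.0, mat=0.03)
        assert np.all(ro.infer_dark_protein(trace) == 0.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_exact_round_trip_random_profiles(self, seed):
        """The inference equations invert the forward step recursion exactly."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        syn = rng.uniform(0.0, 2.0, n)
        dil = rng.uniform(0.05, 0.3)
        dt = rng.uniform(5.0, 12.0)
        mat = rng.uniform(0.01, 0.08)
        trace, Pd_true = _trace_from_syn(syn, dil, dt, mat)
        Pd = ro.infer_dark_protein(trace)
        np.testing.assert_allclose(Pd, Pd_true[:-1], atol=1e-10)
        rec = ro.infer_synthesis_rate(trace, Pd)
        np.testing.assert_allclose(rec, syn[:-1], rtol=1e-9, atol=1e-9)

    def test_zero_maturation_rejected(self):
        with pytest.raises(ValueError):
            ro.FluorescenceTrace(times=np.arange(4) * 8.0, Pf=np.zeros(4),
                                 dil=0.15, dt=8.0, mat=0.0)


class TestAssembly:
    def test_recovers_truth_noiseless(self, hill_truth):
        spec = ro.SynthSpec(seed=1, noise_cv=0.0, truth=hill_truth)
        prom, rep, hidden = ro.gen_transfer_experiment(spec)
        curve = ro.assemble_transfer_curve(prom, rep, smooth=False)
        expected = ro.hill_repression(curve.x, hill_truth["ymin"],
                                      hill_truth["K_M"], hill_truth["n"])
        np.testing.assert_allclose(curve.y, expected, atol=5e-3)
        assert np.all(curve.x > 1.0)

    def test_zero_repressor_run_filtered_empty(self, hill_truth):
        spec = ro.SynthSpec(seed=2, noise_cv=0.0, truth=hill_truth, ramp_peak=1e-6)
        prom, rep, _ = ro.gen_transfer_experiment(spec)
        curve = ro.assemble_transfer_curve(prom, rep, smooth=False)
        assert len(curve) == 0

    def test_misaligned_traces_rejected(self, hill_truth):
        spec = ro.SynthSpec(seed=3, noise_cv=0.0, truth=hill_truth)
        prom, rep, _ = ro.gen_transfer_experiment(spec)
        other = ro.FluorescenceTrace(times=rep.times[:-1], Pf=rep.Pf[:-1],
                                     dil=rep.dil, dt=rep.dt, mat=rep.mat)
        with pytest.raises(ValueError):
            ro.assemble_transfer_curve(prom, other)

    def test_dilution_time_invariance_noiseless(self, hill_truth):
        """One truth rendered at two dilution protocols gives one curve."""
        fits = []
        for dil in (0.10, 0.25):
            spec = ro.SynthSpec(seed=4, noise_cv=0.0, dil=dil, truth=hill_truth)
            prom, rep, _ = ro.gen_transfer_experiment(spec)
            fits.append(ro.fit_hill(ro.assemble_transfer_curve(prom, rep, smooth=False)))
        assert fits[0].K_M == pytest.approx(fits[1].K_M, rel=0.01)
        assert fits[0].n_hill == pytest.approx(fits[1].n_hill, abs=0.02)


class TestHillFit:
    def _curve(self, ymin=0.05, K=5.0, n=2.0, npts=30, cv=0.0, seed=0):
        x = np.geomspace(1.1, 60.0, npts)
        y = ro.hill_repression(x, ymin, K, n)
        if cv > 0:
            rng = np.random.default_rng(seed)
            sig = np.sqrt(np.log1p(cv ** 2))
            x = x * rng.lognormal(-0.5 * sig ** 2, sig, npts)
            y = y * rng.lognormal(-0.5 * sig ** 2, sig, npts)
        return ro.TransferCurve(x=x, y=y, v_max=1.0)

    def test_noiseless_exact_recovery(self):
        res = ro.fit_hill(self._curve())
        assert res.ymin == pytest.approx(0.05, abs=1e-6)
        assert res.K_M == pytest.approx(5.0, abs=1e-5)
        assert res.n_hill == pytest.approx(2.0, abs=1e-6)

    def test_midpoint_identity(self):
        res = ro.fit_hill(self._curve(cv=0.09, seed=5))
        mid = res.predict(res.K_M)
        assert mid == pytest.approx(res.ymin + (1 - res.ymin) / 2, abs=1e-12)

    def test_monte_carlo_recovery_at_stated_noise(self):
        """9% errors-in-variables noise on both axes, 200 seeded replicates."""
        errK, errN = [], []
        for seed in range(200):
            res = ro.fit_hill(self._curve(cv=0.09, seed=seed))
            errK.append(abs(res.K_M - 5.0) / 5.0)
            errN.append(abs(res.n_hill - 2.0))
        assert np.median(errK) < 0.15
        assert np.median(errN) < 0.3

    def test_insufficient_span_refused(self):
        x = np.geomspace(1.1, 8.0, 20)
        y = ro.hill_repression(x, 0.05, 100.0, 2.0)   # K_M far above data range
        with pytest.raises(ValueError, match="half-maximal"):
            ro.HillTransferModel(ro.TransferCurve(x=x, y=y, v_max=1.0))

    def test_too_few_points_refused(self):
        c = self._curve(npts=5)
        with pytest.raises(ValueError, match="6 curve points"):
            ro.HillTransferModel(c)

    def test_normalization_scale_invariance(self):
        """Rescaling raw rates before normalization leaves K_M and n unchanged."""
        spec = ro.SynthSpec(seed=6, noise_cv=0.0,
                            truth={"ymin": 0.05, "K_M": 5.0, "n": 2.0, "v_max": 1.0})
        p1, r1, _ = ro.gen_transfer_experiment(spec)
        spec2 = ro.SynthSpec(seed=6, noise_cv=0.0,
                             truth={"ymin": 0.05, "K_M": 5.0, "n": 2.0, "v_max": 7.7})
        p2, r2, _ = ro.gen_transfer_experiment(spec2)
        f1 = ro.fit_hill(ro.assemble_transfer_curve(p1, r1, smooth=False))
        f2 = ro.fit_hill(ro.assemble_transfer_curve(p2, r2, smooth=False))
        assert f1.K_M == pytest.approx(f2.K_M, rel=1e-6)
        assert f1.n_hill == pytest.approx(f2.n_hill, rel=1e-6)

    def test_summary_renders(self):
        s = ro.fit_hill(self._curve()).summary()
        assert "K_M" in s and "nM" in s

    def test_maturation_uncertainty_insensitivity(self, hill_truth):
        """Fits shift < 10% in K_M when the assumed maturation times move
        within their measured uncertainties (15+-4, 29+-3 min)."""
        spec = ro.SynthSpec(seed=7, noise_cv=0.0, truth=hill_truth)
        prom, rep, _ = ro.gen_transfer_experiment(spec)
        ref = ro.fit_hill(ro.assemble_transfer_curve(prom, rep, smooth=False))
        for t_cer, t_cit in [(11.0, 26.0), (19.0, 32.0)]:
            rep_p = ro.FluorescenceTrace(rep.times, rep.Pf, rep.dil, rep.dt,
                                         ro.transfer.maturation_rate_from_time(t_cer))
            prom_p = ro.FluorescenceTrace(prom.times, prom.Pf, prom.dil, prom.dt,
                                          ro.transfer.maturation_rate_from_time(t_cit))
            fit = ro.fit_hill(ro.assemble_transfer_curve(prom_p, rep_p, smooth=False))
            assert abs(fit.K_M - ref.K_M) / ref.K_M < 0.10


class TestVmaxNormalization:
    def test_basic_and_idempotent(self):
        out = ro.normalize_vmax({"A": 2.0, "B": 4.0}, "A")
        assert out == {"A": 1.0, "B": 2.0}
        assert ro.normalize_vmax(out, "A") == out

    def test_single_entry(self):
        assert ro.normalize_vmax({"ref": 3.3}, "ref") == {"ref": 1.0}

    def test_errors(self):
        with pytest.raises(KeyError):
            ro.normalize_vmax({"A": 1.0}, "B")
        with pytest.raises(ValueError):
            ro.normalize_vmax({"A": 0.0}, "A")
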