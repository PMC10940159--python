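"""Pressure-clamp analysis: step amplitudes, Boltzmann fit, I-V, noise analysis."""

import numpy as np
import pytest

from lysomech import synthetic as syn
from lysomech.ephys import (
    NoReversalError,
    PressureProtocol,
    ProtocolAlignmentError,
    SweepEnsemble,
    ZeroGatingVarianceError,
    boltzmann_fit,
    iv_reversal,
    mean_step_amplitudes,
    nonstationary_noise,
    step_amplitudes,
)


def synthetic_ensemble(plateaus, sample_rate=100.0, baseline=0.0):
    """Deterministic square-step sweep built directly from the protocol."""
    proto = PressureProtocol(
        steps_mmhg=[-10.0 * (k + 1) for k in range(len(plateaus))],
        step_duration_s=0.5,
        baseline_duration_s=0.2,
    )
    n = int(round(proto.total_duration_s() * sample_rate))
    sweep = np.full(n, baseline)
    for (bsl, stp), level in zip(proto.windows(sample_rate), plateaus):
        sweep[stp] = level
    return SweepEnsemble(
        sweeps=np.vstack([sweep, sweep]), sample_rate_hz=sample_rate, protocol=proto
    )


class TestStepAmplitudes:
    def test_plateau_minus_baseline(self):
        ens = synthetic_ensemble([-50.0], baseline=0.0)
        amps = step_amplitudes(ens)
        assert amps.amplitude_pa.to_list() == pytest.approx([-50.0, -50.0])

    def test_flat_sweep_all_zero(self):
        ens = synthetic_ensemble([0.0, 0.0, 0.0])
        assert (step_amplitudes(ens).amplitude_pa == 0).all()

    def test_forward_model_saturating_step(self):
        gating = syn.GatingSpec(
            n_channels=100, unitary_current_pa=0.1, p50_mmhg=45, slope_mmhg=1e-9,
            sample_rate_hz=500,
        )
        proto = PressureProtocol(steps_mmhg=[-80.0])
        ens = syn.simulate_sweeps(gating, proto, n_sweeps=3, seed=0)
        amps = step_amplitudes(ens)
        assert amps.amplitude_pa.to_list() == pytest.approx([10.0] * 3)

    def test_linearity_in_current_scale(self):
        ens = synthetic_ensemble([-10.0, -20.0, -40.0])
        a1 = step_amplitudes(ens).amplitude_pa.to_numpy()
        ens.sweeps = 3.0 * ens.sweeps
        a3 = step_amplitudes(ens).amplitude_pa.to_numpy()
        assert np.allclose(a3, 3.0 * a1)

    def test_misaligned_protocol_raises(self):
        ens = synthetic_ensemble([-50.0])
        ens.sweeps = ens.sweeps[:, :10]
        with pytest.raises(ProtocolAlignmentError):
            step_amplitudes(ens)

    def test_peak_mode(self):
        ens = synthetic_ensemble([-50.0])
        stp = ens.protocol.windows(100.0)[0][1]
        ens.sweeps[:, stp.start] = -80.0  # transient peak at step onset
        steady = step_amplitudes(ens, mode="steady").amplitude_pa.iloc[0]
        peak = step_amplitudes(ens, mode="peak").amplitude_pa.iloc[0]
        assert steady == pytest.approx(-50.0)
        assert peak == pytest.approx(-80.0)


class TestBoltzmannFit:
    def test_noise_free_exact_recovery(self):
        p = -np.arange(10.0, 90.0, 10.0)
        i = 20.0 / (1.0 + np.exp((45.0 - np.abs(p)) / 6.0))
        fit = boltzmann_fit(p, i)
        assert fit.p50_mmhg == pytest.approx(45.0, rel=1e-3)
        assert fit.slope_mmhg == pytest.approx(6.0, rel=1e-3)
        assert fit.imax_pa == pytest.approx(20.0, rel=1e-3)
        assert not fit.extrapolated

    def test_midpoint_identity(self):
        p = -np.arange(10.0, 90.0, 10.0)
        i = 20.0 / (1.0 + np.exp((45.0 - np.abs(p)) / 6.0))
        fit = boltzmann_fit(p, i)
        assert fit.predict(np.array([fit.p50_mmhg]))[0] == pytest.approx(
            fit.imax_pa / 2.0, rel=1e-6
        )

    def test_pressure_shift_equivariance(self):
        p = np.arange(10.0, 90.0, 10.0)
        i = 20.0 / (1.0 + np.exp((45.0 - p) / 6.0))
        base = boltzmann_fit(p, i)
        shifted = boltzmann_fit(p + 15.0, i)
        assert shifted.p50_mmhg == pytest.approx(base.p50_mmhg + 15.0, rel=1e-3)
        scaled = boltzmann_fit(p, 4.0 * i)
        assert scaled.p50_mmhg == pytest.approx(base.p50_mmhg, rel=1e-3)
        assert scaled.imax_pa == pytest.approx(4.0 * base.imax_pa, rel=1e-3)

    def test_negative_inward_currents(self):
        p = np.arange(10.0, 90.0, 10.0)
        i = -20.0 / (1.0 + np.exp((45.0 - p) / 6.0))  # inward convention
        fit = boltzmann_fit(p, i)
        assert fit.p50_mmhg == pytest.approx(45.0, rel=1e-3)
        assert fit.imax_pa == pytest.approx(-20.0, rel=1e-3)

    def test_multiplicative_noise_median_recovery(self):
        rng = np.random.default_rng(0)
        p = np.arange(10.0, 90.0, 10.0)
        clean = 20.0 / (1.0 + np.exp((45.0 - p) / 6.0))
        errs = []
        for _ in range(100):
            noisy = clean * rng.normal(1.0, 0.05, size=len(p))
            errs.append(abs(boltzmann_fit(p, noisy).p50_mmhg - 45.0))
        assert np.median(errs) < 0.10 * 45.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_fit([10, 20, 30], [1, 2, 3])
        with pytest.raises(ValueError):
            boltzmann_fit([10, 20, 30, 40], [5, 5, 5, 5])


class TestIVReversal:
    def test_symmetric_pair(self):
        e, g = iv_reversal([-60.0, 60.0], [-10.0, 10.0])
        assert e == pytest.approx(0.0)
        assert g == pytest.approx(10.0 / 60.0)

    def test_ohmic_exact_root(self):
        v = np.array([-40.0, -10.0, 20.0, 50.0, 80.0])
        i = 0.3 * (v - 20.0)
        e, g = iv_reversal(v, i)
        assert e == pytest.approx(20.0)
        assert g == pytest.approx(0.3)

    def test_affine_root_property(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            g_true = rng.uniform(0.05, 2.0)
            e_true = rng.uniform(-50.0, 50.0)
            v = np.linspace(-80.0, 80.0, 9)
            e, g = iv_reversal(v, g_true * (v - e_true))
            assert e == pytest.approx(e_true, abs=1e-9)
            assert g == pytest.approx(g_true, abs=1e-12)

    def test_no_reversal_raises(self):
        # the non-permeant-cation case: current never changes sign
        with pytest.raises(NoReversalError):
            iv_reversal([-60.0, 0.0, 60.0], [5.0, 8.0, 12.0])


class TestNonstationaryNoise:
    def test_parabola_apex_identity(self):
        gating = syn.GatingSpec(noise_sd_pa=0.5, sample_rate_hz=1000)
        proto = PressureProtocol.ramp()
        ens = syn.simulate_sweeps(gating, proto, n_sweeps=200, seed=0)
        res = nonstationary_noise(
            ens.sweeps, baseline_window=proto.windows(1000)[0][0]
        )
        # binomial identities on the fitted parabola: apex at (N i/2, N i^2/4)
        assert res.apex_current_pa == pytest.approx(
            res.n_channels * res.unitary_current_pa / 2.0, rel=1e-12
        )
        assert res.apex_variance_pa2 == pytest.approx(
            res.n_channels * res.unitary_current_pa**2 / 4.0, rel=1e-12
        )
        assert res.apex_in_support

    def test_parameter_recovery(self):
        gating = syn.GatingSpec(noise_sd_pa=0.5, sample_rate_hz=1000)
        proto = PressureProtocol.ramp()
        ens = syn.simulate_sweeps(gating, proto, n_sweeps=200, seed=3)
        res = nonstationary_noise(
            ens.sweeps,
            baseline_window=proto.windows(1000)[0][0],
            holding_mv=-60.0,
            reversal_mv=0.0,
        )
        assert res.unitary_current_pa == pytest.approx(0.1, rel=0.15)
        assert res.n_channels == pytest.approx(100.0, rel=0.25)
        # gamma = i / |V - E_rev|: 0.1 pA / 60 mV = 1.667 pS
        assert res.conductance_ps == pytest.approx(0.1 / 60.0 * 1000.0, rel=0.15)

    def test_deterministic_input_rejected(self):
        sweeps = np.tile(np.linspace(0, 10, 100), (25, 1))
        with pytest.raises(ZeroGatingVarianceError):
            nonstationary_noise(sweeps)

    def test_too_few_sweeps_rejected(self):
        with pytest.raises(ValueError):
            nonstationary_noise(np.random.default_rng(0).normal(size=(5, 100)))
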