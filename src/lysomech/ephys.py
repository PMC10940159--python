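"""Pressure-clamp electrophysiology analysis.

Covers the quantities reported for stretch-activated currents: per-step
current amplitudes under a stepwise suction protocol, a two-state
Boltzmann dose-response in pressure magnitude with half-activation
pressure P50, the reversal potential from an I-V relation, and
non-stationary noise analysis (ensemble variance vs mean current
parabola) yielding the unitary current i, channel count N, and the
single-channel conductance gamma = i / (V_hold - E_rev).

Sign conventions: suction pressures are negative (as delivered by the
pressure clamp); fits use the pressure magnitude |P|. Current sign is
whatever the recording convention provides — amplitudes are returned
signed, and the dose-response / noise analysis operate on magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class ProtocolAlignmentError(ValueError):
    pass


class NoReversalError(ValueError):
    pass


class ZeroGatingVarianceError(ValueError):
    pass


@dataclass
class PressureProtocol:
    """Stepwise suction protocol.

    Each step consists of a zero-pressure baseline window of
    ``baseline_duration_s`` followed by ``step_duration_s`` at the step
    pressure. Defaults follow the 500-ms step convention.
    """

    steps_mmhg: list[float]
    step_duration_s: float = 0.5
    baseline_duration_s: float = 0.2

    def __post_init__(self):
        if self.step_duration_s <= 0 or self.baseline_duration_s <= 0:
            raise ValueError("durations must be positive")

    @classmethod
    def ramp(
        cls, start: float = -10.0, stop: float = -80.0, increment: float = -10.0, **kw
    ) -> "PressureProtocol":
        """Stepwise ramp, e.g. -10 to -80 mmHg in 10-mmHg increments."""
        n = int(round((stop - start) / increment)) + 1
        return cls(steps_mmhg=[start + k * increment for k in range(n)], **kw)

    @property
    def n_steps(self) -> int:
        return len(self.steps_mmhg)

    def total_duration_s(self) -> float:
        return self.n_steps * (self.baseline_duration_s + self.step_duration_s)

    def windows(self, sample_rate_hz: float) -> list[tuple[slice, slice]]:
        """(baseline_slice, step_slice) sample windows for each step."""
        nb = int(round(self.baseline_duration_s * sample_rate_hz))
        ns = int(round(self.step_duration_s * sample_rate_hz))
        out = []
        pos = 0
        for _ in self.steps_mmhg:
            out.append((slice(pos, pos + nb), slice(pos + nb, pos + nb + ns)))
            pos += nb + ns
        return out

    def pressure_series(self, sample_rate_hz: float) -> np.ndarray:
        """Commanded pressure at every sample."""
        n = int(round(self.total_duration_s() * sample_rate_hz))
        p = np.zeros(n)
        for (bsl, stp), pr in zip(self.windows(sample_rate_hz), self.steps_mmhg):
            p[stp] = pr
        return p


@dataclass
class SweepEnsemble:
    """Repeated current sweeps aligned to one pressure protocol."""

    sweeps: np.ndarray  # (n_sweeps, n_samples), pA
    sample_rate_hz: float
    protocol: PressureProtocol
    holding_mv: float | None = None

    def __post_init__(self):
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.sweeps.shape[1]) / self.sample_rate_hz


@dataclass
class DoseResponseFit:
    p50_mmhg: float
    slope_mmhg: float
    imax_pa: float
    p50_stderr: float
    p50_interpolated_mmhg: float
    extrapolated: bool
    pressures_mmhg: np.ndarray = field(repr=False)
    normalized_currents: np.ndarray = field(repr=False)

    def predict(self, pressure_mmhg: np.ndarray) -> np.ndarray:
        return _boltzmann(np.abs(pressure_mmhg), self.imax_pa, self.p50_mmhg, self.slope_mmhg)


@dataclass
class NoiseAnalysisResult:
    unitary_current_pa: float
    n_channels: float
    baseline_variance_pa2: float
    apex_current_pa: float
    apex_variance_pa2: float
    apex_in_support: bool
    conductance_ps: float | None
    bin_mean_pa: np.ndarray = field(repr=False)
    bin_variance_pa2: np.ndarray = field(repr=False)


def step_amplitudes(
    ensemble: SweepEnsemble,
    mode: str = "steady",
    steady_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-step, per-sweep current amplitude relative to the preceding
    baseline.

    ``mode='steady'`` (default): mean over the last ``steady_fraction`` of
    the step window minus the baseline-window mean — appropriate for
    slow, non-inactivating stretch currents. ``mode='peak'``: extremal
    deviation from baseline within the step window.
    """
    wins = ensemble.protocol.windows(ensemble.sample_rate_hz)
    n_samp = ensemble.sweeps.shape[1]
    if wins[-1][1].stop > n_samp:
        raise ProtocolAlignmentError(
            f"protocol needs {wins[-1][1].stop} samples, sweeps have {n_samp}"
        )
    rows = []
    for step_idx, ((bsl, stp), p) in enumerate(
        zip(wins, ensemble.protocol.steps_mmhg)
    ):
        base = ensemble.sweeps[:, bsl].mean(axis=1)
        seg = ensemble.sweeps[:, stp]
        if mode == "steady":
            k = int(round(seg.shape[1] * (1 - steady_fraction)))
            amp = seg[:, k:].mean(axis=1) - base
        elif mode == "peak":
            dev = seg - base[:, None]
            idx = np.argmax(np.abs(dev), axis=1)
            amp = dev[np.arange(len(idx)), idx]
        else:
            raise ValueError(f"unknown mode: {mode}")
        for s, a in enumerate(amp):
            rows.append(
                {
                    "sweep": s,
                    "step": step_idx,
                    "pressure_mmhg": p,
                    "amplitude_pa": float(a),
                }
            )
    return pd.DataFrame(rows, columns=["sweep", "step", "pressure_mmhg", "amplitude_pa"])


def mean_step_amplitudes(amplitudes: pd.DataFrame) -> pd.DataFrame:
    """Ensemble-mean amplitude per pressure step."""
    out = (
        amplitudes.groupby(["step", "pressure_mmhg"], as_index=False)["amplitude_pa"]
        .mean()
        .sort_values("step", ignore_index=True)
    )
    return out


def _boltzmann(p_abs, imax, p50, s):
    return imax / (1.0 + np.exp((p50 - p_abs) / s))


def boltzmann_fit(
    pressures_mmhg: np.ndarray, amplitudes_pa: np.ndarray
) -> DoseResponseFit:
    """Two-state Boltzmann dose-response fit in pressure magnitude.

    Fits I(P) = Imax / (1 + exp((P50 - |P|)/s)) by least squares and also
    reports a fit-free P50 obtained by linear interpolation of the
    measured curve at half its maximal amplitude. Requires >= 4 distinct
    pressure levels and a non-degenerate amplitude range.
    """
    p = np.abs(np.asarray(pressures_mmhg, dtype=float))
    i_raw = np.asarray(amplitudes_pa, dtype=float)
    if len(np.unique(p)) < 4:
        raise ValueError("need at least 4 distinct pressure levels")
    if np.ptp(i_raw) == 0:
        raise ValueError("degenerate dose-response: all amplitudes equal")
    order = np.argsort(p)
    p, i_raw = p[order], i_raw[order]
    sign = np.sign(i_raw[np.argmax(np.abs(i_raw))])
    i = i_raw * sign  # fit on magnitudes; restore sign on Imax at the end

    imax0 = float(i.max())
    half = imax0 / 2.0
    above = np.nonzero(i >= half)[0]
    p50_0 = float(p[above[0]]) if len(above) else float(p[-1])
    s0 = max((p.max() - p.min()) / 10.0, 1.0)
    popt, pcov = curve_fit(
        _boltzmann,
        p,
        i,
        p0=[imax0, p50_0, s0],
        maxfev=20000,
    )
    imax, p50, slope = popt
    if slope < 0:  # equivalent mirrored optimum; canonicalize rising form
        slope = abs(slope)
    p50_err = float(np.sqrt(np.abs(pcov[1, 1])))

    # fit-free interpolated P50 at half of the largest measured amplitude
    p50_interp = float(np.interp(half, i, p))
    return DoseResponseFit(
        p50_mmhg=float(p50),
        slope_mmhg=float(slope),
        imax_pa=float(imax * sign),
        p50_stderr=p50_err,
        p50_interpolated_mmhg=p50_interp,
        extrapolated=not (p.min() <= p50 <= p.max()),
        pressures_mmhg=p,
        normalized_currents=i / imax if imax != 0 else i,
    )


def iv_reversal(
    voltages_mv: np.ndarray, currents_pa: np.ndarray
) -> tuple[float, float]:
    """Reversal potential and slope conductance from an I-V relation.

    E_rev is found by linear interpolation between the bracketing voltage
    pair where the current changes sign (an exact zero counts). The slope
    conductance (nS) is the local chord slope across the bracketing pair.
    Raises :class:`NoReversalError` when the current never changes sign in
    the sampled range — e.g. for a non-permeant cation.
    """
    v = np.asarray(voltages_mv, dtype=float)
    i = np.asarray(currents_pa, dtype=float)
    order = np.argsort(v)
    v, i = v[order], i[order]
    zero = np.nonzero(i == 0)[0]
    if len(zero):
        k = int(zero[0])
        lo, hi = max(k - 1, 0), min(k + 1, len(v) - 1)
        g = (i[hi] - i[lo]) / (v[hi] - v[lo]) if v[hi] != v[lo] else float("nan")
        return float(v[k]), float(g)
    sign_change = np.nonzero(np.sign(i[:-1]) != np.sign(i[1:]))[0]
    if not len(sign_change):
        raise NoReversalError("current does not reverse in the sampled voltage range")
    k = int(sign_change[0])
    g = (i[k + 1] - i[k]) / (v[k + 1] - v[k])
    e_rev = v[k] - i[k] / g
    return float(e_rev), float(g)


def nonstationary_noise(
    sweeps: np.ndarray,
    baseline_window: slice | None = None,
    n_bins: int = 10,
    holding_mv: float | None = None,
    reversal_mv: float | None = None,
) -> NoiseAnalysisResult:
    """Non-stationary noise analysis of a sweep ensemble.

    At each time sample the ensemble mean current I and across-sweep
    variance sigma^2 are computed; the baseline variance (from
    ``baseline_window`` when given) is subtracted; samples are pooled into
    ``n_bins`` equal-count bins by mean current and the binomial parabola

        sigma^2(I) = i*I - I^2/N

    is fit by least squares, giving the unitary current i and channel
    count N. When holding and reversal potentials are supplied the
    single-channel conductance gamma = i/(V_hold - E_rev) is returned in
    pS. Requires >= 20 sweeps and a mean current spanning a range wide
    enough to identify the parabola.
    """
    sweeps = np.asarray(sweeps, dtype=float)
    if sweeps.ndim != 2 or sweeps.shape[0] < 20:
        raise ValueError("need a 2-D ensemble with at least 20 sweeps")
    mean_t = sweeps.mean(axis=0)
    var_t = sweeps.var(axis=0, ddof=1)
    if baseline_window is not None:
        i0 = float(mean_t[baseline_window].mean())
        sigma0 = float(var_t[baseline_window].mean())
    else:
        i0, sigma0 = 0.0, 0.0
    # work on magnitude of the baseline-subtracted mean current
    di = mean_t - i0
    sign = np.sign(di[np.argmax(np.abs(di))]) or 1.0
    cur = di * sign
    var_g = var_t - sigma0

    if np.ptp(cur) <= 0 or float(np.max(var_g)) <= 0:
        raise ZeroGatingVarianceError("ensemble shows no gating variance")

    order = np.argsort(cur)
    cur_s, var_s = cur[order], var_g[order]
    edges = np.linspace(0, len(cur_s), n_bins + 1).astype(int)
    bin_i, bin_i2, bin_v = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi > lo:
            bin_i.append(cur_s[lo:hi].mean())
            bin_i2.append((cur_s[lo:hi] ** 2).mean())
            bin_v.append(var_s[lo:hi].mean())
    bin_i = np.asarray(bin_i)
    bin_i2 = np.asarray(bin_i2)
    bin_v = np.asarray(bin_v)
    if np.ptp(bin_i) <= 0:
        raise ZeroGatingVarianceError("mean current does not span a range")

    # regress bin-mean variance on bin means of I and I^2: under the model
    # var = i*I - I^2/N, averaging within a bin is exact for these moments,
    # whereas squaring the bin-mean current would bias the quadratic term
    design = np.column_stack([bin_i, bin_i2])
    coef, *_ = np.linalg.lstsq(design, bin_v, rcond=None)
    a, b = coef
    if a <= 0 or b >= 0:
        raise ZeroGatingVarianceError(
            "variance-mean relation is not a concave parabola through the origin"
        )
    i_unit = float(a)
    n_chan = float(-1.0 / b)
    apex_i = n_chan * i_unit / 2.0
    apex_v = n_chan * i_unit**2 / 4.0
    gamma = None
    if holding_mv is not None and reversal_mv is not None:
        dv = holding_mv - reversal_mv
        if dv == 0:
            raise ValueError("holding potential equals reversal potential")
        gamma = abs(i_unit / dv) * 1000.0  # pA/mV = nS -> pS
    return NoiseAnalysisResult(
        unitary_current_pa=i_unit,
        n_channels=n_chan,
        baseline_variance_pa2=sigma0,
        apex_current_pa=apex_i,
        apex_variance_pa2=apex_v,
        apex_in_support=bool(bin_i.min() <= apex_i <= bin_i.max()),
        conductance_ps=gamma,
        bin_mean_pa=bin_i,
        bin_variance_pa2=bin_v,
    )
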