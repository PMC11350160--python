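"""Inverse problem: recover (mua, musp) from a measured DTOF.

The measured curve is compared with the IRF-convolved, amplitude-scaled and
time-shifted semi-infinite diffusion model over a restricted fit range: the
channels with counts above 80% of the peak on the leading edge and above 1%
of the peak on the falling edge. The objective is a Pearson chi-square with
model variance, appropriate for Poisson counting statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .curves import DTOFCurve, IRFCurve, OpticalProperties
from .forward import convolve_with_irf, tr_reflectance

__all__ = [
    "FitRange",
    "FitResult",
    "determine_fit_range",
    "fit_homogeneous",
    "estimate_tmax",
]


@dataclass(frozen=True)
class FitRange:
    """Inclusive channel-index interval used for fitting."""

    i_start: int
    i_end: int

    def __post_init__(self) -> None:
        if self.i_start >= self.i_end:
            raise ValueError(f"need i_start < i_end, got [{self.i_start}, {self.i_end}]")

    def slice(self) -> slice:
        return slice(self.i_start, self.i_end + 1)


@dataclass(frozen=True)
class FitResult:
    mua: float
    musp: float
    amplitude: float
    time_shift: float
    chi2_reduced: float
    fit_range: FitRange
    converged: bool


def determine_fit_range(
    dtof: DTOFCurve,
    leading_frac: float = 0.80,
    falling_frac: float = 0.01,
) -> FitRange:
    """Fit range from relative thresholds on the two edges of the DTOF.

    Scanning backward from the peak, the leading edge keeps the contiguous
    channels whose counts exceed ``leading_frac`` of the peak value; the
    falling edge extends to the first channel at or below ``falling_frac`` of
    the peak (the crossing channel is included; if the curve never crosses,
    the range ends at the last channel). Both thresholds are relative, so the
    range is invariant under rescaling of the counts.
    """
    counts = dtof.counts
    peak = float(counts.max())
    if peak <= 0:
        raise ValueError("cannot determine a fit range on an all-zero curve")
    i_peak = int(np.argmax(counts))  # earliest channel on ties

    i_start = i_peak
    while i_start > 0 and counts[i_start - 1] > leading_frac * peak:
        i_start -= 1

    i_end = dtof.axis.n_channels - 1
    for i in range(i_peak + 1, dtof.axis.n_channels):
        if counts[i] <= falling_frac * peak:
            i_end = i
            break
    if i_start >= i_end:
        raise ValueError(
            f"degenerate fit range [{i_start}, {i_end}]: peak at the trailing edge"
        )
    return FitRange(i_start=i_start, i_end=i_end)


def _model_counts(
    params: np.ndarray,
    dtof: DTOFCurve,
    irf: IRFCurve,
    n_in: float,
    n_out: float,
) -> np.ndarray:
    mua, musp, log_amp, shift = params
    props = OpticalProperties(mua=max(mua, 0.0), musp=musp, n_in=n_in, n_out=n_out)
    t = dtof.axis.centers - shift
    refl = tr_reflectance(dtof.rho, t, props)
    conv = convolve_with_irf(refl, irf, dtof.axis)
    return np.exp(log_amp) * conv


def fit_homogeneous(
    dtof: DTOFCurve,
    irf: IRFCurve,
    init: tuple[float, float] | None = None,
    fit_range: FitRange | None = None,
    n_in: float = 1.4,
    n_out: float = 1.0,
    mua_bounds: tuple[float, float] = (0.0, 2.0),
    musp_bounds: tuple[float, float] = (1.0, 50.0),
    shift_bound: float = 0.1,
    n_restarts: int = 3,
) -> FitResult:
    """Fit (mua, musp) plus amplitude and a bounded time shift to a DTOF.

    Minimises the Pearson chi-square (variance = model counts) between the
    measured counts and the IRF-convolved diffusion model, restricted to the
    fit range of :func:`determine_fit_range`. A free global amplitude and a
    time shift bounded to +/-``shift_bound`` ns (residual offset of the t = 0
    definition at the IRF peak) are always fitted. On optimizer failure up to
    ``n_restarts`` perturbed restarts are attempted before returning
    ``converged=False``.
    """
    if not np.all(np.isfinite(dtof.counts)):
        raise ValueError("DTOF counts must be finite")
    if fit_range is None:
        fit_range = determine_fit_range(dtof)
    sl = fit_range.slice()
    data = dtof.counts[sl]

    mua0, musp0 = init if init is not None else (0.1, 10.0)
    mua0 = float(np.clip(mua0, mua_bounds[0] + 1e-6, mua_bounds[1] - 1e-6))
    musp0 = float(np.clip(musp0, musp_bounds[0] + 1e-6, musp_bounds[1] - 1e-6))

    lb = np.array([mua_bounds[0], musp_bounds[0], -60.0, -shift_bound])
    ub = np.array([mua_bounds[1], musp_bounds[1], 60.0, shift_bound])

    def residuals(params: np.ndarray) -> np.ndarray:
        model = _model_counts(params, dtof, irf, n_in, n_out)[sl]
        sigma = np.sqrt(np.maximum(model, 1e-12))
        return (data - model) / sigma

    def initial_log_amp(mua: float, musp: float) -> float:
        raw = _model_counts(np.array([mua, musp, 0.0, 0.0]), dtof, irf, n_in, n_out)[sl]
        tot = raw.sum()
        return float(np.log(max(data.sum(), 1e-12) / max(tot, 1e-300)))

    rng = np.random.default_rng(0)
    best = None
    for attempt in range(1 + n_restarts):
        if attempt == 0:
            m0, s0 = mua0, musp0
        else:
            m0 = float(np.clip(mua0 * rng.uniform(0.5, 2.0), lb[0] + 1e-6, ub[0] - 1e-6))
            s0 = float(np.clip(musp0 * rng.uniform(0.6, 1.6), lb[1] + 1e-6, ub[1] - 1e-6))
        x0 = np.array([m0, s0, initial_log_amp(m0, s0), 0.0])
        try:
            sol = least_squares(residuals, x0, bounds=(lb, ub), method="trf", xtol=1e-10)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and sol.cost / max(data.size - 4, 1) < 10.0:
            break

    if best is None:
        return FitResult(
            mua=mua0, musp=musp0, amplitude=np.nan, time_shift=0.0,
            chi2_reduced=np.inf, fit_range=fit_range, converged=False,
        )
    mua, musp, log_amp, shift = best.x
    dof = max(data.size - 4, 1)
    return FitResult(
        mua=float(mua),
        musp=float(musp),
        amplitude=float(np.exp(log_amp)),
        time_shift=float(shift),
        chi2_reduced=float(2.0 * best.cost / dof),
        fit_range=fit_range,
        converged=bool(best.success),
    )


def estimate_tmax(
    dtof: DTOFCurve,
    gate_width: float = 0.5,
    count_rate_threshold: float = 1.0e4,
) -> float | None:
    """Latest gate start still collecting more than the threshold count rate.

    Scans gates [t, t + gate_width) with t on the channel grid and returns the
    largest start time whose gated counts exceed
    ``count_rate_threshold * acq_time`` (default 10,000 counts/s, the 1%
    shot-noise condition for a 0.5 ns late gate). Returns None when no gate
    qualifies. The criterion is a rate, so the answer is invariant to changes
    of acquisition time at a fixed count rate.
    """
    if gate_width <= 0:
        raise ValueError(f"gate width must be > 0, got {gate_width}")
    axis = dtof.axis
    need = count_rate_threshold * dtof.acq_time
    centers = axis.centers
    csum = np.concatenate(([0.0], np.cumsum(dtof.counts)))
    n_gate = max(int(round(gate_width / axis.dt)), 1)
    best: float | None = None
    # only gates that fit entirely on the axis are considered
    for i in range(axis.n_channels - n_gate + 1):
        gated = csum[i + n_gate] - csum[i]
        if gated > need:
            best = float(centers[i])
    return best
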