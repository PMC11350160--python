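"""Time-resolved diffuse reflectance of a semi-infinite medium.

The forward model for all DTOF fitting: the solution of the time-dependent
diffusion equation for a homogeneous semi-infinite medium under the
extrapolated boundary condition, using a single positive/negative image-source
pair. The extrapolated (zero-fluence) plane sits a distance z_e = 2 A D above
the physical surface, where D = 1/(3 mus') is the diffusion coefficient and A
accounts for the refractive-index mismatch at the surface. The overall
amplitude is arbitrary: fits always carry a free scale factor.
"""

from __future__ import annotations

import numpy as np

from .curves import IRFCurve, OpticalProperties, TimeAxis

__all__ = ["boundary_reflection_factor", "tr_reflectance", "convolve_with_irf"]


def boundary_reflection_factor(n_in: float, n_out: float = 1.0) -> float:
    """Boundary factor A for the extrapolated boundary condition.

    Uses the internal-reflection parametrisation A = (1 + r_d)/(1 - r_d) with
    the Groenhuis polynomial approximation of the angle-averaged Fresnel
    reflectance r_d in the relative index n = n_in/n_out. A(1.4) ~ 3.25;
    matched indices give A = 1 (no internal reflection).
    """
    n = n_in / n_out
    if n <= 0:
        raise ValueError("refractive indices must be positive")
    if abs(n - 1.0) < 1e-12:
        return 1.0
    r_d = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    r_d = min(max(r_d, 0.0), 0.999)
    return (1.0 + r_d) / (1.0 - r_d)


def tr_reflectance(
    rho: float,
    t_axis: TimeAxis | np.ndarray,
    props: OpticalProperties,
) -> np.ndarray:
    """Time-resolved reflectance R(rho, t) of a homogeneous semi-infinite medium.

    Evaluates the dipole (image-source) solution of the diffusion equation at
    the channel centres of ``t_axis``: an isotropic source buried at depth
    z0 = 1/mus', mirrored across the extrapolated boundary at -(z0 + 2 z_e).
    Causality holds exactly: R = 0 for t <= 0. Units of the returned curve are
    arbitrary (photons per unit area per unit time up to a global scale).

    Parameters
    ----------
    rho : float
        Source-detector distance, cm (> 0).
    t_axis : TimeAxis or array of times (ns)
    props : OpticalProperties

    Returns
    -------
    ndarray of R evaluated at the channel centres.
    """
    if rho <= 0:
        raise ValueError(f"source-detector distance must be > 0, got rho={rho}")
    t = t_axis.centers if isinstance(t_axis, TimeAxis) else np.asarray(t_axis, dtype=float)

    v = props.v
    D = 1.0 / (3.0 * props.musp)
    z0 = 1.0 / props.musp
    A = boundary_reflection_factor(props.n_in, props.n_out)
    ze = 2.0 * A * D
    z_img = z0 + 2.0 * ze

    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    tp = t[pos]
    dvt4 = 4.0 * D * v * tp
    # dipole flux across the physical surface
    pref = np.exp(-props.mua * v * tp - rho**2 / dvt4) / (
        2.0 * (4.0 * np.pi * D * v) ** 1.5 * tp**2.5
    )
    out[pos] = pref * (
        z0 * np.exp(-z0**2 / dvt4) + z_img * np.exp(-z_img**2 / dvt4)
    )
    return out


def convolve_with_irf(
    model: np.ndarray,
    irf: IRFCurve,
    model_axis: TimeAxis,
) -> np.ndarray:
    """Convolve a model reflectance curve with a measured IRF.

    Discrete linear convolution, truncated back to the model's own axis. The
    two axes must share the channel width; the IRF may start at negative times
    (its peak defines t = 0), which is handled as an integer channel offset.
    The result approximates integral convolution: a single-channel unit IRF at
    t = 0 returns the model scaled by dt.
    """
    if not model_axis.compatible_with(irf.axis):
        raise ValueError(
            f"channel widths differ: model dt={model_axis.dt}, irf dt={irf.axis.dt}"
        )
    model = np.asarray(model, dtype=float)
    if model.size != model_axis.n_channels:
        raise ValueError("model length does not match its axis")

    full = np.convolve(model, irf.counts) * model_axis.dt
    # full[k] sits at time model.t0 + irf.t0 + k*dt; map back onto model.t0 + k*dt
    shift = int(round(irf.axis.t0 / model_axis.dt))
    n = model_axis.n_channels
    out = np.zeros(n, dtype=float)
    k0 = max(0, shift)                    # first output channel with a source sample
    j0 = k0 - shift
    m = min(n - k0, full.size - j0)
    if m > 0:
        out[k0 : k0 + m] = full[j0 : j0 + m]
    return out
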