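"""Layered-slab time-resolved Monte Carlo with trajectory storage.

The engine follows the microscopic Lambert-Beer strategy: photons are
propagated WITHOUT absorption, and for every detected photon the geometric
path length spent in each layer is stored, along with the exit time, exit
radius and the maximum depth visited. Absorption is applied afterwards by
weighting each trajectory with exp(-sum_j mua_j * L_j); a single absorption-
free run therefore serves every absorption state of the same geometry, and
perturbation contrasts computed from the SAME trajectories (correlated
sampling) carry far less variance than independent runs.

Scattering is isotropic (g = 0, so mus = mus'); free paths are exponential
with mean 1/mus of the current layer; the top surface applies unpolarised
Fresnel reflection/refraction for the n_in/n_out mismatch. Transport is
absorption-free, so the only terminations are escape through the surface or
exceeding the recording time limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .constants import speed_in_medium
from .curves import DTOFCurve, OpticalProperties, TimeAxis

__all__ = [
    "LayeredSlabMedium",
    "DetectionGeometry",
    "MCResult",
    "run_mc",
    "apply_absorption",
    "perturbation_contrast",
    "GateContrast",
    "mean_max_depth_curve",
]


@dataclass(frozen=True)
class LayeredSlabMedium:
    """Ordered stack of layers; the last layer is semi-infinite.

    Each entry is (thickness_cm, OpticalProperties); use ``math.inf`` (or any
    non-finite value) for the last thickness. All layers must share the same
    refractive index: the model has a single internal index and one external
    boundary at z = 0.
    """

    layers: tuple[tuple[float, OpticalProperties], ...]

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("need at least one layer")
        object.__setattr__(self, "layers", tuple((float(t), p) for t, p in self.layers))
        for i, (thick, _props) in enumerate(self.layers[:-1]):
            if not (np.isfinite(thick) and thick > 0):
                raise ValueError(f"layer {i} thickness must be finite and > 0, got {thick}")
        n_set = {p.n_in for _, p in self.layers} | {p.n_out for _, p in self.layers}
        if len({p.n_in for _, p in self.layers}) > 1:
            raise ValueError(f"all layers must share n_in, got {sorted(n_set)}")

    @classmethod
    def homogeneous(cls, props: OpticalProperties) -> "LayeredSlabMedium":
        return cls(layers=((np.inf, props),))

    @classmethod
    def two_layer(
        cls, top: OpticalProperties, top_thickness: float, bottom: OpticalProperties
    ) -> "LayeredSlabMedium":
        return cls(layers=((top_thickness, top), (np.inf, bottom)))

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_in(self) -> float:
        return self.layers[0][1].n_in

    @property
    def n_out(self) -> float:
        return self.layers[0][1].n_out

    @property
    def v(self) -> float:
        return speed_in_medium(self.n_in)

    @property
    def interfaces(self) -> np.ndarray:
        """Depths of the internal interfaces (cumulative thicknesses), cm."""
        return np.cumsum([t for t, _ in self.layers[:-1]])

    @property
    def musp_per_layer(self) -> np.ndarray:
        return np.array([p.musp for _, p in self.layers])

    @property
    def mua_per_layer(self) -> np.ndarray:
        return np.array([p.mua for _, p in self.layers])


@dataclass(frozen=True)
class DetectionGeometry:
    """Where and until when exiting photons are recorded.

    Photons leaving the surface at radius within rho +/- ring_half_width are
    detected; with ``accept_all_exits`` every exiting photon is kept (the mode
    used for depth statistics, which are independent of rho). Trajectories
    still inside the medium at ``t_max_record`` are abandoned.
    """

    rho: float = 3.0
    ring_half_width: float = 0.25
    t_max_record: float = 10.0
    accept_all_exits: bool = False

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")
        if self.ring_half_width <= 0:
            raise ValueError(f"ring_half_width must be > 0, got {self.ring_half_width}")
        if self.t_max_record <= 0:
            raise ValueError(f"t_max_record must be > 0, got {self.t_max_record}")


@dataclass
class MCResult:
    """Detected trajectories of one Monte Carlo run.

    Arrays are aligned: row i of ``layer_pathlengths`` (cm, one column per
    layer) belongs to ``exit_time[i]`` (ns), ``exit_radius[i]`` (cm) and
    ``max_depth[i]`` (cm). ``complete`` is False when the launch budget ran
    out before the detection target was met.
    """

    layer_pathlengths: np.ndarray
    exit_time: np.ndarray
    exit_radius: np.ndarray
    max_depth: np.ndarray
    n_launched: int
    seed: int
    medium: LayeredSlabMedium
    geometry: DetectionGeometry
    complete: bool = True

    @property
    def n_detected(self) -> int:
        return int(self.exit_time.size)

    @property
    def v(self) -> float:
        return self.medium.v


_INV_2_53 = 1.0 / 9007199254740992.0
_U64 = np.uint64


@njit(cache=True, inline="always")
def _xoro_next(s0, s1):
    """xoroshiro128+ step: returns (uniform in [0,1), new s0, new s1)."""
    u = ((s0 + s1) >> _U64(11)) * _INV_2_53
    s1 ^= s0
    s0 = ((s0 << _U64(55)) | (s0 >> _U64(9))) ^ s1 ^ (s1 << _U64(14))
    s1 = (s1 << _U64(36)) | (s1 >> _U64(28))
    return u, s0, s1


@njit(cache=True, inline="always")
def _splitmix64(x):
    x = x + _U64(0x9E3779B97F4A7C15)
    z = x
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    return x, z ^ (z >> _U64(31))


@njit(cache=True, fastmath=True)
def _transport_kernel(
    seed: int,
    n_target: int,
    launch_budget: int,
    mus: np.ndarray,          # per-layer scattering coefficient (= musp at g=0)
    interfaces: np.ndarray,   # depths of internal interfaces, ascending
    n_rel: float,             # n_in / n_out
    v: float,                 # cm/ns
    rho: float,
    half_width: float,
    accept_all: int,
    t_max: float,
    out_paths: np.ndarray,    # (n_target, n_layers)
    out_time: np.ndarray,
    out_radius: np.ndarray,
    out_zmax: np.ndarray,
):
    # deterministic xoroshiro128+ stream seeded via splitmix64
    sm = _U64(seed)
    sm, s0 = _splitmix64(sm)
    sm, s1 = _splitmix64(sm)
    if s0 == _U64(0) and s1 == _U64(0):
        s1 = _U64(0x1234567)
    n_layers = mus.size
    s_max_total = v * t_max
    crit_cos2 = 0.0
    if n_rel > 1.0:
        # cos^2 of the total-internal-reflection angle
        crit_cos2 = 1.0 - 1.0 / (n_rel * n_rel)

    n_det = 0
    n_launch = 0
    L = np.zeros(n_layers)
    while n_det < n_target and n_launch < launch_budget:
        n_launch += 1
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        for j in range(n_layers):
            L[j] = 0.0
        total = 0.0
        zmax = 0.0
        layer = 0
        alive = True
        exited = False

        while alive:
            u, s0, s1 = _xoro_next(s0, s1)
            tau = -np.log(u + 1e-300)
            while tau > 0.0 and alive:
                m = mus[layer]
                s = tau / m
                # distance to the layer boundary along the current direction
                if uz > 0.0:
                    zb = interfaces[layer] if layer < n_layers - 1 else 1.0e30
                    db = (zb - z) / uz
                elif uz < 0.0:
                    zb = 0.0 if layer == 0 else interfaces[layer - 1]
                    db = (zb - z) / uz
                else:
                    db = 1.0e30
                if s < db:
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    L[layer] += s
                    total += s
                    tau = 0.0
                else:
                    x += ux * db
                    y += uy * db
                    z = zb
                    L[layer] += db
                    total += db
                    tau -= db * m
                    if uz < 0.0 and layer == 0:
                        # top surface: Fresnel decision
                        ci = -uz
                        st2 = n_rel * n_rel * (1.0 - ci * ci)
                        refl = 1.0
                        if st2 < 1.0:
                            ct = np.sqrt(1.0 - st2)
                            # unpolarised Fresnel with n1=n_rel, n2=1
                            rs = (n_rel * ci - ct) / (n_rel * ci + ct)
                            rp = (n_rel * ct - ci) / (n_rel * ct + ci)
                            refl = 0.5 * (rs * rs + rp * rp)
                        u, s0, s1 = _xoro_next(s0, s1)
                        if u < refl:
                            uz = -uz
                        else:
                            alive = False
                            exited = True
                    else:
                        if uz > 0.0:
                            layer += 1
                        else:
                            layer -= 1
                if z > zmax:
                    zmax = z
                if total + z > s_max_total:
                    # cannot reach the surface within the recording limit
                    alive = False
            if alive:
                # isotropic scattering; azimuth via von Neumann rejection (no trig)
                u, s0, s1 = _xoro_next(s0, s1)
                uz = 2.0 * u - 1.0
                sz = np.sqrt(max(0.0, 1.0 - uz * uz))
                while True:
                    u, s0, s1 = _xoro_next(s0, s1)
                    a = 2.0 * u - 1.0
                    u, s0, s1 = _xoro_next(s0, s1)
                    b = 2.0 * u - 1.0
                    r2 = a * a + b * b
                    if 0.0 < r2 < 1.0:
                        break
                ux = sz * (a * a - b * b) / r2
                uy = sz * (2.0 * a * b) / r2
                if accept_all == 0:
                    # exact cull: minimum remaining path to any ring exit point
                    r_now = np.sqrt(x * x + y * y)
                    dr = 0.0
                    if r_now < rho - half_width:
                        dr = rho - half_width - r_now
                    elif r_now > rho + half_width:
                        dr = r_now - rho - half_width
                    if total + np.sqrt(dr * dr + z * z) > s_max_total:
                        alive = False

        if exited and total <= s_max_total:
            r = np.sqrt(x * x + y * y)
            if accept_all == 1 or (r >= rho - half_width and r <= rho + half_width):
                for j in range(n_layers):
                    out_paths[n_det, j] = L[j]
                out_time[n_det] = total / v
                out_radius[n_det] = r
                out_zmax[n_det] = zmax
                n_det += 1

    return n_det, n_launch


def run_mc(
    medium: LayeredSlabMedium,
    geometry: DetectionGeometry,
    n_detected_target: int,
    seed: int,
    launch_budget: int | None = None,
) -> MCResult:
    """Run an absorption-free Monte Carlo until the detection target is met.

    Photons are launched at the origin, normally into the medium. Detected
    trajectories are returned with per-layer path lengths, exit time/radius
    and maximum visited depth. Identical (seed, parameters) give identical
    results. If ``launch_budget`` launches are exhausted first, a partial
    result is returned with ``complete=False``.
    """
    if n_detected_target < 1:
        raise ValueError("n_detected_target must be >= 1")
    if launch_budget is None:
        launch_budget = int(max(1_000_000, 10_000 * n_detected_target))

    n_layers = medium.n_layers
    out_paths = np.zeros((n_detected_target, n_layers))
    out_time = np.zeros(n_detected_target)
    out_radius = np.zeros(n_detected_target)
    out_zmax = np.zeros(n_detected_target)

    n_det, n_launch = _transport_kernel(
        int(seed) & 0x7FFFFFFF,
        int(n_detected_target),
        int(launch_budget),
        medium.musp_per_layer.astype(np.float64),
        medium.interfaces.astype(np.float64),
        medium.n_in / medium.n_out,
        medium.v,
        geometry.rho,
        geometry.ring_half_width,
        1 if geometry.accept_all_exits else 0,
        geometry.t_max_record,
        out_paths,
        out_time,
        out_radius,
        out_zmax,
    )

    return MCResult(
        layer_pathlengths=out_paths[:n_det],
        exit_time=out_time[:n_det],
        exit_radius=out_radius[:n_det],
        max_depth=out_zmax[:n_det],
        n_launched=int(n_launch),
        seed=int(seed),
        medium=medium,
        geometry=geometry,
        complete=(n_det >= n_detected_target),
    )


def trajectory_weights(result: MCResult, mua_per_layer) -> np.ndarray:
    """Microscopic Lambert-Beer weights exp(-sum_j mua_j L_j) per trajectory."""
    mua = np.asarray(mua_per_layer, dtype=float)
    if mua.ndim != 1 or mua.size != result.medium.n_layers:
        raise ValueError(
            f"expected {result.medium.n_layers} absorption values, got {mua.size}"
        )
    if np.any(mua < 0):
        raise ValueError("absorption coefficients must be >= 0")
    return np.exp(-result.layer_pathlengths @ mua)


def apply_absorption(
    result: MCResult,
    mua_per_layer,
    t_axis: TimeAxis | None = None,
    wavelength: float | None = None,
) -> DTOFCurve:
    """Absorption-weighted exit-time histogram of a Monte Carlo run.

    Each trajectory contributes exp(-sum_j mua_j L_j) to its exit-time bin;
    with all mua_j = 0 this is the plain detected-photon histogram.
    """
    if t_axis is None:
        t_axis = TimeAxis.default(dt=0.050, t_span=result.geometry.t_max_record)
    w = trajectory_weights(result, mua_per_layer)
    hist, _ = np.histogram(result.exit_time, bins=t_axis.edges, weights=w)
    rho = result.geometry.rho if result.geometry.rho > 0 else 1e-6
    return DTOFCurve(axis=t_axis, counts=hist, rho=rho, wavelength=wavelength)


@dataclass(frozen=True)
class GateContrast:
    """Contrast of one time gate; ``defined`` is False when the gate is empty."""

    t_start: float
    width: float
    contrast: float
    n_photons: int
    defined: bool


def perturbation_contrast(
    result: MCResult,
    baseline_mua,
    perturbed_mua,
    gates,
) -> list[GateContrast]:
    """Gated relative contrast between two absorption states of one run.

    Both states reweight the SAME trajectories (correlated sampling), so for
    absorption-only perturbations the contrast estimate is far more stable
    than the counting noise of either histogram alone. For each gate
    (t, width), C = (S_pert - S_base)/S_base with S the weighted sum over
    trajectories whose exit time falls in [t, t + width). Empty gates are
    flagged as undefined rather than returned as 0.
    """
    w0 = trajectory_weights(result, baseline_mua)
    w1 = trajectory_weights(result, perturbed_mua)
    t = result.exit_time
    out: list[GateContrast] = []
    for t_start, width in gates:
        if width <= 0:
            raise ValueError(f"gate width must be > 0, got {width}")
        sel = (t >= t_start) & (t < t_start + width)
        n = int(sel.sum())
        if n == 0:
            out.append(GateContrast(t_start, width, np.nan, 0, False))
            continue
        s0 = float(w0[sel].sum())
        s1 = float(w1[sel].sum())
        out.append(GateContrast(t_start, width, (s1 - s0) / s0, n, True))
    return out


def mean_max_depth_curve(
    result: MCResult,
    t_axis: TimeAxis,
    min_records: int = 50,
):
    """Mean maximum visited depth <z_max> per exit-time bin.

    Depth statistics use the unweighted (zero-absorption) trajectories: within
    a time bin a homogeneous absorption weight exp(-mua*v*t) is constant, so
    the average is rigorously absorption independent; it is also independent
    of the detection radius, which is why the generating run should use
    ``accept_all_exits``. Bins holding fewer than ``min_records`` trajectories
    are flagged unreliable.

    Returns
    -------
    (centers, mean_zmax, n_records, reliable) arrays; mean_zmax is NaN where
    a bin holds no records.
    """
    if result.n_detected == 0:
        raise ValueError("empty Monte Carlo result")
    edges = t_axis.edges
    idx = np.digitize(result.exit_time, edges) - 1
    nbins = t_axis.n_channels
    valid = (idx >= 0) & (idx < nbins)
    counts = np.bincount(idx[valid], minlength=nbins)
    sums = np.bincount(idx[valid], weights=result.max_depth[valid], minlength=nbins)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return t_axis.centers, mean, counts, counts >= min_records
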