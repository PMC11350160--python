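"""File I/O and pipeline orchestration.

Curves travel as two-column CSV (time_ns, counts) with a JSON sidecar holding
acquisition metadata, or as one HDF5 group per acquisition; Monte Carlo
results persist as HDF5. ``run_pipeline`` ties the synthetic generator, the
broadband fits and the protocol analysis into one reproducible run driven by
a validated JSON-able configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .curves import DTOFCurve, OpticalProperties, TimeAxis
from .constants import C_VACUUM_CM_NS
from .fitting import estimate_tmax, fit_homogeneous
from .montecarlo import (
    DetectionGeometry,
    LayeredSlabMedium,
    MCResult,
    mean_max_depth_curve,
    perturbation_contrast,
    run_mc,
)
from .protocol import PROT5, PROT10, GateSpec, gated_contrast, phase_plateau_summary
from .spectra import (
    PowerLawFit,
    SpectralDataset,
    TissueComposition,
    fit_composition,
    fit_power_law,
    synthetic_chromophore_basis,
)
from .synth import (
    NoiseModel,
    PhaseModulation,
    SyntheticScenario,
    generate_irf,
    generate_protocol_series,
    generate_spectral_series,
)

__all__ = [
    "read_dtof",
    "write_dtof",
    "read_dtof_h5",
    "write_dtof_h5",
    "write_mc_result",
    "read_mc_result",
    "RunConfig",
    "run_pipeline",
]


def write_dtof(path: str | Path, dtof: DTOFCurve) -> None:
    """Write a curve as CSV (time_ns, counts) with a JSON metadata sidecar."""
    path = Path(path)
    t = dtof.axis.centers
    with open(path, "w") as fh:
        fh.write("time_ns,counts\n")
        for ti, ci in zip(t, dtof.counts):
            fh.write(f"{ti:.9g},{ci:.10g}\n")
    meta = {
        "rho_cm": dtof.rho,
        "wavelength_nm": dtof.wavelength,
        "acq_time_s": dtof.acq_time,
        "label": dtof.label,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_dtof(path: str | Path) -> DTOFCurve:
    """Read a CSV + JSON-sidecar curve; counts are validated on load."""
    path = Path(path)
    rows = path.read_text().strip().splitlines()
    if not rows or rows[0].strip().lower() != "time_ns,counts":
        raise ValueError(f"{path}: malformed header, expected 'time_ns,counts'")
    t = np.empty(len(rows) - 1)
    c = np.empty(len(rows) - 1)
    for i, row in enumerate(rows[1:]):
        try:
            a, b = row.split(",")
            t[i], c[i] = float(a), float(b)
        except ValueError as err:
            raise ValueError(f"{path}: bad row {i + 2}: {row!r}") from err
        if c[i] < 0:
            raise ValueError(f"{path}: negative count at row {i + 2}")
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 channels")
    dt = float(np.median(np.diff(t)))
    axis = TimeAxis(t0=float(t[0]), dt=dt, n_channels=t.size)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise ValueError(f"{path}: missing metadata sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    for key in ("rho_cm", "acq_time_s"):
        if key not in meta:
            raise ValueError(f"{sidecar}: missing metadata key {key!r}")
    return DTOFCurve(
        axis=axis,
        counts=c,
        rho=float(meta["rho_cm"]),
        wavelength=meta.get("wavelength_nm"),
        acq_time=float(meta["acq_time_s"]),
        label=meta.get("label", ""),
    )


def write_dtof_h5(group: h5py.Group, dtof: DTOFCurve) -> None:
    """Write a curve into an open HDF5 group."""
    group.create_dataset("time_ns", data=dtof.axis.centers)
    group.create_dataset("counts", data=dtof.counts)
    group.attrs["rho_cm"] = dtof.rho
    group.attrs["acq_time_s"] = dtof.acq_time
    group.attrs["label"] = dtof.label
    if dtof.wavelength is not None:
        group.attrs["wavelength_nm"] = dtof.wavelength


def read_dtof_h5(group: h5py.Group) -> DTOFCurve:
    t = np.asarray(group["time_ns"])
    c = np.asarray(group["counts"], dtype=float)
    axis = TimeAxis(t0=float(t[0]), dt=float(np.median(np.diff(t))), n_channels=t.size)
    wl = group.attrs.get("wavelength_nm")
    return DTOFCurve(
        axis=axis,
        counts=c,
        rho=float(group.attrs["rho_cm"]),
        wavelength=None if wl is None else float(wl),
        acq_time=float(group.attrs["acq_time_s"]),
        label=str(group.attrs.get("label", "")),
    )


def write_mc_result(path: str | Path, result: MCResult) -> None:
    """Persist a Monte Carlo run (trajectory arrays + provenance) as HDF5."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("layer_pathlengths", data=result.layer_pathlengths)
        fh.create_dataset("exit_time", data=result.exit_time)
        fh.create_dataset("exit_radius", data=result.exit_radius)
        fh.create_dataset("max_depth", data=result.max_depth)
        fh.attrs["n_launched"] = result.n_launched
        fh.attrs["seed"] = result.seed
        fh.attrs["complete"] = result.complete
        fh.attrs["rho"] = result.geometry.rho
        fh.attrs["ring_half_width"] = result.geometry.ring_half_width
        fh.attrs["t_max_record"] = result.geometry.t_max_record
        fh.attrs["accept_all_exits"] = result.geometry.accept_all_exits
        fh.attrs["layer_thickness"] = [t for t, _ in result.medium.layers]
        fh.attrs["layer_musp"] = result.medium.musp_per_layer
        fh.attrs["layer_mua"] = result.medium.mua_per_layer
        fh.attrs["n_in"] = result.medium.n_in
        fh.attrs["n_out"] = result.medium.n_out


def read_mc_result(path: str | Path) -> MCResult:
    with h5py.File(path, "r") as fh:
        layers = tuple(
            (
                float(t),
                OpticalProperties(
                    mua=float(a), musp=float(s),
                    n_in=float(fh.attrs["n_in"]), n_out=float(fh.attrs["n_out"]),
                ),
            )
            for t, s, a in zip(
                fh.attrs["layer_thickness"], fh.attrs["layer_musp"], fh.attrs["layer_mua"]
            )
        )
        medium = LayeredSlabMedium(layers=layers)
        geometry = DetectionGeometry(
            rho=float(fh.attrs["rho"]),
            ring_half_width=float(fh.attrs["ring_half_width"]),
            t_max_record=float(fh.attrs["t_max_record"]),
            accept_all_exits=bool(fh.attrs["accept_all_exits"]),
        )
        return MCResult(
            layer_pathlengths=np.asarray(fh["layer_pathlengths"]),
            exit_time=np.asarray(fh["exit_time"]),
            exit_radius=np.asarray(fh["exit_radius"]),
            max_depth=np.asarray(fh["max_depth"]),
            n_launched=int(fh.attrs["n_launched"]),
            seed=int(fh.attrs["seed"]),
            medium=medium,
            geometry=geometry,
            complete=bool(fh.attrs["complete"]),
        )


@dataclass
class RunConfig:
    """Validated configuration of a demo pipeline run.

    Serialised (with the seed and the constants in use) into every summary
    for provenance. Sizes default to a quick demonstration scale.
    """

    seed: int = 1
    n_in: float = 1.4
    n_out: float = 1.0
    rho_spectral: float = 3.0
    rho_protocol: float = 6.0
    protocol: str = "prot10"
    top_musp: float = 7.0
    top_mua: float = 0.15
    lung_musp: float = 12.0
    lung_mua: float = 0.15
    lung_depth: float = 3.0
    mc_detected: int = 20_000
    spectral_wl_step: float = 25.0
    gate_starts: tuple = (0.5, 1.5, 2.5, 3.5, 4.5)
    gate_width: float = 0.5
    count_rate: float = 1.0e6

    def validate(self) -> None:
        if self.protocol not in ("prot10", "prot5"):
            raise ValueError(f"protocol must be 'prot10' or 'prot5', got {self.protocol!r}")
        for name in (
            "rho_spectral", "rho_protocol", "top_musp", "lung_musp",
            "lung_depth", "gate_width", "count_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("top_mua", "lung_mua"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mc_detected < 1000:
            raise ValueError("mc_detected below 1000 gives meaningless statistics")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "gate_starts" in raw:
            raw["gate_starts"] = tuple(raw["gate_starts"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the synthetic end-to-end demonstration and write a JSON summary.

    Stages: broadband synthetic series -> composition + power-law fits;
    two-layer Monte Carlo -> depth statistics, t_max and gated perturbation
    contrast; synthetic breathing protocol -> gated contrast and plateau
    summary. The summary (with config and seed) is written to
    ``out_dir/summary.json`` and returned.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed) & 0x7FFFFFFF

    basis = synthetic_chromophore_basis()
    truth_comp = TissueComposition(Hb=3.0, HbO2=15.5, water=0.29, lipid=0.63, collagen=0.11)
    truth_pl = PowerLawFit(a=9.0, b=0.78)
    wavelengths = np.arange(600.0, 1101.0, config.spectral_wl_step)
    curves, truth_spec = generate_spectral_series(
        truth_comp, truth_pl, basis,
        rho=config.rho_spectral,
        noise=NoiseModel(total_count_rate=config.count_rate, acq_time=4.0, seed=rng_seed),
        wavelengths=wavelengths,
    )
    irf_axis = TimeAxis(t0=-1.0, dt=curves[0].axis.dt, n_channels=200)
    irf = generate_irf(irf_axis, seed=rng_seed)
    mua_fit = np.empty(len(curves))
    musp_fit = np.empty(len(curves))
    guess = (0.1, 10.0)
    for i, c in enumerate(curves):
        res = fit_homogeneous(c, irf, init=guess, n_in=config.n_in, n_out=config.n_out)
        mua_fit[i] = res.mua
        musp_fit[i] = res.musp
        if res.converged:
            guess = (res.mua, res.musp)
    fitted = SpectralDataset(wavelengths, mua_fit, musp_fit)
    comp, resid = fit_composition(fitted, basis)
    pl = fit_power_law(fitted)

    # two-layer Monte Carlo: contrast, depth statistics, t_max
    top = OpticalProperties(config.top_mua, config.top_musp, config.n_in, config.n_out)
    lung = OpticalProperties(config.lung_mua, config.lung_musp, config.n_in, config.n_out)
    medium = LayeredSlabMedium.two_layer(top, config.lung_depth, lung)
    geometry = DetectionGeometry(rho=config.rho_protocol)
    mc = run_mc(medium, geometry, config.mc_detected, seed=rng_seed + 11)
    gates = [(t, config.gate_width) for t in config.gate_starts]
    base = np.array([config.top_mua, config.lung_mua])
    pert = base * np.array([1.0, 0.9])
    contrasts = perturbation_contrast(mc, base, pert, gates)

    depth_geom = DetectionGeometry(rho=config.rho_protocol, accept_all_exits=True)
    mc_depth = run_mc(
        LayeredSlabMedium.homogeneous(top), depth_geom, config.mc_detected, seed=rng_seed + 13
    )
    zmax_axis = TimeAxis(t0=0.1, dt=0.2, n_channels=30)
    t_centers, zmax, n_rec, ok = mean_max_depth_curve(mc_depth, zmax_axis)

    dtof_mc = apply_absorption_scaled(mc, base, config.count_rate)
    tmax = estimate_tmax(dtof_mc, gate_width=config.gate_width)

    protocol = PROT10 if config.protocol == "prot10" else PROT5
    scenario = SyntheticScenario(
        medium=medium, protocol=protocol, rho=config.rho_protocol,
        modulation=PhaseModulation(mua_factor_in=0.9),
    )
    series, truth_protocol = generate_protocol_series(
        scenario,
        NoiseModel(total_count_rate=config.count_rate, seed=rng_seed + 17),
        n_detected=config.mc_detected,
        mc_baseline=mc,
    )
    gate_specs = [GateSpec(t, config.gate_width) for t in config.gate_starts]
    cs = gated_contrast(series, gate_specs)
    plateau = phase_plateau_summary(cs)

    summary = {
        "config": {**asdict(config), "gate_starts": list(config.gate_starts)},
        "constants": {"c_vacuum_cm_ns": C_VACUUM_CM_NS},
        "spectral": {
            "composition_true": asdict(truth_comp),
            "composition_fit": asdict(comp),
            "composition_residual": resid,
            "power_law_true": {"a": truth_pl.a, "b": truth_pl.b},
            "power_law_fit": {"a": pl.a, "b": pl.b},
        },
        "monte_carlo": {
            "n_detected": mc.n_detected,
            "n_launched": mc.n_launched,
            "contrast_percent": {
                f"{g.t_start:.1f}ns": (100.0 * g.contrast if g.defined else None)
                for g in contrasts
            },
            "zmax_cm_at": {
                f"{t:.1f}ns": (float(z) if good else None)
                for t, z, good in zip(t_centers, zmax, ok)
            },
            "t_max_ns": tmax,
        },
        "protocol": {
            "n_acquisitions": len(series),
            "plateau_in": plateau.mean_in.tolist(),
            "plateau_out": plateau.mean_out.tolist(),
            "plateau_in_minus_out": plateau.difference.tolist(),
            "gates_ns": [g.t_start for g in gate_specs],
        },
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def apply_absorption_scaled(mc, mua_per_layer, count_rate: float, acq_time: float = 1.0):
    """Absorption-weighted MC histogram rescaled to a TCSPC count rate."""
    from .montecarlo import apply_absorption

    dtof = apply_absorption(mc, mua_per_layer)
    total = dtof.counts.sum()
    if total <= 0:
        return dtof
    scaled = dtof.counts / total * count_rate * acq_time
    return DTOFCurve(
        axis=dtof.axis, counts=scaled, rho=dtof.rho,
        wavelength=dtof.wavelength, acq_time=acq_time,
    )
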