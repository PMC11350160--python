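"""Core measurement records: time axes, photon time-of-flight histograms, IRFs.

A DTOF (distribution of times of flight) is the basic record produced by a
TCSPC acquisition: photon counts per arrival-time channel, together with the
source-detector distance, wavelength and acquisition time needed to interpret
it. The instrument response function (IRF) is the same histogram measured with
source and collection fibres facing each other; its peak defines t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import N_EXTERNAL_DEFAULT, N_TISSUE_DEFAULT, speed_in_medium

__all__ = ["TimeAxis", "OpticalProperties", "DTOFCurve", "IRFCurve"]


@dataclass(frozen=True)
class TimeAxis:
    """Uniform TCSPC channel grid.

    Parameters
    ----------
    t0 : float
        Centre of the first channel, ns.
    dt : float
        Channel width, ns.
    n_channels : int
        Number of channels (>= 2).
    """

    t0: float
    dt: float
    n_channels: int

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"channel width must be positive, got dt={self.dt}")
        if self.n_channels < 2:
            raise ValueError(f"need at least 2 channels, got {self.n_channels}")

    @property
    def centers(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_channels)

    @property
    def edges(self) -> np.ndarray:
        """Channel bin edges (length n_channels + 1)."""
        return self.t0 + self.dt * (np.arange(self.n_channels + 1) - 0.5)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.n_channels - 1)

    def compatible_with(self, other: "TimeAxis", rtol: float = 1e-9) -> bool:
        return bool(np.isclose(self.dt, other.dt, rtol=rtol))

    @classmethod
    def default(cls, dt: float = 0.010, t_span: float = 10.0, t0: float | None = None) -> "TimeAxis":
        """10 ps channels over 0-10 ns unless told otherwise."""
        n = int(round(t_span / dt))
        return cls(t0=0.0 if t0 is None else t0, dt=dt, n_channels=n)


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of a diffusive medium.

    mua, musp in 1/cm; n_in is the tissue refractive index, n_out the index
    of the external medium (air). The reduced scattering coefficient
    musp = mus * (1 - g) is the natural parameter of diffusion theory.
    """

    mua: float
    musp: float
    n_in: float = N_TISSUE_DEFAULT
    n_out: float = N_EXTERNAL_DEFAULT

    def __post_init__(self) -> None:
        if self.mua < 0:
            raise ValueError(f"absorption must be >= 0, got mua={self.mua}")
        if self.musp <= 0:
            raise ValueError(f"reduced scattering must be > 0, got musp={self.musp}")
        if self.n_in < 1 or self.n_out < 1:
            raise ValueError(f"refractive indices must be >= 1, got {self.n_in}, {self.n_out}")

    @property
    def v(self) -> float:
        """Speed of light in the medium, cm/ns."""
        return speed_in_medium(self.n_in)

    def with_mua(self, mua: float) -> "OpticalProperties":
        return replace(self, mua=mua)


def _validate_counts(counts: np.ndarray, axis: TimeAxis) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size != axis.n_channels:
        raise ValueError(
            f"counts must be 1-D with {axis.n_channels} entries, got shape {counts.shape}"
        )
    if not np.all(np.isfinite(counts)):
        raise ValueError("counts must be finite")
    if np.any(counts < 0):
        bad = int(np.argmin(counts))
        raise ValueError(f"counts must be nonnegative; channel {bad} holds {counts[bad]}")
    return counts


@dataclass(frozen=True)
class DTOFCurve:
    """A photon time-of-flight histogram plus its acquisition metadata."""

    axis: TimeAxis
    counts: np.ndarray
    rho: float
    wavelength: float | None = None
    acq_time: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", _validate_counts(self.counts, self.axis))
        if self.rho <= 0:
            raise ValueError(f"source-detector distance must be > 0, got rho={self.rho}")
        if self.acq_time <= 0:
            raise ValueError(f"acquisition time must be > 0, got {self.acq_time}")

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    @property
    def count_rate(self) -> float:
        """Total counts per second of acquisition."""
        return self.total_counts / self.acq_time

    def gate_sum(self, t_start: float, width: float) -> float:
        """Sum of counts over channels whose centres fall in [t_start, t_start + width)."""
        c = self.axis.centers
        sel = (c >= t_start) & (c < t_start + width)
        return float(self.counts[sel].sum())


@dataclass(frozen=True)
class IRFCurve:
    """Instrument response function histogram; total counts must be positive."""

    axis: TimeAxis
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", _validate_counts(self.counts, self.axis))
        if self.counts.sum() <= 0:
            raise ValueError("IRF must contain at least one count")

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    @property
    def peak_time(self) -> float:
        return float(self.axis.centers[int(np.argmax(self.counts))])
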