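"""Paced-breathing protocol analysis.

A protocol series is a laboratory-time sequence of DTOFs acquired while the
subject alternates suspended full inspiration (IN) and expiration (OUT).
Analyses: per-gate relative contrast of the count-rate-normalised gated
signal against the whole-exercise mean (the reference state R0), folding
averages across protocol repetitions, plateau summaries of the IN and OUT
phases, and per-acquisition homogeneous fits over laboratory time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import DTOFCurve, IRFCurve
from .fitting import FitResult, fit_homogeneous

__all__ = [
    "BreathingProtocol",
    "GateSpec",
    "ProtocolSeries",
    "ContrastSeries",
    "default_gates",
    "gated_contrast",
    "folding_average",
    "phase_plateau_summary",
    "fit_timeseries",
    "PROT10",
    "PROT5",
]


@dataclass(frozen=True)
class BreathingProtocol:
    """Timing of the paced-breathing exercise.

    Each repetition is an IN phase followed by an OUT phase, both lasting
    ``phase_duration`` seconds. ``reference_prefix`` marks a leading
    normal-breathing repetition (used by the 5 s protocol) that is excluded
    from folding and, by default, from the reference state.
    """

    phase_duration: float
    n_repetitions: int
    reference_prefix: bool = False

    def __post_init__(self) -> None:
        if self.phase_duration <= 0:
            raise ValueError(f"phase duration must be > 0, got {self.phase_duration}")
        if self.n_repetitions < 1:
            raise ValueError(f"need >= 1 repetition, got {self.n_repetitions}")

    @property
    def cycle_duration(self) -> float:
        return 2.0 * self.phase_duration

    def label_sequence(self, cadence: float = 1.0) -> list[str]:
        """Per-acquisition phase labels (REF/IN/OUT) at ``cadence`` acq/s."""
        n_phase = int(round(self.phase_duration * cadence))
        labels: list[str] = []
        if self.reference_prefix:
            labels += ["REF"] * (2 * n_phase)
        for _ in range(self.n_repetitions):
            labels += ["IN"] * n_phase + ["OUT"] * n_phase
        return labels


#: 5 repetitions of 10 s inhale + 10 s exhale.
PROT10 = BreathingProtocol(phase_duration=10.0, n_repetitions=5)
#: 10 repetitions of 5 s phases, preceded by one normal-breathing repetition.
PROT5 = BreathingProtocol(phase_duration=5.0, n_repetitions=10, reference_prefix=True)


@dataclass(frozen=True)
class GateSpec:
    """A photon arrival-time window [t_start, t_start + width), ns."""

    t_start: float
    width: float = 0.5

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"gate width must be > 0, got {self.width}")


def default_gates() -> list[GateSpec]:
    """The standard family: starts 0.5-4.5 ns, width 0.5 ns."""
    return [GateSpec(t) for t in (0.5, 1.5, 2.5, 3.5, 4.5)]


@dataclass
class ProtocolSeries:
    """Time-ordered DTOF acquisitions with phase labels."""

    acquisitions: list[DTOFCurve]
    timestamps: np.ndarray
    labels: list[str]
    protocol: BreathingProtocol

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        if not (len(self.acquisitions) == ts.size == len(self.labels)):
            raise ValueError("acquisitions, timestamps and labels must align")
        if ts.size and np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        bad = set(self.labels) - {"IN", "OUT", "REF"}
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")
        self.timestamps = ts

    def __len__(self) -> int:
        return len(self.acquisitions)


@dataclass
class ContrastSeries:
    """Per-acquisition, per-gate relative contrast values.

    ``contrast`` has shape (n_acquisitions, n_gates); entries where the
    reference gate integral vanished are NaN with ``defined`` False.
    """

    contrast: np.ndarray
    defined: np.ndarray
    gates: list[GateSpec]
    timestamps: np.ndarray
    labels: list[str]
    protocol: BreathingProtocol
    reference: str = "whole-exercise mean (count-rate normalised)"


def _rate_curves(series: ProtocolSeries) -> np.ndarray:
    """Count-rate-normalised curves, one row per acquisition."""
    return np.stack([a.counts / a.acq_time for a in series.acquisitions])


def gated_contrast(
    series: ProtocolSeries,
    gates: list[GateSpec] | None = None,
    include_reference: bool = False,
) -> ContrastSeries:
    """Relative contrast C = (S - S0)/S0 of the gated signal per acquisition.

    The reference state R0 is the element-wise mean of the count-rate
    normalised curves over the whole exercise (REF-labelled acquisitions are
    excluded unless ``include_reference``); gate integrals are sums of the
    channels whose centres fall inside the gate. C is therefore the relative
    change of the gated signal with respect to its exercise mean, and is
    invariant under a global rescaling of all acquisitions.
    """
    if gates is None:
        gates = default_gates()
    if len(series) == 0:
        raise ValueError("empty protocol series")
    axis = series.acquisitions[0].axis
    for a in series.acquisitions:
        if not a.axis.compatible_with(axis):
            raise ValueError("all acquisitions must share a channel width")
    rates = _rate_curves(series)
    in_ref = np.array([lab == "REF" for lab in series.labels])
    use = ~in_ref if (not include_reference and (~in_ref).any()) else np.ones(len(series), bool)
    r0 = rates[use].mean(axis=0)

    centers = axis.centers
    n_g = len(gates)
    contrast = np.full((len(series), n_g), np.nan)
    defined = np.zeros((len(series), n_g), dtype=bool)
    for j, g in enumerate(gates):
        sel = (centers >= g.t_start) & (centers < g.t_start + g.width)
        s0 = float(r0[sel].sum())
        if s0 <= 0:
            continue
        s = rates[:, sel].sum(axis=1)
        contrast[:, j] = (s - s0) / s0
        defined[:, j] = True
    return ContrastSeries(
        contrast=contrast,
        defined=defined,
        gates=list(gates),
        timestamps=series.timestamps.copy(),
        labels=list(series.labels),
        protocol=series.protocol,
    )


def folding_average(
    values: np.ndarray,
    protocol: BreathingProtocol,
    cadence: float = 1.0,
) -> np.ndarray:
    """Average a per-acquisition series across protocol repetitions.

    ``values`` may be 1-D (one number per acquisition) or 2-D (acquisitions by
    gates). A leading normal-breathing repetition, when the protocol declares
    one, is dropped before folding. The remaining length must be exactly
    n_repetitions full cycles at the given cadence.
    """
    values = np.asarray(values, dtype=float)
    n_cycle = int(round(protocol.cycle_duration * cadence))
    n_prefix = n_cycle if protocol.reference_prefix else 0
    expected = n_prefix + protocol.n_repetitions * n_cycle
    if values.shape[0] != expected:
        raise ValueError(
            f"series length {values.shape[0]} does not match protocol: expected "
            f"{expected} acquisitions ({n_prefix} reference + "
            f"{protocol.n_repetitions} x {n_cycle})"
        )
    body = values[n_prefix:]
    shape = (protocol.n_repetitions, n_cycle) + body.shape[1:]
    return body.reshape(shape).mean(axis=0)


@dataclass(frozen=True)
class PlateauSummary:
    """Mean contrast in the IN and OUT breath-hold plateaus, per gate."""

    gates: list[GateSpec]
    mean_in: np.ndarray
    mean_out: np.ndarray
    difference: np.ndarray  # IN - OUT


def phase_plateau_summary(
    contrast: ContrastSeries,
    transient: float = 2.0,
    cadence: float = 1.0,
) -> PlateauSummary:
    """Average contrast over the breath-hold plateau of each phase.

    The plateau of a phase excludes its first ``transient`` seconds (the
    inhalation/exhalation transition). Returns per-gate IN and OUT means and
    their difference, mirroring an IN/OUT/IN-OUT summary plot.
    """
    labels = contrast.labels
    ts = contrast.timestamps
    n_skip = int(round(transient * cadence))
    in_plateau = np.zeros(len(labels), dtype=bool)
    # mark acquisitions deeper than `transient` into their phase
    start = 0
    for i in range(len(labels) + 1):
        if i == len(labels) or (i > 0 and labels[i] != labels[i - 1]):
            if i > start and labels[start] in ("IN", "OUT"):
                in_plateau[start + n_skip : i] = True
            start = i
    del ts
    sel_in = in_plateau & np.array([lab == "IN" for lab in labels])
    sel_out = in_plateau & np.array([lab == "OUT" for lab in labels])
    if not sel_in.any() or not sel_out.any():
        raise ValueError(
            f"empty plateau: transient {transient}s leaves no IN or OUT acquisitions"
        )
    mean_in = np.nanmean(contrast.contrast[sel_in], axis=0)
    mean_out = np.nanmean(contrast.contrast[sel_out], axis=0)
    return PlateauSummary(
        gates=list(contrast.gates),
        mean_in=mean_in,
        mean_out=mean_out,
        difference=mean_in - mean_out,
    )


def fit_timeseries(
    series: ProtocolSeries,
    irf: IRFCurve,
    init: tuple[float, float] | None = None,
    **fit_kwargs,
) -> list[FitResult]:
    """Independent homogeneous fits of every acquisition, warm-started.

    Each acquisition is fitted with :func:`lungtdos.fitting.fit_homogeneous`;
    the previous acquisition's converged result seeds the next fit. Failures
    are recorded per acquisition (converged=False) and never abort the series.
    """
    results: list[FitResult] = []
    guess = init
    for dtof in series.acquisitions:
        try:
            res = fit_homogeneous(dtof, irf, init=guess, **fit_kwargs)
        except Exception:
            res = FitResult(
                mua=np.nan, musp=np.nan, amplitude=np.nan, time_shift=0.0,
                chi2_reduced=np.inf,
                fit_range=None,  # type: ignore[arg-type]
                converged=False,
            )
        results.append(res)
        if res.converged and np.isfinite(res.mua):
            guess = (res.mua, res.musp)
    return results
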