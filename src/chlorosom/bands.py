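"""Double-normalised variable-fluorescence curves and difference bands.

Between two marker steps the relative variable fluorescence

    W(t) = (F(t) - F(start)) / (F(end) - F(start))

runs from 0 to 1 regardless of the absolute fluorescence scale.  Subtracting
the W curve of a control group from that of a treatment group yields a
difference band whose sign and amplitude are diagnostic: a positive O-K band
(the L band) indicates reduced energetic connectivity between antenna
complexes and PSII reaction centres, a positive O-J band (K band) an
impaired oxygen-evolving complex, and J-I / I-P bands an imbalance around
the plastoquinone pool and the PSI acceptor side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ojip import MARKER_TIMES, FluorescenceTransient, extract_markers

__all__ = [
    "PHASES",
    "NormalisedCurve",
    "DifferenceBand",
    "double_normalise",
    "control_curve",
    "difference_band",
    "band_table",
]

#: Phase name -> (start marker, end marker); "P" means the per-sample t(F_M).
PHASES = {
    "O-K": ("O", "K"),
    "O-J": ("O", "J"),
    "J-I": ("J", "I"),
    "I-P": ("I", "P"),
}


class NonRisingPhaseError(ValueError):
    """Raised when the end-anchor intensity does not exceed the start anchor."""


@dataclass(frozen=True)
class NormalisedCurve:
    """Double-normalised fluorescence over one phase window."""

    phase: str
    times: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {sorted(PHASES)}")
        if self.times.shape != self.W.shape:
            raise ValueError("times and W must have equal length")


@dataclass(frozen=True)
class DifferenceBand:
    """Pointwise W difference of a sample (or group) against a control."""

    phase: str
    times: np.ndarray
    delta_W: np.ndarray
    peak_value: float
    peak_time: float


def _phase_window(transient: FluorescenceTransient, phase: str) -> tuple[float, float]:
    start_name, end_name = PHASES[phase]
    t_start = MARKER_TIMES[start_name]
    if end_name == "P":
        t_end = float(transient.times[int(np.argmax(transient.intensity))])
    else:
        t_end = MARKER_TIMES[end_name]
    return t_start, t_end


def double_normalise(transient: FluorescenceTransient, phase: str) -> NormalisedCurve:
    """W(t) between the phase's start and end anchors.

    The P anchor of the I-P phase is the per-sample time of maximum
    fluorescence, not a fixed 300 ms.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {sorted(PHASES)}")
    t_start, t_end = _phase_window(transient, phase)
    t, f = transient.times, transient.intensity
    mask = (t >= t_start * (1 - 1e-12)) & (t <= t_end * (1 + 1e-12))
    times = t[mask]
    if times.size < 2:
        raise NonRisingPhaseError(
            f"sample {transient.sample_id!r}: {phase} window is empty "
            f"(curve maximum at {t_end:g} s)"
        )
    F_start = float(np.interp(t_start, t, f))
    F_end = float(np.interp(t_end, t, f))
    if F_end <= F_start:
        raise NonRisingPhaseError(
            f"sample {transient.sample_id!r}: non-rising {phase} phase "
            f"(F({t_end:g}s)={F_end:g} <= F({t_start:g}s)={F_start:g})"
        )
    W = (f[mask] - F_start) / (F_end - F_start)
    return NormalisedCurve(phase=phase, times=times, W=W)


def control_curve(
    transients: Iterable[FluorescenceTransient], phase: str
) -> NormalisedCurve:
    """Pointwise mean W of a group: normalise each member first, then average.

    For the I-P phase, whose end anchor is per-sample, the mean is taken on
    the common grid restricted to the shortest member window.
    """
    curves = [double_normalise(tr, phase) for tr in transients]
    if not curves:
        raise ValueError("control group is empty")
    n_common = min(c.times.size for c in curves)
    times = curves[0].times[:n_common]
    W = np.mean([c.W[:n_common] for c in curves], axis=0)
    return NormalisedCurve(phase=phase, times=times, W=W)


def difference_band(sample: NormalisedCurve, control: NormalisedCurve) -> DifferenceBand:
    """delta_W = W_sample - W_control; positive means sample above control."""
    if sample.phase != control.phase:
        raise ValueError(f"phase mismatch: {sample.phase!r} vs {control.phase!r}")
    n = min(sample.times.size, control.times.size)
    if not np.allclose(sample.times[:n], control.times[:n], rtol=1e-9):
        raise ValueError("sample and control curves are on different time grids")
    delta = sample.W[:n] - control.W[:n]
    i_peak = int(np.argmax(np.abs(delta)))
    return DifferenceBand(
        phase=sample.phase,
        times=sample.times[:n],
        delta_W=delta,
        peak_value=float(delta[i_peak]),
        peak_time=float(sample.times[i_peak]),
    )


def band_table(bands: Sequence[tuple[str, DifferenceBand]]) -> pd.DataFrame:
    """Peak summary table with columns (group, phase, peak_value, peak_time)."""
    return pd.DataFrame(
        [
            {"group": name, "phase": b.phase,
             "peak_value": b.peak_value, "peak_time": b.peak_time}
            for name, b in bands
        ]
    )
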