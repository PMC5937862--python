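"""Fast chlorophyll *a* fluorescence transients and the JIP test.

A dark-adapted leaf exposed to strong actinic light emits fluorescence that
rises polyphasically from the minimal level F_o to the maximal level F_M
within about one second.  The inflection steps of this OJIP rise — O
(origin, 20 µs), K (300 µs), J (2 ms), I (30 ms) and P (the peak, typically
near 300 ms) — carry information about the successive electron-transport
bottlenecks of photosystem II and I.  The JIP test converts the intensities
read at these steps into quantum yields, probabilities, specific energy
fluxes per reaction centre, and multiplicative performance indices.

This module provides the standard 118-point acquisition grid of a
Handy-PEA-class fluorimeter, the transient container, marker extraction and
the full JIP-test parameter set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MARKER_TIMES",
    "STANDARD_GRID",
    "JIP_PARAMETER_ORDER",
    "NonRisingTransientError",
    "DegenerateTransientError",
    "FluorescenceTransient",
    "OJIPMarkers",
    "JIPParameters",
    "build_timing_grid",
    "extract_markers",
    "compute_jip_parameters",
    "batch_parameter_table",
]

#: Times (s) of the canonical OJIP marker steps.
MARKER_TIMES: Mapping[str, float] = {
    "O": 20e-6,
    "K": 300e-6,
    "J": 2e-3,
    "I": 30e-3,
    "P": 300e-3,
}

N_GRID_POINTS = 118
N_FAST_POINTS = 30  # 10 µs sampling up to and including 0.3 ms


class NonRisingTransientError(ValueError):
    """Raised when a transient does not rise above its 20 µs level."""


class DegenerateTransientError(ValueError):
    """Raised when the J or I step coincides with F_o or F_M."""


def build_timing_grid() -> np.ndarray:
    """Return the standard 118-point acquisition time grid in seconds.

    The instrument samples at 10^5 points/s (every 10 µs) from 10 µs up to
    and including 0.3 ms (30 points), after which the sampling frequency
    decreases; the remaining 88 points are logarithmically spaced up to the
    1 s recording end, with the 2 ms, 30 ms and 300 ms marker times snapped
    onto the nearest grid members so that all five OJIP anchors are exact
    grid points.
    """
    fast = np.arange(1, N_FAST_POINTS + 1) * 10e-6
    fast[1] = MARKER_TIMES["O"]
    fast[-1] = MARKER_TIMES["K"]
    tail = np.geomspace(MARKER_TIMES["K"], 1.0, N_GRID_POINTS - N_FAST_POINTS + 1)[1:]
    for anchor in (MARKER_TIMES["J"], MARKER_TIMES["I"], MARKER_TIMES["P"]):
        tail[int(np.argmin(np.abs(tail - anchor)))] = anchor
    grid = np.concatenate([fast, tail])
    if not np.all(np.diff(grid) > 0):  # pragma: no cover - construction guard
        raise AssertionError("timing grid is not strictly increasing")
    return grid


#: The canonical grid, shared by readers, writers and the synthesiser.
STANDARD_GRID: np.ndarray = build_timing_grid()
STANDARD_GRID.setflags(write=False)


def _grid_index(times: np.ndarray, t: float) -> int:
    """Index of the grid point equal to ``t`` (to 1e-9 relative)."""
    i = int(np.argmin(np.abs(times - t)))
    if not math.isclose(times[i], t, rel_tol=1e-9, abs_tol=1e-12):
        raise ValueError(f"time {t!r} s is not a grid point")
    return i


@dataclass(frozen=True)
class FluorescenceTransient:
    """One sample's fluorescence induction curve on the standard grid."""

    times: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensity", intensity)
        if intensity.shape != times.shape:
            raise ValueError(
                f"sample {self.sample_id!r}: intensity length {intensity.size} "
                f"does not match grid length {times.size}"
            )
        if not np.all(np.isfinite(intensity)):
            raise ValueError(f"sample {self.sample_id!r}: non-finite intensity")
        if np.any(intensity < 0):
            t_bad = times[intensity < 0][0]
            raise ValueError(
                f"sample {self.sample_id!r}: negative intensity at t={t_bad:g} s"
            )
        if not np.all(np.diff(times) > 0):
            raise ValueError(f"sample {self.sample_id!r}: times not strictly increasing")

    def scaled(self, c: float) -> "FluorescenceTransient":
        """Return a copy with intensities multiplied by ``c``."""
        return FluorescenceTransient(self.times, self.intensity * c,
                                     self.sample_id, dict(self.metadata))


@dataclass(frozen=True)
class OJIPMarkers:
    """Marker intensities of one OJIP transient.

    ``area_above`` is the integral of (F_M - F(t)) dt from the O step to the
    time of the maximum, a measure of the electron-acceptor pool size.
    """

    F_o: float
    F_K: float
    F_J: float
    F_I: float
    F_M: float
    t_FM: float
    area_above: float


def extract_markers(transient: FluorescenceTransient) -> OJIPMarkers:
    """Read the O/K/J/I marker intensities and the curve maximum.

    F_o, F_K, F_J and F_I are read at the exact 20 µs, 300 µs, 2 ms and
    30 ms grid points; F_M is the curve maximum (first occurrence).  The
    area above the curve is integrated by the trapezoidal rule on the
    non-uniform grid between the O step and t(F_M).
    """
    t, f = transient.times, transient.intensity
    i_o = _grid_index(t, MARKER_TIMES["O"])
    i_m = int(np.argmax(f))
    F_o = float(f[i_o])
    F_M = float(f[i_m])
    if F_M <= F_o:
        raise NonRisingTransientError(
            f"sample {transient.sample_id!r}: non-rising transient (F_M <= F_o)"
        )
    sl = slice(i_o, i_m + 1)
    area = float(np.trapezoid(F_M - f[sl], t[sl]))
    return OJIPMarkers(
        F_o=F_o,
        F_K=float(f[_grid_index(t, MARKER_TIMES["K"])]),
        F_J=float(f[_grid_index(t, MARKER_TIMES["J"])]),
        F_I=float(f[_grid_index(t, MARKER_TIMES["I"])]),
        F_M=F_M,
        t_FM=float(t[i_m]),
        area_above=area,
    )


#: Column order of parameter tables.
JIP_PARAMETER_ORDER = (
    "F_o", "F_M", "F_V", "V_J", "V_I", "M_o",
    "phi_Po", "psi_Eo", "phi_Eo", "delta_Ro", "phi_Ro",
    "ABS_RC", "TR_RC", "ET_RC", "DI_RC", "gamma_RC", "RC_CSo",
    "S_m", "N_turnover", "PI_ABS", "PI_total",
)


@dataclass(frozen=True)
class JIPParameters:
    """The derived JIP-test parameter vector of one transient.

    Yields and probabilities (phi_Po, psi_Eo, phi_Eo, delta_Ro, phi_Ro)
    are dimensionless fractions in [0, 1]; M_o is the initial slope of the
    relative variable fluorescence per ms; the specific fluxes ABS/RC,
    TR/RC, ET/RC and DI/RC are per active PSII reaction centre.
    """

    F_o: float
    F_M: float
    F_V: float
    V_J: float
    V_I: float
    M_o: float
    phi_Po: float
    psi_Eo: float
    phi_Eo: float
    delta_Ro: float
    phi_Ro: float
    ABS_RC: float
    TR_RC: float
    ET_RC: float
    DI_RC: float
    gamma_RC: float
    RC_CSo: float
    S_m: float
    N_turnover: float
    PI_ABS: float
    PI_total: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in JIP_PARAMETER_ORDER}


def compute_jip_parameters(m: OJIPMarkers) -> JIPParameters:
    """Compute the full JIP-test parameter set from marker intensities.

    Implements the standard Strasser formula set:

    ==========  =====================================================
    V_J, V_I    (F_J - F_o)/F_V, (F_I - F_o)/F_V
    M_o         4 (F_K - F_o)/F_V          [per ms; K at 300 µs]
    phi_Po      F_V / F_M
    psi_Eo      1 - V_J
    phi_Eo      phi_Po psi_Eo
    delta_Ro    (1 - V_I)/(1 - V_J)
    phi_Ro      phi_Po (1 - V_I)
    ABS/RC      (M_o / V_J) / phi_Po
    TR/RC       M_o / V_J
    ET/RC       (M_o / V_J) psi_Eo
    DI/RC       ABS/RC - TR/RC
    gamma_RC    1 / (1 + ABS/RC)
    RC/CS_o     phi_Po (V_J / M_o) F_o
    S_m         area_above / F_V
    N           S_m M_o / V_J
    PI_ABS      [gamma/(1-gamma)] [phi_Po/(1-phi_Po)] [psi_Eo/(1-psi_Eo)]
    PI_total    PI_ABS delta_Ro/(1 - delta_Ro)
    ==========  =====================================================
    """
    if m.F_M <= m.F_o:
        raise NonRisingTransientError("non-rising transient (F_M <= F_o)")
    F_V = m.F_M - m.F_o
    V_J = (m.F_J - m.F_o) / F_V
    V_I = (m.F_I - m.F_o) / F_V
    if V_J <= 0.0 or V_J >= 1.0:
        raise DegenerateTransientError(f"degenerate J step (V_J={V_J:g})")
    if V_I >= 1.0:
        raise DegenerateTransientError(f"degenerate I step (V_I={V_I:g})")
    M_o = 4.0 * (m.F_K - m.F_o) / F_V
    phi_Po = F_V / m.F_M
    psi_Eo = 1.0 - V_J
    phi_Eo = phi_Po * psi_Eo
    delta_Ro = (1.0 - V_I) / (1.0 - V_J)
    phi_Ro = phi_Po * (1.0 - V_I)
    TR_RC = M_o / V_J
    ABS_RC = TR_RC / phi_Po
    ET_RC = TR_RC * psi_Eo
    DI_RC = ABS_RC - TR_RC
    gamma_RC = 1.0 / (1.0 + ABS_RC)
    RC_CSo = phi_Po * (V_J / M_o) * m.F_o
    S_m = m.area_above / F_V
    N_turnover = S_m * M_o / V_J
    PI_ABS = (1.0 / ABS_RC) * (phi_Po / (1.0 - phi_Po)) * (psi_Eo / (1.0 - psi_Eo))
    PI_total = PI_ABS * delta_Ro / (1.0 - delta_Ro)
    return JIPParameters(
        F_o=m.F_o, F_M=m.F_M, F_V=F_V, V_J=V_J, V_I=V_I, M_o=M_o,
        phi_Po=phi_Po, psi_Eo=psi_Eo, phi_Eo=phi_Eo, delta_Ro=delta_Ro,
        phi_Ro=phi_Ro, ABS_RC=ABS_RC, TR_RC=TR_RC, ET_RC=ET_RC, DI_RC=DI_RC,
        gamma_RC=gamma_RC, RC_CSo=RC_CSo, S_m=S_m, N_turnover=N_turnover,
        PI_ABS=PI_ABS, PI_total=PI_total,
    )


def batch_parameter_table(
    transients: Iterable[FluorescenceTransient],
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """JIP parameters for a batch of transients.

    Returns a (table, failures) pair: the table has one row per successfully
    processed transient in input order, columns in :data:`JIP_PARAMETER_ORDER`;
    failures is a list of (sample_id, message) for transients whose markers
    or parameters could not be computed.  Failed samples are reported, never
    silently dropped.
    """
    transients = list(transients)
    if not transients:
        raise ValueError("batch_parameter_table requires at least one transient")
    rows: list[dict[str, float]] = []
    index: list[str] = []
    failures: list[tuple[str, str]] = []
    for tr in transients:
        try:
            p = compute_jip_parameters(extract_markers(tr))
        except (NonRisingTransientError, DegenerateTransientError, ValueError) as e:
            failures.append((tr.sample_id, str(e)))
            continue
        rows.append(p.as_dict())
        index.append(tr.sample_id)
    table = pd.DataFrame(rows, index=pd.Index(index, name="sample_id"),
                         columns=list(JIP_PARAMETER_ORDER))
    return table, failures
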