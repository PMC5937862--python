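"""Synthetic cohorts of nutrient-deficient rapeseed-like samples.

Reference profiles for five nutrient-status classes of greenhouse-grown
rapeseed — no, slight, moderate and strong combined deficiency plus an
Fe-specific deficiency — define, per class, the mean and dispersion of nine
leaf element contents (N, P, K, Ca, Mg in g/kg; Cu, Fe, Mn, Zn in mg/kg)
and of eight JIP-test parameters (F_o, M_o, phi_Po, phi_Eo, delta_Ro,
phi_Ro, PI_total, gamma_RC).  The generator draws group-structured samples
from these profiles and synthesises raw OJIP transients whose recomputed
JIP parameters recover the sampled targets, so the whole pipeline
(marker extraction -> multivariate grouping -> SOM classification) can be
exercised end to end without any measured data.

Within-sample correlation between elements and fluorescence is induced by
a per-sample latent severity factor (loading 0.6): a sample that drew an
unluckier severity than its group mean is simultaneously lower in
nutrients and lower in photochemical yields, which gives the cohorts the
gradient structure that PCA, clustering and the SOM rely on.

Transient shape: each phase (O-K, K-J, J-I, I-P) is a smooth saturating
segment s(x; c) = (1 - exp(-c x))/(1 - exp(-c)) in log-time fraction x.
The O-K curvature c rises with deficiency severity, emulating the loss of
antenna connectivity that produces positive L bands in stressed plants,
and the I-P curvature falls with severity, emulating the slower refilling
of the PSI acceptor pool (negative I-P bands).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .ojip import MARKER_TIMES, STANDARD_GRID, FluorescenceTransient

__all__ = [
    "ELEMENTS",
    "CHLF_PARAMETERS",
    "GROUP_ORDER",
    "GroupProfile",
    "GROUP_PROFILES",
    "SyntheticCohort",
    "sample_cohort",
    "synthesize_transient",
    "derive_targets",
    "write_cohort",
    "read_cohort",
]

FIXTURE_VERSION = "1.0"

ELEMENTS = ("N", "P", "K", "Ca", "Mg", "Cu", "Fe", "Mn", "Zn")
CHLF_PARAMETERS = ("F_o", "M_o", "phi_Po", "phi_Eo",
                   "delta_Ro", "phi_Ro", "PI_total", "gamma_RC")
GROUP_ORDER = ("no deficiency", "Fe-specific deficiency", "slight deficiency",
               "moderate deficiency", "strong deficiency")
#: Severity ranks of the four combined-deficiency classes.
SEVERITY_ORDER = ("no deficiency", "slight deficiency",
                  "moderate deficiency", "strong deficiency")


@dataclass(frozen=True)
class GroupProfile:
    """Mean and SD of each element and ChlF parameter for one class.

    ``ok_curvature``/``ip_curvature`` shape the synthetic transients'
    O-K and I-P phases (higher O-K curvature -> earlier rise -> positive
    L band against the control; lower I-P curvature -> negative I-P band).
    """

    name: str
    elements: Mapping[str, tuple[float, float]]
    chlf: Mapping[str, tuple[float, float]]
    ok_curvature: float
    ip_curvature: float

    def __post_init__(self) -> None:
        for k, (_, sd) in {**dict(self.elements), **dict(self.chlf)}.items():
            if sd <= 0:
                raise ValueError(f"{self.name}: SD of {k} must be > 0")


def _profile(name, N, P, K, Ca, Mg, Cu, Fe, Mn, Zn,
             F_o, M_o, phi_Po, phi_Eo, delta_Ro, phi_Ro, PI_total, gamma_RC,
             ok_c, ip_c) -> GroupProfile:
    return GroupProfile(
        name=name,
        elements={"N": N, "P": P, "K": K, "Ca": Ca, "Mg": Mg,
                  "Cu": Cu, "Fe": Fe, "Mn": Mn, "Zn": Zn},
        chlf={"F_o": F_o, "M_o": M_o, "phi_Po": phi_Po, "phi_Eo": phi_Eo,
              "delta_Ro": delta_Ro, "phi_Ro": phi_Ro,
              "PI_total": PI_total, "gamma_RC": gamma_RC},
        ok_curvature=ok_c, ip_curvature=ip_c,
    )


# Frozen reference profiles (mean, SD) for five nutrient-status classes of
# young (25 days after sowing) greenhouse rapeseed.  Elements N..Mg in g/kg,
# Cu..Zn in mg/kg; F_o in relative fluorescence units; M_o per ms; yields
# dimensionless.  The curvatures are generator shape parameters, chosen so
# that L-band amplitude grows and the I-P band turns negative with severity.
GROUP_PROFILES: Mapping[str, GroupProfile] = {
    "no deficiency": _profile(
        "no deficiency",
        N=(45.92, 3.66), P=(6.41, 1.54), K=(42.23, 5.28), Ca=(19.67, 4.78),
        Mg=(6.39, 1.26), Cu=(44.53, 7.03), Fe=(82.65, 17.00),
        Mn=(913.55, 37.42), Zn=(93.32, 46.63),
        F_o=(809.70, 382.79), M_o=(1.13, 0.08), phi_Po=(0.79, 0.04),
        phi_Eo=(0.37, 0.11), delta_Ro=(0.35, 0.04), phi_Ro=(0.13, 0.04),
        PI_total=(7.82, 1.26), gamma_RC=(0.74, 0.04),
        ok_c=2.0, ip_c=2.0),
    "Fe-specific deficiency": _profile(
        "Fe-specific deficiency",
        N=(32.90, 1.74), P=(7.13, 0.86), K=(43.28, 4.95), Ca=(18.64, 2.29),
        Mg=(5.78, 0.30), Cu=(42.25, 3.33), Fe=(51.8, 44.01),
        Mn=(1216.25, 234.82), Zn=(95.8, 29.70),
        F_o=(500.00, 156.74), M_o=(0.86, 0.23), phi_Po=(0.77, 0.07),
        phi_Eo=(0.40, 0.09), delta_Ro=(0.36, 0.04), phi_Ro=(0.15, 0.04),
        PI_total=(4.48, 1.20), gamma_RC=(0.69, 0.03),
        ok_c=3.6, ip_c=1.8),
    "slight deficiency": _profile(
        "slight deficiency",
        N=(24.76, 5.55), P=(5.30, 1.40), K=(25.66, 7.37), Ca=(17.34, 2.74),
        Mg=(7.45, 1.55), Cu=(35.00, 6.71), Fe=(35.50, 8.90),
        Mn=(38.84, 4.98), Zn=(39.23, 14.15),
        F_o=(734.63, 121.97), M_o=(1.09, 0.07), phi_Po=(0.76, 0.04),
        phi_Eo=(0.36, 0.05), delta_Ro=(0.39, 0.03), phi_Ro=(0.14, 0.02),
        PI_total=(6.15, 1.36), gamma_RC=(0.71, 0.01),
        ok_c=3.2, ip_c=1.6),
    "moderate deficiency": _profile(
        "moderate deficiency",
        N=(17.53, 4.34), P=(4.50, 1.16), K=(16.41, 5.18), Ca=(12.42, 2.09),
        Mg=(5.86, 1.95), Cu=(19.16, 5.91), Fe=(20.85, 5.65),
        Mn=(31.63, 7.30), Zn=(31.90, 18.75),
        F_o=(950.06, 152.38), M_o=(1.27, 0.07), phi_Po=(0.72, 0.05),
        phi_Eo=(0.32, 0.04), delta_Ro=(0.21, 0.07), phi_Ro=(0.07, 0.03),
        PI_total=(2.73, 1.32), gamma_RC=(0.76, 0.03),
        ok_c=4.4, ip_c=1.2),
    "strong deficiency": _profile(
        "strong deficiency",
        N=(13.38, 3.15), P=(3.40, 0.77), K=(12.80, 3.64), Ca=(14.70, 3.66),
        Mg=(4.07, 1.19), Cu=(13.89, 3.09), Fe=(19.66, 7.45),
        Mn=(17.33, 11.29), Zn=(20.62, 7.14),
        F_o=(1948.00, 386.35), M_o=(1.42, 0.20), phi_Po=(0.39, 0.14),
        phi_Eo=(0.14, 0.06), delta_Ro=(0.19, 0.04), phi_Ro=(0.03, 0.01),
        PI_total=(1.64, 0.66), gamma_RC=(0.85, 0.05),
        ok_c=6.0, ip_c=0.8),
}

#: Per-feature severity direction: +1 if the feature increases with
#: deficiency (strong mean above no-deficiency mean), else -1.
def _severity_directions() -> dict[str, float]:
    no = GROUP_PROFILES["no deficiency"]
    strong = GROUP_PROFILES["strong deficiency"]
    out = {}
    for k in ELEMENTS:
        out[k] = 1.0 if strong.elements[k][0] > no.elements[k][0] else -1.0
    for k in CHLF_PARAMETERS:
        out[k] = 1.0 if strong.chlf[k][0] > no.chlf[k][0] else -1.0
    return out


_DIRECTIONS = _severity_directions()


# ---------------------------------------------------------------------------
# Transient synthesis


def _phase_shape(x: np.ndarray, c: float) -> np.ndarray:
    """Saturating segment through (0,0) and (1,1); c>0 concave, c<0 convex."""
    if abs(c) < 1e-9:
        return x
    return (1.0 - np.exp(-c * x)) / (1.0 - np.exp(-c))


def _log_fraction(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    return (np.log(t) - np.log(t0)) / (np.log(t1) - np.log(t0))


#: Common rescaling of the PI-derived initial slope.  The slope implied by
#: the profile PI_total values alone would be ~0.01-0.2 per ms, an order of
#: magnitude below what fast fluorimeters record, and the resulting tiny
#: F(300us)-F(20us) difference would be drowned by measurement noise.  One
#: shared factor moves the slope into the instrument's typical ~1/ms range
#: while leaving the PI-based severity ordering intact (the recomputed
#: PI_total of a noiseless transient is the sampled PI_total / M_O_SCALE).
M_O_SCALE = 8.0
#: Lower bound on the synthesis slope.  A slope below ~0.5/ms puts the
#: 20 us - 300 us rise inside the measurement noise and makes the derived
#: 1/M_o statistics heavy-tailed; flooring only pushes the recomputed
#: PI_total of the affected (most deficient) samples further down, so the
#: severity ordering is preserved.
M_O_FLOOR = 0.5


def derive_targets(chlf: Mapping[str, float]) -> dict[str, float]:
    """Invert sampled JIP parameters into transient synthesis targets.

    From (F_o, phi_Po, phi_Eo, delta_Ro, PI_total):

        V_J = 1 - phi_Eo/phi_Po
        V_I = 1 - delta_Ro (1 - V_J)
        F_M = F_o / (1 - phi_Po)
        M_o from PI_total, by inverting
            PI_ABS = (1/ABS_RC) [phi/(1-phi)] [psi/(1-psi)],
            ABS_RC = (M_o/V_J)/phi_Po,  PI_total = PI_ABS d/(1-d),
        then rescaled by :data:`M_O_SCALE`.

    M_o is recovered from PI_total rather than taken from the sampled
    profile because the two are mutually exclusive under the standard
    formula set; PI_total is the severity axis of the whole analysis, so
    its ordering is the property preserved.
    """
    phi_Po = chlf["phi_Po"]
    V_J = 1.0 - chlf["phi_Eo"] / phi_Po
    V_J = float(np.clip(V_J, 0.02, 0.95))
    delta = chlf["delta_Ro"]
    V_I = 1.0 - delta * (1.0 - V_J)
    F_o = chlf["F_o"]
    F_M = F_o / (1.0 - phi_Po)
    psi = 1.0 - V_J
    PI_ABS = chlf["PI_total"] * (1.0 - delta) / delta
    abs_rc = (phi_Po / (1.0 - phi_Po)) * (psi / (1.0 - psi)) / PI_ABS
    M_o = abs_rc * phi_Po * V_J * M_O_SCALE
    M_o = float(np.clip(M_o, M_O_FLOOR, 3.6 * V_J))
    return {"F_o": F_o, "F_M": F_M, "V_J": V_J, "V_I": V_I, "M_o": M_o}


def synthesize_transient(
    targets: Mapping[str, float],
    seed: int | None = None,
    noise_sd: float = 0.0,
    sample_id: str = "synthetic",
    ok_curvature: float = 2.0,
    ip_curvature: float = 2.0,
    metadata: Mapping[str, object] | None = None,
) -> FluorescenceTransient:
    """Build a monotone OJIP transient hitting the given JIP targets.

    ``targets`` must provide F_o, F_M, V_J, V_I and M_o (per ms).  The
    curve passes exactly through F(20 us)=F_o, F(300 us)=F_o+(M_o/4) F_V,
    F(2 ms)=F_o+V_J F_V, F(30 ms)=F_o+V_I F_V and F(300 ms)=F_M, is flat
    afterwards, and interpolates each phase with a smooth saturating
    segment in log time.  Multiplicative Gaussian noise with relative SD
    ``noise_sd`` is applied when positive.
    """
    F_o, F_M = float(targets["F_o"]), float(targets["F_M"])
    V_J, V_I, M_o = float(targets["V_J"]), float(targets["V_I"]), float(targets["M_o"])
    problems = []
    if not F_o > 0:
        problems.append(f"F_o={F_o:g} must be > 0")
    if not F_M > F_o:
        problems.append(f"F_M={F_M:g} must exceed F_o={F_o:g}")
    if not 0.0 < V_J < 1.0:
        problems.append(f"V_J={V_J:g} must lie in (0, 1)")
    if not V_J < V_I < 1.0:
        problems.append(f"V_I={V_I:g} must lie in (V_J, 1)")
    if not M_o > 0:
        problems.append(f"M_o={M_o:g} must be > 0")
    F_V = F_M - F_o
    F_K = F_o + (M_o / 4.0) * F_V
    if not problems and not F_K <= F_o + V_J * F_V:
        problems.append(
            f"M_o={M_o:g} implies F(300us)={F_K:g} above the J step "
            f"F(2ms)={F_o + V_J * F_V:g}")
    if problems:
        raise ValueError("infeasible transient targets: " + "; ".join(problems))

    F_J = F_o + V_J * F_V
    F_I = F_o + V_I * F_V
    t = STANDARD_GRID
    f = np.empty_like(t)
    tO, tK, tJ, tI, tP = (MARKER_TIMES[m] for m in "OKJIP")
    segments = [
        (tO, tK, F_o, F_K, ok_curvature),
        (tK, tJ, F_K, F_J, 1.5),
        (tJ, tI, F_J, F_I, 1.5),
        (tI, tP, F_I, F_M, ip_curvature),
    ]
    f[t <= tO] = F_o
    for t0, t1, f0, f1, c in segments:
        m = (t > t0) & (t <= t1)
        x = _log_fraction(t[m], t0, t1)
        f[m] = f0 + (f1 - f0) * _phase_shape(x, c)
    f[t > tP] = F_M
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f * (1.0 + noise_sd * rng.standard_normal(f.shape))
        f = np.maximum(f, 0.0)
    return FluorescenceTransient(t, f, sample_id=sample_id,
                                 metadata=dict(metadata or {}))


# ---------------------------------------------------------------------------
# Cohort sampling


@dataclass
class SyntheticCohort:
    """Row-aligned element table, JIP target table, transients and labels."""

    elements: pd.DataFrame
    jip_targets: pd.DataFrame
    transients: list[FluorescenceTransient]
    labels: pd.Series
    seed: int
    n_per_group: int
    noise_sd: float


def _truncate_chlf(row: dict[str, float]) -> dict[str, float]:
    """Clip a sampled ChlF vector into the physically admissible region."""
    row["F_o"] = max(row["F_o"], 50.0)
    # 0.15 floor: below that there is almost no variable fluorescence and
    # the JIP ratio estimators are ill-conditioned; living leaves sit above.
    row["phi_Po"] = float(np.clip(row["phi_Po"], 0.15, 0.90))
    row["phi_Eo"] = float(np.clip(row["phi_Eo"], 0.01, 0.98 * row["phi_Po"]))
    row["delta_Ro"] = float(np.clip(row["delta_Ro"], 0.02, 0.95))
    row["PI_total"] = max(row["PI_total"], 0.1)
    row["gamma_RC"] = float(np.clip(row["gamma_RC"], 0.05, 0.95))
    row["phi_Ro"] = float(np.clip(row["phi_Ro"], 0.005, 0.95))
    row["M_o"] = max(row["M_o"], 0.05)
    return row


def sample_cohort(
    n_per_group: int = 30,
    seed: int = 1,
    noise_sd: float = 0.005,
    latent_loading: float = 0.6,
    sd_scale: float = 1.0,
    with_transients: bool = True,
) -> SyntheticCohort:
    """Draw a five-group cohort from the frozen class profiles.

    Per sample, a latent severity factor g ~ N(0,1) is shared between the
    element and ChlF vectors with loading ``latent_loading`` (residual
    loading sqrt(1 - loading^2) keeps the marginal SDs at the profile
    values).  Elements are truncated positive; yields are clipped into
    (0, 1) with delta_Ro < 1 so that V_I < 1 holds jointly.  Transients are
    synthesised from PI-consistent targets (see :func:`derive_targets`)
    with multiplicative noise ``noise_sd``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not 0.0 <= latent_loading < 1.0:
        raise ValueError("latent_loading must be in [0, 1)")
    rng = np.random.default_rng(seed)
    resid = float(np.sqrt(1.0 - latent_loading**2))

    element_rows, target_rows, labels, ids = [], [], [], []
    transients: list[FluorescenceTransient] = []
    for g_idx, group in enumerate(GROUP_ORDER):
        prof = GROUP_PROFILES[group]
        for i in range(n_per_group):
            sid = f"{group.split()[0].replace('-', '')}_{i:03d}"
            g = rng.standard_normal()
            erow = {}
            for k in ELEMENTS:
                mu, sd = prof.elements[k]
                sd = sd * sd_scale
                x = mu + sd * (latent_loading * _DIRECTIONS[k] * g
                               + resid * rng.standard_normal())
                erow[k] = max(x, 0.02 * mu)  # truncation: contents stay positive
            crow = {}
            for k in CHLF_PARAMETERS:
                mu, sd = prof.chlf[k]
                sd = sd * sd_scale
                crow[k] = mu + sd * (latent_loading * _DIRECTIONS[k] * g
                                     + resid * rng.standard_normal())
            crow = _truncate_chlf(crow)
            targets = derive_targets(crow)
            if with_transients:
                tr_seed = int(rng.integers(0, 2**31 - 1))
                transients.append(synthesize_transient(
                    targets, seed=tr_seed, noise_sd=noise_sd, sample_id=sid,
                    ok_curvature=prof.ok_curvature,
                    ip_curvature=prof.ip_curvature,
                    metadata={"group": group}))
            element_rows.append(erow)
            target_rows.append({**crow, **{f"target_{k}": v for k, v in targets.items()}})
            labels.append(group)
            ids.append(sid)

    index = pd.Index(ids, name="sample_id")
    return SyntheticCohort(
        elements=pd.DataFrame(element_rows, index=index, columns=list(ELEMENTS)),
        jip_targets=pd.DataFrame(target_rows, index=index),
        transients=transients,
        labels=pd.Series(labels, index=index, name="group"),
        seed=seed,
        n_per_group=n_per_group,
        noise_sd=noise_sd,
    )


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write transients, element table, labels and a manifest to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "transients": directory / "transients.csv",
        "elements": directory / "elements.csv",
        "jip_targets": directory / "jip_targets.csv",
        "labels": directory / "labels.csv",
        "manifest": directory / "manifest.json",
    }
    if cohort.transients:
        cio.write_transients(paths["transients"], cohort.transients)
    cio.write_feature_table(paths["elements"], cohort.elements)
    cio.write_feature_table(paths["jip_targets"], cohort.jip_targets)
    cohort.labels.to_frame().to_csv(paths["labels"], index_label="sample_id")
    manifest = {
        "fixture_version": FIXTURE_VERSION,
        "seed": cohort.seed,
        "n_per_group": cohort.n_per_group,
        "noise_sd": cohort.noise_sd,
        "groups": list(GROUP_ORDER),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=1))
    return paths


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Regenerate a cohort from its manifest (bit-reproducible from seed)."""
    manifest = json.loads((Path(directory) / "manifest.json").read_text())
    return sample_cohort(n_per_group=manifest["n_per_group"],
                         seed=manifest["seed"],
                         noise_sd=manifest["noise_sd"])
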