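"""End-to-end nutrient-status workflow.

Stages, in order: transient ingestion -> JIP parameter table ->
standardisation -> correlation PCA of the leaf element table ->
hierarchical k-means grouping -> one-way ANOVA + Tukey letters per element
-> multilayer SOM training (LEC + ChlF + class layers) -> codebook
classification into five deficiency classes -> ChlF-only per-sample
classification -> difference bands of each class against the
no-deficiency class -> report.

Every stage writes its intermediate table to the output directory; a JSON-
lines log records seed, stage timings and versions.  Outputs are
deterministic for a fixed configuration (timestamps live only in the log).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .bands import PHASES, band_table, control_curve, difference_band, double_normalise
from .multivariate import CorrelationPCA, HKMeans, anova_tukey, dendrogram_to_newick, standardise
from .ojip import JIP_PARAMETER_ORDER, batch_parameter_table
from .som import DeficiencyClassMap, SuperSOM, classify_units, predict_deficiency, som_diagnostics
from .synthetic import sample_cohort, write_cohort

__all__ = ["PipelineConfig", "DeficiencyReport", "run_pipeline", "demo",
           "DEFAULT_CHLF_FEATURES"]

#: The eight fluorescence parameters used as the SOM's ChlF layer.
DEFAULT_CHLF_FEATURES = ("F_o", "M_o", "PI_total", "delta_Ro",
                         "phi_Po", "phi_Ro", "phi_Eo", "gamma_RC")


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    transients: str
    elements: str
    out: str
    seed: int = 1
    element_k: int | str = "auto"
    class_k: int = 5
    alpha: float = 0.05
    som_epochs: int = 100
    som_rows: int = 4
    som_cols: int = 9
    class_layer_weight: float = 0.5
    chlf_features: Sequence[str] = field(default_factory=lambda: list(DEFAULT_CHLF_FEATURES))
    plots: bool = False
    force: bool = False

    @classmethod
    def from_dict(cls, raw: Mapping[str, object]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)  # type: ignore[arg-type]
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def validate(self) -> None:
        if self.element_k != "auto" and (not isinstance(self.element_k, int) or self.element_k < 2):
            raise ValueError("element_k must be 'auto' or an integer >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.som_epochs < 0:
            raise ValueError("som_epochs must be >= 0")
        if self.class_k < 1:
            raise ValueError("class_k must be >= 1")
        if not self.chlf_features:
            raise ValueError("chlf_features must not be empty")


@dataclass
class DeficiencyReport:
    """Per-sample results plus per-stage summaries."""

    samples: pd.DataFrame            # JIP params + group + class + BMU
    failures: list[tuple[str, str]]  # (sample_id, reason)
    tukey: dict[str, object]         # feature -> GroupComparison
    band_peaks: pd.DataFrame
    classmap: DeficiencyClassMap
    model: SuperSOM
    diagnostics: dict[str, float]


def _snr_screen(tr, min_rise_sigmas: float = 4.0) -> tuple[bool, str]:
    """Reject transients whose O-K rise is within the measurement noise.

    The point noise is estimated from first differences on the plateau
    (t >= 0.4 s), where the curve is flat up to noise; the difference of
    two noisy points has SD sqrt(2) times the point noise.  Noise-free
    curves (estimate 0) always pass.
    """
    from .ojip import MARKER_TIMES, _grid_index

    t, f = tr.times, tr.intensity
    plateau = f[t >= 0.4]
    sigma_pair = float(np.std(np.diff(plateau))) if plateau.size >= 3 else 0.0
    rise = f[_grid_index(t, MARKER_TIMES["K"])] - f[_grid_index(t, MARKER_TIMES["O"])]
    if rise < min_rise_sigmas * sigma_pair:
        return False, (f"low signal-to-noise O-K rise "
                       f"({rise:.1f} < {min_rise_sigmas:g} x {sigma_pair:.1f})")
    return True, ""


class _StageLog:
    def __init__(self, path: Path, seed: int):
        self.path = path
        self.t0 = time.perf_counter()
        self._write({"event": "start", "seed": seed, "version": __version__,
                     "numpy": np.__version__, "pandas": pd.__version__})

    def _write(self, record: dict) -> None:
        record["elapsed_s"] = round(time.perf_counter() - self.t0, 4)
        with self.path.open("a") as fh:
            fh.write(json.dumps(record) + "\n")

    def stage(self, name: str, **info) -> None:
        self._write({"event": "stage", "stage": name, **info})


def run_pipeline(config: PipelineConfig) -> DeficiencyReport:
    """Execute all stages and write intermediates under ``config.out``."""
    config.validate()
    out = Path(config.out)
    report_path = out / "report.csv"
    if report_path.exists() and not config.force:
        raise FileExistsError(
            f"{report_path} exists; pass force=True (--force) to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLog(out / "log.jsonl", config.seed)

    def _fail(stage: str, err: Exception) -> Exception:
        log.stage(stage, status="failed", error=str(err))
        return RuntimeError(f"pipeline stage {stage!r} failed: {err}")

    # 1. ingest
    try:
        transients = cio.read_transients(config.transients)
        elements = cio.read_feature_table(config.elements)
    except Exception as e:
        raise _fail("ingest", e)
    log.stage("ingest", n_transients=len(transients), n_element_rows=len(elements))

    # 2. QC screen + JIP parameters.  Curves whose O-K rise is smaller than
    # a few times the plateau noise produce wildly ill-conditioned ratio
    # statistics (1/M_o, double-normalised W); they are rejected up front
    # and reported as failures, as instrument QC protocols do.
    screened, snr_failures = [], []
    for tr in transients:
        ok, reason = _snr_screen(tr)
        (screened if ok else snr_failures).append(tr if ok else (tr.sample_id, reason))
    if not screened:
        raise _fail("qc", ValueError("no transient passed the SNR screen"))
    try:
        params, failures = batch_parameter_table(screened)
    except Exception as e:
        raise _fail("jip_parameters", e)
    failures = snr_failures + failures
    cio.write_feature_table(out / "jip_parameters.csv", params)
    pd.DataFrame(failures, columns=["sample_id", "reason"]).to_csv(
        out / "failures.csv", index=False)
    log.stage("jip_parameters", n_ok=len(params), n_failed=len(failures))

    # align samples present in both tables
    common = params.index.intersection(elements.index)
    if len(common) < 10:
        raise _fail("align", ValueError(
            f"only {len(common)} samples shared between transients and elements"))
    params = params.loc[common]
    elements = elements.loc[common]

    # 3. PCA of the element table
    try:
        z = standardise(elements)
        pca_model = CorrelationPCA().fit(elements)
    except Exception as e:
        raise _fail("pca", e)
    scores = pd.DataFrame(pca_model.scores_, index=elements.index,
                          columns=[f"PC{j+1}" for j in range(pca_model.scores_.shape[1])])
    cio.write_feature_table(out / "pca_scores.csv", scores)
    loadings = pd.DataFrame(pca_model.loadings_, index=elements.columns,
                            columns=scores.columns)
    loadings.to_csv(out / "pca_loadings.csv", index_label="feature")
    log.stage("pca", variance=[round(v, 4) for v in pca_model.proportion_variance_[:4].tolist()])

    # 4. hierarchical k-means on the informative components (eigenvalue > 1,
    #    at least the first two)
    n_keep = max(2, int(np.sum(pca_model.eigenvalues_ > 1.0)))
    try:
        km = HKMeans(k=config.element_k, seed=config.seed).fit(
            scores.iloc[:, :n_keep])
    except Exception as e:
        raise _fail("hkmeans", e)
    groups = pd.Series(km.labels_, index=elements.index, name="element_group")
    groups.to_frame().to_csv(out / "element_groups.csv", index_label="sample_id")
    (out / "dendrogram.nwk").write_text(
        dendrogram_to_newick(km.linkage_, list(map(str, elements.index))))
    log.stage("hkmeans", k=km.k_, wss=round(km.inertia_, 4))

    # 5. ANOVA + Tukey per element across the h-k-means groups
    tukey: dict[str, object] = {}
    letter_rows = []
    group_sizes = groups.value_counts()
    if (group_sizes >= 2).all() and len(group_sizes) >= 2:
        for feat in elements.columns:
            cmp_ = anova_tukey(elements[feat].to_numpy(), groups.to_numpy(),
                               alpha=config.alpha, feature=feat)
            tukey[feat] = cmp_
            for g in cmp_.group_order:
                letter_rows.append({"feature": feat, "group": g,
                                    "mean": cmp_.means[g], "se": cmp_.se[g],
                                    "letters": cmp_.letters[g],
                                    "F": cmp_.F, "p": cmp_.p})
    pd.DataFrame(letter_rows).to_csv(out / "tukey_letters.csv", index=False)
    log.stage("anova_tukey", n_features=len(tukey))

    # 6. SOM training
    chlf = params[list(config.chlf_features)]
    class_onehot = pd.get_dummies(groups.astype(str), prefix="g").astype(float)
    layers = {"LEC": elements, "ChlF": chlf, "class": class_onehot}
    try:
        model = SuperSOM(n_rows=config.som_rows, n_cols=config.som_cols,
                         layer_weights={"class": config.class_layer_weight},
                         epochs=config.som_epochs, seed=config.seed).fit(layers)
    except Exception as e:
        raise _fail("som_train", e)
    model.to_json(out / "som_model.json")
    diagnostics = som_diagnostics(model, {"LEC": elements, "ChlF": chlf})
    log.stage("som_train", qe_init=round(model.qe_init_, 4), qe=round(model.qe_, 4),
              **{k: round(v, 4) for k, v in diagnostics.items()})

    # 7. codebook classification + ChlF-only per-sample prediction
    try:
        classmap = classify_units(model, k=config.class_k, seed=config.seed)
    except Exception as e:
        raise _fail("classify_units", e)
    chlf_values = chlf.to_numpy(dtype=float)
    labels, bmus, dists = [], [], []
    for i in range(len(chlf)):
        lab, b, d = predict_deficiency(model, classmap, chlf_values[i])
        labels.append(lab)
        bmus.append(model.grid_.unit_names()[b])
        dists.append(d)
    unit_df = pd.DataFrame({"unit": model.grid_.unit_names(),
                            "class": classmap.unit_labels,
                            "cluster": classmap.cluster_ids})
    unit_df.to_csv(out / "unit_classes.csv", index=False)
    log.stage("classify", classes=sorted(set(classmap.unit_labels)))

    # 8. difference bands of each class against the no-deficiency class
    samples = params.copy()
    samples["element_group"] = groups
    samples["class"] = labels
    samples["bmu"] = bmus
    samples["bmu_distance"] = dists
    by_id = {tr.sample_id: tr for tr in transients}
    control_ids = [sid for sid, lab in zip(samples.index, labels)
                   if lab == "no deficiency"]
    peaks = pd.DataFrame(columns=["group", "phase", "peak_value", "peak_time"])
    from .bands import NonRisingPhaseError

    def _group_curve(ids, phase):
        curves = []
        for sid in ids:
            try:
                curves.append(double_normalise(by_id[sid], phase))
            except NonRisingPhaseError:
                continue  # noisy flat phase; sample excluded from the band
        if not curves:
            return None
        n_common = min(c.times.size for c in curves)
        times = curves[0].times[:n_common]
        W = np.mean([c.W[:n_common] for c in curves], axis=0)
        from .bands import NormalisedCurve
        return NormalisedCurve(phase=phase, times=times, W=W)

    if control_ids:
        band_rows = []
        curve_rows = []
        for phase in PHASES:
            control = _group_curve(control_ids, phase)
            if control is None:
                continue
            for cls in sorted(set(labels)):
                ids = [sid for sid, lab in zip(samples.index, labels) if lab == cls]
                cls_curve = _group_curve(ids, phase)
                if cls_curve is None:
                    continue
                band = difference_band(cls_curve, control)
                band_rows.append((cls, band))
                for t, dw in zip(band.times, band.delta_W):
                    curve_rows.append({"phase": phase, "group": cls,
                                       "time_s": t, "delta_W": dw})
        peaks = band_table(band_rows)
        peaks.to_csv(out / "band_peaks.csv", index=False)
        pd.DataFrame(curve_rows).to_csv(out / "band_curves.csv", index=False)
    log.stage("bands", n_controls=len(control_ids))

    # 9. report
    samples.to_csv(report_path, index_label="sample_id")
    log.stage("report", n_samples=len(samples), n_failures=len(failures))

    report = DeficiencyReport(samples=samples, failures=failures, tukey=tukey,
                              band_peaks=peaks, classmap=classmap, model=model,
                              diagnostics=diagnostics)
    if config.plots:
        from . import plots
        plots.write_all(report, elements, out, pca_model, km)
        log.stage("plots")
    return report


def demo(seed: int = 1, out: str | Path = "chlorosom-demo",
         n_per_group: int = 20, plots: bool = True,
         force: bool = False) -> DeficiencyReport:
    """Generate a default synthetic cohort, run the pipeline, write QC plots."""
    out = Path(out)
    cohort = sample_cohort(n_per_group=n_per_group, seed=seed)
    paths = write_cohort(cohort, out / "cohort")
    config = PipelineConfig(
        transients=str(paths["transients"]),
        elements=str(paths["elements"]),
        out=str(out / "results"),
        seed=seed,
        plots=plots,
        force=force,
    )
    report = run_pipeline(config)
    truth = cohort.labels.reindex(report.samples.index)
    agreement = float((report.samples["class"] == truth).mean())
    (out / "results" / "demo_summary.json").write_text(json.dumps({
        "seed": seed,
        "n_samples": int(len(report.samples)),
        "label_agreement": round(agreement, 4),
        "classes": sorted(report.samples["class"].unique().tolist()),
    }, indent=1))
    return report
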