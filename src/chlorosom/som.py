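"""Multilayer (super-organising) self-organising map for nutrient phenotyping.

A super-organising map shares one grid of neurons across several data
layers — here leaf element content (LEC), JIP-test parameters (ChlF) and a
one-hot class layer — each with its own codebook and a configurable layer
weight.  The best-matching unit (BMU) of a sample is the unit minimising
the weighted sum of per-layer squared Euclidean distances, each layer
normalised by its mean pairwise training distance so that no layer
dominates merely by dimensionality or scale.

Training is classic online Kohonen learning: every presented sample pulls
every unit's codebook (in every layer) toward it by alpha(t) * h(u, BMU, t),
with a Gaussian neighbourhood h on the hexagonal grid whose radius shrinks
during training.  Because the grid is two-dimensional, similar samples land
on nearby neurons, which makes the trained map directly plottable as per-
feature heat layers.

After training, the codebooks are clustered (hierarchical k-means) into
nutrient-deficiency classes, and new samples can be classified from their
ChlF layer alone — the practical goal: diagnosing nutrient status from a
non-invasive fluorescence measurement.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .multivariate import HKMeans

__all__ = [
    "SomGrid",
    "LayerSpec",
    "SuperSOM",
    "DeficiencyClassMap",
    "DEFICIENCY_CLASSES",
    "classify_units",
    "predict_deficiency",
    "som_diagnostics",
]

#: Canonical class names, from least to most severe, plus the Fe-specific one.
DEFICIENCY_CLASSES = (
    "no deficiency",
    "slight deficiency",
    "moderate deficiency",
    "strong deficiency",
    "Fe-specific deficiency",
)


@dataclass(frozen=True)
class SomGrid:
    """Hexagonal unit grid, default 9 columns x 4 rows = 36 units.

    Units are indexed row-major; unit names follow the column-digit /
    row-letter scheme ("1A" ... "9D").  Odd rows are offset by half a unit,
    so each unit's six neighbours all lie at planar distance 1.
    """

    n_rows: int = 4
    n_cols: int = 9

    @property
    def n_units(self) -> int:
        return self.n_rows * self.n_cols

    def coordinates(self) -> np.ndarray:
        coords = np.empty((self.n_units, 2))
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                coords[r * self.n_cols + c] = (c + 0.5 * (r % 2),
                                               r * np.sqrt(3) / 2)
        return coords

    def distances(self) -> np.ndarray:
        xy = self.coordinates()
        return np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))

    def unit_names(self) -> list[str]:
        letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        return [f"{c + 1}{letters[r]}"
                for r in range(self.n_rows) for c in range(self.n_cols)]

    @property
    def diameter(self) -> float:
        return float(self.distances().max())


@dataclass
class LayerSpec:
    """One data layer: feature names, weight and frozen z-score scaling."""

    name: str
    feature_names: list[str]
    weight: float = 1.0
    categorical: bool = False
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        # weight 0 is allowed and removes the layer from the BMU metric
        if self.weight < 0:
            raise ValueError(f"layer {self.name!r}: weight must be >= 0")


class SuperSOM(BaseEstimator):
    """Multilayer Kohonen map with weighted best-matching-unit search.

    Parameters
    ----------
    n_rows, n_cols : grid shape (default 4 x 9 = 36 hexagonal units).
    layer_weights : mapping layer name -> positive weight.  Unlisted layers
        get weight 1.  The conventional class layer weight is 0.5.
    categorical_layers : layer names that are one-hot encoded and therefore
        not z-scored (default: ("class",)).
    epochs : full passes over the data (default 100).
    alpha : (start, end) learning rate, decayed linearly per presented
        sample (default (0.05, 0.01)).
    radius : (start, end) Gaussian neighbourhood radius in grid-plane
        units; default (2/3 of the grid diameter, 1), linear decay.
    seed : seed for codebook initialisation and per-epoch shuffling.

    Fitted attributes
    -----------------
    grid_ : :class:`SomGrid`
    layers_ : list of :class:`LayerSpec` (with frozen scaling)
    codebooks_ : dict layer name -> (n_units, n_features) array (scaled space)
    norms_ : dict layer name -> mean pairwise squared training distance
    qe_init_, qe_ : quantization error at initialisation / after training
    """

    def __init__(self, n_rows=4, n_cols=9, layer_weights=None,
                 categorical_layers=("class",), epochs=100,
                 alpha=(0.05, 0.01), radius=None, seed=1):
        self.n_rows = n_rows
        self.n_cols = n_cols
        self.layer_weights = layer_weights
        self.categorical_layers = categorical_layers
        self.epochs = epochs
        self.alpha = alpha
        self.radius = radius
        self.seed = seed

    # -- data preparation --------------------------------------------------
    def _prepare(self, data: Mapping[str, pd.DataFrame]):
        if not data:
            raise ValueError("need at least one data layer")
        weights = dict(self.layer_weights or {})
        layers: list[LayerSpec] = []
        arrays: dict[str, np.ndarray] = {}
        n = None
        for name, table in data.items():
            if isinstance(table, pd.DataFrame):
                features = list(table.columns)
                values = table.to_numpy(dtype=float)
            else:
                values = np.asarray(table, dtype=float)
                features = [f"{name}_{j}" for j in range(values.shape[1])]
            if n is None:
                n = values.shape[0]
            elif values.shape[0] != n:
                raise ValueError(f"layer {name!r}: rows not aligned across layers")
            if np.any(~np.isfinite(values)):
                i, j = np.argwhere(~np.isfinite(values))[0]
                raise ValueError(
                    f"layer {name!r}: non-finite value for sample {i}, "
                    f"feature {features[j]!r}"
                )
            spec = LayerSpec(name=name, feature_names=features,
                             weight=float(weights.get(name, 1.0)),
                             categorical=name in self.categorical_layers)
            if spec.categorical:
                spec.mean = np.zeros(values.shape[1])
                spec.sd = np.ones(values.shape[1])
            else:
                spec.mean = values.mean(axis=0)
                sd = values.std(axis=0, ddof=1)
                sd[sd == 0] = 1.0
                spec.sd = sd
            arrays[name] = (values - spec.mean) / spec.sd
            layers.append(spec)
        return layers, arrays, n

    def _scale_layer(self, spec: LayerSpec, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - spec.mean) / spec.sd

    # -- fitting -----------------------------------------------------------
    def fit(self, data: Mapping[str, pd.DataFrame], y=None):
        """Initialise and train the map on row-aligned layer tables."""
        layers, arrays, n = self._prepare(data)
        rng = np.random.default_rng(self.seed)
        grid = SomGrid(self.n_rows, self.n_cols)
        n_units = grid.n_units

        codebooks: dict[str, np.ndarray] = {}
        if n >= n_units:
            idx = rng.choice(n, size=n_units, replace=False)
            for spec in layers:
                codebooks[spec.name] = arrays[spec.name][idx].copy()
        else:
            warnings.warn(
                f"only {n} samples for {n_units} units; "
                "initialising codebooks uniformly within feature ranges"
            )
            for spec in layers:
                a = arrays[spec.name]
                lo, hi = a.min(axis=0), a.max(axis=0)
                codebooks[spec.name] = rng.uniform(lo, hi, size=(n_units, a.shape[1]))

        norms: dict[str, float] = {}
        for spec in layers:
            a = arrays[spec.name]
            # mean pairwise squared Euclidean distance = 2 * sum of per-
            # feature population variances * n/(n-1)... computed directly.
            sq = (a**2).sum(axis=1)
            m = (sq[:, None] + sq[None, :] - 2 * a @ a.T)
            norms[spec.name] = float(m.sum() / (n * (n - 1))) if n > 1 else 1.0
            if norms[spec.name] <= 0:
                norms[spec.name] = 1.0

        self.grid_ = grid
        self.layers_ = layers
        self.codebooks_ = codebooks
        self.norms_ = norms
        self._grid_d = grid.distances()
        self.qe_init_ = self._quantization_error(arrays)

        alpha0, alpha1 = self.alpha
        if self.radius is None:
            r0, r1 = grid.diameter * 2.0 / 3.0, 1.0
        else:
            r0, r1 = self.radius
        total = max(self.epochs * n, 1)
        step = 0
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for i in order:
                frac = step / total
                a_t = alpha0 + (alpha1 - alpha0) * frac
                r_t = max(r0 + (r1 - r0) * frac, 1e-9)
                self._update_step({s.name: arrays[s.name][i] for s in layers},
                                  a_t, r_t)
                step += 1
        self.qe_ = self._quantization_error(arrays)
        return self

    def _update_step(self, sample: Mapping[str, np.ndarray],
                     alpha: float, radius: float) -> int:
        """One online Kohonen update: units within ``radius`` of the BMU (in
        the grid plane) move toward the (scaled) sample by alpha * h(unit,
        BMU), with a truncated Gaussian h of scale radius/2, so that the
        final training phase (radius 1) updates little beyond the BMU and
        the map sharpens instead of smoothing out.  Returns the BMU index."""
        bmu_idx, _ = self._bmu_scaled(sample)
        d = self._grid_d[bmu_idx]
        sigma = radius / 2.0
        h = np.where(d <= radius, np.exp(-(d**2) / (2.0 * sigma**2)), 0.0)
        for name, x in sample.items():
            cb = self.codebooks_[name]
            cb += (alpha * h)[:, None] * (x - cb)
        return bmu_idx

    # -- BMU search --------------------------------------------------------
    def _bmu_scaled(self, sample: Mapping[str, np.ndarray],
                    layers_used: Sequence[str] | None = None):
        """BMU for an already-scaled sample; returns (index, distance)."""
        names = list(sample) if layers_used is None else list(layers_used)
        total = np.zeros(self.grid_.n_units)
        specs = {s.name: s for s in self.layers_}
        for name in names:
            spec = specs[name]
            if spec.weight == 0:
                continue
            diff = self.codebooks_[name] - sample[name][None, :]
            total += (spec.weight / self.norms_[name]) * (diff**2).sum(axis=1)
        i = int(np.argmin(total))  # ties resolve to the lowest unit index
        return i, float(total[i])

    def bmu(self, sample: Mapping[str, np.ndarray],
            layers_used: Sequence[str] | None = None):
        """Best-matching unit of one raw (unscaled) sample.

        ``sample`` maps layer name -> 1-D feature vector; ``layers_used``
        restricts the search to those layers (e.g. ``["ChlF"]`` for
        fluorescence-only classification).
        """
        specs = {s.name: s for s in self.layers_}
        names = list(sample) if layers_used is None else list(layers_used)
        scaled = {}
        for name in names:
            if name not in specs:
                raise KeyError(f"unknown layer {name!r}")
            v = np.asarray(sample[name], dtype=float)
            if v.shape != (len(specs[name].feature_names),):
                raise ValueError(
                    f"layer {name!r}: expected {len(specs[name].feature_names)} "
                    f"features, got {v.shape}")
            if np.any(~np.isfinite(v)):
                raise ValueError(f"layer {name!r}: missing value in sample")
            scaled[name] = self._scale_layer(specs[name], v)
        return self._bmu_scaled(scaled, names)

    def predict(self, data: Mapping[str, pd.DataFrame],
                layers_used: Sequence[str] | None = None) -> np.ndarray:
        """BMU indices for row-aligned layer tables."""
        names = list(data) if layers_used is None else list(layers_used)
        tables = {k: (v.to_numpy(dtype=float) if isinstance(v, pd.DataFrame)
                      else np.asarray(v, float)) for k, v in data.items()}
        n = next(iter(tables.values())).shape[0]
        out = np.empty(n, dtype=int)
        for i in range(n):
            out[i], _ = self.bmu({k: tables[k][i] for k in names}, names)
        return out

    def _quantization_error(self, arrays: Mapping[str, np.ndarray]) -> float:
        n = next(iter(arrays.values())).shape[0]
        total = 0.0
        for i in range(n):
            _, d = self._bmu_scaled({k: arrays[k][i] for k in arrays})
            total += np.sqrt(d)
        return total / n

    # -- persistence -------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        """Serialise grid, layer specs, codebooks and schedule as JSON."""
        payload = {
            "n_rows": self.n_rows, "n_cols": self.n_cols,
            "epochs": self.epochs, "alpha": list(self.alpha),
            "radius": None if self.radius is None else list(self.radius),
            "seed": self.seed,
            "layers": [
                {"name": s.name, "feature_names": s.feature_names,
                 "weight": s.weight, "categorical": s.categorical,
                 "mean": s.mean.tolist(), "sd": s.sd.tolist()}
                for s in self.layers_
            ],
            "norms": self.norms_,
            "codebooks": {k: v.tolist() for k, v in self.codebooks_.items()},
            "qe_init": self.qe_init_, "qe": self.qe_,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SuperSOM":
        payload = json.loads(Path(path).read_text())
        model = cls(n_rows=payload["n_rows"], n_cols=payload["n_cols"],
                    epochs=payload["epochs"], alpha=tuple(payload["alpha"]),
                    radius=None if payload["radius"] is None else tuple(payload["radius"]),
                    seed=payload["seed"])
        model.grid_ = SomGrid(payload["n_rows"], payload["n_cols"])
        model._grid_d = model.grid_.distances()
        model.layers_ = [
            LayerSpec(name=s["name"], feature_names=s["feature_names"],
                      weight=s["weight"], categorical=s["categorical"],
                      mean=np.asarray(s["mean"]), sd=np.asarray(s["sd"]))
            for s in payload["layers"]
        ]
        model.norms_ = dict(payload["norms"])
        model.codebooks_ = {k: np.asarray(v) for k, v in payload["codebooks"].items()}
        model.qe_init_ = payload["qe_init"]
        model.qe_ = payload["qe"]
        return model

    def codebook_raw(self, layer: str) -> pd.DataFrame:
        """Codebook of one layer in original (unscaled) feature units."""
        spec = {s.name: s for s in self.layers_}[layer]
        values = self.codebooks_[layer] * spec.sd + spec.mean
        return pd.DataFrame(values, columns=spec.feature_names,
                            index=self.grid_.unit_names())


@dataclass
class DeficiencyClassMap:
    """Class labels of SOM units, and of samples via their BMU."""

    unit_labels: list[str]
    class_names: list[str]
    cluster_ids: np.ndarray  # 1..k per unit

    def sample_label(self, model: SuperSOM, sample: Mapping[str, np.ndarray],
                     layers_used: Sequence[str] | None = None) -> tuple[str, int, float]:
        i, d = model.bmu(sample, layers_used)
        return self.unit_labels[i], i, d


def _name_clusters(model: SuperSOM, cluster_ids: np.ndarray, k: int,
                   element_layer: str, chlf_layer: str) -> list[str]:
    """Name codebook clusters by severity (PI_total) and the Fe rule.

    The Fe-specific class is the nutrient-rich cluster (above-average N and
    K) whose Fe content is lowest relative to that richness; the remaining
    clusters are named no/slight/moderate/strong in descending order of
    mean PI_total.
    """
    chlf = model.codebook_raw(chlf_layer)
    pi_col = "PI_total" if "PI_total" in chlf.columns else chlf.columns[0]
    pi_means = {c: chlf.loc[cluster_ids == c, pi_col].mean()
                for c in range(1, k + 1)}
    names: dict[int, str] = {}
    clusters = list(range(1, k + 1))

    if k == 5 and element_layer in model.codebooks_:
        lec = model.codebook_raw(element_layer)
        cmeans = pd.DataFrame({c: lec.loc[cluster_ids == c].mean()
                               for c in clusters}).T
        if {"N", "K", "Fe"} <= set(cmeans.columns):
            # z-scores of the cluster means, per element: the Fe-specific
            # cluster is rich in N and K but poor in Fe *relative to* that
            # richness
            z = (cmeans - cmeans.mean()) / cmeans.std(ddof=0).replace(0, 1)
            richness = (z["N"] + z["K"]) / 2.0
            score = richness - z["Fe"]
            rich = [c for c in clusters if richness[c] > 0]
            pool = rich if rich else clusters
            fe_cluster = max(pool, key=lambda c: score[c])
            names[fe_cluster] = "Fe-specific deficiency"

    remaining = sorted([c for c in clusters if c not in names],
                       key=lambda c: -pi_means[c])
    severity_names = ["no deficiency", "slight deficiency",
                      "moderate deficiency", "strong deficiency"]
    for i, c in enumerate(remaining):
        names[c] = severity_names[i] if i < len(severity_names) else f"class-{i + 1}"
    return [names[c] for c in cluster_ids]


def classify_units(model: SuperSOM, k: int = 5, seed: int = 1,
                   element_layer: str = "LEC",
                   chlf_layer: str = "ChlF") -> DeficiencyClassMap:
    """Cluster the trained codebooks into k deficiency classes.

    Hierarchical k-means runs on the concatenation of the per-layer
    codebooks, each layer scaled by sqrt(weight / norm) — the same metric
    the BMU search uses.  With k=5 the clusters are named via PI_total
    ordering and the Fe rule; otherwise they are named by PI_total order.
    """
    if k > model.grid_.n_units:
        raise ValueError(f"k={k} exceeds the number of units ({model.grid_.n_units})")
    blocks = []
    for spec in model.layers_:
        w = np.sqrt(spec.weight / model.norms_[spec.name])
        blocks.append(model.codebooks_[spec.name] * w)
    X = np.hstack(blocks)
    km = HKMeans(k=k, seed=seed).fit(X)
    unit_labels = _name_clusters(model, km.labels_, k, element_layer, chlf_layer)
    return DeficiencyClassMap(
        unit_labels=unit_labels,
        class_names=list(dict.fromkeys(unit_labels)),
        cluster_ids=km.labels_,
    )


def predict_deficiency(model: SuperSOM, classmap: DeficiencyClassMap,
                       chlf_sample, chlf_layer: str = "ChlF") -> tuple[str, int, float]:
    """Classify a sample from its ChlF features alone.

    Returns (class label, BMU index, BMU distance).  The class layer is
    never consulted at prediction time.
    """
    sample = np.asarray(chlf_sample, dtype=float)
    label, bmu_idx, d = classmap.sample_label(model, {chlf_layer: sample},
                                              [chlf_layer])
    return label, bmu_idx, d


def som_diagnostics(model: SuperSOM, data: Mapping[str, pd.DataFrame]) -> dict[str, float]:
    """Quantization error and topographic error on a dataset.

    Quantization error is the mean BMU distance (square root of the
    weighted squared distance).  Topographic error is the fraction of
    samples whose first and second BMUs are not grid-adjacent.
    """
    tables = {k: (v.to_numpy(dtype=float) if isinstance(v, pd.DataFrame)
                  else np.asarray(v, float)) for k, v in data.items()}
    specs = {s.name: s for s in model.layers_}
    n = next(iter(tables.values())).shape[0]
    gd = model.grid_.distances()
    qe = 0.0
    te = 0
    for i in range(n):
        total = np.zeros(model.grid_.n_units)
        for name, arr in tables.items():
            spec = specs[name]
            x = model._scale_layer(spec, arr[i])
            diff = model.codebooks_[name] - x[None, :]
            total += (spec.weight / model.norms_[name]) * (diff**2).sum(axis=1)
        order = np.argsort(total, kind="stable")
        first, second = int(order[0]), int(order[1])
        qe += np.sqrt(total[first])
        if gd[first, second] > 1.1:  # hex neighbours sit at distance 1
            te += 1
    return {"quantization_error": qe / n, "topographic_error": te / n}
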