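"""Multilayer self-organising map: grid, BMU search, training, classing."""

import numpy as np
import pandas as pd
import pytest

from chlorosom.som import (
    DeficiencyClassMap,
    SomGrid,
    SuperSOM,
    classify_units,
    predict_deficiency,
    som_diagnostics,
)


def _brute_force_bmu(model, sample, layers):
    """Independent loop-based BMU: weighted, normalised squared distances."""
    specs = {s.name: s for s in model.layers_}
    best, best_d = None, np.inf
    for u in range(model.grid_.n_units):
        d = 0.0
        for name in layers:
            spec = specs[name]
            x = (np.asarray(sample[name]) - spec.mean) / spec.sd
            if spec.weight == 0:
                continue
            d += spec.weight / model.norms_[name] * float(
                ((model.codebooks_[name][u] - x) ** 2).sum())
        if d < best_d:
            best, best_d = u, d
    return best, best_d


class TestSomGrid:
    def test_default_grid_is_9_by_4_hexagonal(self):
        grid = SomGrid()
        assert grid.n_units == 36
        names = grid.unit_names()
        assert names[0] == "1A" and names[8] == "9A" and names[-1] == "9D"
        d = grid.distances()
        assert np.allclose(d, d.T)
        # every interior unit's six hexagonal neighbours sit at distance 1
        interior = 1 * 9 + 4  # row B, column 5
        assert np.sum(np.isclose(d[interior], 1.0)) == 6


def _layers(rng, n=40, f1=5, f2=3):
    return {
        "L1": pd.DataFrame(rng.standard_normal((n, f1)),
                           columns=[f"a{j}" for j in range(f1)]),
        "L2": pd.DataFrame(rng.standard_normal((n, f2)),
                           columns=[f"b{j}" for j in range(f2)]),
    }


class TestInitialisation:
    def test_seeded_init_is_deterministic(self, rng):
        data = _layers(rng)
        m1 = SuperSOM(epochs=0, seed=5).fit(data)
        m2 = SuperSOM(epochs=0, seed=5).fit(data)
        for k in m1.codebooks_:
            assert np.array_equal(m1.codebooks_[k], m2.codebooks_[k])

    def test_codebooks_are_sampled_training_rows(self, rng):
        data = {"L": pd.DataFrame(rng.standard_normal((36, 4)))}
        m = SuperSOM(epochs=0, seed=1).fit(data)
        scaled = (data["L"].to_numpy() - m.layers_[0].mean) / m.layers_[0].sd
        cb = m.codebooks_["L"]
        # rows are a permutation of the (scaled) samples
        assert sorted(map(tuple, np.round(cb, 9))) == sorted(
            map(tuple, np.round(scaled, 9)))

    def test_layers_share_unit_ordering(self, rng):
        data = _layers(rng, n=50)
        m = SuperSOM(epochs=0, seed=2).fit(data)
        s1 = (data["L1"].to_numpy() - m.layers_[0].mean) / m.layers_[0].sd
        s2 = (data["L2"].to_numpy() - m.layers_[1].mean) / m.layers_[1].sd
        # for each unit, the row index chosen in L1 matches the one in L2
        for u in range(36):
            i1 = int(np.argmin(((s1 - m.codebooks_["L1"][u]) ** 2).sum(1)))
            i2 = int(np.argmin(((s2 - m.codebooks_["L2"][u]) ** 2).sum(1)))
            assert i1 == i2

    def test_fewer_samples_than_units_warns(self, rng):
        data = {"L": pd.DataFrame(rng.standard_normal((10, 3)))}
        with pytest.warns(UserWarning, match="initialising codebooks"):
            SuperSOM(epochs=0, seed=1).fit(data)


class TestBMU:
    def test_exact_codebook_match_has_zero_distance(self, rng):
        data = _layers(rng)
        m = SuperSOM(epochs=0, seed=3).fit(data)
        raw = {s.name: m.codebooks_[s.name][7] * s.sd + s.mean
               for s in m.layers_}
        idx, d = m.bmu(raw)
        assert idx == 7
        assert d == pytest.approx(0.0, abs=1e-18)

    def test_bmu_matches_brute_force_on_random_queries(self, rng):
        data = _layers(rng)
        m = SuperSOM(epochs=10, seed=3).fit(data)
        for _ in range(100):
            q = {"L1": rng.standard_normal(5), "L2": rng.standard_normal(3)}
            idx, d = m.bmu(q)
            oidx, od = _brute_force_bmu(m, q, ["L1", "L2"])
            assert idx == oidx
            assert d == pytest.approx(od, rel=1e-12)

    def test_zero_weight_layer_is_eliminated(self, rng):
        data = _layers(rng)
        mw = SuperSOM(epochs=0, seed=4, layer_weights={"L2": 0.0}).fit(data)
        m1 = SuperSOM(epochs=0, seed=4).fit(data)
        for _ in range(20):
            q = {"L1": rng.standard_normal(5), "L2": rng.standard_normal(3)}
            assert mw.bmu(q)[0] == m1.bmu(q, layers_used=["L1"])[0]

    def test_missing_values_rejected(self, rng):
        m = SuperSOM(epochs=0, seed=1).fit(_layers(rng))
        with pytest.raises(ValueError, match="missing"):
            m.bmu({"L1": np.array([np.nan] * 5), "L2": np.zeros(3)})


class TestTraining:
    def test_zero_epochs_leaves_codebooks_at_initialisation(self, rng):
        data = _layers(rng)
        m0 = SuperSOM(epochs=0, seed=6).fit(data)
        # qe after "training" equals qe at initialisation: nothing moved
        assert m0.qe_ == pytest.approx(m0.qe_init_)

    def test_quantization_error_does_not_increase_at_cohort_scale(self):
        """With many more samples than units (the study's regime), training
        lowers the quantization error below its sampled-row initialisation."""
        from chlorosom.synthetic import sample_cohort

        c = sample_cohort(60, seed=4, with_transients=False)
        layers = {"LEC": c.elements,
                  "ChlF": c.jip_targets[["F_o", "M_o", "PI_total", "delta_Ro",
                                         "phi_Po", "phi_Ro", "phi_Eo",
                                         "gamma_RC"]]}
        m = SuperSOM(epochs=100, seed=4).fit(layers)
        assert m.qe_ <= m.qe_init_

    def test_training_improves_on_uniform_random_codebooks(self, rng):
        data = {"L": pd.DataFrame(rng.standard_normal((20, 4)))}
        with pytest.warns(UserWarning):
            untrained = SuperSOM(epochs=0, seed=6).fit(data)
        with pytest.warns(UserWarning):
            trained = SuperSOM(epochs=50, seed=6).fit(data)
        assert trained.qe_ <= untrained.qe_

    def test_single_sample_fixed_point(self, rng):
        data = {"L": pd.DataFrame([[1.0, -2.0, 0.5]], columns=list("abc"))}
        with pytest.warns(UserWarning):
            m = SuperSOM(n_rows=1, n_cols=2, epochs=400, seed=1,
                         radius=(0.1, 1e-6), categorical_layers=("L",)).fit(data)
        idx, _ = m.bmu({"L": np.array([1.0, -2.0, 0.5])})
        assert np.allclose(m.codebooks_["L"][idx], [1.0, -2.0, 0.5], atol=1e-3)

    def test_single_update_step_matches_hand_arithmetic(self, rng):
        """Toy 2-unit, 1-D map; alpha=0.5, neighbourhood (1, 0.5)."""
        data = {"L": pd.DataFrame({"x": [0.0, 4.0]})}
        m = SuperSOM(n_rows=1, n_cols=2, epochs=0, seed=0,
                     categorical_layers=("L",)).fit(data)
        m.codebooks_["L"] = np.array([[0.0], [4.0]])
        # units sit at planar distance 1; with h = exp(-d^2/(2 (r/2)^2)),
        # h(1) = 0.5 requires r = sqrt(2/ln 2)
        radius = float(np.sqrt(2.0 / np.log(2.0)))
        bmu = m._update_step({"L": np.array([1.0])}, alpha=0.5, radius=radius)
        assert bmu == 0
        # BMU moves by 0.5*(1-0): 0 -> 0.5; neighbour by 0.5*0.5*(1-4): 4 -> 3.25
        assert m.codebooks_["L"][0, 0] == pytest.approx(0.5)
        assert m.codebooks_["L"][1, 0] == pytest.approx(3.25)

    def test_training_is_deterministic_given_seed(self, rng):
        data = _layers(rng, n=45)
        m1 = SuperSOM(epochs=20, seed=9).fit(data)
        m2 = SuperSOM(epochs=20, seed=9).fit(data)
        for k in m1.codebooks_:
            assert np.array_equal(m1.codebooks_[k], m2.codebooks_[k])

    def test_non_finite_input_names_the_layer(self, rng):
        data = _layers(rng)
        data["L1"].iloc[3, 2] = np.inf
        with pytest.raises(ValueError, match="L1"):
            SuperSOM(epochs=1, seed=1).fit(data)


class TestClassification:
    def _blob_model(self, rng):
        """Codebooks hand-set as 5 separated blobs after a trivial fit."""
        n = 40
        data = {
            "LEC": pd.DataFrame(rng.standard_normal((n, 3)),
                                columns=["N", "K", "Fe"]),
            "ChlF": pd.DataFrame(rng.standard_normal((n, 2)),
                                 columns=["PI_total", "phi_Po"]),
        }
        m = SuperSOM(epochs=0, seed=2).fit(data)
        blob = np.repeat(np.arange(5), 8)[:36]
        rng.shuffle(blob)
        # blob 0: rich in everything; blob 1: rich in N/K but relatively
        # poor in Fe (the Fe-specific signature); blobs 2-4: increasingly
        # deficient overall
        m.codebooks_["LEC"] = (np.array([[5, 5, 3], [4.5, 4.5, 0.5],
                                         [2, 2, -0.5], [0, 0, -1.5],
                                         [-2, -2, -2]])[blob]
                               + 0.01 * rng.standard_normal((36, 3)))
        m.codebooks_["ChlF"] = (np.array([[5.0, 2], [4, 1.8], [2, 1],
                                          [0, 0], [-2, -1]])[blob]
                                + 0.01 * rng.standard_normal((36, 2)))
        return m, blob

    def test_separated_blobs_recovered_and_named_by_severity(self, rng):
        m, blob = self._blob_model(rng)
        cm = classify_units(m, k=5, seed=1)
        # one class per blob
        for b in range(5):
            labels = {cm.unit_labels[u] for u in np.where(blob == b)[0]}
            assert len(labels) == 1
        # blob 1 (high N/K, lowest Fe among the nutrient-rich) is Fe-specific;
        # the rest are named in descending PI_total order
        assert cm.unit_labels[int(np.where(blob == 1)[0][0])] == "Fe-specific deficiency"
        assert cm.unit_labels[int(np.where(blob == 0)[0][0])] == "no deficiency"
        assert cm.unit_labels[int(np.where(blob == 4)[0][0])] == "strong deficiency"

    def test_k_one_gives_single_class(self, rng):
        m, _ = self._blob_model(rng)
        cm = classify_units(m, k=1, seed=1)
        assert len(set(cm.unit_labels)) == 1

    def test_k_above_unit_count_is_an_error(self, rng):
        m, _ = self._blob_model(rng)
        with pytest.raises(ValueError):
            classify_units(m, k=37)

    def test_prediction_of_exact_chlf_codebook(self, rng):
        m, _ = self._blob_model(rng)
        cm = classify_units(m, k=5, seed=1)
        spec = {s.name: s for s in m.layers_}["ChlF"]
        raw = m.codebooks_["ChlF"][11] * spec.sd + spec.mean
        label, bmu, d = predict_deficiency(m, cm, raw)
        assert bmu == 11
        assert label == cm.unit_labels[11]
        assert d == pytest.approx(0.0, abs=1e-18)

    def test_missing_chlf_feature_is_an_error(self, rng):
        m, _ = self._blob_model(rng)
        cm = classify_units(m, k=5, seed=1)
        with pytest.raises(ValueError):
            predict_deficiency(m, cm, np.array([1.0]))  # wrong length


class TestDiagnostics:
    def test_codebook_data_has_zero_quantization_error(self, rng):
        data = _layers(rng)
        m = SuperSOM(epochs=5, seed=8).fit(data)
        raw = {s.name: m.codebooks_[s.name] * s.sd + s.mean for s in m.layers_}
        diag = som_diagnostics(m, raw)
        assert diag["quantization_error"] == pytest.approx(0.0, abs=1e-12)

    def test_topographic_error_on_hand_built_line_map(self, rng):
        data = {"L": pd.DataFrame({"x": [0.0, 1.0, 10.0]})}
        m = SuperSOM(n_rows=1, n_cols=3, epochs=0, seed=0,
                     categorical_layers=("L",)).fit(data)
        m.codebooks_["L"] = np.array([[0.0], [10.0], [1.0]])
        # x=0.4: nearest units 0 and 2, which are two grid steps apart
        # x=9.0: nearest units 1 and 2, adjacent
        diag = som_diagnostics(m, {"L": pd.DataFrame({"x": [0.4, 9.0]})})
        assert diag["topographic_error"] == pytest.approx(0.5)


class TestPersistence:
    def test_json_round_trip_preserves_predictions(self, tmp_path, rng):
        data = _layers(rng)
        m = SuperSOM(epochs=10, seed=11).fit(data)
        m.to_json(tmp_path / "som.json")
        back = SuperSOM.from_json(tmp_path / "som.json")
        q = {"L1": rng.standard_normal(5), "L2": rng.standard_normal(3)}
        assert back.bmu(q) == m.bmu(q)
        for k in m.codebooks_:
            assert np.allclose(back.codebooks_[k], m.codebooks_[k])
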