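"""Savitzky-Golay preprocessing, SRI registry, VIF and stepwise selection."""

import numpy as np
import pandas as pd
import pytest

from cyanophen import spectra as sp
from cyanophen.syndata import SpectraMatrix


def _spec(values, wl):
    values = np.atleast_2d(values)
    return SpectraMatrix([f"i{k}" for k in range(values.shape[0])],
                         np.asarray(values, float), np.asarray(wl, float))


class TestPreprocess:
    def test_linear_spectrum_constant_derivative(self):
        wl = np.arange(400, 700, 2.0)
        y = 0.001 * wl + 0.05
        out = sp.preprocess(_spec(y, wl), window=11, polyorder=2, derivative=1,
                            center=False, scale=False)
        assert np.allclose(out.values, 0.001, atol=1e-12)

    def test_cubic_matches_analytic_derivative(self):
        wl = np.arange(400.0, 900.0, 1.0)
        a, b, c, d = 2e-9, -1e-6, 3e-4, 0.1
        y = a * wl ** 3 + b * wl ** 2 + c * wl + d
        out = sp.preprocess(_spec(y, wl), window=37, polyorder=3, derivative=1,
                            center=False, scale=False)
        analytic = 3 * a * out.wavelengths ** 2 + 2 * b * out.wavelengths + c
        assert np.max(np.abs(out.values[0] - analytic)) < 1e-8

    def test_constant_spectrum_zero_derivative(self):
        wl = np.arange(400, 600, 1.0)
        out = sp.preprocess(_spec(np.full(wl.size, 0.3), wl), window=37,
                            center=False, scale=False)
        assert np.allclose(out.values, 0.0, atol=1e-12)

    def test_normalized_bands_centered_scaled(self, small_population):
        _, _, spectra, _, _ = small_population
        X = spectra.values - spectra.values.mean(axis=0)
        X /= X.std(axis=0)
        assert np.allclose(X.mean(axis=0), 0, atol=1e-8)
        assert np.allclose(X.std(axis=0), 1, atol=1e-8)
        out = sp.preprocess(spectra)
        # edge loss: w' = w - (window - 1)
        assert out.values.shape[1] == spectra.values.shape[1] - 36

    def test_interpolation_limit_reproduces_input(self):
        rng = np.random.default_rng(1)
        wl = np.arange(0, 21, 1.0)
        y = rng.random(wl.size)
        out = sp.preprocess(_spec(y, wl), window=5, polyorder=4, derivative=0,
                            center=False, scale=False)
        assert np.allclose(out.values[0], y[2:-2], atol=1e-10)

    @pytest.mark.parametrize("kwargs", [
        dict(window=36), dict(window=300), dict(window=5, polyorder=5),
        dict(window=5, polyorder=1, derivative=2)])
    def test_invalid_settings_rejected(self, kwargs):
        wl = np.arange(400, 500, 1.0)
        with pytest.raises(ValueError):
            sp.preprocess(_spec(np.ones(wl.size), wl), **kwargs)

    def test_nonuniform_grid_rejected(self):
        wl = np.array([400.0, 401.0, 403.0, 404.0, 405, 406, 407])
        with pytest.raises(ValueError):
            sp.preprocess(_spec(np.ones(7), wl), window=5)


class TestSRIRegistry:
    def test_hand_computed_ratio_indices(self):
        wl = np.arange(400, 801, 1.0)
        r = np.full(wl.size, 0.5)
        r[wl == 605] = 0.20
        r[wl == 455] = 0.10
        r[wl == 550] = 0.10
        r[wl == 700] = 0.20
        out = sp.compute_sri(_spec(r, wl), ["LRDSI1", "ARI"])
        assert out["LRDSI1"].iloc[0] == pytest.approx(12.6, abs=1e-12)
        assert out["ARI"].iloc[0] == pytest.approx(5.0, abs=1e-12)

    def test_npci_zero_when_bands_equal(self):
        wl = np.arange(400, 701, 1.0)
        out = sp.compute_sri(_spec(np.full(wl.size, 0.3), wl), ["NPCI"])
        assert out["NPCI"].iloc[0] == 0.0

    def test_row_order_and_unrelated_band_invariance(self, small_population):
        _, _, spectra, _, _ = small_population
        full = sp.compute_sri(spectra, ["BGI", "GMI1"], interpolate=True)
        rev = spectra.subset(list(reversed(spectra.ids)))
        flipped = sp.compute_sri(rev, ["BGI", "GMI1"], interpolate=True)
        assert np.allclose(full.loc[spectra.ids[0]],
                           flipped.loc[spectra.ids[0]])
        # perturbing an unused band leaves a ratio index unchanged
        pert = spectra.values.copy()
        pert[:, -1] *= 2
        pert_sri = sp.compute_sri(
            SpectraMatrix(spectra.ids, pert, spectra.wavelengths),
            ["BGI"], interpolate=True)
        assert np.allclose(pert_sri["BGI"], full["BGI"])

    def test_missing_band_names_index_and_band(self):
        wl = np.arange(400, 500, 1.0)
        with pytest.raises(ValueError, match="NDLI.*1754"):
            sp.compute_sri(_spec(np.ones(wl.size) / 2, wl), ["NDLI"])

    def test_unknown_index_rejected(self, small_population):
        _, _, spectra, _, _ = small_population
        with pytest.raises(KeyError):
            sp.compute_sri(spectra, ["NOTANINDEX"])

    def test_derivative_indices_positive_on_vegetation_curve(self, small_population):
        _, _, spectra, _, _ = small_population
        out = sp.compute_sri(spectra, ["EGFN", "EGFNR"], interpolate=True)
        # red-edge slope dwarfs the green-edge slope on a vegetation curve
        assert (out["EGFNR"] > 1).mean() > 0.85
        assert np.isfinite(out["EGFN"]).all()
        # normalized difference stays in (-1, 1] whenever both maxima are
        # positive, which holds for the vast majority of vegetation curves
        assert out["EGFN"].between(-1, 1).mean() > 0.9


class TestVIF:
    def test_orthogonal_columns_unit_vif(self):
        # zero-mean, mutually orthogonal columns
        X = pd.DataFrame({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1],
                          "c": [1, -1, -1, 1]}, dtype=float)
        assert np.allclose(sp.vif(X), 1.0)

    def test_correlated_pair_closed_form(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(20000)
        x = 0.9 * z + np.sqrt(1 - 0.81) * rng.standard_normal(20000)
        v = sp.vif(pd.DataFrame({"a": z, "b": x}))
        assert np.allclose(v, 1 / (1 - 0.81), rtol=0.05)

    def test_identical_columns_infinite(self):
        z = np.arange(10.0)
        v = sp.vif(pd.DataFrame({"a": z, "b": z}))
        assert np.isinf(v).all()

    def test_interpretation_bands(self):
        assert sp.vif_class(5) == "none"
        assert sp.vif_class(10) == "strong"
        assert sp.vif_class(100) == "severe"


class TestStepwise:
    def test_null_candidate_selection_matches_aic_rate(self):
        """Under the null, AIC admits a single candidate iff its chi-square
        statistic exceeds 2, i.e. with probability ~0.157; the observed rate
        over 40 draws must be consistent with that."""
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(40):
            y = rng.standard_normal(500)
            x = pd.DataFrame({"idx": rng.standard_normal(500)})
            hits += bool(sp.stepwise_select(x, y).selected)
        assert 1 <= hits <= 14

    def test_duplicated_column_selected_once(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal(300)
        y = 0.5 * z + rng.standard_normal(300)
        X = pd.DataFrame({"a": z, "b": z.copy()})
        rep = sp.stepwise_select(X, y)
        assert len(rep.selected) == 1
        assert np.isinf(sp.vif(X)).all()

    def test_power_to_find_true_trio(self):
        rng = np.random.default_rng(6)
        found = 0
        for _ in range(10):
            X = pd.DataFrame(rng.standard_normal((400, 30)),
                             columns=[f"c{k}" for k in range(30)])
            y = (0.3 * X["c3"] + 0.3 * X["c11"] + 0.3 * X["c25"]
                 + rng.standard_normal(400)).to_numpy()
            rep = sp.stepwise_select(X, y)
            found += {"c3", "c11", "c25"} <= set(rep.selected)
        assert found >= 8

    def test_aic_trajectory_decreases_and_affine_invariance(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((200, 5)), columns=list("abcde"))
        y = (X["a"] - 0.5 * X["d"] + 0.5 * rng.standard_normal(200)).to_numpy()
        rep = sp.stepwise_select(X, y)
        assert all(x > y_ for x, y_ in zip(rep.aic_trajectory,
                                           rep.aic_trajectory[1:]))
        scaled = X * [3.0, 0.1, 7.0, 100.0, 1e-3] + [1, 2, 3, 4, 5]
        rep2 = sp.stepwise_select(scaled, y)
        assert set(rep.selected) == set(rep2.selected)

    def test_constant_column_excluded_with_warning(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame({"flat": np.ones(100),
                          "x": rng.standard_normal(100)})
        y = X["x"].to_numpy() + 0.1 * rng.standard_normal(100)
        with pytest.warns(UserWarning, match="constant"):
            rep = sp.stepwise_select(X, y)
        assert rep.selected == ["x"]
        assert rep.r_squared > 0.9
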