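"""Preprocessing contracts: background subtraction, stabilization,
calibration, and fixed-effects residualization."""

import numpy as np
import pandas as pd
import pytest

from diallelgg import arraydesign, normalize, simdata


def _long_table(values_by_channel, subgrid=0, bg=0.0):
    rows = []
    for (slide, channel), vals in values_by_channel.items():
        for i, v in enumerate(vals):
            rows.append((slide, channel, subgrid, f"g{i}", v + bg, bg))
    return pd.DataFrame(rows, columns=["slide", "channel", "subgrid", "spot",
                                       "foreground", "background"])


class TestBackground:
    def test_subtraction_and_negative_retention(self):
        raw = pd.DataFrame(
            {"slide": ["s"] * 2, "channel": ["Cy3"] * 2, "subgrid": [0, 0],
             "spot": ["a", "b"], "foreground": [100.0, 10.0],
             "background": [30.0, 30.0]})
        out = normalize.subtract_background(raw)
        assert list(out["net"]) == [70.0, -20.0]

    def test_zero_background_is_identity(self):
        raw = _long_table({("s", "Cy3"): [1.0, 2.0, 3.0]})
        out = normalize.subtract_background(raw)
        assert (out["net"] == out["foreground"]).all()

    def test_missing_background_rejected(self):
        raw = _long_table({("s", "Cy3"): [1.0, 2.0]})
        raw.loc[0, "background"] = np.nan
        with pytest.raises(ValueError):
            normalize.subtract_background(raw)


class TestVsn:
    def test_centering_at_channel_median(self):
        raw = _long_table({("s", "Cy3"): [1.0, 2.0, 3.0, 4.0, 5.0]})
        raw["net"] = raw["foreground"]
        out = normalize.vsn_transform(raw)
        assert out.loc[2, "h"] == pytest.approx(0.0)

    def test_strictly_monotone(self):
        vals = np.sort(np.random.default_rng(0).gamma(2.0, 100.0, size=200))
        raw = _long_table({("s", "Cy5"): list(vals)})
        raw["net"] = raw["foreground"]
        out = normalize.vsn_transform(raw)
        assert (np.diff(out["h"]) > 0).all()

    def test_constant_channel_rejected(self):
        raw = _long_table({("s", "Cy3"): [5.0] * 10})
        raw["net"] = raw["foreground"]
        with pytest.raises(ValueError):
            normalize.vsn_transform(raw)

    def test_variance_stabilization_on_mult_plus_add_noise(self):
        # genes with increasing true level under multiplicative (sigma=0.3)
        # plus additive noise: after the transform, the spread-vs-rank slope
        # must collapse versus the raw scale
        rng = np.random.default_rng(1)
        n_genes, n_rep = 150, 40
        mu = np.geomspace(50, 2000, n_genes)
        frames = []
        for r in range(n_rep):
            x = mu * np.exp(rng.normal(0, 0.3, n_genes)) + rng.normal(0, 150, n_genes)
            frames.append(pd.DataFrame(
                {"slide": f"s{r}", "channel": "Cy3", "subgrid": 0,
                 "spot": [f"g{i}" for i in range(n_genes)],
                 "foreground": x, "background": 0.0, "net": x}))
        tab = normalize.vsn_transform(pd.concat(frames, ignore_index=True))
        wide_x = tab.pivot(index="slide", columns="spot", values="net")
        wide_h = tab.pivot(index="slide", columns="spot", values="h")
        order = [f"g{i}" for i in range(n_genes)]
        rank = np.arange(n_genes, dtype=float)

        def slope(spread):
            return np.polyfit(rank, spread / spread.mean(), 1)[0]

        s_raw = slope(wide_x[order].std().to_numpy())
        s_h = slope(wide_h[order].std().to_numpy())
        assert abs(s_h) <= 0.25 * abs(s_raw)


class TestCalibration:
    def test_common_median_and_mad(self):
        rng = np.random.default_rng(2)
        raw = _long_table({("s1", "Cy3"): list(rng.normal(5, 1, 100)),
                           ("s1", "Cy5"): list(rng.normal(0, 3, 100))})
        raw["h"] = raw["foreground"]
        out = normalize.calibrate_across_slides(raw)
        for _key, grp in out.groupby(["slide", "channel"]):
            assert np.median(grp["h"]) == pytest.approx(0.0, abs=1e-9)
            mad = np.median(np.abs(grp["h"] - np.median(grp["h"])))
            assert mad == pytest.approx(1.0, abs=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        raw = _long_table({("s1", "Cy3"): list(rng.normal(0, 1, 50)),
                           ("s2", "Cy5"): list(rng.normal(2, 2, 50))})
        raw["h"] = raw["foreground"]
        once = normalize.calibrate_across_slides(raw)
        twice = normalize.calibrate_across_slides(once)
        assert np.allclose(once["h"], twice["h"], atol=1e-12)


class TestTechnicalModel:
    def _toy(self, rng, n=60, n_genes=5, dye_effect=0.0, block_effects=None):
        dyes = np.array(["Cy3", "Cy5"])[rng.integers(0, 2, n)]
        blocks = np.array(["A", "B", "C"])[rng.integers(0, 3, n)]
        h = rng.normal(0, 1, (n, n_genes))
        h += np.where(dyes == "Cy5", dye_effect / 2, -dye_effect / 2)[:, None]
        if block_effects:
            h += np.array([block_effects[b] for b in blocks])[:, None]
        cov = pd.DataFrame({"dye": dyes, "block": blocks, "batch": "b1",
                            "person": "p1", "family": "f1",
                            "individual": [f"i{k}" for k in range(n)]})
        return pd.DataFrame(h, columns=[f"g{j}" for j in range(n_genes)]), cov

    def test_dye_offset_removed(self):
        h, cov = self._toy(np.random.default_rng(4), dye_effect=0.5)
        resid, _ = normalize.fit_technical_model(h, cov, "eq1")
        resid_obs = h.to_numpy() - (h.to_numpy() - resid.loc[cov["individual"]].to_numpy())
        per_dye = pd.DataFrame(resid.loc[cov["individual"]].to_numpy()).groupby(
            cov["dye"].to_numpy()).mean()
        assert np.allclose(per_dye.to_numpy(), 0.0, atol=1e-9)

    def test_single_level_factors_reduce_to_centering(self):
        rng = np.random.default_rng(5)
        n = 20
        h = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=list("abc"))
        cov = pd.DataFrame({"dye": "Cy3", "block": "A", "batch": "b1",
                            "person": "p1",
                            "individual": [f"i{k}" for k in range(n)]})
        resid, _ = normalize.fit_technical_model(h, cov, "eq1")
        expected = h - h.mean()
        assert np.allclose(resid.loc[cov["individual"]].to_numpy(),
                           expected.to_numpy(), atol=1e-9)

    def test_block_contrasts_recovered_vs_ols_oracle(self):
        import statsmodels.api as sm

        effects = {"A": -1.0, "B": 0.0, "C": 1.0}
        h, cov = self._toy(np.random.default_rng(6), n=120, block_effects=effects)
        _, est = normalize.fit_technical_model(h, cov, "eq1")
        # independent oracle: per-gene OLS with the same coding
        X = pd.get_dummies(cov[["dye", "block"]], drop_first=False)
        design = pd.DataFrame({
            "const": 1.0,
            "block[A]": np.where(cov["block"] == "A", 1.0,
                                 np.where(cov["block"] == "C", -1.0, 0.0)),
            "block[B]": np.where(cov["block"] == "B", 1.0,
                                 np.where(cov["block"] == "C", -1.0, 0.0)),
            "dye[Cy3]": np.where(cov["dye"] == "Cy3", 1.0, -1.0),
        })
        for g in h.columns:
            fit = sm.OLS(h[g].to_numpy(), design.to_numpy()).fit()
            ab = dict(zip(design.columns, fit.params))
            se = dict(zip(design.columns, fit.bse))
            assert est.at["block[A]", g] == pytest.approx(ab["block[A]"], abs=1e-8)
            # recovered contrast close to planted within 3 SE
            assert abs(ab["block[A]"] - (-1.0)) <= 3 * se["block[A]"]

    def test_residuals_orthogonal_to_design(self):
        h, cov = self._toy(np.random.default_rng(7), n=90, dye_effect=0.3,
                           block_effects={"A": -0.5, "B": 0.1, "C": 0.4})
        resid, _ = normalize.fit_technical_model(h, cov, "eq1")
        r = resid.loc[cov["individual"]].to_numpy()
        for col in (np.ones(len(cov)),
                    (cov["dye"] == "Cy5").astype(float).to_numpy(),
                    (cov["block"] == "A").astype(float).to_numpy()):
            dots = np.abs(col @ r) / len(col)
            assert (dots < 1e-8).all()

    def test_residualizing_residuals_is_idempotent(self):
        h, cov = self._toy(np.random.default_rng(8), n=50, dye_effect=0.7)
        resid, _ = normalize.fit_technical_model(h, cov, "eq1")
        again, _ = normalize.fit_technical_model(
            resid.loc[cov["individual"]].reset_index(drop=True), cov, "eq1")
        assert np.allclose(again.to_numpy(), resid.to_numpy(), atol=1e-9)

    def test_confounded_factors_named(self):
        rng = np.random.default_rng(9)
        n = 30
        blocks = np.array(["A", "B"])[rng.integers(0, 2, n)]
        cov = pd.DataFrame({"dye": "Cy3", "block": blocks, "batch": blocks,
                            "person": "p1",
                            "individual": [f"i{k}" for k in range(n)]})
        cov["batch"] = np.where(cov["block"] == "A", "b1", "b2")  # aliased
        h = pd.DataFrame(rng.normal(0, 1, (n, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="aliased"):
            normalize.fit_technical_model(h, cov, "eq1")


class TestRoundTrip:
    def test_residuals_track_latent_genetic_signal(self, diallel_pop):
        # needs a realistic panel width: the per-channel robust calibration
        # estimates each array's location from the spot ensemble, so with
        # very few genes it would subtract common-mode biological signal
        gmap = diallel_pop.gmap
        rng = np.random.default_rng(0)
        parents = sorted(diallel_pop.parents)
        traits = []
        for i in range(150):
            m = gmap.marker_ids[rng.integers(gmap.n_markers)]
            j = gmap.marker_ids.index(m)
            eff = ({p: 1.0 for p in parents if diallel_pop.heterozygous(p)[j]}
                   or {parents[0]: 1.0})
            traits.append(simdata.ExprTrait(f"g{i}",
                                            (simdata.PlantedQtl(m, eff),),
                                            None, 0.1))
        arch = simdata.EqtlArchitecture(tuple(traits), background_sd=0.2)
        plan = arraydesign.build_design(diallel_pop, seed=0, n_restarts=2)
        intens, truth = simdata.simulate_expression(
            diallel_pop, arch, simdata.TechnicalModel(sigma_eps=0.05), plan, seed=3)
        resid, _ = normalize.residualize(intens, "eq1")
        lat = truth["latent"].loc[resid.index]
        cors = [np.corrcoef(resid[g], lat[g])[0, 1] for g in resid.columns]
        assert np.median(cors) >= 0.9
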