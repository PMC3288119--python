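"""Simulator tests: Mendelian structure, Haldane recombination, planted
signals in expression and phenotypes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diallelgg import arraydesign, simdata
from diallelgg.genmap import haldane_r


def _one_cross(gmap, n, het=1.0, seed=0):
    design = simdata.DiallelDesign(
        females=("F",), males=("M",), crosses=(("cx", "F", "M", n),)
    )
    return simdata.simulate_diallel(design, gmap, het_fraction=het, seed=seed)


class TestParents:
    def test_het_fraction_boundaries(self, small_map):
        none = simdata.simulate_parents(small_map, ["P1", "P2"], 0.0, seed=1)
        assert not any(none.heterozygous(p).any() for p in ("P1", "P2"))
        full = simdata.simulate_parents(small_map, ["P1", "P2"], 1.0, seed=1)
        assert all(full.heterozygous(p).all() for p in ("P1", "P2"))

    def test_het_count_within_binomial_99_interval(self, framework_map):
        lo, hi = stats.binom.ppf([0.005, 0.995], 252, 0.5)
        pg = simdata.simulate_parents(framework_map, ["P1"], 0.5, seed=7)
        assert lo <= pg.heterozygous("P1").sum() <= hi

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            simdata.GeneticMap(pd.DataFrame(columns=["marker_id", "linkage_group",
                                                     "position_cm"]))

    def test_invalid_het_fraction(self, small_map):
        with pytest.raises(ValueError):
            simdata.simulate_parents(small_map, 2, 1.5, seed=0)


class TestMeiosis:
    def test_zero_distance_markers_cosegregate(self):
        gmap = simdata.GeneticMap(pd.DataFrame(
            {"marker_id": ["a", "b"], "linkage_group": [1, 1], "position_cm": [5.0, 5.0]}
        ))
        pop = _one_cross(gmap, 200, seed=3)
        for p in ("F", "M"):
            t = pop.truth_transmissions(p)
            assert (t["a"] == t["b"]).all()

    def test_unknown_parent_rejected(self, small_map):
        parents = simdata.simulate_parents(small_map, ["P1", "P2"], 0.5, seed=0)
        with pytest.raises(KeyError):
            simdata.simulate_cross(parents, ("cx", "P1", "nope", 5), small_map, seed=0)

    @pytest.mark.parametrize("d_cm", [5.0, 10.0, 20.0, 50.0])
    def test_haldane_recombination_fraction_recovered(self, d_cm):
        gmap = simdata.GeneticMap(pd.DataFrame(
            {"marker_id": ["a", "b"], "linkage_group": [1, 1],
             "position_cm": [0.0, d_cm]}
        ))
        pop = _one_cross(gmap, 10_000, seed=int(d_cm))
        t = pop.truth_transmissions("F")
        rec = (t["a"] != t["b"]).mean()
        assert abs(rec - haldane_r(d_cm)) < 0.01

    def test_unlinked_markers_independent(self):
        gmap = simdata.GeneticMap(pd.DataFrame(
            {"marker_id": ["a", "b"], "linkage_group": [1, 2],
             "position_cm": [0.0, 0.0]}
        ))
        pop = _one_cross(gmap, 10_000, seed=9)
        t = pop.truth_transmissions("F")
        rec = (t["a"] != t["b"]).mean()
        assert abs(rec - 0.5) < 0.015

    def test_mendelian_conservation(self, small_pop):
        """Every progeny allele occurs in the corresponding parent."""
        for ind in small_pop.individuals:
            mat, pat = small_pop.progeny_alleles(ind)
            mo = small_pop.parents[small_pop.mother_of[ind]]
            fa = small_pop.parents[small_pop.father_of[ind]]
            assert all(a in mo[:, j] for j, a in enumerate(mat))
            assert all(a in fa[:, j] for j, a in enumerate(pat))

    def test_transmission_fairness(self, small_map):
        """Each parental haplotype transmitted at ~0.5 over >=5000 meioses."""
        pop = _one_cross(small_map, 5000, het=1.0, seed=5)
        t = pop.truth_transmissions("F")
        freq = t.mean(axis=0)
        se = 0.5 / np.sqrt(len(t))
        assert ((freq - 0.5).abs() <= 3 * se).all()


class TestExpression:
    def _plan(self, pop):
        return arraydesign.build_design(pop, seed=0, n_restarts=2)

    def test_no_signal_means_flat_latent(self, small_pop):
        arch = simdata.EqtlArchitecture(
            tuple(simdata.ExprTrait(f"g{i}", (), None, 0.0) for i in range(4)),
            background_sd=0.0,
        )
        tech = simdata.TechnicalModel(sigma_eps=0.0)
        _, truth = simdata.simulate_expression(small_pop, arch, tech,
                                               self._plan(small_pop), seed=0)
        assert np.allclose(truth["latent"].to_numpy(), 0.0)

    def test_planted_effect_recovered_as_group_contrast(self, small_map):
        pop = _one_cross(small_map, 200, seed=2)
        m = small_map.marker_ids[0]
        arch = simdata.EqtlArchitecture(
            (simdata.ExprTrait("g1", (simdata.PlantedQtl(m, {"F": 1.0}),), None, 0.3),),
            background_sd=0.0,
        )
        _, truth = simdata.simulate_expression(pop, arch, simdata.TechnicalModel(),
                                               self._plan(pop), seed=2)
        x = pop.truth_transmissions("F")[m]
        y = truth["latent"]["g1"]
        diff = y[x == 1].mean() - y[x == 0].mean()
        se = 0.3 * np.sqrt(1 / (x == 1).sum() + 1 / (x == 0).sum())
        assert abs(diff - 1.0) <= 3 * se

    def test_dye_offset_visible_before_residualization(self, small_pop):
        arch = simdata.EqtlArchitecture(
            tuple(simdata.ExprTrait(f"g{i}", (), None, 0.1) for i in range(40)),
            background_sd=0.0,
        )
        tech = simdata.TechnicalModel(sigma_eps=0.05)
        intens, _ = simdata.simulate_expression(small_pop, arch, tech,
                                                self._plan(small_pop), seed=4)
        # invert intensity to the latent h scale exactly (known scale/background)
        h = np.arcsinh(intens["foreground"] - intens["background"])
        by_channel = h.groupby(intens["channel"]).mean()
        # arsinh compresses; check the ordering and a nonzero separation
        assert by_channel["Cy5"] > by_channel["Cy3"]

    def test_unknown_marker_in_architecture_rejected(self, small_pop):
        arch = simdata.EqtlArchitecture(
            (simdata.ExprTrait("g1", (simdata.PlantedQtl("nope", {"F": 1.0}),)),)
        )
        with pytest.raises(KeyError):
            simdata.simulate_expression(small_pop, arch, simdata.TechnicalModel(),
                                        self._plan(small_pop), seed=0)


class TestPhenotypes:
    def test_ordinal_class_frequencies_match_normal_tails(self, small_map):
        pop = _one_cross(small_map, 2000, seed=6)
        th = (-0.4, 0.9)
        arch = simdata.PhenoArchitecture(
            (simdata.PhenoTrait("atk2000", "ordinal", (), thresholds=th),),
            sums={}, background_sd=0.0,
        )
        ph = simdata.simulate_phenotypes(pop, arch, seed=6)
        obs = ph["atk2000"].value_counts().reindex(range(3), fill_value=0)
        cdf = stats.norm.cdf(np.array([*th, np.inf]))
        expected = np.diff(np.concatenate([[0.0], cdf])) * len(ph)
        chi2 = ((obs - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, 2) > 0.01

    def test_extreme_thresholds_collapse_to_single_class(self, small_pop):
        arch = simdata.PhenoArchitecture(
            (simdata.PhenoTrait("egg2000", "ordinal", (), thresholds=(1e9,)),),
            sums={}, background_sd=0.0,
        )
        ph = simdata.simulate_phenotypes(small_pop, arch, seed=0)
        assert (ph["egg2000"] == 0).all()

    def test_sum_traits_are_yearly_sums(self, small_pop):
        arch = simdata.default_pheno_architecture(small_pop.gmap, small_pop, seed=0)
        ph = simdata.simulate_phenotypes(small_pop, arch, seed=1)
        assert (ph["sum_atk"] == ph["atk2000"] + ph["atk2001"]).all()
        assert (ph["sum_egg"] == ph["egg2000"] + ph["egg2001"]).all()

    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError):
            simdata.PhenoTrait("bad", "ordinal", thresholds=(1.0, 0.5))


class TestIO:
    def test_genotype_csv_round_trip(self, small_pop, tmp_path):
        path = tmp_path / "geno.csv"
        small_pop.to_csv(path)
        back = simdata.PhasedGenotypes.from_csv(path, small_pop.gmap)
        assert set(back.parents) == set(small_pop.parents)
        for p in small_pop.trans:
            a = small_pop.transmissions(p).fillna(-1)
            b = back.transmissions(p).fillna(-1)
            pd.testing.assert_frame_equal(a, b, check_dtype=False)

    def test_map_tsv_round_trip(self, small_map, tmp_path):
        path = tmp_path / "map.tsv"
        small_map.to_tsv(path)
        back = simdata.GeneticMap.from_tsv(path)
        pd.testing.assert_frame_equal(back.table, small_map.table)

    def test_default_map_structure(self, framework_map):
        assert framework_map.n_markers == 252
        assert framework_map.linkage_groups == list(range(1, 14))

    def test_segregating_loci_near_study_average(self, diallel_pop):
        seg = [diallel_pop.n_segregating(c) for c in ("26", "27", "29", "32")]
        assert 95 <= np.mean(seg) <= 150
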