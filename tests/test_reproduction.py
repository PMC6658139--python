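"""Partitioning chosen Adults into Newborns."""

import numpy as np
import pytest

from commsel.agents import Community, H, M
from commsel.analysis import newborn_fluctuation_stats
from commsel.cli_io import make_fixture
from commsel.params import PREADAPTED_GROWTH
from commsel.reproduction import (AdultTooSmall, SortingPool, dilution_fold,
                                  found_monoculture,
                                  partition_fix_single_determinant,
                                  partition_fixed_fold, partition_pipetting,
                                  partition_sort_biomass,
                                  partition_sort_cellnumber)


class TestDilutionFold:
    @pytest.mark.parametrize("bm, expected", [(7000, 70), (6999, 69),
                                              (100, 1), (199.9, 1)])
    def test_floor_arithmetic(self, bm, expected):
        assert dilution_fold(bm, 100.0) == expected

    def test_mean_newborn_biomass_just_above_target(self):
        assert 6999 / dilution_fold(6999, 100.0) == pytest.approx(101.4, abs=0.05)

    def test_too_small_adult_raises(self):
        with pytest.raises(AdultTooSmall):
            dilution_fold(99.0, 100.0)


class TestPipetting:
    def test_conserves_cells_and_resets_chemicals(self, adult_7000, rng):
        newborns = partition_pipetting(adult_7000, 100.0, rng, R0=1.0)
        assert len(newborns) == 70
        assert sum(nb.n_cells for nb in newborns) == adult_7000.n_cells
        assert sum(nb.biomass for nb in newborns) == pytest.approx(7000.0)
        for nb in newborns[:5]:
            assert nb.chem.R == 1.0 and nb.chem.B == 0.0 and nb.chem.P == 0.0

    def test_mean_newborn_biomass_near_target(self, adult_7000, rng):
        newborns = partition_pipetting(adult_7000, 100.0, rng, R0=1.0)
        assert np.mean([nb.biomass for nb in newborns]) == pytest.approx(100.0)

    def test_biomass_variance_matches_poisson_prediction(self, rng):
        """Var of Newborn biomass ~ BM_target * mean cell length (~150)."""
        adult = make_fixture("adult_7000")
        # mixed lengths with mean 1.5 across both species
        bm = []
        for _ in range(150):
            for nb in partition_pipetting(adult, 100.0, rng, R0=1.0):
                bm.append(nb.biomass)
        predicted_sd, _ = newborn_fluctuation_stats(100.0, adult.phi_M)
        assert np.var(bm) == pytest.approx(predicted_sd ** 2, rel=0.10)

    def test_species_ratio_variance_matches_prediction(self, rng):
        """Var[M(0)/H(0)] follows the first-order propagation formula.

        The formula is a delta-method expansion in the component
        fluctuations; at BM_target = 100 the neglected higher-order terms
        contribute ~10-15%, so the comparison tolerance is 20%.  The
        component variances it is built from are checked at 10%.
        """
        adult = Community.from_counts(1867, 2800, PREADAPTED_GROWTH, 0.13,
                                      L=1.5)  # every cell at the mean length
        phi = adult.phi_M
        ratios, m0, h0 = [], [], []
        for _ in range(150):
            for nb in partition_pipetting(adult, 100.0, rng, R0=1.0):
                hb = nb.H_biomass
                m0.append(nb.M_biomass)
                h0.append(hb)
                if hb > 0:
                    ratios.append(nb.M_biomass / hb)
        _, predicted_var = newborn_fluctuation_stats(100.0, phi)
        assert np.var(ratios) == pytest.approx(predicted_var, rel=0.20)
        # Poissonian component fluctuations: Var ~ E[biomass] * L_bar
        assert np.var(m0) == pytest.approx(100 * phi * 1.5, rel=0.10)
        assert np.var(h0) == pytest.approx(100 * (1 - phi) * 1.5, rel=0.10)
        assert abs(np.corrcoef(m0, h0)[0, 1]) < 0.05  # independent species


class TestSorting:
    def test_biomass_windows(self, adult_7000, rng):
        phi = adult_7000.phi_M
        nb = partition_sort_biomass(adult_7000, 100.0, phi, rng)
        assert 100 * phi - 2 < nb.M_biomass <= 100 * phi
        assert 100 * (1 - phi) - 2 < nb.H_biomass <= 100 * (1 - phi)

    def test_unit_length_cells_give_exact_counts(self, rng):
        adult = Community.from_counts(400, 600, PREADAPTED_GROWTH, 0.13)
        nb = partition_sort_biomass(adult, 100.0, 0.6, rng)
        assert nb.I_M == 60 and nb.I_H == 40

    def test_repeated_draws_are_disjoint_until_exhaustion(self, adult_7000, rng):
        pool = SortingPool(adult_7000, rng)
        total = 0
        for _ in range(20):
            nb = partition_sort_biomass(adult_7000, 100.0, adult_7000.phi_M,
                                        rng, pool=pool)
            total += nb.n_cells
        assert total <= adult_7000.n_cells
        assert total == pytest.approx(20 * 100 / 1.45, rel=0.1)

    def test_cellnumber_counts(self, rng):
        adult = Community.from_counts(4000, 6000, PREADAPTED_GROWTH, 0.13)
        adult.L[:] = 1.0 + rng.random(adult.n_cells)
        nb = partition_sort_cellnumber(adult, 100.0, 0.6, rng)
        assert nb.I_M == 40 and nb.I_H == 26  # floor(60/1.5), floor(40/1.5)

    def test_cellnumber_all_manufacturer(self, rng):
        adult = Community.from_counts(0, 600, PREADAPTED_GROWTH, 0.13)
        nb = partition_sort_cellnumber(adult, 100.0, 1.0, rng)
        assert nb.I_M == 66 and nb.I_H == 0


class TestFixSingleDeterminant:
    def test_bm_only_window(self, adult_7000, rng):
        newborns = partition_fix_single_determinant(adult_7000, "BM_only",
                                                    100.0, rng)
        assert len(newborns) >= 60
        for nb in newborns:
            assert 98.0 < nb.biomass <= 100.0

    def test_bm_only_unit_lengths_exact(self, rng):
        adult = Community.from_counts(500, 500, PREADAPTED_GROWTH, 0.13)
        newborns = partition_fix_single_determinant(adult, "BM_only", 100.0, rng)
        assert all(nb.biomass == 100.0 for nb in newborns)
        assert len(newborns) == 10

    def test_phim_only_count_and_composition(self, adult_7000, rng):
        newborns = partition_fix_single_determinant(adult_7000, "phiM_only",
                                                    100.0, rng)
        assert len(newborns) == 70
        phis = [nb.phi_M for nb in newborns if nb.n_cells > 10]
        assert np.mean(phis) == pytest.approx(adult_7000.phi_M, abs=0.02)


class TestFixedFold:
    def test_conserves_cells_across_fixed_folds(self, adult_7000, rng):
        newborns = partition_fixed_fold(adult_7000, 100, rng)
        assert len(newborns) == 100
        assert sum(nb.n_cells for nb in newborns) == adult_7000.n_cells

    def test_newborn_size_tracks_adult_not_target(self, rng):
        small = Community.from_counts(100, 100, PREADAPTED_GROWTH, 0.13)
        big = Community.from_counts(1000, 1000, PREADAPTED_GROWTH, 0.13)
        nb_s = partition_fixed_fold(small, 10, rng)
        nb_b = partition_fixed_fold(big, 10, rng)
        assert np.mean([n.biomass for n in nb_s]) == pytest.approx(20.0)
        assert np.mean([n.biomass for n in nb_b]) == pytest.approx(200.0)


class TestMonoculture:
    def test_single_founder_cell(self):
        nb = found_monoculture(0.13, PREADAPTED_GROWTH, R0=1.0)
        assert nb.n_cells == 1 and nb.species[0] == M
        assert nb.L[0] == 1.0 and nb.f_P[0] == 0.13
        assert nb.chem.R == 1.0
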