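"""Introgression, mating-system and zygosity-LD statistics against oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from parapop.errors import ValidationError
from parapop.genotypes import GenotypeMatrix
from parapop.popgen import (
    ZygosityProfile,
    correlation_of_zygosity,
    fis_multilocus,
    ld_extent,
    mating_conversions,
    outcrossing_progeny_array,
    patterson_d,
    zygosity_profile_from_genotypes,
)
from parapop.synthetic import (
    ProgenyArray,
    equilibrium_f,
    simulate_inbred_genotypes,
    simulate_progeny_arrays,
    simulate_zygosity_tracts,
)


def gm(genotypes, pos=None, chrom=None, ids=None, polarized=True):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    return GenotypeMatrix(
        sample_ids=ids or [f"s{i}" for i in range(n)],
        chrom=np.array(chrom if chrom is not None else ["c1"] * m, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, m + 1)),
        genotypes=genotypes,
        polarized=polarized,
    )


def quartet_matrix(n_abba, n_baba):
    """Hom genotypes encoding ABBA (0,2,2,0) and BABA (2,0,2,0) site patterns."""
    cols = [[0, 2, 2, 0]] * n_abba + [[2, 0, 2, 0]] * n_baba
    return gm(np.array(cols).T, ids=["p1", "p2", "p3", "out"])


QUARTET = (["p1"], ["p2"], ["p3"], ["out"])


class TestPattersonD:
    def test_balanced_patterns_give_zero(self):
        r = patterson_d(quartet_matrix(10, 10), QUARTET)
        assert r.d == 0
        assert r.abba == 10 and r.baba == 10

    def test_abba_excess_arithmetic(self):
        r = patterson_d(quartet_matrix(15, 5), QUARTET)
        assert r.d == pytest.approx(0.5)

    def test_antisymmetric_under_p1_p2_swap(self, rng):
        g = gm(rng.integers(0, 3, size=(4, 200)), ids=["p1", "p2", "p3", "out"])
        a = patterson_d(g, QUARTET, block_size_bp=50)
        b = patterson_d(g, (["p2"], ["p1"], ["p3"], ["out"]), block_size_bp=50)
        assert a.d == pytest.approx(-b.d)
        assert a.se == pytest.approx(b.se)

    def test_no_informative_sites_is_flagged_undefined(self):
        g = gm(np.zeros((4, 5)), ids=["p1", "p2", "p3", "out"])
        r = patterson_d(g, QUARTET)
        assert r.undefined and np.isnan(r.d)

    def test_too_few_blocks_refuses_jackknife_but_reports_d(self):
        r = patterson_d(quartet_matrix(15, 5), QUARTET, block_size_bp=10_000)
        assert r.jackknife_refused and np.isnan(r.se)
        assert r.d == pytest.approx(0.5)

    def test_overlapping_quartet_sets_rejected(self):
        with pytest.raises(ValidationError):
            patterson_d(quartet_matrix(1, 1), (["p1"], ["p1"], ["p3"], ["out"]))


class TestFis:
    def test_excess_heterozygosity_gives_negative_fis(self):
        g = gm(np.ones((4, 3)))  # everyone heterozygous, p = 0.5
        est = fis_multilocus(g)
        assert est.fis < 0
        assert np.all(est.fis_per_locus < 0)

    def test_no_heterozygotes_gives_fis_one(self):
        g = gm([[0, 0], [0, 2], [2, 0], [2, 2]])
        assert fis_multilocus(g).fis == pytest.approx(1.0)

    def test_monomorphic_panel_undefined(self):
        est = fis_multilocus(gm(np.full((4, 3), 2)))
        assert est.undefined

    def test_equilibrium_recovery_at_study_selfing_rate(self):
        s = 0.6486  # F = s/(2-s) = 0.48
        vals = [
            fis_multilocus(simulate_inbred_genotypes(50, 19, s, seed=k)).fis
            for k in range(6)
        ]
        assert abs(np.mean(vals) - equilibrium_f(s)) < 0.05

    def test_invariant_under_allele_relabeling(self, rng):
        g = gm(rng.integers(0, 3, size=(10, 25)))
        flipped = gm(2 - g.genotypes)
        assert fis_multilocus(g).fis == pytest.approx(fis_multilocus(flipped).fis)


class TestConversions:
    @pytest.mark.parametrize("F,t", [(0.0, 1.0), (1.0, 0.0), (1 / 3, 0.5)])
    def test_equilibrium_identities(self, F, t):
        out = mating_conversions(F=F)
        assert out["t"] == pytest.approx(t)
        assert out["s"] == pytest.approx(1 - t)

    @given(s=st.floats(min_value=0.0, max_value=1.0))
    def test_round_trip_through_f(self, s):
        F = mating_conversions(s=s)["F"]
        assert mating_conversions(F=F)["s"] == pytest.approx(s, abs=1e-12)

    def test_calibration_table_overrides_equilibrium_map(self):
        # an empirical F -> t curve steeper than the equilibrium identity:
        cal = np.array([[0.0, 1.0], [0.48, 0.15], [1.0, 0.0]])
        out = mating_conversions(F=0.48, calibration=cal)
        assert out["t"] == pytest.approx(0.15)
        mid = mating_conversions(F=0.24, calibration=cal)
        assert out["t"] < mid["t"] < 1.0

    def test_out_of_range_and_overdetermined_inputs_rejected(self):
        with pytest.raises(ValidationError):
            mating_conversions(F=1.5)
        with pytest.raises(ValidationError):
            mating_conversions(F=0.1, s=0.1)
        with pytest.raises(ValidationError):
            mating_conversions()


class TestProgenyArrayEstimator:
    def test_fully_maternal_offspring_give_zero_rate_with_zero_sd(self):
        arrays = simulate_progeny_arrays(10, 10, 19, 1.0, seed=5)
        est = outcrossing_progeny_array(arrays, seed=1)
        assert est.t_m == 0.0 and est.sd == 0.0

    def test_detection_corrected_arithmetic(self):
        # one locus, mother aa, pollen freq of the alternate allele 0.5 so
        # P_det = 0.5; 2 of 8 offspring heterozygous -> detected 0.25 -> t = 0.5
        arr = ProgenyArray(
            maternal_genotype=[0],
            offspring_genotypes=[[1], [1], [0], [0], [0], [0], [0], [0]],
            pollen_pool_freqs=[0.5],
        )
        est = outcrossing_progeny_array([arr], n_boot=10, seed=0)
        assert est.t_m == pytest.approx(0.5)

    def test_homozygous_mother_detects_heterozygous_offspring(self):
        arr = ProgenyArray(
            maternal_genotype=[0], offspring_genotypes=[[1]], pollen_pool_freqs=[1.0]
        )
        est = outcrossing_progeny_array([arr], n_boot=5, seed=0)
        assert est.t_m == pytest.approx(1.0)

    def test_incompatible_offspring_excluded_and_counted(self):
        # mother aa, offspring AA shares no maternal allele -> genotyping error
        arr = ProgenyArray(
            maternal_genotype=[0, 0],
            offspring_genotypes=[[2, 0], [0, 0]],
            pollen_pool_freqs=[0.5, 0.5],
        )
        est = outcrossing_progeny_array([arr], n_boot=5, seed=0)
        assert est.n_excluded == 1
        assert est.t_m == 0.0

    @pytest.mark.parametrize("s", [0.0, 0.5, 1.0])
    def test_recovers_generating_selfing_rate(self, s):
        arrays = simulate_progeny_arrays(30, 30, 19, s, seed=17)
        est = outcrossing_progeny_array(arrays, n_boot=100, seed=3)
        spread = max(3 * est.sd, 0.05)
        assert abs(est.t_m - (1 - s)) <= spread

    def test_pollen_from_maternal_plants_option(self):
        arrays = simulate_progeny_arrays(25, 25, 19, 0.5, seed=23)
        est = outcrossing_progeny_array(arrays, n_boot=50, seed=3, pollen_freqs="maternal")
        assert abs(est.t_m - 0.5) < 0.15


EDGES = np.array([1, 3, 10, 30, 100, 300, 1000, 3000, 10_000], dtype=float)


class TestCorrelationOfZygosity:
    def test_iid_sites_uncorrelated(self, rng):
        z = (rng.random(200_000) < 0.3).astype(float)
        prof = correlation_of_zygosity(z, EDGES)
        assert np.nanmax(np.abs(prof.delta)) < 0.02

    def test_periodic_track_gives_perfect_correlation(self):
        # period-4 track: every pair at distance 4 has identical zygosity
        z = np.tile([1.0, 1.0, 0.0, 0.0], 2500)
        prof = correlation_of_zygosity(z, np.array([3.5, 4.5]))
        assert prof.delta[0] == pytest.approx(1.0)

    def test_markov_tracts_match_geometric_decay(self):
        rho = 0.999
        z = simulate_zygosity_tracts(0.2, rho, 1_000_000, seed=2).astype(float)
        prof = correlation_of_zygosity(z, EDGES)
        # exact oracle: pair-pooled expectation, the mean of rho^d over the
        # integer lags inside each bin
        expect = np.array(
            [
                np.mean(rho ** np.arange(np.ceil(lo), hi))
                for lo, hi in zip(EDGES[:-1], EDGES[1:])
            ]
        )
        assert np.nanmax(np.abs(prof.delta - expect)) < 0.04

    def test_all_homozygous_flagged_undefined(self):
        prof = correlation_of_zygosity(np.zeros(100), EDGES)
        assert prof.undefined

    def test_pairs_never_span_region_boundaries(self):
        # lags 1 and 2 over two 50-site regions: 97 ordered pairs fit inside
        # each region; the 3 boundary-spanning pairs must not be counted
        z = np.concatenate([np.ones(50), np.zeros(50)])
        regions = np.repeat([0, 1], 50)
        prof = correlation_of_zygosity(z, np.array([0.5, 2.5]), regions=regions)
        assert prof.n_pairs[0] == 2 * 97

    def test_profile_from_genotype_matrix_counts_heterozygous_sites(self):
        g = gm([[0, 1, 1, 2, 1]], ids=["a"])
        prof = zygosity_profile_from_genotypes(g, "a", np.array([0.5, 10.0]))
        assert prof.theta == pytest.approx(3 / 5)


class TestLdExtent:
    def closed_form_profile(self, rho):
        centers = np.sqrt(EDGES[:-1] * EDGES[1:])
        delta = rho**centers
        return ZygosityProfile("x", 0.2, EDGES, centers, delta, delta, np.ones(len(centers)))

    def test_matches_closed_form_within_one_bin(self):
        ext = ld_extent(self.closed_form_profile(0.999), threshold=0.1)
        true = np.log(0.1) / np.log(0.999)  # 2301.4 bp
        # within one log10-spaced bin of the analytic crossing
        bins = EDGES
        j = np.searchsorted(bins, true)
        assert bins[j - 1] <= ext.extent_bp <= bins[j + 1]

    def test_flat_profile_right_censored(self):
        centers = np.sqrt(EDGES[:-1] * EDGES[1:])
        prof = ZygosityProfile(
            "x", 0.2, EDGES, centers, np.ones(len(centers)),
            np.ones(len(centers)), np.ones(len(centers)),
        )
        ext = ld_extent(prof, threshold=0.1)
        assert ext.censored and np.isnan(ext.extent_bp)

    def test_threshold_one_returns_first_bin_center(self):
        prof = self.closed_form_profile(0.999)
        assert ld_extent(prof, threshold=1.0).extent_bp == pytest.approx(
            prof.bin_centers[0]
        )

    def test_extent_monotone_in_tract_persistence(self):
        extents = []
        for rho in (0.99, 0.999, 0.9999):
            z = simulate_zygosity_tracts(0.2, rho, 600_000, seed=4).astype(float)
            prof = correlation_of_zygosity(z, EDGES)
            ext = ld_extent(prof, threshold=0.1)
            extents.append(ext.extent_bp if not ext.censored else np.inf)
        assert extents[0] < extents[1] < extents[2]
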