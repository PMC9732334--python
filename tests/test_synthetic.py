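"""Generators against closed-form coalescent and Markov-chain oracles."""

import numpy as np
import pytest

from parapop.coalescent import sfs_branch_lengths, simulate_coalescent_sfs_data
from parapop.errors import ValidationError
from parapop.models import DemographicModel, Population, SplitEvent
from parapop.popgen import fis_multilocus
from parapop.synthetic import (
    equilibrium_f,
    simulate_annotated_vcf,
    simulate_expansion_load,
    simulate_progeny_arrays,
    simulate_zygosity_tracts,
)


def single_pop(n_dip, theta_locus=1.0, L=10_000, Ne=10_000.0, selfing=0.0):
    mu = theta_locus / (4 * Ne * L)
    return DemographicModel(
        populations=[Population("A", Ne, selfing, n_dip)], mutation_rate=mu, locus_length=L
    )


def test_zero_mutation_rate_gives_zero_segregating_sites():
    g = simulate_coalescent_sfs_data(single_pop(3, theta_locus=0.0), 50, seed=1)
    assert g.n_sites == 0


def test_watterson_segregating_sites_and_singletons():
    # theta_locus = 1: E[S] = sum_{i<6} 1/i = 2.2833, E[singletons] = theta = 1
    n_loci = 2000
    g = simulate_coalescent_sfs_data(single_pop(3, theta_locus=1.0), n_loci, seed=7)
    s_mean = g.n_sites / n_loci
    # Var(S) = theta sum 1/i + theta^2 sum 1/i^2 => SE of the mean
    se = np.sqrt((2.2833 + 1.4636) / n_loci)
    assert abs(s_mean - 2.2833) < 3 * se
    singletons = (g.genotypes.sum(axis=0) == 1).sum() / n_loci
    assert abs(singletons - 1.0) < 3 * np.sqrt(2.0 / n_loci)


def test_single_population_branch_sfs_proportional_to_one_over_i():
    bl = np.zeros(7)
    for s in range(3):
        bl += sfs_branch_lengths(single_pop(3), 4000, seed=s)
    p = bl[1:-1] / bl[1:-1].sum()
    expect = (1 / np.arange(1, 6)) / (1 / np.arange(1, 6)).sum()
    assert np.abs(p - expect).max() < 0.02


def test_selfing_produces_equilibrium_heterozygote_deficit():
    s = 0.8  # F = s/(2-s) = 2/3
    g = simulate_coalescent_sfs_data(single_pop(20, theta_locus=2.0, selfing=s), 1500, seed=3)
    est = fis_multilocus(g)
    assert abs(est.fis - equilibrium_f(s)) < 0.05


def _hudson_fst(g, set1, set2):
    def freqs(ids):
        sub = g.take_samples(ids)
        return sub.genotypes.sum(axis=0) / (2 * sub.n_samples), 2 * sub.n_samples

    p1, n1 = freqs(set1)
    p2, n2 = freqs(set2)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num.sum() / den.sum()


def test_fst_increases_with_split_time():
    fsts = []
    for t in (500.0, 5_000.0, 50_000.0):
        m = DemographicModel(
            populations=[Population("A", 10_000.0, 0.0, 3), Population("B", 10_000.0, 0.0, 3)],
            splits=[SplitEvent(t, "B", "A")],
            mutation_rate=0.355e-8,
            locus_length=10_000,
        )
        g = simulate_coalescent_sfs_data(m, 1500, seed=11)
        a = [s for s in g.sample_ids if s.startswith("A_")]
        b = [s for s in g.sample_ids if s.startswith("B_")]
        fsts.append(_hudson_fst(g, a, b))
    assert fsts[0] < fsts[1] < fsts[2]


def test_coalescent_simulation_is_bit_reproducible():
    m = single_pop(3)
    g1 = simulate_coalescent_sfs_data(m, 100, seed=42)
    g2 = simulate_coalescent_sfs_data(m, 100, seed=42)
    assert np.array_equal(g1.genotypes, g2.genotypes)
    assert np.array_equal(g1.pos, g2.pos)
    g3 = simulate_coalescent_sfs_data(m, 100, seed=43)
    assert not (
        g1.n_sites == g3.n_sites and np.array_equal(g1.genotypes, g3.genotypes)
    )


def test_msprime_cross_check_two_population_split_branch_sfs():
    """Independent oracle: msprime's branch-mode joint AFS on the same model."""
    msprime = pytest.importorskip("msprime")
    NA, NB, T = 10_000.0, 5_000.0, 8_000.0
    mAB, mBA = 2e-5, 5e-6
    mine = DemographicModel(
        populations=[Population("A", NA, 0.0, 2), Population("B", NB, 0.0, 2)],
        splits=[SplitEvent(T, "B", "A")],
        migration={("A", "B"): mAB, ("B", "A"): mBA},
        mutation_rate=0,
        locus_length=1,
    )
    bl = np.zeros((5, 5))
    for s in range(4):
        bl += sfs_branch_lengths(mine, 3000, seed=s)
    total = np.indices(bl.shape).sum(axis=0)
    poly = (total > 0) & (total < 8)
    p_mine = bl[poly] / bl[poly].sum()

    dem = msprime.Demography()
    dem.add_population(name="A", initial_size=NA)
    dem.add_population(name="B", initial_size=NB)
    dem.add_population(name="ANC", initial_size=NA)
    dem.set_migration_rate(source="A", dest="B", rate=mAB)
    dem.set_migration_rate(source="B", dest="A", rate=mBA)
    dem.add_population_split(time=T, derived=["A", "B"], ancestral="ANC")
    afs = np.zeros((5, 5))
    reps = msprime.sim_ancestry(
        samples={"A": 2, "B": 2}, demography=dem, ploidy=2,
        num_replicates=12_000, random_seed=7,
    )
    for ts in reps:
        afs += ts.allele_frequency_spectrum(
            sample_sets=[ts.samples(population=0), ts.samples(population=1)],
            mode="branch", polarised=True, span_normalise=False,
        )
    p_ms = afs[poly] / afs[poly].sum()
    assert 0.5 * np.abs(p_mine - p_ms).sum() < 0.03  # total-variation distance


# ------------------------------------------------------------------- tracts
def test_tracts_iid_when_rho_zero():
    z = simulate_zygosity_tracts(0.3, 0.0, 200_000, seed=5).astype(float)
    r = np.corrcoef(z[:-1], z[1:])[0, 1]
    assert abs(r) < 0.01


def test_tract_mean_matches_theta_within_markov_standard_error():
    theta, rho, L = 0.01, 0.999, 1_000_000
    z = simulate_zygosity_tracts(theta, rho, L, seed=2)
    se = np.sqrt(theta * (1 - theta) * (1 + rho) / ((1 - rho) * L))
    assert abs(z.mean() - theta) < 3 * se


def test_tract_lag_autocorrelation_is_geometric():
    z = simulate_zygosity_tracts(0.2, 0.999, 1_000_000, seed=9).astype(float)
    lag = 100
    r = np.corrcoef(z[:-lag], z[lag:])[0, 1]
    assert abs(r - 0.999**lag) < 0.02  # 0.999^100 = 0.9048


@pytest.mark.parametrize("theta,rho", [(0.0, 0.5), (1.0, 0.5), (0.3, 1.0), (0.3, -0.1)])
def test_tract_parameter_validation(theta, rho):
    with pytest.raises(ValidationError):
        simulate_zygosity_tracts(theta, rho, 1000, seed=0)


# ------------------------------------------------------------ progeny arrays
def test_complete_selfing_never_introduces_non_maternal_alleles():
    for seed in range(3):
        for arr in simulate_progeny_arrays(5, 8, 12, 1.0, seed=seed):
            for o in range(arr.n_offspring):
                off = arr.offspring_genotypes[o]
                hom = arr.maternal_genotype != 1
                # at maternally homozygous loci the offspring must be identical
                assert np.array_equal(off[hom], arr.maternal_genotype[hom])


def test_full_outcrossing_from_fixed_pollen_pool():
    # mother aa (all-zero at equilibrium of s=0... force via pollen freq 1):
    arrs = simulate_progeny_arrays(3, 10, 5, 0.0, pollen_pool_freqs=1.0, seed=1)
    for arr in arrs:
        assert np.all(arr.maternal_genotype == 2)  # pollen freq 1 fixes mothers too
        assert np.all(arr.offspring_genotypes == 2)
    # heterozygous detection case: mothers fixed for allele 0, pollen all allele 1
    arr0 = simulate_progeny_arrays(1, 10, 5, 0.0, pollen_pool_freqs=0.0, seed=1)[0]
    assert np.all(arr0.offspring_genotypes == 0)


def test_half_selfing_detected_fraction_matches_enumerated_probability():
    s = 0.5
    arrs = simulate_progeny_arrays(40, 50, 10, s, seed=6)
    detected = 0
    total = 0
    p_det = []
    for arr in arrs:
        hom = arr.maternal_genotype != 1
        q = 1.0
        for l in np.flatnonzero(hom):
            pa = arr.pollen_pool_freqs[l]
            q *= (1 - pa) if arr.maternal_genotype[l] == 0 else pa
        p_det.append(1 - q)
        for o in range(arr.n_offspring):
            off = arr.offspring_genotypes[o]
            total += 1
            detected += int(np.any(off[hom] != arr.maternal_genotype[hom]))
    frac = detected / total
    expect = (1 - s) * np.mean(p_det)
    se = np.sqrt(expect * (1 - expect) / total)
    assert abs(frac - expect) < 4 * se


# ------------------------------------------------------------- annotated VCF
def test_annotated_vcf_ground_truth_zero_cases(tmp_path):
    probs = {"LOW": 0.25, "MODERATE": 0.25, "HIGH": 0.25, "MODIFIER": 0.25}
    t1 = simulate_annotated_vcf(4, 50, probs, 0.0, 1, str(tmp_path / "a.vcf"))
    assert (t1["true_load"] == 0).all()
    t2 = simulate_annotated_vcf(4, 50, {"LOW": 1.0}, 0.5, 1, str(tmp_path / "b.vcf"))
    assert (t2["true_load"] == 0).all()


def test_annotated_vcf_high_impact_binomial_mean(tmp_path):
    t = simulate_annotated_vcf(60, 100, {"HIGH": 1.0}, 0.3, 5, str(tmp_path / "c.vcf"))
    # each sample's load ~ Binomial(100, 0.3)
    assert abs(t["true_load"].mean() - 30) < 3 * np.sqrt(100 * 0.3 * 0.7 / 60)


def test_expansion_load_rises_with_distance():
    df = simulate_expansion_load(seed=3)
    assert df["load"].iloc[-2:].mean() > df["load"].iloc[:2].mean()
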