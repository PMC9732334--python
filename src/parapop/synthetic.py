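"""Synthetic-data generators with known ground truth.

Every pipeline stage has a matching generator here: structured-coalescent
genotypes live in :mod:`parapop.coalescent`; this module adds

* two-state Markov heterozygosity tracts for the correlation-of-zygosity
  analysis (stationary het probability theta, lag-1 autocorrelation rho);
* progeny arrays under mixed mating (selfing rate s, maternal genotypes at
  inbreeding equilibrium F = s/(2-s));
* genotypes of a single population at inbreeding equilibrium, for the
  F_IS estimator;
* impact-annotated toy VCFs with exact per-sample load ground truth;
* a serial-founder range-expansion generator in which drift along the
  route raises the frequency of homozygous deleterious-labelled variants.

All generators are bit-reproducible given the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .errors import ValidationError
from .genotypes import GenotypeMatrix
from .io_formats import IMPACT_LEVELS, write_vcf


@dataclass
class ProgenyArray:
    """One maternal family: mother, offspring, and pollen-pool frequencies.

    Genotypes are derived/alternate allele counts (0, 1, 2);
    ``pollen_pool_freqs`` holds the frequency of allele 1 per locus.
    """

    maternal_genotype: np.ndarray  # (n_loci,)
    offspring_genotypes: np.ndarray  # (n_offspring, n_loci)
    pollen_pool_freqs: np.ndarray  # (n_loci,)

    def __post_init__(self) -> None:
        self.maternal_genotype = np.asarray(self.maternal_genotype, dtype=np.int8)
        self.offspring_genotypes = np.atleast_2d(
            np.asarray(self.offspring_genotypes, dtype=np.int8)
        )
        self.pollen_pool_freqs = np.asarray(self.pollen_pool_freqs, dtype=np.float64)
        if self.offspring_genotypes.shape[1] != self.n_loci:
            raise ValidationError("offspring loci do not match maternal loci")
        if len(self.pollen_pool_freqs) != self.n_loci:
            raise ValidationError("pollen frequencies do not match loci")
        if np.any((self.pollen_pool_freqs < 0) | (self.pollen_pool_freqs > 1)):
            raise ValidationError("pollen frequencies must be in [0,1]")

    @property
    def n_loci(self) -> int:
        return len(self.maternal_genotype)

    @property
    def n_offspring(self) -> int:
        return self.offspring_genotypes.shape[0]


def equilibrium_f(s: float) -> float:
    """Inbreeding coefficient at mixed-mating equilibrium, F = s / (2 - s)."""
    if not 0.0 <= s <= 1.0:
        raise ValidationError("selfing rate must be in [0,1]")
    return s / (2.0 - s)


# --------------------------------------------------------------------- tracts
@njit(cache=True)
def _markov_chain(length, p_stay_het, p_enter_het, start_het, seed):
    np.random.seed(seed)
    z = np.empty(length, np.int8)
    state = start_het
    for i in range(length):
        if state == 1:
            state = 1 if np.random.random() < p_stay_het else 0
        else:
            state = 1 if np.random.random() < p_enter_het else 0
        z[i] = state
    return z


def simulate_zygosity_tracts(
    theta: float, rho: float, length_bp: int, seed: int
) -> np.ndarray:
    """Stationary binary het/hom sequence with mean theta and lag-1 autocorrelation rho.

    The two-state Markov chain with P(het->het) = rho + theta(1-rho) and
    P(hom->het) = theta(1-rho) has stationary het probability theta and
    geometric autocorrelation rho**d at lag d.
    """
    if not 0.0 < theta < 1.0:
        raise ValidationError("theta must be in (0,1)")
    if not 0.0 <= rho < 1.0:
        raise ValidationError("rho must be in [0,1)")
    if length_bp < 2:
        raise ValidationError("length must be >= 2")
    p_enter = theta * (1.0 - rho)
    p_stay = rho + p_enter
    rng = np.random.default_rng(seed)
    start = 1 if rng.random() < theta else 0
    chain_seed = int(rng.integers(2**31))
    return _markov_chain(int(length_bp), p_stay, p_enter, start, chain_seed)


# ------------------------------------------------------------- progeny arrays
def _maternal_genotypes(rng, freqs: np.ndarray, F: float) -> np.ndarray:
    """Diploid genotypes at inbreeding equilibrium for the given allele-1 freqs."""
    ibd = rng.random(len(freqs)) < F
    g = np.where(
        ibd,
        2 * (rng.random(len(freqs)) < freqs),
        rng.binomial(2, freqs),
    )
    return g.astype(np.int8)


def simulate_progeny_arrays(
    n_mothers: int,
    n_offspring: int,
    n_loci: int,
    selfing_rate: float,
    pollen_pool_freqs: np.ndarray | float | None = None,
    seed: int = 0,
) -> list[ProgenyArray]:
    """Progeny arrays under mixed mating with selfing rate ``s``.

    Each offspring is a selfed gamete pair from its mother with probability
    s, otherwise one maternal gamete plus one pollen-pool gamete.  Maternal
    genotypes are drawn at inbreeding equilibrium F = s/(2-s).
    """
    if not 0.0 <= selfing_rate <= 1.0:
        raise ValidationError("selfing rate must be in [0,1]")
    if min(n_mothers, n_offspring, n_loci) < 1:
        raise ValidationError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    if pollen_pool_freqs is None:
        pollen = rng.uniform(0.2, 0.8, size=n_loci)
    else:
        pollen = np.broadcast_to(np.asarray(pollen_pool_freqs, dtype=float), (n_loci,)).copy()
    if np.any((pollen < 0) | (pollen > 1)):
        raise ValidationError("pollen frequencies must be in [0,1]")
    F = equilibrium_f(selfing_rate)
    arrays = []
    for _ in range(n_mothers):
        mom = _maternal_genotypes(rng, pollen, F)
        off = np.empty((n_offspring, n_loci), dtype=np.int8)
        for o in range(n_offspring):
            # maternal gamete: one random allele per locus
            gam1 = (rng.random(n_loci) < mom / 2.0).astype(np.int8)
            if rng.random() < selfing_rate:
                gam2 = (rng.random(n_loci) < mom / 2.0).astype(np.int8)
            else:
                gam2 = (rng.random(n_loci) < pollen).astype(np.int8)
            off[o] = gam1 + gam2
        arrays.append(
            ProgenyArray(
                maternal_genotype=mom,
                offspring_genotypes=off,
                pollen_pool_freqs=pollen,
            )
        )
    return arrays


# -------------------------------------------------- inbreeding-equilibrium SNPs
def simulate_inbred_genotypes(
    n_individuals: int,
    n_loci: int,
    selfing_rate: float,
    seed: int = 0,
    freq_range: tuple[float, float] = (0.2, 0.8),
) -> GenotypeMatrix:
    """Single-population genotypes at inbreeding equilibrium F = s/(2-s).

    Per locus, an allele frequency is drawn uniformly from ``freq_range``;
    per individual and locus, the two alleles are identical by descent with
    probability F (genotype 0 or 2), otherwise Hardy-Weinberg.
    """
    if min(n_individuals, n_loci) < 1:
        raise ValidationError("counts must be >= 1")
    F = equilibrium_f(selfing_rate)
    rng = np.random.default_rng(seed)
    p = rng.uniform(*freq_range, size=n_loci)
    ibd = rng.random((n_individuals, n_loci)) < F
    hom = 2 * (rng.random((n_individuals, n_loci)) < p)
    hw = rng.binomial(2, np.broadcast_to(p, (n_individuals, n_loci)))
    g = np.where(ibd, hom, hw).astype(np.int8)
    return GenotypeMatrix(
        sample_ids=[f"ind_{i}" for i in range(n_individuals)],
        chrom=np.array(["chr1"] * n_loci, dtype=object),
        pos=np.arange(1, n_loci + 1) * 100_000,
        genotypes=g,
        polarized=False,
    )


# ------------------------------------------------------------- annotated VCFs
def simulate_annotated_vcf(
    n_samples: int,
    n_variants: int,
    impact_probs: dict[str, float],
    hom_alt_prob: float,
    seed: int,
    path: str,
) -> pd.DataFrame:
    """Write an ANN-annotated toy VCF; return exact per-sample load ground truth.

    Genotypes are i.i.d.: hom-alt with probability ``hom_alt_prob``, the
    remainder split evenly between het and hom-ref.  The returned frame has
    one row per sample with the true count of homozygous-alternate
    MODERATE- or HIGH-impact variants.
    """
    if min(n_samples, n_variants) < 1:
        raise ValidationError("counts must be >= 1")
    if not 0.0 <= hom_alt_prob <= 1.0:
        raise ValidationError("hom_alt_prob must be in [0,1]")
    probs = np.array([impact_probs.get(k, 0.0) for k in IMPACT_LEVELS], dtype=float)
    if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
        raise ValidationError("impact probabilities must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    impacts = rng.choice(IMPACT_LEVELS, size=n_variants, p=probs)
    u = rng.random((n_samples, n_variants))
    g = np.where(u < hom_alt_prob, 2, np.where(u < hom_alt_prob + (1 - hom_alt_prob) / 2, 1, 0))
    g = g.astype(np.int8)
    sample_ids = [f"s{i}" for i in range(n_samples)]
    pos = np.arange(1, n_variants + 1) * 100
    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.array(["chr1"] * n_variants, dtype=object),
        pos=pos,
        genotypes=g,
    )
    impact_map = {("chr1", int(p)): str(im) for p, im in zip(pos, impacts)}
    write_vcf(path, gm, impacts=impact_map)
    deleterious = np.isin(impacts, ("MODERATE", "HIGH"))
    truth = ((g == 2) & deleterious[None, :]).sum(axis=1)
    return pd.DataFrame({"sample_id": sample_ids, "true_load": truth})


# ------------------------------------------------- serial-founder expansion load
def simulate_expansion_load(
    n_demes: int = 8,
    founders: int = 10,
    n_variants: int = 400,
    p0: float = 0.05,
    deme_spacing_km: float = 300.0,
    n_samples_per_deme: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Serial founder events along an expansion route.

    Deleterious-labelled variants start at frequency ``p0`` in the origin
    deme; each colonisation step resamples frequencies through a founder
    bottleneck of ``founders`` diploids.  Drift inflates E[p^2], so the
    expected per-individual count of homozygous deleterious genotypes rises
    with distance from the origin.  Returns one row per sampled individual
    with its homozygous-deleterious count and route distance.
    """
    if n_demes < 2:
        raise ValidationError("need at least two demes")
    rng = np.random.default_rng(seed)
    p = np.full(n_variants, p0)
    rows = []
    for d in range(n_demes):
        if d > 0:
            p = rng.binomial(2 * founders, p) / (2.0 * founders)
        for i in range(n_samples_per_deme):
            g = rng.binomial(2, p)
            rows.append(
                {
                    "sample_id": f"d{d}_s{i}",
                    "population": f"deme_{d}",
                    "distance_km": max(d * deme_spacing_km, 1.0),
                    "load": int((g == 2).sum()),
                }
            )
    return pd.DataFrame(rows)
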