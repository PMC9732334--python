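"""Diploid genotype table used throughout the pipeline.

Genotypes are stored as the per-sample count of derived (or alternate)
alleles at each biallelic site: 0, 1, 2, or -1 for missing.  Positions are
1-based, as in VCF, and strictly increasing within each chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Samples x sites table of diploid allele counts.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row of ``genotypes``.
    chrom
        Chromosome / locus name per site.
    pos
        1-based position per site, strictly increasing within chromosome.
    genotypes
        int8 array of shape (n_samples, n_sites) with values in
        {0, 1, 2, MISSING}.
    polarized
        True when allele 0 is the ancestral allele (unfolded orientation).
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    genotypes: np.ndarray
    polarized: bool = False
    ploidy: int = field(default=2, init=False)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if len(self.sample_ids) < 1:
            raise ValidationError("at least one sample required")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample ids must be unique")
        if self.genotypes.ndim != 2:
            raise ValidationError("genotypes must be 2-D (samples x sites)")
        if self.genotypes.shape != (len(self.sample_ids), len(self.pos)):
            raise ValidationError(
                f"genotype shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.pos)} sites"
            )
        if len(self.chrom) != len(self.pos):
            raise ValidationError("chrom and pos must have equal length")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError("genotype values must be in {0,1,2,missing}")
        self._check_sorted()

    def _check_sorted(self) -> None:
        if self.n_sites < 2:
            return
        same = self.chrom[1:] == self.chrom[:-1]
        if np.any(same & (np.diff(self.pos) <= 0)):
            raise ValidationError("positions must be strictly increasing within chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (order preserved)."""
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            genotypes=self.genotypes[:, idx],
            polarized=self.polarized,
        )

    def take_samples(self, ids: list[str]) -> "GenotypeMatrix":
        """New matrix restricted to the given samples, in the given order."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise ValidationError(f"unknown samples: {missing}")
        rows = [lookup[s] for s in ids]
        return GenotypeMatrix(
            sample_ids=list(ids),
            chrom=self.chrom,
            pos=self.pos,
            genotypes=self.genotypes[rows, :],
            polarized=self.polarized,
        )

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (ref/ancestral count, alt/derived count) over called genotypes."""
        called = self.genotypes != MISSING
        alt = np.where(called, self.genotypes, 0).sum(axis=0)
        ref = 2 * called.sum(axis=0) - alt
        return ref.astype(np.int64), alt.astype(np.int64)
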