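"""Variant filters and joint unfolded site-frequency spectra.

The study design pools super-populations of three nearby single individuals
(haploid size 6 each) and computes multidimensional unfolded spectra over
them.  Structure/tree site sets use a strict minor-allele-count filter
(MAC > 3) and 20 kb thinning; SFS fitting uses unfiltered sites, so both
filters are explicit, separate operations here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .genotypes import MISSING, GenotypeMatrix
from .io_formats import SampleMetadata

logger = logging.getLogger("parapop")


@dataclass
class JointSFS:
    """Unfolded joint SFS: counts over derived-allele-count tuples.

    ``counts[c1, ..., ck]`` is the number of sites where population p holds
    exactly ``c_p`` derived alleles among its ``sample_sizes[p]`` haploid
    genomes.  The fixed-ancestral (0,...,0) and fixed-derived (n1,...,nk)
    cells are populated but excluded by :meth:`polymorphic_mask`.
    """

    pop_labels: list[str]
    sample_sizes: list[int]  # haploid
    counts: np.ndarray
    polarized: bool = True
    n_dropped: int = 0  # sites dropped for missing genotypes

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        expected = tuple(n + 1 for n in self.sample_sizes)
        if self.counts.shape != expected:
            raise ValidationError(
                f"SFS shape {self.counts.shape} does not match sample sizes {expected}"
            )
        if (self.counts < 0).any():
            raise ValidationError("SFS counts must be non-negative")
        if len(self.pop_labels) != len(self.sample_sizes):
            raise ValidationError("labels and sample sizes differ in length")

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    def polymorphic_mask(self) -> np.ndarray:
        """Boolean mask over cells that are polymorphic in the pooled sample."""
        grids = np.indices(self.counts.shape)
        total = grids.sum(axis=0)
        return (total > 0) & (total < sum(self.sample_sizes))

    def data_hash(self) -> str:
        import hashlib

        h = hashlib.sha1()
        h.update(",".join(self.pop_labels).encode())
        h.update(self.counts.tobytes())
        return h.hexdigest()


def filter_biallelic_mac(g: GenotypeMatrix, mac_min: int = 3) -> GenotypeMatrix:
    """Keep biallelic sites with minor allele count strictly greater than ``mac_min``.

    Missing genotypes are excluded from the counts; monomorphic sites (one
    observed allele) are removed.  The study value is ``mac_min = 3``
    ("minor allele count > 3").
    """
    ref, alt = g.allele_counts()
    minor = np.minimum(ref, alt)
    keep = (ref > 0) & (alt > 0) & (minor > mac_min)
    logger.info(
        "filter_biallelic_mac(mac>%d): %d sites read, %d kept, %d removed",
        mac_min, g.n_sites, int(keep.sum()), int((~keep).sum()),
    )
    return g.take_sites(np.flatnonzero(keep))


def thin_by_distance(g: GenotypeMatrix, min_bp: int = 20_000) -> GenotypeMatrix:
    """Greedy left-to-right thinning: keep a site iff it is >= ``min_bp`` after
    the last kept site on the same chromosome; the first site of each
    chromosome is always kept.  The study value is 20 kb.
    """
    if min_bp < 0:
        raise ValidationError("min_bp must be >= 0")
    keep = np.zeros(g.n_sites, dtype=bool)
    last_chrom = None
    last_pos = None
    for j in range(g.n_sites):
        c, p = g.chrom[j], int(g.pos[j])
        if c != last_chrom or p - last_pos >= min_bp:
            keep[j] = True
            last_chrom, last_pos = c, p
    logger.info(
        "thin_by_distance(%d bp): %d sites read, %d kept", min_bp, g.n_sites, int(keep.sum())
    )
    return g.take_sites(np.flatnonzero(keep))


def pool_superpopulations(
    g: GenotypeMatrix,
    metadata: list[SampleMetadata],
    mapping: dict[str, str],
) -> dict[str, list[str]]:
    """Group the matrix's samples into super-populations.

    ``mapping`` sends each population label to its super-population.  Every
    sample of ``g`` must be mapped; returns an ordered
    super-population -> sample-id grouping (haploid size = 2 x samples).
    """
    if not mapping:
        raise ValidationError("empty population mapping")
    meta = {m.sample_id: m for m in metadata}
    groups: dict[str, list[str]] = {}
    for s in g.sample_ids:
        if s not in meta:
            raise ValidationError(f"sample {s} missing from metadata")
        pop = meta[s].population
        if pop not in mapping:
            raise ValidationError(f"population {pop!r} (sample {s}) not mapped")
        groups.setdefault(mapping[pop], []).append(s)
    return groups


def compute_joint_sfs(
    g: GenotypeMatrix, super_pops: dict[str, list[str]]
) -> JointSFS:
    """Tally the joint unfolded SFS over the given super-population grouping.

    Requires a polarized matrix (allele 0 ancestral).  Sites with any
    missing genotype among the pooled samples are dropped and counted in
    ``n_dropped``.
    """
    if not g.polarized:
        raise ValidationError("compute_joint_sfs requires polarized genotypes")
    if not super_pops:
        raise ValidationError("no super-populations given")
    labels = list(super_pops)
    subs = [g.take_samples(super_pops[lab]) for lab in labels]
    sizes = [2 * len(super_pops[lab]) for lab in labels]
    per_pop = np.stack(
        [
            np.where(s.genotypes == MISSING, -1000, s.genotypes.astype(np.int64)).sum(axis=0)
            for s in subs
        ]
    )  # (k, sites); any missing drives the sum far negative
    ok = (per_pop >= 0).all(axis=0)
    n_dropped = int((~ok).sum())
    counts = np.zeros(tuple(n + 1 for n in sizes), dtype=np.int64)
    np.add.at(counts, tuple(per_pop[:, ok]), 1)
    if n_dropped:
        logger.info("compute_joint_sfs: dropped %d sites with missing genotypes", n_dropped)
    return JointSFS(
        pop_labels=labels, sample_sizes=sizes, counts=counts, polarized=True,
        n_dropped=n_dropped,
    )


def sfs_from_probabilities(
    probs: np.ndarray, labels: list[str], n_sites: int, rng
) -> JointSFS:
    """Multinomial draw of ``n_sites`` sites from cell probabilities (bootstrap)."""
    flat = np.asarray(probs, dtype=float).ravel()
    counts = rng.multinomial(n_sites, flat / flat.sum()).reshape(probs.shape)
    return JointSFS(
        pop_labels=list(labels),
        sample_sizes=[d - 1 for d in probs.shape],
        counts=counts,
    )


# ----------------------------------------------------------------- text layout
def write_sfs(path: str, sfs: JointSFS) -> None:
    """Documented text layout: header lines, then one line per nonzero cell."""
    with open(path, "w") as fh:
        fh.write(f"#labels\t{','.join(sfs.pop_labels)}\n")
        fh.write(f"#haploid_sizes\t{','.join(map(str, sfs.sample_sizes))}\n")
        fh.write(f"#polarized\t{int(sfs.polarized)}\n")
        fh.write(f"#dropped_sites\t{sfs.n_dropped}\n")
        for idx in np.argwhere(sfs.counts > 0):
            cell = "\t".join(map(str, idx))
            fh.write(f"{cell}\t{int(sfs.counts[tuple(idx)])}\n")


def read_sfs(path: str) -> JointSFS:
    labels: list[str] = []
    sizes: list[int] = []
    polarized = True
    dropped = 0
    cells = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#labels"):
                labels = line.split("\t")[1].split(",")
            elif line.startswith("#haploid_sizes"):
                sizes = [int(x) for x in line.split("\t")[1].split(",")]
            elif line.startswith("#polarized"):
                polarized = bool(int(line.split("\t")[1]))
            elif line.startswith("#dropped_sites"):
                dropped = int(line.split("\t")[1])
            elif not line.startswith("#"):
                cells.append([int(x) for x in line.split("\t")])
    if not labels or not sizes:
        raise ValidationError(f"{path}: missing SFS header lines")
    counts = np.zeros(tuple(n + 1 for n in sizes), dtype=np.int64)
    for row in cells:
        counts[tuple(row[:-1])] = row[-1]
    return JointSFS(
        pop_labels=labels, sample_sizes=sizes, counts=counts, polarized=polarized,
        n_dropped=dropped,
    )
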