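"""Introgression, mating-system and individual-LD statistics.

* Patterson's D (ABBA-BABA) in allele-frequency form with delete-one block
  jackknife standard errors;
* multilocus F_IS with sample-size-corrected expected heterozygosity;
* equilibrium conversions between F, selfing rate s and outcrossing rate t
  (F = s/(2-s), t = 1-s), plus an optional empirical calibration table;
* the detection-corrected progeny-array outcrossing-rate estimator;
* the correlation of zygosity Delta(d) — within-genome correlation of
  heterozygosity status between sites at distance d — and the LD extent,
  the distance at which the first-bin-scaled Delta decays to a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import ValidationError
from .genotypes import MISSING, GenotypeMatrix
from .synthetic import ProgenyArray

__all__ = [
    "DStatResult",
    "MatingSystemEstimate",
    "ZygosityProfile",
    "LdExtent",
    "patterson_d",
    "fis_multilocus",
    "mating_conversions",
    "outcrossing_progeny_array",
    "correlation_of_zygosity",
    "zygosity_profile_from_genotypes",
    "ld_extent",
]


# ------------------------------------------------------------------ Patterson D
@dataclass
class DStatResult:
    d: float
    abba: float
    baba: float
    se: float
    z: float
    n_blocks: int
    undefined: bool = False  # ABBA + BABA == 0
    jackknife_refused: bool = False  # fewer than 3 non-empty blocks


def _set_freqs(g: GenotypeMatrix, samples: list[str]) -> np.ndarray:
    sub = g.take_samples(samples)
    called = sub.genotypes != MISSING
    n = 2.0 * called.sum(axis=0)
    alt = np.where(called, sub.genotypes, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, alt / n, np.nan)


def patterson_d(
    g: GenotypeMatrix,
    quartet: tuple[list[str], list[str], list[str], list[str]],
    block_size_bp: int = 1_000_000,
) -> DStatResult:
    """Patterson's D over a (P1, P2, P3, outgroup) quartet of sample sets.

    Allele-frequency form: ABBA = sum (1-p1) p2 p3 (1-p4), BABA = sum
    p1 (1-p2) p3 (1-p4); D = (ABBA - BABA) / (ABBA + BABA).  The standard
    error comes from a delete-one jackknife over contiguous genomic blocks
    of ``block_size_bp``; Z = D / SE.  With fewer than 3 non-empty blocks
    the jackknife is refused (SE and Z are NaN, flagged); ABBA + BABA = 0
    yields an undefined-D flag.
    """
    if len(quartet) != 4:
        raise ValidationError("quartet must have four sample sets")
    flat = [s for grp in quartet for s in grp]
    if len(flat) != len(set(flat)):
        raise ValidationError("quartet sample sets must be disjoint")
    p = [_set_freqs(g, list(grp)) for grp in quartet]
    ok = ~np.any([np.isnan(x) for x in p], axis=0)
    p1, p2, p3, p4 = (x[ok] for x in p)
    abba_site = (1 - p1) * p2 * p3 * (1 - p4)
    baba_site = p1 * (1 - p2) * p3 * (1 - p4)
    abba, baba = float(abba_site.sum()), float(baba_site.sum())
    den = abba + baba
    if den == 0:
        return DStatResult(
            d=float("nan"), abba=abba, baba=baba, se=float("nan"), z=float("nan"),
            n_blocks=0, undefined=True, jackknife_refused=True,
        )
    d = (abba - baba) / den

    block_ids = np.array(
        [f"{c}:{(int(x) - 1) // block_size_bp}" for c, x in zip(g.chrom[ok], g.pos[ok])]
    )
    blocks = np.unique(block_ids)
    n_blocks = len(blocks)
    if n_blocks < 3:
        return DStatResult(
            d=d, abba=abba, baba=baba, se=float("nan"), z=float("nan"),
            n_blocks=n_blocks, jackknife_refused=True,
        )
    num = abba - baba
    d_jack = np.empty(n_blocks)
    for i, b in enumerate(blocks):
        inb = block_ids == b
        num_b = float((abba_site[inb] - baba_site[inb]).sum())
        den_b = float((abba_site[inb] + baba_site[inb]).sum())
        d_jack[i] = (num - num_b) / (den - den_b) if den - den_b != 0 else d
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((d_jack - d_jack.mean()) ** 2)))
    z = d / se if se > 0 else float("nan")
    return DStatResult(d=d, abba=abba, baba=baba, se=se, z=z, n_blocks=n_blocks)


# ----------------------------------------------------------------- mating system
@dataclass
class MatingSystemEstimate:
    fis: float
    fis_per_locus: np.ndarray | None
    t_m: float
    sd: float
    method: str  # fis_equilibrium | progeny_array
    undefined: bool = False
    n_excluded: int = 0  # progeny records incompatible with their mother

    def __post_init__(self) -> None:
        if not self.undefined:
            if np.isfinite(self.t_m) and not 0.0 <= self.t_m <= 1.0:
                raise ValidationError("t_m must lie in [0,1]")
            if np.isfinite(self.sd) and self.sd < 0:
                raise ValidationError("sd must be >= 0")


def fis_multilocus(g: GenotypeMatrix) -> MatingSystemEstimate:
    """Multilocus inbreeding coefficient for one population.

    Per polymorphic locus, H_obs is the heterozygote fraction and
    H_exp = 2 p q n/(n-1) the sample-size-corrected expected
    heterozygosity; the multilocus estimate is
    F_IS = 1 - sum(H_obs) / sum(H_exp).  With no polymorphic locus the
    estimate is undefined (flagged), mirroring populations where F_IS
    cannot be determined for lack of polymorphism.
    """
    if g.n_samples < 2:
        raise ValidationError("F_IS needs at least two samples")
    called = g.genotypes != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, g.genotypes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
        h_obs = np.where(n > 0, (g.genotypes == 1).sum(axis=0) / n, np.nan)
        h_exp = 2 * p * (1 - p) * n / (n - 1)
    poly = (n >= 2) & (p > 0) & (p < 1)
    if not poly.any():
        return MatingSystemEstimate(
            fis=float("nan"), fis_per_locus=None, t_m=float("nan"), sd=float("nan"),
            method="fis_equilibrium", undefined=True,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(poly, 1 - h_obs / h_exp, np.nan)
    fis = float(1 - h_obs[poly].sum() / h_exp[poly].sum())
    t = float(np.clip((1 - fis) / (1 + fis), 0.0, 1.0))
    return MatingSystemEstimate(
        fis=fis, fis_per_locus=per_locus, t_m=t, sd=float("nan"),
        method="fis_equilibrium",
    )


def mating_conversions(
    F: float | None = None,
    s: float | None = None,
    t: float | None = None,
    calibration: np.ndarray | None = None,
) -> dict[str, float]:
    """Convert between inbreeding coefficient F, selfing rate s and
    outcrossing rate t under mixed-mating equilibrium.

    Identities: F = s/(2-s), s = 2F/(1+F), t = 1-s = (1-F)/(1+F).  Exactly
    one of F, s, t must be given.  ``calibration`` optionally supplies an
    empirical F -> t curve as an (m, 2) array; when present it replaces the
    equilibrium F -> t mapping by linear interpolation.
    """
    given = [x is not None for x in (F, s, t)]
    if sum(given) != 1:
        raise ValidationError("give exactly one of F, s, t")
    if F is not None:
        if not 0.0 <= F <= 1.0:
            raise ValidationError("F out of [0,1]")
        s = 2 * F / (1 + F)
    elif s is not None:
        if not 0.0 <= s <= 1.0:
            raise ValidationError("s out of [0,1]")
    else:
        if not 0.0 <= t <= 1.0:
            raise ValidationError("t out of [0,1]")
        s = 1.0 - t
    F = s / (2.0 - s)
    t = 1.0 - s
    if calibration is not None:
        cal = np.asarray(calibration, dtype=float)
        if cal.ndim != 2 or cal.shape[1] != 2:
            raise ValidationError("calibration must be an (m, 2) array of (F, t)")
        order = np.argsort(cal[:, 0])
        t = float(np.interp(F, cal[order, 0], cal[order, 1]))
        s = 1.0 - t
    return {"F": float(F), "s": float(s), "t": float(t)}


def _alleles(genotype: int) -> set[int]:
    return {0} if genotype == 0 else ({1} if genotype == 2 else {0, 1})


def outcrossing_progeny_array(
    arrays: list[ProgenyArray],
    n_boot: int = 200,
    seed: int = 0,
    pollen_freqs: str = "stored",
) -> MatingSystemEstimate:
    """Detection-corrected multilocus outcrossing rate from progeny arrays.

    An offspring is detected as outcrossed iff at some locus it carries an
    allele absent from its mother.  Given outcrossing, the per-family
    detection probability is P_det = 1 - prod_l P(pollen allele within
    maternal alleles at l); the estimate is
    t_m = (detected fraction) / mean(P_det), truncated to [0, 1], with a
    bootstrap over families for the standard deviation.  Offspring carrying
    no maternal allele at some locus are genotyping errors: excluded and
    counted.  ``pollen_freqs='maternal'`` replaces stored pollen-pool
    frequencies by allele frequencies among the maternal plants.
    """
    if not arrays:
        raise ValidationError("no progeny arrays given")
    if pollen_freqs not in ("stored", "maternal"):
        raise ValidationError("pollen_freqs must be 'stored' or 'maternal'")
    if pollen_freqs == "maternal":
        moms = np.stack([a.maternal_genotype for a in arrays])
        shared = moms.mean(axis=0) / 2.0
    fam_detected: list[np.ndarray] = []
    fam_pdet: list[float] = []
    n_excluded = 0
    for arr in arrays:
        pollen = shared if pollen_freqs == "maternal" else arr.pollen_pool_freqs
        mom_sets = [_alleles(int(v)) for v in arr.maternal_genotype]
        q = 1.0
        for l, ms in enumerate(mom_sets):
            if ms == {0, 1}:
                continue
            q *= (1.0 - pollen[l]) if ms == {0} else pollen[l]
        p_det = 1.0 - q
        det = []
        for o in range(arr.n_offspring):
            off = arr.offspring_genotypes[o]
            error = False
            outcrossed = False
            for l, ms in enumerate(mom_sets):
                alleles = _alleles(int(off[l]))
                if not (alleles & ms):
                    error = True
                    break
                if not (alleles <= ms):
                    outcrossed = True
            if error:
                n_excluded += 1
            else:
                det.append(outcrossed)
        if det:
            fam_detected.append(np.array(det, dtype=bool))
            fam_pdet.append(p_det)
    if not fam_detected:
        raise ValidationError("no usable offspring after exclusions")

    def estimate(idx: np.ndarray) -> float:
        det = np.concatenate([fam_detected[i] for i in idx])
        pdet = np.concatenate(
            [np.full(len(fam_detected[i]), fam_pdet[i]) for i in idx]
        )
        mean_pdet = float(pdet.mean())
        if mean_pdet == 0.0:
            return float("nan")
        return float(np.clip(det.mean() / mean_pdet, 0.0, 1.0))

    all_idx = np.arange(len(fam_detected))
    t_hat = estimate(all_idx)
    if np.isnan(t_hat):
        return MatingSystemEstimate(
            fis=float("nan"), fis_per_locus=None, t_m=float("nan"), sd=float("nan"),
            method="progeny_array", undefined=True, n_excluded=n_excluded,
        )
    rng = np.random.default_rng(seed)
    boots = np.array(
        [
            estimate(rng.integers(len(fam_detected), size=len(fam_detected)))
            for _ in range(n_boot)
        ]
    )
    sd = float(np.nanstd(boots))
    return MatingSystemEstimate(
        fis=float("nan"), fis_per_locus=None, t_m=t_hat, sd=sd,
        method="progeny_array", n_excluded=n_excluded,
    )


# ------------------------------------------------------- correlation of zygosity
@dataclass
class ZygosityProfile:
    individual_id: str
    theta: float
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    delta: np.ndarray  # Pearson correlation per bin
    delta_cov_scaled: np.ndarray  # covariance / (theta (1-theta)) variant
    n_pairs: np.ndarray
    undefined: bool = False


@dataclass
class LdExtent:
    extent_bp: float
    censored: bool


@njit(cache=True)
def _pair_stats(z, pos, region, edges, strides):
    nb = len(edges) - 1
    stats = np.zeros((nb, 6))
    n = len(z)
    for b in range(nb):
        for i in range(0, n, strides[b]):
            j0 = np.searchsorted(pos, pos[i] + edges[b])
            j1 = np.searchsorted(pos, pos[i] + edges[b + 1])
            for j in range(j0, j1):
                if j == i or region[j] != region[i]:
                    continue
                a = z[i]
                c = z[j]
                stats[b, 0] += 1.0
                stats[b, 1] += a
                stats[b, 2] += c
                stats[b, 3] += a * c
                stats[b, 4] += a * a
                stats[b, 5] += c * c
    return stats


def correlation_of_zygosity(
    z: np.ndarray,
    bin_edges: np.ndarray,
    pos: np.ndarray | None = None,
    regions: np.ndarray | None = None,
    individual_id: str = "ind",
    max_pairs_per_bin: int = 2_000_000,
) -> ZygosityProfile:
    """Correlation of zygosity Delta(d) over distance bins.

    ``z`` is the heterozygosity indicator over assayed sites (1 = het);
    ``pos`` are their 1-based positions (defaults to contiguous);
    ``regions`` restricts pairing to sites sharing a region label (genic
    regions in real data; pairs never span a boundary).  Per bin, Delta is
    the Pearson correlation of (z(x), z(y)) over in-bin ordered pairs; the
    covariance/theta(1-theta) variant is reported alongside.  When the
    predicted pair count exceeds ``max_pairs_per_bin`` the left-site index
    is strided, which leaves the estimate unbiased.
    """
    z = np.asarray(z, dtype=np.float64)
    if z.ndim != 1 or len(z) < 2:
        raise ValidationError("need at least two sites")
    edges = np.asarray(bin_edges, dtype=np.float64)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin edges must be strictly increasing")
    if pos is None:
        pos = np.arange(1, len(z) + 1, dtype=np.float64)
    else:
        pos = np.asarray(pos, dtype=np.float64)
        if np.any(np.diff(pos) <= 0):
            raise ValidationError("positions must be strictly increasing")
    if regions is None:
        region = np.zeros(len(z), dtype=np.int64)
    else:
        _, region = np.unique(np.asarray(regions), return_inverse=True)
        region = region.astype(np.int64)
    theta = float(z.mean())
    centers = np.sqrt(edges[:-1] * edges[1:])
    if theta == 0.0:
        nb = len(edges) - 1
        return ZygosityProfile(
            individual_id, theta, edges, centers,
            np.full(nb, np.nan), np.full(nb, np.nan), np.zeros(nb),
            undefined=True,
        )
    density = len(z) / max(pos[-1] - pos[0], 1.0)
    per_bin_pairs = len(z) * density * np.diff(edges)
    strides = np.maximum(
        1, np.ceil(per_bin_pairs / max_pairs_per_bin)
    ).astype(np.int64)
    stats = _pair_stats(z, pos, region, edges, strides)
    n = stats[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = stats[:, 3] / n - (stats[:, 1] / n) * (stats[:, 2] / n)
        var_a = stats[:, 4] / n - (stats[:, 1] / n) ** 2
        var_b = stats[:, 5] / n - (stats[:, 2] / n) ** 2
        delta = np.where(n > 1, cov / np.sqrt(var_a * var_b), np.nan)
        delta_cov = np.where(n > 1, cov / (theta * (1 - theta)), np.nan)
    return ZygosityProfile(
        individual_id=individual_id, theta=theta, bin_edges=edges,
        bin_centers=centers, delta=delta, delta_cov_scaled=delta_cov, n_pairs=n,
    )


def zygosity_profile_from_genotypes(
    g: GenotypeMatrix,
    sample: str,
    bin_edges: np.ndarray,
    mask: list[tuple[str, int, int]] | None = None,
) -> ZygosityProfile:
    """Zygosity profile of one individual from its variant-site genotypes.

    ``mask`` optionally restricts sites to BED-like (chrom, start, end)
    intervals (1-based inclusive), each interval acting as a pairing
    region; without it each chromosome is one region.
    """
    if sample not in g.sample_ids:
        raise ValidationError(f"unknown sample {sample}")
    row = g.genotypes[g.sample_ids.index(sample)]
    called = row != MISSING
    if mask is not None:
        inmask = np.zeros(g.n_sites, dtype=bool)
        region = np.full(g.n_sites, -1, dtype=np.int64)
        for k, (c, lo, hi) in enumerate(mask):
            hit = (g.chrom == c) & (g.pos >= lo) & (g.pos <= hi)
            inmask |= hit
            region[hit] = k
        called &= inmask
        regions = region[called]
    else:
        regions = g.chrom[called]
    z = (row[called] == 1).astype(float)
    order_pos = g.pos[called].astype(float)
    # offset positions per region so cross-region distances never fall in a bin
    return correlation_of_zygosity(
        z, bin_edges, pos=_region_offset(order_pos, regions), regions=regions,
        individual_id=sample,
    )


def _region_offset(pos: np.ndarray, regions: np.ndarray) -> np.ndarray:
    out = np.empty(len(pos))
    offset = 0.0
    prev = None
    last = 0.0
    for i in range(len(pos)):
        if regions[i] != prev:
            offset = last + 1e9
            prev = regions[i]
            base = pos[i]
        out[i] = offset + (pos[i] - base)
        last = out[i]
    return out + 1.0


def ld_extent(profile: ZygosityProfile, threshold: float = 0.1) -> LdExtent:
    """Distance at which the first-bin-scaled Delta decays to ``threshold``.

    Delta is rescaled by its value in the shortest-distance defined bin;
    the extent is the distance where the scaled curve first reaches the
    threshold, linearly interpolated between adjacent bin centers in log10
    distance.  A curve that never reaches the threshold is right-censored.
    """
    if profile.undefined:
        raise ValidationError("profile is undefined (theta = 0)")
    if not 0.0 < threshold <= 1.0:
        raise ValidationError("threshold must be in (0, 1]")
    ok = np.isfinite(profile.delta)
    if not ok.any():
        raise ValidationError("no defined bins in profile")
    centers = profile.bin_centers[ok]
    delta = profile.delta[ok]
    ref = delta[0]
    if ref <= 0:
        return LdExtent(extent_bp=float(centers[0]), censored=False)
    scaled = delta / ref
    if threshold >= 1.0 or scaled[0] <= threshold:
        return LdExtent(extent_bp=float(centers[0]), censored=False)
    below = np.flatnonzero(scaled <= threshold)
    if len(below) == 0:
        return LdExtent(extent_bp=float("nan"), censored=True)
    j = below[0]
    x0, x1 = np.log10(centers[j - 1]), np.log10(centers[j])
    y0, y1 = scaled[j - 1], scaled[j]
    x = x0 + (threshold - y0) * (x1 - x0) / (y1 - y0)
    return LdExtent(extent_bp=float(10**x), censored=False)
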