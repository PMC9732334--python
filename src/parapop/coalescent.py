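"""Structured-coalescent engine for splits, migration and partial selfing.

One genealogy per locus (no recombination within loci) is drawn backward in
time: within a population of diploid size N_e, k lineages coalesce at rate
k(k-1)/2 * 1/(2 N_e); lineages migrate from population i to j at backward
rate m[i][j] each; a split event at time t pools all lineages of the derived
population into the ancestral one.  Partial selfing enters through the
equilibrium identity-by-descent probability F = s/(2-s): each sampled
diploid starts as a single lineage carrying both of its haploid genomes
with probability F, and as two independent lineages otherwise.

Two consumers share the engine:

* branch-length accumulation into joint-SFS cells — the Monte-Carlo
  estimate of the expected unfolded SFS used by the composite likelihood
  (the probability that a mutation falls in a cell is proportional to the
  expected branch length subtending that sample configuration);
* explicit genotype simulation — infinite-sites mutations are dropped as a
  Poisson process (rate mu * locus_length per unit branch length) and
  assigned to unique positions, producing a polarized GenotypeMatrix.

The inner loop is numba-compiled; descendant sets are tracked as 64-bit
masks, which caps a model at 64 haploid samples.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .errors import ValidationError
from .genotypes import GenotypeMatrix
from .models import DemographicModel

__all__ = ["sfs_branch_lengths", "simulate_coalescent_sfs_data", "sfs_cell_shape"]


@njit(cache=True)
def _sim_branches(
    dip, F, sizes, mig, split_t, split_from, split_to, exist_start, radix,
    lin_pop, lin_birth, lin_cell, lin_mask, br_mask, br_cell, br_len,
):
    """Draw one genealogy; record every non-root branch (mask, cell, length).

    Returns the number of branches recorded.  Uses the global numpy RNG,
    which the caller seeds.
    """
    npop = dip.shape[0]
    k = 0
    bit = 0
    for p in range(npop):
        for _ in range(dip[p]):
            if np.random.random() < F[p]:
                lin_pop[k] = p
                lin_birth[k] = 0.0
                lin_cell[k] = 2 * radix[p]
                lin_mask[k] = np.uint64(3) << np.uint64(bit)
                k += 1
            else:
                for h in range(2):
                    lin_pop[k] = p
                    lin_birth[k] = 0.0
                    lin_cell[k] = radix[p]
                    lin_mask[k] = np.uint64(1) << np.uint64(bit + h)
                    k += 1
            bit += 2
    n_act = k
    t = 0.0
    si = 0
    nsplit = split_t.shape[0]
    merged = np.zeros(npop, np.uint8)
    cnt = np.zeros(npop, np.int64)
    nb = 0
    while n_act > 1:
        for p in range(npop):
            cnt[p] = 0
        for i in range(n_act):
            cnt[lin_pop[i]] += 1
        total = 0.0
        for p in range(npop):
            if merged[p] == 1 or cnt[p] == 0:
                continue
            total += cnt[p] * (cnt[p] - 1.0) * 0.5 / (2.0 * sizes[p])
            for j in range(npop):
                if j == p or merged[j] == 1:
                    continue
                if mig[p, j] > 0.0 and t >= exist_start[j]:
                    total += cnt[p] * mig[p, j]
        if total > 0.0:
            dt = np.random.exponential(1.0 / total)
        else:
            dt = np.inf
        if si < nsplit and t + dt >= split_t[si]:
            t = split_t[si]
            src = split_from[si]
            dst = split_to[si]
            for i in range(n_act):
                if lin_pop[i] == src:
                    lin_pop[i] = dst
            merged[src] = 1
            si += 1
            continue
        t += dt
        u = np.random.random() * total
        acc = 0.0
        done = False
        for p in range(npop):
            if merged[p] == 1 or cnt[p] == 0:
                continue
            r = cnt[p] * (cnt[p] - 1.0) * 0.5 / (2.0 * sizes[p])
            if r > 0.0 and acc + r >= u:
                # coalescence in p: two distinct uniform lineages
                a = int(np.random.random() * cnt[p])
                if a >= cnt[p]:
                    a = cnt[p] - 1
                b = int(np.random.random() * (cnt[p] - 1))
                if b >= cnt[p] - 1:
                    b = cnt[p] - 2
                if b >= a:
                    b += 1
                ia = -1
                ib = -1
                c = 0
                for i in range(n_act):
                    if lin_pop[i] == p:
                        if c == a:
                            ia = i
                        if c == b:
                            ib = i
                        c += 1
                br_mask[nb] = lin_mask[ia]
                br_cell[nb] = lin_cell[ia]
                br_len[nb] = t - lin_birth[ia]
                nb += 1
                br_mask[nb] = lin_mask[ib]
                br_cell[nb] = lin_cell[ib]
                br_len[nb] = t - lin_birth[ib]
                nb += 1
                lin_mask[ia] |= lin_mask[ib]
                lin_cell[ia] += lin_cell[ib]
                lin_birth[ia] = t
                n_act -= 1
                lin_pop[ib] = lin_pop[n_act]
                lin_birth[ib] = lin_birth[n_act]
                lin_cell[ib] = lin_cell[n_act]
                lin_mask[ib] = lin_mask[n_act]
                done = True
                break
            acc += r
            for j in range(npop):
                if j == p or merged[j] == 1:
                    continue
                if mig[p, j] > 0.0 and t >= exist_start[j]:
                    r2 = cnt[p] * mig[p, j]
                    if acc + r2 >= u:
                        a = int(np.random.random() * cnt[p])
                        if a >= cnt[p]:
                            a = cnt[p] - 1
                        c = 0
                        for i in range(n_act):
                            if lin_pop[i] == p:
                                if c == a:
                                    lin_pop[i] = j
                                    break
                                c += 1
                        done = True
                        break
                    acc += r2
            if done:
                break
        # if floating-point rounding left the event unassigned, redraw
    return nb


@njit(cache=True)
def _accumulate_sfs(
    dip, F, sizes, mig, split_t, split_from, split_to, exist_start, radix,
    ncells, n_loci, seed,
):
    np.random.seed(seed)
    out = np.zeros(ncells, np.float64)
    n = int(2 * dip.sum())
    lin_pop = np.empty(n, np.int64)
    lin_birth = np.empty(n, np.float64)
    lin_cell = np.empty(n, np.int64)
    lin_mask = np.empty(n, np.uint64)
    br_mask = np.empty(2 * n, np.uint64)
    br_cell = np.empty(2 * n, np.int64)
    br_len = np.empty(2 * n, np.float64)
    for _ in range(n_loci):
        nb = _sim_branches(
            dip, F, sizes, mig, split_t, split_from, split_to, exist_start, radix,
            lin_pop, lin_birth, lin_cell, lin_mask, br_mask, br_cell, br_len,
        )
        for b in range(nb):
            out[br_cell[b]] += br_len[b]
    return out


@njit(cache=True)
def _batch_branches(
    dip, F, sizes, mig, split_t, split_from, split_to, exist_start, radix,
    n_loci, seed, masks_out, lens_out, nb_out,
):
    np.random.seed(seed)
    n = int(2 * dip.sum())
    lin_pop = np.empty(n, np.int64)
    lin_birth = np.empty(n, np.float64)
    lin_cell = np.empty(n, np.int64)
    lin_mask = np.empty(n, np.uint64)
    br_mask = np.empty(2 * n, np.uint64)
    br_cell = np.empty(2 * n, np.int64)
    br_len = np.empty(2 * n, np.float64)
    stride = 2 * n
    for l in range(n_loci):
        nb = _sim_branches(
            dip, F, sizes, mig, split_t, split_from, split_to, exist_start, radix,
            lin_pop, lin_birth, lin_cell, lin_mask, br_mask, br_cell, br_len,
        )
        for b in range(nb):
            masks_out[l * stride + b] = br_mask[b]
            lens_out[l * stride + b] = br_len[b]
        nb_out[l] = nb


def _prepare(model: DemographicModel):
    arrays = model.engine_arrays()
    dip = arrays[0]
    n_hap = int(2 * dip.sum())
    if n_hap < 2:
        raise ValidationError("at least two haploid samples required")
    if n_hap > 64:
        raise ValidationError("engine supports at most 64 haploid samples")
    dims = (2 * dip + 1).astype(np.int64)
    radix = np.ones(len(dims), dtype=np.int64)
    for p in range(len(dims) - 2, -1, -1):
        radix[p] = radix[p + 1] * dims[p + 1]
    return arrays, dims, radix


def sfs_cell_shape(model: DemographicModel) -> tuple[int, ...]:
    """Joint-SFS array shape over the model's sampled populations (model order)."""
    dip = np.array([p.samples for p in model.populations])
    return tuple(int(2 * d + 1) for d in dip if d > 0)


def sfs_branch_lengths(model: DemographicModel, n_loci: int, seed: int) -> np.ndarray:
    """Total branch length per joint-SFS cell over ``n_loci`` genealogies.

    The returned array is shaped over the sampled populations only (in model
    declaration order); entry [c1, ..., ck] is the accumulated length of
    branches whose mutations would be carried by exactly c_p haploid genomes
    in population p.
    """
    if n_loci < 1:
        raise ValidationError("n_loci must be >= 1")
    (dip, F, sizes, mig, st, sf, sto, ex), dims, radix = _prepare(model)
    ncells = int(np.prod(dims))
    flat = _accumulate_sfs(
        dip, F, sizes, mig, st, sf, sto, ex, radix, ncells, int(n_loci),
        int(seed) % (2**31),
    )
    return flat.reshape(tuple(dims)).squeeze(
        axis=tuple(i for i, d in enumerate(dims) if d == 1)
    )


def simulate_coalescent_sfs_data(
    model: DemographicModel, n_loci: int, seed: int
) -> GenotypeMatrix:
    """Simulate polarized diploid genotypes at independent non-recombining loci.

    Each locus is a separate chromosome named ``locus_<k>``; infinite-sites
    mutations receive unique 1-based positions within [1, locus_length].
    Sample ids are ``<pop>_<i>`` in model declaration order.
    """
    if n_loci < 1:
        raise ValidationError("n_loci must be >= 1")
    (dip, F, sizes, mig, st, sf, sto, ex), dims, radix = _prepare(model)
    n_hap = int(2 * dip.sum())
    stride = 2 * n_hap
    masks = np.zeros(n_loci * stride, dtype=np.uint64)
    lens = np.zeros(n_loci * stride, dtype=np.float64)
    nb = np.zeros(n_loci, dtype=np.int64)
    ss = np.random.SeedSequence(int(seed))
    engine_seed, mut_seed = ss.spawn(2)
    _batch_branches(
        dip, F, sizes, mig, st, sf, sto, ex, radix,
        int(n_loci), int(engine_seed.generate_state(1)[0] % (2**31)),
        masks, lens, nb,
    )
    rng = np.random.default_rng(mut_seed)
    L = model.locus_length
    rate = model.mutation_rate * L
    sample_ids = [
        f"{p.label}_{i}" for p in model.populations for i in range(p.samples)
    ]
    shifts = np.arange(n_hap, dtype=np.uint64)
    chroms: list[np.ndarray] = []
    poss: list[np.ndarray] = []
    genos: list[np.ndarray] = []
    for l in range(n_loci):
        b = nb[l]
        if b == 0:
            continue
        seg_lens = lens[l * stride : l * stride + b]
        n_mut = rng.poisson(rate * seg_lens)
        total = int(n_mut.sum())
        if total == 0:
            continue
        if total > L:
            raise ValidationError(
                f"locus {l}: {total} mutations exceed locus length {L} (infinite sites)"
            )
        site_masks = np.repeat(masks[l * stride : l * stride + b], n_mut)
        pos = np.sort(rng.choice(L, size=total, replace=False)) + 1
        bits = (site_masks[:, None] >> shifts[None, :]) & np.uint64(1)
        g = (bits[:, 0::2] + bits[:, 1::2]).astype(np.int8)  # (sites, diploids)
        chroms.append(np.full(total, f"locus_{l:05d}", dtype=object))
        poss.append(pos.astype(np.int64))
        genos.append(g)
    if chroms:
        chrom = np.concatenate(chroms)
        pos = np.concatenate(poss)
        gmat = np.vstack(genos).T.copy()
    else:
        chrom = np.empty(0, dtype=object)
        pos = np.empty(0, dtype=np.int64)
        gmat = np.empty((len(sample_ids), 0), dtype=np.int8)
    return GenotypeMatrix(
        sample_ids=sample_ids, chrom=chrom, pos=pos, genotypes=gmat, polarized=True
    )
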