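"""Canonical study scenarios: the speciation model and its alternatives.

This module pins down the demographic scenarios the analyses run on, with
the derived selfing species (*A. arenicola*-like, labelled ``are``)
budding from a northwestern Lake Superior parent population (``LSa``)
6007 generations ago with low bidirectional gene flow.  Sizes and
migration rates are fixed study conditions chosen as realistic for
selfing range-edge populations (see docs/methods.md); the mutation rate
is 0.355e-8 per site per generation and super-populations pool three
diploid individuals (haploid size 6), matching the study design.
"""

from __future__ import annotations

import numpy as np

from .coalescent import simulate_coalescent_sfs_data
from .genotypes import GenotypeMatrix
from .models import DemographicModel, FreeParameter, Population, SplitEvent
from .sfs import JointSFS, compute_joint_sfs

#: best-model split time between the derived species and its parent, generations
SPLIT_TIME_GENERATIONS = 6007.0

#: bounds for the free split time in the refit, generations (log-uniform starts)
SPLIT_TIME_BOUNDS = (500.0, 50_000.0)


def best_split_model(
    split_time: float = SPLIT_TIME_GENERATIONS, free_split: bool = True
) -> DemographicModel:
    """Two-population split-with-gene-flow model of the speciation event.

    ``LSa`` (parent, N_e = 10,000) and ``are`` (derived, N_e = 5,000), each
    sampled as one super-population of 3 diploids; the derived population
    merges into the parent at ``split_time`` generations; bidirectional
    migration at 1e-5 per generation; 10 kb non-recombining loci.
    """
    free = (
        [FreeParameter("split_time:are", SPLIT_TIME_BOUNDS, log=True)]
        if free_split
        else []
    )
    return DemographicModel(
        populations=[
            Population("LSa", 10_000.0, selfing=0.0, samples=3),
            Population("are", 5_000.0, selfing=0.0, samples=3),
        ],
        splits=[SplitEvent(float(split_time), "are", "LSa")],
        migration={("LSa", "are"): 1e-5, ("are", "LSa"): 1e-5},
        mutation_rate=0.355e-8,
        locus_length=10_000,
        free_parameters=free,
        model_id="split_gene_flow",
    )


def sample_groups(g: GenotypeMatrix) -> dict[str, list[str]]:
    """Group simulated samples by their population prefix (``<pop>_<i>``)."""
    groups: dict[str, list[str]] = {}
    for s in g.sample_ids:
        groups.setdefault(s.rsplit("_", 1)[0], []).append(s)
    return groups


def simulate_split_sfs(n_loci: int, seed: int, split_time: float = SPLIT_TIME_GENERATIONS) -> JointSFS:
    """Joint unfolded SFS of a dataset simulated under the best split model."""
    g = simulate_coalescent_sfs_data(best_split_model(split_time), n_loci, seed)
    return compute_joint_sfs(g, sample_groups(g))


# ------------------------------------------------- hierarchical-selection demo
def backbone_trio_model(inner: str, mid: str, model_id: str) -> DemographicModel:
    """Three backbone populations; ``inner`` splits from P1 recently (free
    time), ``mid`` at 9000 generations — a topology candidate."""
    return DemographicModel(
        populations=[
            Population("P1", 5_000.0, samples=2),
            Population("P2", 5_000.0, samples=2),
            Population("P3", 5_000.0, samples=2),
        ],
        splits=[SplitEvent(3000.0, inner, "P1"), SplitEvent(9000.0, mid, "P1")],
        mutation_rate=0.355e-8,
        locus_length=10_000,
        free_parameters=[FreeParameter(f"split_time:{inner}", (200.0, 8000.0), log=True)],
        model_id=model_id,
    )


def placement_quad_model(host: str, model_id: str) -> DemographicModel:
    """Backbone plus the derived selfer ``ARE`` attached to ``host`` — a
    placement candidate for the second selection step."""
    return DemographicModel(
        populations=[
            Population("P1", 5_000.0, samples=2),
            Population("P2", 5_000.0, samples=2),
            Population("P3", 5_000.0, samples=2),
            Population("ARE", 2_000.0, samples=2),
        ],
        splits=[
            SplitEvent(1000.0, "ARE", host),
            SplitEvent(3000.0, "P2", "P1"),
            SplitEvent(9000.0, "P3", "P1"),
        ],
        mutation_rate=0.355e-8,
        locus_length=10_000,
        free_parameters=[FreeParameter("split_time:ARE", (100.0, 2500.0), log=True)],
        model_id=model_id,
    )


def quartet_null_model() -> DemographicModel:
    """(((P1,P2),P3),OUT) with no gene flow — the Patterson's D null."""
    return DemographicModel(
        populations=[
            Population("P1", 10_000.0, samples=1),
            Population("P2", 10_000.0, samples=1),
            Population("P3", 10_000.0, samples=1),
            Population("OUT", 10_000.0, samples=1),
        ],
        splits=[
            SplitEvent(4000.0, "P2", "P1"),
            SplitEvent(10_000.0, "P3", "P1"),
            SplitEvent(40_000.0, "OUT", "P1"),
        ],
        mutation_rate=0.355e-8,
        locus_length=10_000,
        model_id="quartet_null",
    )
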