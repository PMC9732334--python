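"""Mutational load, expansion-route distances, and the load-distance regression.

Per-sample load is the count of variants at which the sample is homozygous
for the alternate allele and the SnpEff impact is MODERATE or HIGH
(missense changes; start/stop-codon changes).  Expansion distances are
great-circle sums along an ordered route of map nodes, and load is
regressed on log10 distance by ordinary least squares.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .genotypes import MISSING
from .io_formats import AnnotatedVariant, SampleMetadata

logger = logging.getLogger("parapop")

EARTH_RADIUS_KM = 6371.0088

DELETERIOUS_IMPACTS = ("MODERATE", "HIGH")


@dataclass
class LoadRecord:
    sample_id: str
    n_hom_moderate: int
    n_hom_high: int
    population: str = ""
    expansion_distance_km: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_hom_moderate < 0 or self.n_hom_high < 0:
            raise ValidationError("load counts must be non-negative")

    @property
    def load(self) -> int:
        return self.n_hom_moderate + self.n_hom_high


@dataclass
class ExpansionRoute:
    """Ordered (label, latitude, longitude) nodes from the expansion origin
    out to a terminal sampling site."""

    nodes: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        if len(self.nodes) < 1:
            raise ValidationError("route needs at least one node")
        for label, lat, lon in self.nodes:
            if not -90.0 <= lat <= 90.0 or not -180.0 <= lon <= 180.0:
                raise ValidationError(f"route node {label}: coordinates out of range")


def count_load(
    variants: list[AnnotatedVariant], sample_ids: list[str], sample: str
) -> LoadRecord:
    """Count homozygous-alternate MODERATE and HIGH impact variants for one sample.

    Heterozygous and homozygous-reference genotypes never count; missing
    genotypes are skipped.
    """
    if sample not in sample_ids:
        raise ValidationError(f"sample {sample} not among {len(sample_ids)} samples")
    i = sample_ids.index(sample)
    n_mod = n_high = 0
    for v in variants:
        gval = int(v.genotypes[i])
        if gval == MISSING or gval != 2:
            continue
        if v.impact == "MODERATE":
            n_mod += 1
        elif v.impact == "HIGH":
            n_high += 1
    return LoadRecord(sample_id=sample, n_hom_moderate=n_mod, n_hom_high=n_high)


def load_table(
    variants: list[AnnotatedVariant],
    sample_ids: list[str],
    metadata: list[SampleMetadata] | None = None,
) -> pd.DataFrame:
    """Per-sample load records as a tidy table (one row per sample)."""
    meta = {m.sample_id: m for m in (metadata or [])}
    rows = []
    for s in sample_ids:
        rec = count_load(variants, sample_ids, s)
        rows.append(
            {
                "sample_id": s,
                "n_hom_moderate": rec.n_hom_moderate,
                "n_hom_high": rec.n_hom_high,
                "load": rec.load,
                "population": meta[s].population if s in meta else "",
            }
        )
    return pd.DataFrame(rows)


def population_mean_load(records: list[LoadRecord]) -> pd.DataFrame:
    """Arithmetic mean load per population (single-sample populations pass through)."""
    if not records:
        raise ValidationError("no load records")
    df = pd.DataFrame(
        {"population": [r.population for r in records], "load": [r.load for r in records]}
    )
    out = df.groupby("population", sort=True)["load"].agg(["mean", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_load", "count": "n_samples"})


def geodesic_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle (haversine) distance in km on a sphere of radius 6371.0088 km."""
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not -90.0 <= lat <= 90.0 or not -180.0 <= lon <= 180.0:
            raise ValidationError("coordinates out of range")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def route_distance(route: ExpansionRoute) -> float:
    """Sum of geodesic distances over consecutive route nodes (0 for one node)."""
    total = 0.0
    for (_, la1, lo1), (_, la2, lo2) in zip(route.nodes, route.nodes[1:]):
        total += geodesic_km(la1, lo1, la2, lo2)
    return total


def load_distance_regression(
    loads: np.ndarray, distances_km: np.ndarray
) -> dict[str, float]:
    """OLS of load on log10 expansion distance; two-sided t-test on the slope.

    Zero distances are offset by +1 km before the log (logged); fewer than
    3 records or constant distances refuse the regression.
    """
    loads = np.asarray(loads, dtype=float)
    d = np.asarray(distances_km, dtype=float)
    if len(loads) != len(d):
        raise ValidationError("loads and distances differ in length")
    if len(loads) < 3:
        raise ValidationError("regression needs at least 3 records")
    if np.any(d < 0):
        raise ValidationError("distances must be non-negative")
    if np.any(d == 0):
        logger.info("load_distance_regression: offsetting %d zero distances by +1 km",
                    int((d == 0).sum()))
        d = d + 1.0
    x = np.log10(d)
    if np.allclose(x, x[0]):
        raise ValidationError("regression refused: all distances equal")
    res = sps.linregress(x, loads)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "p": float(res.pvalue),
        "stderr": float(res.stderr),
        "n": len(loads),
    }
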