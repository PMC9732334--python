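"""Readers and writers for the pipeline's interchange formats.

VCF 4.x (GT genotypes, optional SnpEff-style ANN INFO field) is the genotype
interchange format; sample metadata travels as a header TSV; demographic
models are YAML documents.  Coordinates are 1-based as in VCF.  Every filter
applied during reading is counted and logged so the cascade is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
import yaml

from .errors import AnnotationMissingError, ValidationError, VcfFormatError
from .genotypes import MISSING, GenotypeMatrix
from .models import DemographicModel, model_from_dict

logger = logging.getLogger("parapop")

IMPACT_LEVELS = ("LOW", "MODERATE", "HIGH", "MODIFIER")

METADATA_COLUMNS = [
    "sample_id",
    "population",
    "super_population",
    "species",
    "latitude",
    "longitude",
    "mating_system",
]

MATING_SYSTEMS = ("outcrossing", "selfing", "unknown")


@dataclass
class AnnotatedVariant:
    """One biallelic SNP with its SnpEff impact and per-sample genotypes."""

    chrom: str
    pos: int
    ref: str
    alt: str
    impact: str
    genotypes: np.ndarray  # alt-allele counts per sample, MISSING = -1

    def __post_init__(self) -> None:
        if self.impact not in IMPACT_LEVELS:
            raise ValidationError(f"impact {self.impact!r} not in {IMPACT_LEVELS}")


@dataclass
class SampleMetadata:
    sample_id: str
    population: str
    super_population: str
    species: str
    latitude: float
    longitude: float
    mating_system: str = "unknown"

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"{self.sample_id}: latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"{self.sample_id}: longitude {self.longitude} out of range")
        if self.mating_system not in MATING_SYSTEMS:
            raise ValidationError(
                f"{self.sample_id}: mating system {self.mating_system!r} not in {MATING_SYSTEMS}"
            )


def _parse_ann_impact(ann_value) -> str:
    """Impact of the first ANN annotation (SnpEff orders most-severe first).

    ANN entries are pipe-delimited: Allele|Annotation|Annotation_Impact|...
    """
    if isinstance(ann_value, (tuple, list)):
        first = ann_value[0]
    else:
        first = str(ann_value).split(",")[0]
    fields = str(first).split("|")
    if len(fields) < 3:
        raise VcfFormatError(f"malformed ANN entry: {first!r}")
    impact = fields[2].strip()
    if impact not in IMPACT_LEVELS:
        raise VcfFormatError(f"unknown ANN impact {impact!r}")
    return impact


def read_vcf(
    path: str, require_ann: bool = False
) -> tuple[GenotypeMatrix, list[AnnotatedVariant]]:
    """Read a VCF into a GenotypeMatrix plus per-site impact annotations.

    Multiallelic records and indels are skipped (with a logged count);
    missing genotypes are preserved.  ``require_ann`` demands an ANN INFO
    definition in the header and returns one AnnotatedVariant per kept
    record that carries one.
    """
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        if "GT" not in vf.header.formats:
            raise VcfFormatError(f"{path}: no GT FORMAT field in header")
        has_ann = "ANN" in vf.header.info
        if require_ann and not has_ann:
            raise AnnotationMissingError(f"{path}: ANN INFO field required but absent")
        samples = list(vf.header.samples)
        if not samples:
            raise VcfFormatError(f"{path}: VCF has no samples")
        chroms: list[str] = []
        poss: list[int] = []
        cols: list[np.ndarray] = []
        variants: list[AnnotatedVariant] = []
        n_read = n_skipped = 0
        for rec in vf:
            n_read += 1
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                n_skipped += 1
                continue
            g = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    g[i] = MISSING
                else:
                    g[i] = sum(1 for a in gt if a == 1)
            chroms.append(rec.chrom)
            poss.append(rec.pos)
            cols.append(g)
            if has_ann and "ANN" in rec.info:
                variants.append(
                    AnnotatedVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alts[0],
                        impact=_parse_ann_impact(rec.info["ANN"]),
                        genotypes=g.copy(),
                    )
                )
    logger.info(
        "read_vcf %s: %d records read, %d kept, %d skipped (multiallelic/indel)",
        path, n_read, n_read - n_skipped, n_skipped,
    )
    gm = GenotypeMatrix(
        sample_ids=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        genotypes=np.array(cols, dtype=np.int8).T.reshape(len(samples), -1)
        if cols
        else np.empty((len(samples), 0), dtype=np.int8),
        polarized=False,
    )
    return gm, variants


def write_vcf(
    path: str,
    g: GenotypeMatrix,
    impacts: dict[tuple[str, int], str] | None = None,
    ref: str = "A",
    alt: str = "T",
) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF.

    ``impacts`` maps (chrom, pos) to an impact level, emitted as a minimal
    single-annotation ANN INFO entry; sites without an entry carry no ANN.
    """
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(g.chrom.tolist()):
        header.contigs.add(str(chrom))
    header.formats.add("GT", 1, "String", "Genotype")
    if impacts is not None:
        header.info.add(
            "ANN", ".", "String",
            "Functional annotations: 'Allele|Annotation|Annotation_Impact|Gene_Name'",
        )
    for s in g.sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for j in range(g.n_sites):
            rec = out.new_record(
                contig=str(g.chrom[j]), start=int(g.pos[j]) - 1,
                alleles=(ref, alt), id=".",
            )
            if impacts is not None:
                imp = impacts.get((str(g.chrom[j]), int(g.pos[j])))
                if imp is not None:
                    rec.info["ANN"] = f"{alt}|variant|{imp}|."
            for i, s in enumerate(g.sample_ids):
                v = int(g.genotypes[i, j])
                rec.samples[s]["GT"] = (
                    (None, None) if v == MISSING else ((0, 0), (0, 1), (1, 1))[v]
                )
            out.write(rec)


def read_metadata(path: str) -> list[SampleMetadata]:
    """Read the sample metadata TSV (header columns per METADATA_COLUMNS)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = [c for c in METADATA_COLUMNS if c != "mating_system"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {missing}")
    if "mating_system" not in df.columns:
        df["mating_system"] = "unknown"
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: duplicate sample ids {dups}")
    out = []
    for row in df.itertuples(index=False):
        ms = row.mating_system
        if pd.isna(ms) or str(ms).strip() == "":
            ms = "unknown"
        out.append(
            SampleMetadata(
                sample_id=str(row.sample_id),
                population=str(row.population),
                super_population=str(row.super_population),
                species=str(row.species),
                latitude=float(row.latitude),
                longitude=float(row.longitude),
                mating_system=str(ms),
            )
        )
    logger.info("read_metadata %s: %d samples", path, len(out))
    return out


def write_metadata(path: str, metadata: list[SampleMetadata]) -> None:
    pd.DataFrame([vars(m) for m in metadata]).to_csv(
        path, sep="\t", index=False, columns=METADATA_COLUMNS
    )


def load_model_config(path: str) -> DemographicModel:
    """Load and validate a demographic model from a YAML config file."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict) or "populations" not in spec:
        raise ValidationError(f"{path}: config must be a mapping with a 'populations' section")
    return model_from_dict(spec)


def save_model_config(path: str, model: DemographicModel) -> None:
    spec = {
        "model_id": model.model_id,
        "populations": [
            {"label": p.label, "size": p.size, "selfing": p.selfing, "samples": p.samples}
            for p in model.populations
        ],
        "splits": [
            {"time": ev.time, "derived": ev.derived, "ancestral": ev.ancestral}
            for ev in model.splits
        ],
        "migration": [
            {"from": src, "to": dst, "rate": rate}
            for (src, dst), rate in model.migration.items()
        ],
        "mutation_rate": model.mutation_rate,
        "locus_length": model.locus_length,
        "generation_time_years": list(model.generation_time_years),
        "free_parameters": [
            {"name": f.name, "bounds": list(f.bounds), "log": f.log}
            for f in model.free_parameters
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(spec, fh, sort_keys=False)
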