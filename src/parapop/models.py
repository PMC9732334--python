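"""Demographic models: populations, splits, migration, selfing.

Time is measured in generations backward from sampling.  A split event at
time ``t`` merges the derived population into the ancestral one (standard
backward-coalescent convention); the forward-time interpretation is that
the derived population was founded from the ancestral one ``t`` generations
ago.  Population sizes are diploid effective sizes N_e, migration rates are
per-generation backward lineage-movement rates m[i][j], and each population
carries a selfing rate s in [0, 1] which enters the coalescent through the
equilibrium identity-by-descent probability F = s / (2 - s).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: per-site per-generation mutation rate used throughout the study conditions
DEFAULT_MUTATION_RATE = 0.355e-8


@dataclass
class Population:
    label: str
    size: float  # diploid effective size N_e
    selfing: float = 0.0  # selfing rate s in [0, 1]
    samples: int = 0  # diploid individuals sampled


@dataclass
class SplitEvent:
    time: float  # generations backward
    derived: str
    ancestral: str


@dataclass
class FreeParameter:
    """A parameter left free in optimisation, addressed by a structured name.

    Names: ``split_time:<derived>``, ``size:<pop>``, ``migration:<from>><to>``.
    """

    name: str
    bounds: tuple[float, float]
    log: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValidationError(f"free parameter {self.name}: bounds must be finite with lo < hi")
        if self.log and lo <= 0:
            raise ValidationError(f"free parameter {self.name}: log scale needs positive bounds")


@dataclass
class DemographicModel:
    populations: list[Population]
    splits: list[SplitEvent] = field(default_factory=list)
    migration: dict[tuple[str, str], float] = field(default_factory=dict)
    mutation_rate: float = DEFAULT_MUTATION_RATE
    locus_length: int = 10_000
    generation_time_years: tuple[float, float] = (1.0, 2.0)
    free_parameters: list[FreeParameter] = field(default_factory=list)
    model_id: str = "model"

    # ------------------------------------------------------------------ helpers
    def pop_index(self) -> dict[str, int]:
        return {p.label: i for i, p in enumerate(self.populations)}

    def sampled_populations(self) -> list[Population]:
        return [p for p in self.populations if p.samples > 0]

    @property
    def n_haploid(self) -> int:
        return 2 * sum(p.samples for p in self.populations)

    def merge_time(self, label: str) -> float:
        for ev in self.splits:
            if ev.derived == label:
                return ev.time
        return math.inf

    def _existence_interval(self, label: str) -> tuple[float, float]:
        """Backward-time interval [start, end) during which a population holds lineages.

        Sampled populations exist from time 0; ghost populations that appear
        only as split ancestors come into existence at the earliest split that
        feeds them.
        """
        pop = next(p for p in self.populations if p.label == label)
        end = self.merge_time(label)
        if pop.samples > 0:
            return 0.0, end
        feeding = [ev.time for ev in self.splits if ev.ancestral == label]
        start = min(feeding) if feeding else 0.0
        return start, end

    # --------------------------------------------------------------- validation
    def validate(self) -> None:
        labels = [p.label for p in self.populations]
        if len(labels) != len(set(labels)):
            raise ValidationError("population labels must be unique")
        if not self.populations:
            raise ValidationError("at least one population required")
        for p in self.populations:
            if p.size <= 0:
                raise ValidationError(f"population {p.label}: N_e must be > 0")
            if not 0.0 <= p.selfing <= 1.0:
                raise ValidationError(f"population {p.label}: selfing rate must be in [0,1]")
            if p.samples < 0:
                raise ValidationError(f"population {p.label}: negative sample count")
        if self.mutation_rate < 0:
            raise ValidationError("mutation rate must be >= 0")
        if self.locus_length < 1:
            raise ValidationError("locus length must be >= 1")

        known = set(labels)
        derived_seen: set[str] = set()
        for ev in self.splits:
            if ev.derived not in known or ev.ancestral not in known:
                raise ValidationError(f"split references unknown population: {ev}")
            if ev.derived == ev.ancestral:
                raise ValidationError(f"split cannot merge a population into itself: {ev}")
            if ev.derived in derived_seen:
                raise ValidationError(f"population {ev.derived} merges twice (non-tree splits)")
            if ev.time <= 0:
                raise ValidationError("split times must be > 0")
            derived_seen.add(ev.derived)
        # times strictly ordered along any lineage path: a population must not
        # merge into an ancestor that has itself already merged away by then
        for ev in self.splits:
            anc_end = self.merge_time(ev.ancestral)
            if ev.time >= anc_end:
                raise ValidationError(
                    f"split of {ev.derived} at t={ev.time} targets {ev.ancestral}, "
                    f"which merged at t={anc_end} (non-tree split sequence)"
                )
        # the split forest must leave exactly one final population if >1 pop
        roots = [l for l in labels if math.isinf(self.merge_time(l))]
        if len(self.populations) > 1 and len(roots) != 1:
            raise ValidationError(
                f"splits must connect all populations into one tree (roots: {roots})"
            )
        for (src, dst), rate in self.migration.items():
            if src not in known or dst not in known:
                raise ValidationError(f"migration references unknown population: {src}>{dst}")
            if rate < 0:
                raise ValidationError("migration rates must be >= 0")
            s0, s1 = self._existence_interval(src)
            d0, d1 = self._existence_interval(dst)
            if min(s1, d1) <= max(s0, d0):
                raise ValidationError(
                    f"migration {src}>{dst} connects populations with no coexisting epoch"
                )
        names = [fp.name for fp in self.free_parameters]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate free parameter names")
        for fp in self.free_parameters:
            self.get_param(fp.name)  # raises if the name resolves to nothing

    # ------------------------------------------------------ parameter addressing
    def _resolve(self, name: str):
        kind, _, rest = name.partition(":")
        if kind == "split_time":
            for ev in self.splits:
                if ev.derived == rest:
                    return ("split", ev)
        elif kind == "size":
            for p in self.populations:
                if p.label == rest:
                    return ("size", p)
        elif kind == "migration":
            src, _, dst = rest.partition(">")
            if (src, dst) in self.migration:
                return ("mig", (src, dst))
        raise ValidationError(f"cannot resolve parameter name {name!r}")

    def get_param(self, name: str) -> float:
        kind, obj = self._resolve(name)
        if kind == "split":
            return obj.time
        if kind == "size":
            return obj.size
        return self.migration[obj]

    def set_param(self, name: str, value: float) -> None:
        kind, obj = self._resolve(name)
        if kind == "split":
            obj.time = float(value)
        elif kind == "size":
            obj.size = float(value)
        else:
            self.migration[obj] = float(value)

    def with_params(self, values: dict[str, float]) -> "DemographicModel":
        """Deep copy with the named parameters replaced."""
        m = copy.deepcopy(self)
        for name, value in values.items():
            m.set_param(name, value)
        return m

    # --------------------------------------------------------------- engine view
    def engine_arrays(self):
        """Flat numpy view of the model consumed by the coalescent engine."""
        self.validate()
        idx = self.pop_index()
        npop = len(self.populations)
        dip = np.array([p.samples for p in self.populations], dtype=np.int64)
        sizes = np.array([p.size for p in self.populations], dtype=np.float64)
        fself = np.array(
            [p.selfing / (2.0 - p.selfing) for p in self.populations], dtype=np.float64
        )
        mig = np.zeros((npop, npop), dtype=np.float64)
        for (src, dst), rate in self.migration.items():
            mig[idx[src], idx[dst]] = rate
        order = sorted(range(len(self.splits)), key=lambda i: self.splits[i].time)
        split_t = np.array([self.splits[i].time for i in order], dtype=np.float64)
        split_from = np.array([idx[self.splits[i].derived] for i in order], dtype=np.int64)
        split_to = np.array([idx[self.splits[i].ancestral] for i in order], dtype=np.int64)
        exist_start = np.array(
            [self._existence_interval(p.label)[0] for p in self.populations], dtype=np.float64
        )
        return dip, fself, sizes, mig, split_t, split_from, split_to, exist_start


def model_from_dict(spec: dict) -> DemographicModel:
    """Build and validate a DemographicModel from a plain mapping (config layer)."""
    try:
        pops = [
            Population(
                label=str(p["label"]),
                size=float(p["size"]),
                selfing=float(p.get("selfing", 0.0)),
                samples=int(p.get("samples", 0)),
            )
            for p in spec["populations"]
        ]
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed populations section: {exc}") from exc
    splits = [
        SplitEvent(time=float(s["time"]), derived=str(s["derived"]), ancestral=str(s["ancestral"]))
        for s in spec.get("splits", [])
    ]
    migration = {
        (str(m["from"]), str(m["to"])): float(m["rate"]) for m in spec.get("migration", [])
    }
    free = [
        FreeParameter(
            name=str(f["name"]),
            bounds=(float(f["bounds"][0]), float(f["bounds"][1])),
            log=bool(f.get("log", False)),
        )
        for f in spec.get("free_parameters", [])
    ]
    gty = spec.get("generation_time_years", (1.0, 2.0))
    if np.isscalar(gty):
        gty = (float(gty), float(gty))
    model = DemographicModel(
        populations=pops,
        splits=splits,
        migration=migration,
        mutation_rate=float(spec.get("mutation_rate", DEFAULT_MUTATION_RATE)),
        locus_length=int(spec.get("locus_length", 10_000)),
        generation_time_years=(float(gty[0]), float(gty[1])),
        free_parameters=free,
        model_id=str(spec.get("model_id", "model")),
    )
    model.validate()
    return model
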