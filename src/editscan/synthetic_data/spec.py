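"""Fixture specification and truth-table containers for the generators."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml


@dataclass(frozen=True)
class GenomePlan:
    chrom: str = "chr1"
    length: int = 30_000
    n_genes: int = 10
    exon_length: int = 150
    intron_length: int = 120
    n_duplications: int = 1
    duplication_length: int = 600
    duplication_divergence: float = 0.0
    margin: int = 300
    spacer: int = 400

    def __post_init__(self):
        if not 0 <= self.duplication_divergence <= 1:
            raise ValueError("divergence must be in [0, 1]")
        if min(self.length, self.exon_length, self.intron_length) <= 0:
            raise ValueError("lengths must be positive")


@dataclass(frozen=True)
class EditingPlan:
    n_sites: int = 30
    level: float = 0.5
    depth: int = 40
    substitution_mix: Mapping[str, float] = field(
        default_factory=lambda: {"A>G": 1.0})
    #: floor on emitted alt reads per true site (None = pure binomial draw)
    min_alt_guarantee: int | None = None

    def __post_init__(self):
        if not 0 <= self.level <= 1:
            raise ValueError("level must be in [0, 1]")
        total = sum(self.substitution_mix.values())
        if self.substitution_mix and abs(total - 1.0) > 1e-9:
            raise ValueError("substitution mix must sum to 1")


@dataclass(frozen=True)
class ArtifactPlan:
    n_paralog: int = 10
    n_junction: int = 10
    n_indel: int = 5
    depth: int = 8
    junction_overhang: int = 10
    indel_length: int = 2


@dataclass(frozen=True)
class ReadPlan:
    read_length: int = 50
    error_rate: float = 0.0
    site_margin: int = 5  # planted sites stay this far from read ends

    def __post_init__(self):
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")


@dataclass(frozen=True)
class CohortPlan:
    n_sites: int = 1000
    n_pairs: int = 40
    n_differential: int = 50
    delta: float = 0.15
    depth_mean: float = 100.0
    overdispersion: float = 0.01
    level_low: float = 0.1
    level_high: float = 0.5

    def __post_init__(self):
        if self.n_pairs < 2:
            raise ValueError("need >= 2 pairs")
        if not 0 <= self.overdispersion < 1:
            raise ValueError("overdispersion must be in [0, 1)")


@dataclass(frozen=True)
class CouplingPlan:
    target_r: float = 0.1
    beta: float = 1.0

    def __post_init__(self):
        if not -1 <= self.target_r <= 1:
            raise ValueError("target r must be in [-1, 1]")
        if self.target_r != 0 and self.beta == 0:
            raise ValueError("nonzero target r requires nonzero beta")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    genome: GenomePlan = field(default_factory=GenomePlan)
    editing: EditingPlan = field(default_factory=EditingPlan)
    artifacts: ArtifactPlan = field(default_factory=ArtifactPlan)
    reads: ReadPlan = field(default_factory=ReadPlan)
    cohort: CohortPlan = field(default_factory=CohortPlan)
    coupling: CouplingPlan = field(default_factory=CouplingPlan)

    @classmethod
    def from_yaml(cls, path: str) -> "FixtureSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, sub in (("genome", GenomePlan), ("editing", EditingPlan),
                         ("artifacts", ArtifactPlan), ("reads", ReadPlan),
                         ("cohort", CohortPlan), ("coupling", CouplingPlan)):
            if key in raw:
                if key == "editing" and "substitution_mix" in raw[key]:
                    raw[key]["substitution_mix"] = dict(
                        raw[key]["substitution_mix"])
                kwargs[key] = sub(**raw[key])
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class TruthTable:
    """Ground-truth labels emitted alongside every fixture."""

    #: (chrom, pos0, ref, alt) -> true_editing | MULTI_ALIGNMENT |
    #: SPLICE_JUNCTION | INDEL_ARTIFACT
    variant_labels: dict[tuple[str, int, str, str], str] = field(
        default_factory=dict)
    #: site key -> sample -> true editing level
    site_levels: dict[str, dict[str, float]] = field(default_factory=dict)
    #: site key -> (is_differential, planted delta)
    differential: dict[str, tuple[bool, float]] = field(default_factory=dict)
    #: site key -> target editing/expression coupling r
    coupling_r: dict[str, float] = field(default_factory=dict)

    def variants_to_tsv(self, handle) -> None:
        close = False
        if isinstance(handle, str):
            handle, close = open(handle, "w"), True
        try:
            handle.write("chrom\tpos0\tref\talt\tlabel\n")
            for (chrom, pos0, ref, alt), label in sorted(
                    self.variant_labels.items()):
                handle.write(f"{chrom}\t{pos0}\t{ref}\t{alt}\t{label}\n")
        finally:
            if close:
                handle.close()

    def differential_to_tsv(self, handle) -> None:
        close = False
        if isinstance(handle, str):
            handle, close = open(handle, "w"), True
        try:
            handle.write("site\tis_differential\tdelta\n")
            for key in sorted(self.differential):
                flag, delta = self.differential[key]
                handle.write(f"{key}\t{int(flag)}\t{delta:.6g}\n")
        finally:
            if close:
                handle.close()
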