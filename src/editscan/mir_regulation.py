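"""3'UTR miRNA-seed analysis: intersect editing sites with seed-match
intervals, re-evaluate seed complementarity under A->G editing, correlate
editing changes with expression changes, and classify sites into the
four-subtype regulatory model."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core_model.types import EditingSite

RNA_BASES = frozenset("ACGU")
_CANONICAL_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}


class SeedEffect(Enum):
    DESTROYS = "destroys"
    CREATES = "creates"
    NONE = "none"


@dataclass(frozen=True)
class MirnaTargetSite:
    """A predicted seed-match interval on a target 3'UTR.

    ``seed`` is positions 2-8 of the mature miRNA (RNA alphabet, 5'->3',
    length 7).
    """

    mirna: str
    seed: str
    chrom: str
    start0: int
    end0: int
    strand: str = "+"

    def __post_init__(self):
        if len(self.seed) != 7 or set(self.seed) - RNA_BASES:
            raise ValueError("seed must be a 7-mer over A/C/G/U")
        if self.end0 - self.start0 < 7:
            raise ValueError("seed-match interval must span >= 7 bases")


@dataclass(frozen=True)
class RegulatoryModelCall:
    gene_role: str        # oncogene | tumor_suppressor
    editing_direction: str  # up | down
    seed_effect: SeedEffect
    subtype: str          # I | II | III | IV | inconsistent


def intersect_seed_regions(sites: Sequence[EditingSite],
                           targets: Sequence[MirnaTargetSite],
                           strand_aware: bool = False,
                           ) -> list[tuple[EditingSite, MirnaTargetSite]]:
    """Single-base overlap of editing sites with seed-match intervals
    (half-open; strand-blind by default, like intersectBed)."""
    by_chrom: dict[str, list[MirnaTargetSite]] = {}
    for t in targets:
        by_chrom.setdefault(t.chrom, []).append(t)
    for lst in by_chrom.values():
        lst.sort(key=lambda t: (t.start0, t.end0, t.mirna))
    pairs = []
    for site in sites:
        for target in by_chrom.get(site.chrom, []):
            if target.start0 <= site.pos0 < target.end0:
                if strand_aware and site.strand != target.strand:
                    continue
                pairs.append((site, target))
    return pairs


def _as_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _pairs_perfectly(target7: str, seed: str, wobble_counts: bool) -> bool:
    """target7 is the 5'->3' target subsequence; antisense geometry pairs
    target position k with seed position 6 - k."""
    allowed = _CANONICAL_PAIRS | (_WOBBLE_PAIRS if wobble_counts else set())
    return all((t, seed[6 - k]) in allowed for k, t in enumerate(target7))


def evaluate_seed_effect(target7: str, seed: str, edited_offset: int,
                         wobble_counts: bool = False) -> SeedEffect:
    """Does A->G editing at ``edited_offset`` of the 7-base target
    subsequence destroy or create a perfect Watson-Crick seed match?

    G:U pairs count toward a match only when ``wobble_counts`` is set.
    """
    target7 = _as_rna(target7)
    seed = _as_rna(seed)
    if len(target7) != 7:
        raise ValueError("target subsequence must be length 7")
    if not 0 <= edited_offset < 7:
        raise ValueError("edited offset outside [0, 7)")
    edited = target7
    if target7[edited_offset] == "A":
        edited = target7[:edited_offset] + "G" + target7[edited_offset + 1:]
    before = _pairs_perfectly(target7, seed, wobble_counts)
    after = _pairs_perfectly(edited, seed, wobble_counts)
    if before and not after:
        return SeedEffect.DESTROYS
    if after and not before:
        return SeedEffect.CREATES
    return SeedEffect.NONE


def delta_correlation(editing_deltas: Sequence[float],
                      expression_deltas: Sequence[float],
                      sample_ids: Sequence[str] | None = None,
                      excluded: Iterable[str] | Iterable[int] = (),
                      ) -> float:
    """Pearson r between per-sample editing change and expression change
    after removing excluded (e.g. CNV-altered) samples.

    Returns NaN (with a warning) when fewer than 3 samples remain or
    either vector has zero variance.
    """
    x = np.asarray(editing_deltas, dtype=float)
    y = np.asarray(expression_deltas, dtype=float)
    if x.shape != y.shape:
        raise ValueError("editing and expression vectors differ in length")
    excluded = set(excluded)
    if sample_ids is not None:
        keep = [i for i, s in enumerate(sample_ids) if s not in excluded]
    else:
        keep = [i for i in range(x.size) if i not in excluded]
    x, y = x[keep], y[keep]
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        warnings.warn("correlation undefined (<3 samples or zero variance)",
                      stacklevel=2)
        return math.nan
    r, _p = stats.pearsonr(x, y)
    return float(r)


def compare_correlation_groups(group_a: Sequence[float],
                               group_b: Sequence[float],
                               equal_var: bool = False,
                               ) -> tuple[float, float]:
    """Two-sample t-test between two sets of correlation scores
    (Welch by default, pooled-variance optional)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


#: (gene role, editing direction, seed effect) -> subtype
SUBTYPE_TABLE: Mapping[tuple[str, str, SeedEffect], str] = {
    ("oncogene", "up", SeedEffect.DESTROYS): "I",
    ("tumor_suppressor", "up", SeedEffect.CREATES): "II",
    ("tumor_suppressor", "down", SeedEffect.DESTROYS): "III",
    ("oncogene", "down", SeedEffect.CREATES): "IV",
}


def classify_regulatory_subtype(gene_role: str, editing_direction: str,
                                seed_effect: SeedEffect) -> RegulatoryModelCall:
    """Map (role, direction, effect) onto the four-subtype model; any
    triple outside the table is inconsistent with it."""
    if gene_role not in ("oncogene", "tumor_suppressor"):
        raise ValueError(f"unknown gene role {gene_role!r}")
    if editing_direction not in ("up", "down"):
        raise ValueError(f"unknown direction {editing_direction!r}")
    subtype = SUBTYPE_TABLE.get((gene_role, editing_direction, seed_effect),
                                "inconsistent")
    return RegulatoryModelCall(gene_role, editing_direction, seed_effect,
                               subtype)
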