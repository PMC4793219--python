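"""Cross-sample recurrence, cohort validation, and paired differential
editing with Benjamini-Hochberg FDR control."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_model.types import EditingMatrix, EditingSite


@dataclass(frozen=True)
class ValidationRule:
    """A cohort sample supports an editing event when depth >= 10, alt
    reads >= 1 and allele frequency >= 1% (all inclusive); a site seen in
    >= 2 supporting samples is called real."""

    min_depth: int = 10
    min_alt: int = 1
    min_af: float = 0.01
    real_min_samples: int = 2

    def __post_init__(self):
        if min(self.min_depth, self.min_alt, self.real_min_samples) <= 0 \
                or self.min_af <= 0:
            raise ValueError("all rule thresholds must be positive")

    def supports(self, depth: int, alt: int, af: float) -> bool:
        return depth >= self.min_depth and alt >= self.min_alt \
            and af >= self.min_af


DEFAULT_VALIDATION = ValidationRule()


@dataclass(frozen=True)
class DifferentialResult:
    site_key: str
    tumor_type: str
    n_pairs: int
    mean_tumor: float
    mean_normal: float
    t_statistic: float
    p_value: float
    q_value: float = math.nan

    @property
    def delta(self) -> float:
        return self.mean_tumor - self.mean_normal

    @property
    def direction(self) -> str:
        return "up" if self.delta > 0 else "down"

    def significant(self, alpha: float = 0.05) -> bool:
        return self.q_value <= alpha


@dataclass(frozen=True)
class GeneDirectionSummary:
    gene: str
    n_sites_up: int
    n_sites_down: int

    @property
    def consistent(self) -> bool:
        lo = min(self.n_sites_up, self.n_sites_down)
        hi = max(self.n_sites_up, self.n_sites_down)
        return lo == 0 and hi > 0


def recurrence_distribution(matrix: EditingMatrix, min_depth: int = 20,
                            ) -> dict[str, int]:
    """Per-site count of samples with non-zero editing, restricted to
    sites covered at >= min_depth in EVERY sample."""
    if not matrix.samples:
        raise ValueError("matrix has no samples")
    out: dict[str, int] = {}
    sufficient = np.all(matrix.depth >= min_depth, axis=1)
    for i, key in enumerate(matrix.site_keys):
        if sufficient[i]:
            out[key] = int(np.sum(matrix.level[i] > 0))
    return out


def validate_against_cohort(site: EditingSite,
                            cohort_cells: Sequence[tuple[int, int, float]],
                            rule: ValidationRule = DEFAULT_VALIDATION) -> str:
    """Classify a site against a cohort of (depth, alt, af) observations.

    real: >= real_min_samples supporting; likely: exactly one;
    insufficient: no sample has depth >= min_depth; unsupported: covered
    samples exist but none supports.
    """
    n_support = sum(1 for d, a, f in cohort_cells if rule.supports(d, a, f))
    n_covered = sum(1 for d, _a, _f in cohort_cells if d >= rule.min_depth)
    if n_support >= rule.real_min_samples:
        return "real"
    if n_support == 1:
        return "likely"
    if n_covered == 0:
        return "insufficient"
    return "unsupported"


def paired_t_test(tumor: Sequence[float], normal: Sequence[float],
                  ) -> tuple[float, float]:
    """Classic paired t on differences, df = n - 1, two-sided p.

    Degenerate conventions: all-zero differences give (0, 1); zero
    variance with nonzero mean gives (+-inf, 0) with a warning.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.shape != normal.shape:
        raise ValueError("tumor and normal vectors differ in length")
    n = tumor.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    diff = tumor - normal
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        warnings.warn("zero-variance differences with nonzero mean; "
                      "p -> 0 by convention", stacklevel=2)
        return math.copysign(math.inf, mean), 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone by cumulative
    minimum from the largest p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _rej, q, _a, _b = multipletests(p, method="fdr_bh")
    return q


def differential_editing(matrix: EditingMatrix,
                         pairs: Sequence[tuple[str, str]],
                         tumor_type: str,
                         alpha: float = 0.05,
                         min_pairs: int = 10) -> list[DifferentialResult]:
    """Paired tumor-normal test per site; BH across all tested sites of
    the tumor type.

    Pairs with a MISSING cell in either member are dropped per site;
    sites with fewer than ``min_pairs`` usable pairs are not tested.
    """
    t_idx = [matrix.sample_index(t) for t, _n in pairs]
    n_idx = [matrix.sample_index(n) for _t, n in pairs]
    tested: list[tuple[str, int, float, float, float, float]] = []
    for i, key in enumerate(matrix.site_keys):
        t_depth = matrix.depth[i, t_idx]
        n_depth = matrix.depth[i, n_idx]
        usable = (t_depth >= 0) & (n_depth >= 0)
        n_usable = int(usable.sum())
        if n_usable < min_pairs:
            continue
        t_lev = matrix.level[i, t_idx][usable]
        n_lev = matrix.level[i, n_idx][usable]
        t_stat, p = paired_t_test(t_lev, n_lev)
        tested.append((key, n_usable, float(t_lev.mean()),
                       float(n_lev.mean()), t_stat, p))
    if not tested:
        warnings.warn(f"no testable sites for {tumor_type}", stacklevel=2)
        return []
    q = bh_fdr([row[5] for row in tested])
    return [DifferentialResult(site_key=key, tumor_type=tumor_type,
                               n_pairs=np, mean_tumor=mt, mean_normal=mn,
                               t_statistic=t, p_value=p, q_value=float(qi))
            for (key, np, mt, mn, t, p), qi in zip(tested, q)]


def classify_site_direction(results: Iterable[DifferentialResult | tuple],
                            alpha: float = 0.05) -> str:
    """Per-site call across tumor types.

    up (resp. down) requires >= 2 tumor types significant in that
    direction and <= 1 significant in the opposite one; anything else is
    not_called.  ``results`` entries are DifferentialResult or
    (significant, direction) tuples.
    """
    n_up = n_down = 0
    for entry in results:
        if isinstance(entry, DifferentialResult):
            sig, direction = entry.significant(alpha), entry.direction
        else:
            sig, direction = entry
        if not sig:
            continue
        if direction == "up":
            n_up += 1
        else:
            n_down += 1
    if n_up >= 2 and n_down <= 1:
        return "up"
    if n_down >= 2 and n_up <= 1:
        return "down"
    return "not_called"


def summarize_gene_directions(site_calls: Mapping[str, str],
                              site_to_gene: Mapping[str, str],
                              gene_filter: Iterable[str] | None = None,
                              min_sites: int = 2,
                              ) -> list[GeneDirectionSummary]:
    """Per-gene counts of sites called up/down, keeping genes with at
    least ``min_sites`` direction-called sites (optionally restricted to
    ``gene_filter``)."""
    genes: dict[str, list[int]] = {}
    for site_key, call in site_calls.items():
        gene = site_to_gene.get(site_key)
        if gene is None or call == "not_called":
            continue
        up_down = genes.setdefault(gene, [0, 0])
        if call == "up":
            up_down[0] += 1
        else:
            up_down[1] += 1
    allowed = set(gene_filter) if gene_filter is not None else None
    out = []
    for gene in sorted(genes):
        up, down = genes[gene]
        if up + down < min_sites:
            continue
        if allowed is not None and gene not in allowed:
            continue
        out.append(GeneDirectionSummary(gene, up, down))
    return out
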