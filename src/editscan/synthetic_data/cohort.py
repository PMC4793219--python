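"""Paired tumor/normal cohort and coupled-expression generators."""

from __future__ import annotations

import numpy as np

from ..core_model.types import EditingMatrix
from .spec import CohortPlan, CouplingPlan, TruthTable


def _beta_binomial(rng: np.random.Generator, depth: np.ndarray,
                   mean: float, rho: float) -> np.ndarray:
    """Edited-read counts with beta-distributed per-cell level.

    rho = 0 degenerates to a plain binomial at ``mean``.
    """
    if rho <= 0:
        return rng.binomial(depth, mean)
    s = (1.0 - rho) / rho
    p = rng.beta(mean * s, (1.0 - mean) * s, size=depth.shape)
    return rng.binomial(depth, p)


def simulate_editing_cohort(plan: CohortPlan, rng: np.random.Generator,
                            ) -> tuple[EditingMatrix,
                                       list[tuple[str, str]], TruthTable]:
    """Sites x (tumor + normal) editing matrix with planted shifts.

    The first ``n_differential`` sites get their tumor mean shifted by
    ``delta``; the truth table records the per-site flag and shift.
    """
    n, m = plan.n_sites, plan.n_pairs
    tumors = [f"T{i:03d}" for i in range(m)]
    normals = [f"N{i:03d}" for i in range(m)]
    pairs = list(zip(tumors, normals))
    site_keys = [f"chrS:{1000 + i}:A>G" for i in range(n)]
    truth = TruthTable()

    mus = rng.uniform(plan.level_low, plan.level_high, size=n)
    depth = np.maximum(rng.poisson(plan.depth_mean, size=(n, 2 * m)), 1)
    level = np.empty((n, 2 * m), dtype=float)
    for i in range(n):
        is_diff = i < plan.n_differential
        mu_t = min(mus[i] + plan.delta, 0.99) if is_diff else mus[i]
        edited_t = _beta_binomial(rng, depth[i, :m], mu_t, plan.overdispersion)
        edited_n = _beta_binomial(rng, depth[i, m:], mus[i],
                                  plan.overdispersion)
        level[i, :m] = edited_t / depth[i, :m]
        level[i, m:] = edited_n / depth[i, m:]
        truth.differential[site_keys[i]] = (
            bool(is_diff), (mu_t - mus[i]) if is_diff else 0.0)
    matrix = EditingMatrix(site_keys, tumors + normals, depth, level)
    return matrix, pairs, truth


def simulate_coupled_expression(editing_deltas: np.ndarray,
                                site_keys: list[str],
                                target_r: np.ndarray | float,
                                rng: np.random.Generator,
                                plan: CouplingPlan | None = None,
                                ) -> tuple[np.ndarray, TruthTable]:
    """Per-sample expression changes linearly coupled to editing changes.

    For each site, d_expr = beta * d_edit + Gaussian noise with the noise
    scale chosen so the population Pearson r equals the target:
    r = beta * sd_edit / sqrt(beta^2 sd_edit^2 + sd_noise^2).
    """
    plan = plan or CouplingPlan()
    deltas = np.asarray(editing_deltas, dtype=float)
    n, m = deltas.shape
    r = np.broadcast_to(np.asarray(target_r, dtype=float), (n,)).copy()
    if np.any(np.abs(r) > 1):
        raise ValueError("target r outside [-1, 1]")
    truth = TruthTable()
    expr = np.empty_like(deltas)
    for i in range(n):
        sd_edit = deltas[i].std()
        if abs(r[i]) >= 1.0 - 1e-12:
            if sd_edit == 0:
                raise ValueError("target |r| = 1 infeasible: editing has "
                                 "zero variance")
            beta = np.sign(r[i]) * plan.beta
            expr[i] = beta * deltas[i]
        elif r[i] == 0:
            expr[i] = rng.normal(0.0, 1.0, size=m)
        else:
            if sd_edit == 0:
                raise ValueError("nonzero target r infeasible: editing has "
                                 "zero variance")
            beta = np.sign(r[i]) * plan.beta
            sd_noise = abs(beta) * sd_edit * np.sqrt(1.0 / r[i] ** 2 - 1.0)
            expr[i] = beta * deltas[i] + rng.normal(0.0, sd_noise, size=m)
        truth.coupling_r[site_keys[i]] = float(r[i])
    return expr, truth


def write_delta_tsv(handle, site_keys: list[str], samples: list[str],
                    values: np.ndarray) -> None:
    close = False
    if isinstance(handle, str):
        handle, close = open(handle, "w"), True
    try:
        handle.write("site\t" + "\t".join(samples) + "\n")
        for key, row in zip(site_keys, values):
            handle.write(key + "\t"
                         + "\t".join(f"{v:.6g}" for v in row) + "\n")
    finally:
        if close:
            handle.close()


def write_pairs_tsv(handle, pairs: list[tuple[str, str]]) -> None:
    close = False
    if isinstance(handle, str):
        handle, close = open(handle, "w"), True
    try:
        handle.write("tumor\tnormal\n")
        for t, n in pairs:
            handle.write(f"{t}\t{n}\n")
    finally:
        if close:
            handle.close()


def read_pairs_tsv(handle) -> list[tuple[str, str]]:
    close = False
    if isinstance(handle, str):
        handle, close = open(handle), True
    try:
        pairs = []
        for lineno, line in enumerate(handle):
            if lineno == 0 and line.startswith("tumor"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                pairs.append((parts[0], parts[1]))
        return pairs
    finally:
        if close:
            handle.close()
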