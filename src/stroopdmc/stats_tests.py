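"""Monte-Carlo permutation inference for within-subject designs.

Two tests are provided: a paired Fisher-Pitman test (sign flips of
within-pair differences) for two-condition designs, and a maxT-adjusted
Kruskal-Wallis-type rank test (condition labels permuted within each
participant) for three-condition, multi-parameter designs.  Holm's
step-down correction is implemented for families of raw p-values.

Monte-Carlo p-values use the add-one correction
``p = (1 + #{extreme permutations}) / (1 + n_perm)`` so they are never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["TestResult", "fisher_pitman_paired", "kruskal_maxT", "holm"]


@dataclass
class TestResult:
    statistic: float
    p_mc: float
    p_adjusted: float | None
    n_permutations: int
    seed: int | None
    name: str = ""


def fisher_pitman_paired(
    x, y, n_perm: int = 10_000, seed: int | None = None
) -> TestResult:
    """Two-sided paired Fisher-Pitman permutation test.

    The statistic is the standardized sum of within-pair differences,
    Z = sum(d) / sqrt(sum(d^2)); the null is generated by independently
    flipping each pair's sign.  With all differences zero, Z = 0 and p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be 1-d, equal length, n >= 2")
    d = x - y
    denom = float(np.sqrt(np.sum(d * d)))
    if denom == 0:
        return TestResult(0.0, 1.0, None, n_perm, seed, "fisher_pitman")
    z_obs = float(np.sum(d)) / denom

    rng = np.random.default_rng(seed)
    signs = rng.choice(np.array([-1.0, 1.0]), size=(n_perm, len(d)))
    z_perm = signs @ d / denom
    p = (1.0 + np.count_nonzero(np.abs(z_perm) >= abs(z_obs) - 1e-12)) / (1.0 + n_perm)
    return TestResult(z_obs, float(p), None, n_perm, seed, "fisher_pitman")


def _kw_statistics(ranks: np.ndarray, tie_correction: float) -> np.ndarray:
    """Kruskal-Wallis H per parameter from a (n_subj, k, n_params) rank array."""
    n_subj, k, _ = ranks.shape
    n_total = n_subj * k
    group_means = ranks.mean(axis=0)  # (k, n_params)
    grand = (n_total + 1) / 2.0
    h = 12.0 * n_subj / (n_total * (n_total + 1)) * np.sum((group_means - grand) ** 2, axis=0)
    if tie_correction > 0:
        h = h / tie_correction
    return h


def kruskal_maxT(
    values, n_perm: int = 10_000, seed: int | None = None, parameter_names=None
) -> list[TestResult]:
    """maxT-adjusted Kruskal-Wallis permutation tests across parameters.

    ``values`` has shape (n_participants, n_conditions, n_parameters) and
    must be a complete grid.  Per parameter, the observed Kruskal-Wallis H
    (mid-ranks, tie-corrected) is standardized against its permutation
    distribution; the joint null permutes condition labels within each
    participant (the same permutation across parameters, preserving their
    dependence).  Single-step maxT: adjusted p for parameter j is the
    proportion of permutations whose maximum standardized statistic across
    parameters reaches the observed statistic of j.  A constant parameter
    gets statistic 0 and p = 1.
    """
    values = np.asarray(values, float)
    if values.ndim == 2:
        values = values[:, :, None]
    if values.ndim != 3:
        raise ValueError("values must have shape (n_participants, n_conditions, n_parameters)")
    n_subj, k, n_par = values.shape
    if n_subj < 2 or k < 2:
        raise ValueError("need at least 2 participants and 2 conditions")
    if parameter_names is None:
        parameter_names = [f"param_{j}" for j in range(n_par)]

    # mid-ranks and tie corrections over the pooled sample, per parameter
    ranks = np.empty_like(values)
    tie_corr = np.empty(n_par)
    n_total = n_subj * k
    for j in range(n_par):
        flat = values[:, :, j].ravel()
        ranks[:, :, j] = rankdata(flat).reshape(n_subj, k)
        _, counts = np.unique(flat, return_counts=True)
        tie_corr[j] = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)

    h_obs = _kw_statistics(ranks, 1.0)
    h_obs = np.where(tie_corr > 0, h_obs / np.where(tie_corr > 0, tie_corr, 1.0), 0.0)

    rng = np.random.default_rng(seed)
    # within-participant label permutations, shared across parameters
    perm_order = np.argsort(rng.random((n_perm, n_subj, k)), axis=2)
    h_perm = np.empty((n_perm, n_par))
    for b in range(n_perm):
        permuted = np.take_along_axis(ranks, perm_order[b][:, :, None], axis=1)
        h = _kw_statistics(permuted, 1.0)
        h_perm[b] = np.where(tie_corr > 0, h / np.where(tie_corr > 0, tie_corr, 1.0), 0.0)

    mu = h_perm.mean(axis=0)
    sd = h_perm.std(axis=0)
    degenerate = sd <= 0
    sd_safe = np.where(degenerate, 1.0, sd)
    t_obs = np.where(degenerate, 0.0, (h_obs - mu) / sd_safe)
    t_perm = np.where(degenerate[None, :], 0.0, (h_perm - mu[None, :]) / sd_safe[None, :])

    max_t_perm = t_perm.max(axis=1)
    results = []
    for j in range(n_par):
        if degenerate[j]:
            results.append(TestResult(0.0, 1.0, 1.0, n_perm, seed, str(parameter_names[j])))
            continue
        p_raw = (1.0 + np.count_nonzero(t_perm[:, j] >= t_obs[j] - 1e-12)) / (1.0 + n_perm)
        p_adj = (1.0 + np.count_nonzero(max_t_perm >= t_obs[j] - 1e-12)) / (1.0 + n_perm)
        results.append(
            TestResult(float(t_obs[j]), float(p_raw), float(min(p_adj, 1.0)), n_perm, seed, str(parameter_names[j]))
        )
    return results


def holm(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values, in input order.

    Sort ascending, multiply the i-th smallest by (m - i), enforce
    monotonicity by a running maximum, cap at 1.
    """
    p = np.asarray(p_values, float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-d")
    if len(p) == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted
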