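"""Quantile-binned G² goodness of fit and multi-restart Nelder-Mead fitting.

Observed RT/accuracy data per congruency condition are reduced to a
multinomial over RT-quantile bins (correct responses split at the 10th,
30th, 50th, 70th, and 90th percentiles; errors likewise when there are
enough of them, otherwise pooled).  The model's predicted proportions come
from simulating the decision process and classifying simulated trials into
the observed bin edges.  The fit minimises

    G² = 2 * sum_cond n_cond * sum_bins p_obs * ln(p_obs / p_pred)

by Nelder-Mead from multiple uniform random starting points, with common
random numbers per restart so the objective is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from . import dmc_core
from ._kernels import first_passage
from .dmc_core import DMCParams, PARAM_NAMES, SimConfig

__all__ = [
    "CONGRUENCIES",
    "ObservedSummary",
    "BinSpec",
    "BinnedCondition",
    "FitConfig",
    "RestartRecord",
    "FitResult",
    "bin_observed",
    "predicted_proportions",
    "g_squared",
    "fit_dataset",
]

CONGRUENCIES = ("congruent", "incongruent")

#: Default uniform start ranges for the seven parameters (desk defaults;
#: override through FitConfig.start_ranges).
DEFAULT_START_RANGES: dict[str, tuple[float, float]] = {
    "a": (40.0, 120.0),
    "mu_c": (0.2, 0.8),
    "zeta": (5.0, 40.0),
    "alpha": (1.5, 4.5),
    "tau": (20.0, 200.0),
    "ter": (200.0, 400.0),
    "sr": (5.0, 60.0),
}

_DOMAIN_LOWER = {"a": 1e-3, "zeta": 0.0, "alpha": 1.0 + 1e-6, "tau": 1e-3, "ter": 1e-3, "sr": 0.0}
_PENALTY = 1e9


@dataclass
class ObservedSummary:
    """Per-congruency sorted correct/error RTs; the data side of the G² interface."""

    correct_rts: dict[str, np.ndarray]
    error_rts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for cond in CONGRUENCIES:
            if cond not in self.correct_rts or cond not in self.error_rts:
                raise ValueError(f"missing condition {cond!r}")
            self.correct_rts[cond] = np.sort(np.asarray(self.correct_rts[cond], float))
            self.error_rts[cond] = np.sort(np.asarray(self.error_rts[cond], float))
            rts = np.concatenate([self.correct_rts[cond], self.error_rts[cond]])
            if rts.size and (not np.isfinite(rts).all() or (rts <= 0).any()):
                raise ValueError(f"RTs in condition {cond!r} must be positive and finite")
            if len(self.correct_rts[cond]) < 1:
                raise ValueError(f"condition {cond!r} has no correct trials")

    def n_total(self, cond: str) -> int:
        return len(self.correct_rts[cond]) + len(self.error_rts[cond])

    @classmethod
    def from_trials(cls, frame: pd.DataFrame) -> "ObservedSummary":
        """Build from a trial table with columns congruency, rt_ms, correct."""
        correct_rts, error_rts = {}, {}
        for cond in CONGRUENCIES:
            sub = frame[frame["congruency"] == cond]
            ok = sub["correct"].astype(bool)
            correct_rts[cond] = sub.loc[ok, "rt_ms"].to_numpy(float)
            error_rts[cond] = sub.loc[~ok, "rt_ms"].to_numpy(float)
        return cls(correct_rts, error_rts)

    @classmethod
    def from_simulation(cls, results: Mapping[str, dmc_core.SimulationResult]) -> "ObservedSummary":
        correct_rts, error_rts = {}, {}
        for cond in CONGRUENCIES:
            res = results[cond]
            rt = res.rt
            ok = res.correct & res.absorbed
            correct_rts[cond] = rt[ok]
            error_rts[cond] = rt[~ok]
        return cls(correct_rts, error_rts)


@dataclass(frozen=True)
class BinSpec:
    correct_percentile_cuts: tuple[float, ...] = (10, 30, 50, 70, 90)
    error_percentile_cuts: tuple[float, ...] = (10, 30, 50, 70, 90)
    min_errors_for_binning: int = 11

    def __post_init__(self) -> None:
        for cuts in (self.correct_percentile_cuts, self.error_percentile_cuts):
            arr = np.asarray(cuts, float)
            if not ((arr > 0).all() and (arr < 100).all() and (np.diff(arr) > 0).all()):
                raise ValueError("percentile cuts must be strictly increasing within (0, 100)")


@dataclass
class BinnedCondition:
    """Realized bin structure and observed proportions for one congruency."""

    correct_edges: np.ndarray  # interior RT edges for correct bins
    error_edges: np.ndarray | None  # None => single pooled error bin (or none)
    has_error_bin: bool
    props: np.ndarray  # correct-bin proportions then error-bin proportions
    n_total: int

    @property
    def n_correct_bins(self) -> int:
        return len(self.correct_edges) + 1


def _bin_counts(sorted_rts: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Counts per bin for interior edges; len(edges)+1 bins."""
    idx = np.searchsorted(sorted_rts, edges, side="right")
    return np.diff(np.concatenate([[0], idx, [len(sorted_rts)]]))


def bin_observed(data: ObservedSummary, spec: BinSpec | None = None) -> dict[str, BinnedCondition]:
    """Reduce observed RTs to per-condition quantile-bin proportions.

    Correct RTs are split at the empirical percentiles in
    ``spec.correct_percentile_cuts``.  Errors get their own percentile bins
    only when there are at least ``spec.min_errors_for_binning`` of them;
    fewer errors form one pooled bin; zero errors contribute no error bin.
    Proportions are relative to the condition's total trial count and sum
    to 1 per condition.
    """
    spec = spec or BinSpec()
    out: dict[str, BinnedCondition] = {}
    for cond in CONGRUENCIES:
        crts = data.correct_rts[cond]
        erts = data.error_rts[cond]
        n_total = len(crts) + len(erts)
        c_edges = np.percentile(crts, spec.correct_percentile_cuts)
        parts = [_bin_counts(crts, c_edges)]
        if len(erts) >= spec.min_errors_for_binning:
            e_edges = np.percentile(erts, spec.error_percentile_cuts)
            parts.append(_bin_counts(erts, e_edges))
            has_err = True
        elif len(erts) > 0:
            e_edges = None
            parts.append(np.array([len(erts)]))
            has_err = True
        else:
            e_edges = None
            has_err = False
        counts = np.concatenate(parts).astype(float)
        out[cond] = BinnedCondition(c_edges, e_edges, has_err, counts / n_total, n_total)
    return out


@dataclass(frozen=True)
class FitConfig:
    """Fitting configuration; desk-scale defaults, paper scale via ``paper_scale()``."""

    n_sim: int = 5_000  # simulated observations per congruency per evaluation
    max_iterations: int = 100  # Nelder-Mead iteration cap per restart
    n_restarts: int = 5
    start_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_START_RANGES)
    )
    common_random_numbers: bool = True
    dt: float = 1.0
    sigma: float = 4.0
    max_time: float = 1500.0
    bin_spec: BinSpec = field(default_factory=BinSpec)

    def __post_init__(self) -> None:
        if self.n_sim < 100:
            raise ValueError("n_sim must be >= 100")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        for name, (lo, hi) in self.start_ranges.items():
            if not lo < hi:
                raise ValueError(f"start range for {name} has lower >= upper")

    @classmethod
    def paper_scale(cls, **overrides) -> "FitConfig":
        """Published settings: 50,000 sims per congruency, 250 iterations, 30 restarts."""
        defaults = dict(n_sim=50_000, max_iterations=250, n_restarts=30)
        defaults.update(overrides)
        return cls(**defaults)

    def sim_config(self, n_trials: int | None = None) -> SimConfig:
        return SimConfig(
            dt=self.dt,
            sigma=self.sigma,
            n_trials=n_trials or self.n_sim,
            max_time=self.max_time,
        )


@dataclass
class RestartRecord:
    start: DMCParams
    start_g2: float
    final_g2: float
    iterations: int
    final_vector: np.ndarray


@dataclass
class FitResult:
    best_params: DMCParams
    g2: float
    restarts: list[RestartRecord]
    config: FitConfig
    seed: int
    total_simulated: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"parameter": k, "value": v} for k, v in self.best_params.as_dict().items()]
        t_max, t_90 = dmc_core.derived_times(self.best_params)
        rows += [
            {"parameter": "t_max", "value": t_max},
            {"parameter": "t_90", "value": t_90},
            {"parameter": "g2", "value": self.g2},
        ]
        return pd.DataFrame(rows)

    def restart_frame(self) -> pd.DataFrame:
        rows = []
        for i, rec in enumerate(self.restarts):
            row = {"restart": i, "start_g2": rec.start_g2, "final_g2": rec.final_g2, "iterations": rec.iterations}
            row.update({f"start_{k}": v for k, v in rec.start.as_dict().items()})
            rows.append(row)
        return pd.DataFrame(rows)


class FitFailureError(RuntimeError):
    def __init__(self, message: str, restarts: list[RestartRecord]):
        super().__init__(message)
        self.restarts = restarts


def _classify(rt: np.ndarray, ok: np.ndarray, binned: BinnedCondition, n_sim: int) -> np.ndarray:
    """Counts of simulated trials in the observed bin structure."""
    c_rt = np.sort(rt[ok])
    e_rt = np.sort(rt[~ok])
    parts = [_bin_counts(c_rt, binned.correct_edges)]
    if binned.error_edges is not None:
        parts.append(_bin_counts(e_rt, binned.error_edges))
    elif binned.has_error_bin:
        parts.append(np.array([len(e_rt)]))
    # no observed error bin: simulated errors fall outside the multinomial
    return np.concatenate(parts).astype(float)


def _floor_renormalize(counts: np.ndarray, n_sim: int) -> np.ndarray:
    props = counts / max(counts.sum(), 1.0)
    props = np.maximum(props, 1.0 / (2.0 * n_sim))
    return props / props.sum()


def predicted_proportions(
    params: DMCParams,
    binned: Mapping[str, BinnedCondition],
    fit_config: FitConfig,
    seed: int | None = None,
    _noise: Mapping[str, np.ndarray] | None = None,
    _residual_seed=None,
) -> dict[str, np.ndarray]:
    """Model-predicted bin proportions by simulation and classification.

    Simulates ``fit_config.n_sim`` trials per congruency, classifies each
    (rt, correct) pair into the observed bin edges, floors proportions at
    1 / (2 n_sim) and renormalizes.  ``_noise`` / ``_residual_seed`` are the
    common-random-numbers hooks used by the fit objective.
    """
    cfg = fit_config.sim_config()
    out: dict[str, np.ndarray] = {}
    if _noise is not None:
        auto_inc = dmc_core.unit_activation_increments(params, cfg)
        bound = dmc_core.effective_bound(params.a, cfg)
        for cond in CONGRUENCIES:
            sign = 1.0 if cond == "congruent" else -1.0
            signed = np.full(cfg.n_trials, sign * params.zeta)
            steps, ok, absorbed = first_passage(
                _noise[cond], params.mu_c * cfg.dt, auto_inc, signed, bound
            )
            rng_r = np.random.default_rng(_residual_seed)
            residual = dmc_core._draw_residuals(cfg.n_trials, params.ter, params.sr, rng_r)
            rt = steps * cfg.dt + residual
            ok = ok & absorbed
            out[cond] = _floor_renormalize(_classify(rt, ok, binned[cond], cfg.n_trials), cfg.n_trials)
        return out

    rng = np.random.default_rng(seed)
    for cond in CONGRUENCIES:
        res = dmc_core.simulate_decisions(params, cond, cfg, rng=rng)
        ok = res.correct & res.absorbed
        out[cond] = _floor_renormalize(_classify(res.rt, ok, binned[cond], cfg.n_trials), cfg.n_trials)
    return out


def g_squared(
    observed_props: Mapping[str, np.ndarray],
    predicted_props: Mapping[str, np.ndarray],
    n_per_condition: Mapping[str, int],
) -> float:
    """Likelihood-ratio goodness of fit over the binned multinomials.

    G² = 2 * sum_cond n_cond * sum_bins p_obs * ln(p_obs / p_pred);
    bins with p_obs = 0 contribute 0.
    """
    total = 0.0
    for cond, p_obs in observed_props.items():
        p_obs = np.asarray(p_obs, float)
        p_pred = np.asarray(predicted_props[cond], float)
        if p_obs.shape != p_pred.shape:
            raise ValueError(f"bin structure mismatch in condition {cond!r}")
        nz = p_obs > 0
        total += 2.0 * n_per_condition[cond] * float(
            np.sum(p_obs[nz] * np.log(p_obs[nz] / p_pred[nz]))
        )
    return total


def _vector_to_params(theta: np.ndarray) -> DMCParams | None:
    vals = dict(zip(PARAM_NAMES, theta))
    for name, lo in _DOMAIN_LOWER.items():
        if vals[name] < lo:
            return None
    return DMCParams(**vals)


def _domain_penalty(theta: np.ndarray) -> float:
    dist2 = 0.0
    vals = dict(zip(PARAM_NAMES, theta))
    for name, lo in _DOMAIN_LOWER.items():
        if vals[name] < lo:
            dist2 += (lo - vals[name]) ** 2
    return _PENALTY + dist2


def fit_dataset(
    data: ObservedSummary,
    fit_config: FitConfig | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit the seven parameters to one dataset by multi-restart Nelder-Mead.

    Each restart draws a uniform starting point from
    ``fit_config.start_ranges`` and minimises the simulated G² for at most
    ``fit_config.max_iterations`` iterations.  With common random numbers
    (the default) the diffusion noise is drawn once per restart and reused
    across objective evaluations, so the objective is a deterministic
    function of the parameters and the whole fit is reproducible per seed.
    """
    fit_config = fit_config or FitConfig()
    binned = bin_observed(data, fit_config.bin_spec)
    observed = {c: binned[c].props for c in CONGRUENCIES}
    n_per_cond = {c: binned[c].n_total for c in CONGRUENCIES}
    cfg = fit_config.sim_config()
    scale = fit_config.sigma * math.sqrt(fit_config.dt)

    restarts: list[RestartRecord] = []
    evals = {"n": 0}
    for r in range(fit_config.n_restarts):
        rng = np.random.default_rng([seed, r])
        start = np.array([rng.uniform(*fit_config.start_ranges[k]) for k in PARAM_NAMES])
        if fit_config.common_random_numbers:
            noise = {
                cond: rng.standard_normal((fit_config.n_sim, cfg.n_steps)) * scale
                for cond in CONGRUENCIES
            }
            residual_seed = [seed, r, 104729]
        else:
            noise = None
            residual_seed = None

        def objective(theta: np.ndarray) -> float:
            params = _vector_to_params(theta)
            if params is None:
                return _domain_penalty(theta)
            evals["n"] += 1
            if noise is not None:
                pred = predicted_proportions(
                    params, binned, fit_config, _noise=noise, _residual_seed=residual_seed
                )
            else:
                pred = predicted_proportions(
                    params, binned, fit_config, seed=rng.integers(2**63)
                )
            return g_squared(observed, pred, n_per_cond)

        start_g2 = objective(start)
        res = optimize.minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={"maxiter": fit_config.max_iterations, "xatol": 1e-4, "fatol": 1e-4},
        )
        final = min(res.fun, start_g2)
        final_vec = res.x if res.fun <= start_g2 else start
        restarts.append(
            RestartRecord(
                start=DMCParams(**dict(zip(PARAM_NAMES, start))),
                start_g2=start_g2,
                final_g2=final,
                iterations=int(res.nit),
                final_vector=np.asarray(final_vec, float),
            )
        )

    valid = [rec for rec in restarts if _vector_to_params(rec.final_vector) is not None]
    if not valid:
        raise FitFailureError("all restarts ended outside the parameter domain", restarts)
    best = min(valid, key=lambda rec: rec.final_g2)
    best_params = _vector_to_params(best.final_vector)
    total_sim = evals["n"] * 2 * fit_config.n_sim
    return FitResult(best_params, best.final_g2, restarts, fit_config, seed, total_sim)
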