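"""Synthetic Stroop session generator.

Produces complete color-word task sessions — balanced stimulus sequences,
chi-squared interstimulus intervals, an adaptive practice phase, and
responses simulated from the conflict diffusion model — with configurable
conflict-adaptation and stimulation effects, as a stand-in for the
request-only behavioral data.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import behavior
from ._kernels import first_passage
from .dmc_core import (
    DMCParams,
    SimConfig,
    _draw_residuals,
    effective_bound,
    unit_activation_increments,
)

__all__ = [
    "StimulusMapping",
    "StimEffect",
    "CohortConfig",
    "CohortResult",
    "generate_sequence",
    "sample_isi",
    "simulate_practice",
    "simulate_session",
    "simulate_cohort",
]

PRACTICE_MIN = 50
PRACTICE_WINDOW = 20
PRACTICE_CRITERION = 18
PRACTICE_CAP = 500

ISI_LOW, ISI_HIGH, ISI_MEAN, ISI_DF = 0.3, 0.7, 0.5, 4.0


@dataclass(frozen=True)
class StimulusMapping:
    """Two-button mapping of the four colors (two colors per button)."""

    buttons: Mapping[str, int] = field(
        default_factory=lambda: {"green": 1, "red": 1, "yellow": 2, "blue": 2}
    )

    def __post_init__(self) -> None:
        ids = set(self.buttons.values())
        if len(ids) != 2:
            raise ValueError("mapping must use exactly two buttons")
        for b in ids:
            if sum(v == b for v in self.buttons.values()) != 2:
                raise ValueError("each button must carry exactly two colors")

    @property
    def colors(self) -> tuple[str, ...]:
        return tuple(self.buttons)

    def button(self, color: str) -> int:
        return self.buttons[color]

    def other_button_colors(self, color: str) -> list[str]:
        b = self.buttons[color]
        return [c for c, v in self.buttons.items() if v != b]

    def other_button(self, button: int) -> int:
        return next(v for v in set(self.buttons.values()) if v != button)


def _balanced_cycle(items: Sequence[str], n: int, rng: np.random.Generator) -> list[str]:
    """n draws cycling through items as evenly as possible, remainder randomized."""
    reps, extra = divmod(n, len(items))
    out = list(items) * reps + list(rng.permutation(list(items))[:extra])
    return out


def generate_sequence(
    n_per_congruency: int = 300,
    mapping: StimulusMapping | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Randomized main-phase stimulus sequence.

    Exactly ``n_per_congruency`` congruent and incongruent trials in a
    uniformly random order.  Congruent trials have word == font color;
    incongruent trials pair a font color with a word from the *other*
    response button.  Words and font colors are balanced across the four
    colors up to remainder.
    """
    if n_per_congruency < 1:
        raise ValueError("n_per_congruency must be >= 1")
    mapping = mapping or StimulusMapping()
    if rng is None:
        rng = np.random.default_rng(seed)

    rows = []
    for font in _balanced_cycle(mapping.colors, n_per_congruency, rng):
        rows.append({"word": font, "font_color": font, "congruency": "congruent"})
    # incongruent: cycle each font color through its two cross-button words
    counters: dict[str, itertools.cycle] = {
        c: itertools.cycle(rng.permutation(mapping.other_button_colors(c))) for c in mapping.colors
    }
    for font in _balanced_cycle(mapping.colors, n_per_congruency, rng):
        rows.append({"word": next(counters[font]), "font_color": font, "congruency": "incongruent"})

    frame = pd.DataFrame(rows)
    return frame.iloc[rng.permutation(len(frame))].reset_index(drop=True)


def _isi_scale() -> float:
    """Chi-squared scale calibrated so the [0.3, 0.7] truncated mean is 0.5 s."""

    def truncated_mean(s: float) -> float:
        c = (ISI_HIGH - ISI_LOW) / s
        num = ISI_DF * stats.chi2.cdf(c, ISI_DF + 2)
        den = stats.chi2.cdf(c, ISI_DF)
        return ISI_LOW + s * num / den

    return float(optimize.brentq(lambda s: truncated_mean(s) - ISI_MEAN, 0.01, 0.5))


_ISI_SCALE = _isi_scale()


def sample_isi(n: int, seed: int | None = None, rng: np.random.Generator | None = None) -> np.ndarray:
    """Interstimulus intervals (s): shifted, scaled chi-squared on [0.3, 0.7].

    chi2(df=4) draws are scaled, shifted by 0.3 s, and rejection-truncated
    to [0.3, 0.7]; the scale is calibrated so the truncated mean is 0.5 s.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = ISI_LOW + _ISI_SCALE * rng.chisquare(ISI_DF, size=n)
    bad = out > ISI_HIGH
    while bad.any():
        out[bad] = ISI_LOW + _ISI_SCALE * rng.chisquare(ISI_DF, size=int(bad.sum()))
        bad = out > ISI_HIGH
    return out


def _simulate_trials(
    params: DMCParams,
    signed_zetas: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(rt_ms, correct) for a batch of trials with per-trial signed amplitudes.

    Unabsorbed trials and responses beyond the trial window are recorded as
    errors at the window edge, so every recorded RT lies in (0, max_time].
    """
    n = len(signed_zetas)
    noise = rng.standard_normal((n, cfg.n_steps)) * (cfg.sigma * math.sqrt(cfg.dt))
    auto_inc = unit_activation_increments(params, cfg)
    steps, correct, absorbed = first_passage(
        noise, params.mu_c * cfg.dt, auto_inc, signed_zetas, effective_bound(params.a, cfg)
    )
    residual = _draw_residuals(n, params.ter, params.sr, rng)
    rt = steps * cfg.dt + residual
    late = ~absorbed | (rt > cfg.max_time)
    rt = np.where(late, cfg.max_time, rt)
    correct = correct & ~late
    return rt, correct


@dataclass(frozen=True)
class StimEffect:
    """Generative stimulation effect: multipliers on amplitude and adaptation.

    ``zeta_mult`` scales the automatic amplitude; with
    ``only_after_congruent`` it applies only on trials not preceded by an
    incongruent trial (where no endogenous adaptation is expected).
    ``kappa_mult`` scales the conflict-adaptation coefficient.
    """

    zeta_mult: float = 1.0
    kappa_mult: float = 1.0
    only_after_congruent: bool = True

    def __post_init__(self) -> None:
        if self.zeta_mult <= 0 or self.kappa_mult <= 0:
            raise ValueError("multipliers must be > 0")


DEFAULT_PARAM_MEANS = {"a": 85.0, "mu_c": 0.5, "zeta": 20.0, "alpha": 2.0, "tau": 50.0, "ter": 300.0, "sr": 30.0}
DEFAULT_PARAM_SDS = {"a": 8.0, "mu_c": 0.05, "zeta": 4.0, "alpha": 0.25, "tau": 10.0, "ter": 25.0, "sr": 5.0}


@dataclass(frozen=True)
class CohortConfig:
    """Group-level generative settings for a synthetic cohort."""

    n_subjects: int = 12
    param_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PARAM_MEANS))
    param_sds: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PARAM_SDS))
    kappa: float = 0.3  # fractional zeta reduction after an incongruent trial
    stim_effects: Mapping[str, StimEffect] = field(
        default_factory=lambda: {"6hz": StimEffect(zeta_mult=0.7), "9.7hz": StimEffect(zeta_mult=1.0)}
    )
    conditions: tuple[str, ...] = ("sham", "6hz")
    n_per_congruency: int = 300
    include_practice: bool = True
    seed: int = 0
    dt: float = 1.0
    sigma: float = 4.0
    max_time: float = 1500.0

    def __post_init__(self) -> None:
        if not 0 <= self.kappa < 1:
            raise ValueError("kappa must lie in [0, 1)")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    def sim_config(self, n_trials: int) -> SimConfig:
        return SimConfig(dt=self.dt, sigma=self.sigma, n_trials=n_trials, max_time=self.max_time)

    def stim_effect(self, condition: str) -> StimEffect:
        return self.stim_effects.get(condition, StimEffect(zeta_mult=1.0, kappa_mult=1.0))


def simulate_practice(
    params: DMCParams,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    mapping: StimulusMapping | None = None,
    sim_config: SimConfig | None = None,
) -> pd.DataFrame:
    """Adaptive practice phase: at least 50 trials, until 18 of the last 20 correct.

    Stimuli are drawn uniformly (50% congruent); responses come from the
    base parameters without adaptation or stimulation effects.  Capped at
    500 trials with a warning for non-terminating configurations.
    """
    mapping = mapping or StimulusMapping()
    if rng is None:
        rng = np.random.default_rng(seed)
    cfg = sim_config or SimConfig(n_trials=1)

    rows: list[dict] = []
    history: list[bool] = []
    while True:
        congruent = bool(rng.random() < 0.5)
        font = str(rng.choice(mapping.colors))
        word = font if congruent else str(rng.choice(mapping.other_button_colors(font)))
        sign = 1.0 if congruent else -1.0
        rt, ok = _simulate_trials(params, np.array([sign * params.zeta]), cfg, rng)
        ok_b = bool(ok[0])
        history.append(ok_b)
        rows.append(
            {
                "phase": "practice",
                "word": word,
                "font_color": font,
                "congruency": "congruent" if congruent else "incongruent",
                "correct": ok_b,
                "rt_ms": float(rt[0]),
            }
        )
        n = len(history)
        if n >= PRACTICE_MIN and sum(history[-PRACTICE_WINDOW:]) >= PRACTICE_CRITERION:
            break
        if n >= PRACTICE_CAP:
            warnings.warn("practice phase hit the 500-trial cap without meeting the criterion")
            break
    return pd.DataFrame(rows)


def _effective_zetas(
    cpt: np.ndarray, zeta: float, kappa: float, effect: StimEffect
) -> np.ndarray:
    """Trial-wise automatic amplitude under adaptation and stimulation."""
    after_conflict = cpt == "incongruent"
    kappa_eff = min(kappa * effect.kappa_mult, 0.999)
    z = zeta * np.where(after_conflict, 1.0 - kappa_eff, 1.0)
    if effect.only_after_congruent:
        z = z * np.where(after_conflict, 1.0, effect.zeta_mult)
    else:
        z = z * effect.zeta_mult
    return z


def simulate_session(
    subject_params: DMCParams,
    condition: str,
    cohort_config: CohortConfig | None = None,
    seed: int | None = None,
    participant: str = "s00",
    mapping: StimulusMapping | None = None,
) -> pd.DataFrame:
    """One full session (practice + main phase) as a validated trial table.

    The main phase uses a balanced randomized sequence; each trial's
    automatic amplitude is the subject's zeta scaled by conflict adaptation
    (previous-trial congruency) and the condition's stimulation effect.
    Responses beyond the trial window count as errors at the window edge.
    """
    cohort_config = cohort_config or CohortConfig()
    mapping = mapping or StimulusMapping()
    rng = np.random.default_rng(seed)
    effect = cohort_config.stim_effect(condition)

    frames = []
    if cohort_config.include_practice:
        practice = simulate_practice(
            subject_params, rng=rng, mapping=mapping, sim_config=cohort_config.sim_config(1)
        )
        practice["prev_congruency"] = "none"
        frames.append(practice)

    seq = generate_sequence(cohort_config.n_per_congruency, mapping, rng=rng)
    cpt = seq["congruency"].shift(1).fillna("none").to_numpy()
    signs = np.where(seq["congruency"] == "congruent", 1.0, -1.0)
    zetas = _effective_zetas(cpt, subject_params.zeta, cohort_config.kappa, effect)
    cfg = cohort_config.sim_config(len(seq))
    rt, correct = _simulate_trials(subject_params, signs * zetas, cfg, rng)
    main = seq.copy()
    main["phase"] = "main"
    main["prev_congruency"] = cpt
    main["correct"] = correct
    main["rt_ms"] = rt
    frames.append(main)

    session = pd.concat(frames, ignore_index=True)
    session["participant"] = participant
    session["condition"] = condition
    session["trial_idx"] = np.arange(len(session))
    session["isi_s"] = sample_isi(len(session), rng=rng)
    buttons = session["font_color"].map(mapping.buttons)
    session["response"] = np.where(
        session["correct"], buttons, buttons.map(mapping.other_button)
    ).astype(int)
    return session[behavior.SESSION_COLUMNS]


def _lognormal_for(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and SD."""
    var = sd * sd
    sigma2 = math.log(1.0 + var / (mean * mean))
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_subject_params(
    means: Mapping[str, float], sds: Mapping[str, float], rng: np.random.Generator
) -> DMCParams:
    """Between-subject draw: normal for a, mu_c, ter; log-normal for the rest."""
    for _ in range(100):
        vals = {}
        for name in ("a", "mu_c", "ter"):
            vals[name] = rng.normal(means[name], sds[name])
        for name in ("zeta", "tau", "sr"):
            mu, s = _lognormal_for(means[name], sds[name])
            vals[name] = rng.lognormal(mu, s)
        mu, s = _lognormal_for(means["alpha"] - 1.0, sds["alpha"])
        vals["alpha"] = 1.0 + rng.lognormal(mu, s)
        try:
            return DMCParams(**vals)
        except ValueError:
            continue
    raise RuntimeError("could not draw valid subject parameters in 100 attempts")


@dataclass
class CohortResult:
    sessions: pd.DataFrame
    truth: pd.DataFrame  # one row per participant, columns = parameters
    condition_order: pd.DataFrame


def simulate_cohort(config: CohortConfig | None = None) -> CohortResult:
    """Within-subject cohort: every subject completes every condition.

    Condition order is counterbalanced by cycling through the permutations
    of the condition list across subjects.  Returns the stacked sessions,
    the per-subject true parameters, and the recorded session orders.
    """
    config = config or CohortConfig()
    root = np.random.default_rng(config.seed)
    orders = list(itertools.permutations(config.conditions))

    sessions, truth_rows, order_rows = [], [], []
    for i in range(config.n_subjects):
        pid = f"s{i:02d}"
        params = _draw_subject_params(config.param_means, config.param_sds, np.random.default_rng([config.seed, i]))
        truth_rows.append({"participant": pid, **params.as_dict()})
        order = orders[i % len(orders)]
        for pos, cond in enumerate(order):
            cond_idx = config.conditions.index(cond)
            sess = simulate_session(
                params, cond, config, seed=[config.seed, i, cond_idx, 7919], participant=pid
            )
            sessions.append(sess)
            order_rows.append({"participant": pid, "condition": cond, "session_order": pos})
    _ = root  # reserved for future cohort-level draws
    return CohortResult(
        pd.concat(sessions, ignore_index=True),
        pd.DataFrame(truth_rows),
        pd.DataFrame(order_rows),
    )
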