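"""Trial-level session handling: loading, sequence annotation, exclusions, effects.

Sessions are tidy DataFrames with one row per trial.  Effects are
descriptive cell means: the congruency (Stroop) effect, its stratification
by previous-trial congruency, and the Gratton contrast, plus sham-vs-active
deltas across stimulation conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SESSION_COLUMNS",
    "SessionValidationError",
    "TrialRecord",
    "EffectTable",
    "load_sessions",
    "annotate_sequence",
    "apply_exclusions",
    "effect_table",
    "delta_vs_sham",
]

SESSION_COLUMNS = [
    "participant",
    "condition",
    "trial_idx",
    "phase",
    "word",
    "font_color",
    "congruency",
    "prev_congruency",
    "response",
    "correct",
    "rt_ms",
    "isi_s",
]

_REQUIRED = ["participant", "condition", "trial_idx", "phase", "word", "font_color", "correct", "rt_ms"]

CONGRUENCIES = ("congruent", "incongruent")
RT_MAX_MS = 1500.0


class SessionValidationError(ValueError):
    """Raised with the offending row indices when a session table is malformed."""

    def __init__(self, message: str, rows=None):
        if rows is not None:
            rows = list(rows)
            preview = rows[:20]
            message = f"{message} (rows: {preview}{'...' if len(rows) > 20 else ''})"
        super().__init__(message)
        self.rows = rows


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial; ``as_dict`` matches the session CSV schema."""

    participant: str
    condition: str
    trial_idx: int
    phase: str
    word: str
    font_color: str
    congruency: str
    prev_congruency: str
    response: int
    correct: bool
    rt_ms: float
    isi_s: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in SESSION_COLUMNS}


def _session_groups(trials: pd.DataFrame):
    return trials.groupby(["participant", "condition"], sort=False)


def load_sessions(path) -> pd.DataFrame:
    """Read and validate a session CSV (``#`` lines are treated as comments).

    Congruency is recomputed from word vs. font color (case-insensitive) and
    cross-checked against any provided congruency column; mismatches, missing
    columns, and out-of-range RTs raise :class:`SessionValidationError`.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SessionValidationError(f"missing required columns: {missing}")

    derived = np.where(
        df["word"].astype(str).str.lower() == df["font_color"].astype(str).str.lower(),
        "congruent",
        "incongruent",
    )
    if "congruency" in df.columns:
        bad = df.index[df["congruency"].astype(str) != derived]
        if len(bad):
            raise SessionValidationError("congruency column disagrees with word/font_color", bad)
    df["congruency"] = derived

    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad_rt = df.index[~((rt > 0) & (rt <= RT_MAX_MS))]
    if len(bad_rt):
        raise SessionValidationError(f"rt_ms outside (0, {RT_MAX_MS:g}]", bad_rt)
    df["rt_ms"] = rt
    df["correct"] = df["correct"].astype(bool)
    df["trial_idx"] = df["trial_idx"].astype(int)
    return df


def annotate_sequence(trials: pd.DataFrame) -> pd.DataFrame:
    """Fill ``prev_congruency`` (CPT) from the previous main-phase trial.

    Within each (participant, condition) session, main trial k inherits the
    congruency of main trial k-1; the first main trial gets ``"none"``.
    Practice trials never feed the sequence and are themselves ``"none"``.
    """
    trials = trials.copy()
    trials["prev_congruency"] = "none"
    for _, group in _session_groups(trials):
        if not (np.diff(group["trial_idx"].to_numpy()) > 0).all():
            raise SessionValidationError("trials not ordered by trial_idx within session")
        main_idx = group.index[group["phase"] == "main"]
        prev = trials.loc[main_idx, "congruency"].shift(1).fillna("none")
        trials.loc[main_idx, "prev_congruency"] = prev
    return trials


def apply_exclusions(trials: pd.DataFrame, for_rt: bool) -> pd.DataFrame:
    """Apply trial exclusions: practice always; errors and post-error for RT.

    For RT analyses (``for_rt=True``) error trials and the single trial
    immediately following an error are dropped.  For accuracy analyses all
    main-phase trials are retained.  Idempotent.
    """
    trials = trials[trials["phase"] == "main"]
    if not for_rt:
        return trials.copy()
    keep = pd.Series(True, index=trials.index)
    for _, group in _session_groups(trials):
        err = ~group["correct"].to_numpy(bool)
        post_err = np.concatenate([[False], err[:-1]])
        keep.loc[group.index] = ~err & ~post_err
    return trials[keep].copy()


@dataclass
class EffectTable:
    """Descriptive cell means and derived contrasts for one condition.

    ``stroop_effect`` is mean RT(incongruent) - mean RT(congruent);
    ``stroop_by_cpt`` stratifies it by previous-trial congruency;
    ``gratton = stroop_by_cpt['congruent'] - stroop_by_cpt['incongruent']``.
    """

    condition: str
    stroop_effect: float
    stroop_by_cpt: dict = field(default_factory=dict)
    gratton: float = float("nan")
    rt_cells: dict = field(default_factory=dict)  # cct -> mean RT
    acc_cells: dict = field(default_factory=dict)  # cct -> accuracy
    rt_cells_cpt: dict = field(default_factory=dict)  # (cct, cpt) -> mean RT
    rt_sd_cells: dict = field(default_factory=dict)
    n_cells: dict = field(default_factory=dict)
    missing_cells: list = field(default_factory=list)

    @classmethod
    def from_summary(
        cls,
        condition: str,
        stroop_effect: float,
        stroop_by_cpt: Mapping[str, float] | None = None,
    ) -> "EffectTable":
        """Build a table from summary effect estimates (e.g. published values)."""
        by_cpt = dict(stroop_by_cpt or {})
        gratton = (
            by_cpt["congruent"] - by_cpt["incongruent"]
            if {"congruent", "incongruent"} <= by_cpt.keys()
            else float("nan")
        )
        return cls(condition=condition, stroop_effect=float(stroop_effect), stroop_by_cpt=by_cpt, gratton=gratton)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"condition": self.condition, "effect": "stroop", "value": self.stroop_effect}]
        for cpt, v in self.stroop_by_cpt.items():
            rows.append({"condition": self.condition, "effect": f"stroop_cpt_{cpt}", "value": v})
        rows.append({"condition": self.condition, "effect": "gratton", "value": self.gratton})
        for cct, v in self.rt_cells.items():
            rows.append({"condition": self.condition, "effect": f"mean_rt_{cct}", "value": v})
        for cct, v in self.acc_cells.items():
            rows.append({"condition": self.condition, "effect": f"accuracy_{cct}", "value": v})
        return pd.DataFrame(rows)


def _mean_or_nan(values: pd.Series) -> float:
    return float(values.mean()) if len(values) else float("nan")


def _effects_one_condition(condition: str, annotated: pd.DataFrame) -> EffectTable:
    rt_trials = apply_exclusions(annotated, for_rt=True)
    acc_trials = apply_exclusions(annotated, for_rt=False)

    table = EffectTable(condition=condition, stroop_effect=float("nan"))
    for cct in CONGRUENCIES:
        rt_cell = rt_trials.loc[rt_trials["congruency"] == cct, "rt_ms"]
        acc_cell = acc_trials.loc[acc_trials["congruency"] == cct, "correct"]
        table.rt_cells[cct] = _mean_or_nan(rt_cell)
        table.rt_sd_cells[cct] = float(rt_cell.std()) if len(rt_cell) > 1 else float("nan")
        table.acc_cells[cct] = _mean_or_nan(acc_cell.astype(float))
        table.n_cells[cct] = len(rt_cell)
        if not len(rt_cell):
            table.missing_cells.append(cct)
    table.stroop_effect = table.rt_cells["incongruent"] - table.rt_cells["congruent"]

    # CPT-stratified cells exclude trials with undefined previous congruency
    strat = rt_trials[rt_trials["prev_congruency"].isin(CONGRUENCIES)]
    for cpt in CONGRUENCIES:
        sub = strat[strat["prev_congruency"] == cpt]
        for cct in CONGRUENCIES:
            cell = sub.loc[sub["congruency"] == cct, "rt_ms"]
            table.rt_cells_cpt[(cct, cpt)] = _mean_or_nan(cell)
            table.n_cells[(cct, cpt)] = len(cell)
            if not len(cell):
                table.missing_cells.append((cct, cpt))
        table.stroop_by_cpt[cpt] = (
            table.rt_cells_cpt[("incongruent", cpt)] - table.rt_cells_cpt[("congruent", cpt)]
        )
    table.gratton = table.stroop_by_cpt["congruent"] - table.stroop_by_cpt["incongruent"]
    return table


def effect_table(trials: pd.DataFrame, by: str = "condition") -> dict[str, EffectTable]:
    """Compute effect tables per level of ``by`` (default: stimulation condition).

    Expects sequence-annotated trials (see :func:`annotate_sequence`);
    exclusions are applied internally per analysis type — error/post-error
    trials are dropped for RT means, while accuracy uses all main trials.
    """
    if "prev_congruency" not in trials.columns:
        raise ValueError("trials must be sequence-annotated first (annotate_sequence)")
    return {
        str(level): _effects_one_condition(str(level), group)
        for level, group in trials.groupby(by, sort=False)
    }


def delta_vs_sham(
    effects: Mapping[str, EffectTable], sham: str = "sham"
) -> dict[str, dict[str, float]]:
    """Per-effect differences (sham minus each active condition).

    Returns ``{active_condition: {"stroop_effect": ..., "gratton": ...,
    "stroop_cpt_congruent": ..., "stroop_cpt_incongruent": ...}}``.
    """
    if sham not in effects:
        raise KeyError(f"sham condition {sham!r} missing from effects")
    ref = effects[sham]
    out: dict[str, dict[str, float]] = {}
    for cond, tab in effects.items():
        if cond == sham:
            continue
        deltas = {"stroop_effect": ref.stroop_effect - tab.stroop_effect}
        if not (np.isnan(ref.gratton) or np.isnan(tab.gratton)):
            deltas["gratton"] = ref.gratton - tab.gratton
        for cpt in CONGRUENCIES:
            if cpt in ref.stroop_by_cpt and cpt in tab.stroop_by_cpt:
                deltas[f"stroop_cpt_{cpt}"] = ref.stroop_by_cpt[cpt] - tab.stroop_by_cpt[cpt]
        out[cond] = deltas
    return out
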