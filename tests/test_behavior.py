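import numpy as np
import pandas as pd
import pytest

from stroopdmc import behavior, synthetic_data
from stroopdmc.behavior import (
    EffectTable,
    SessionValidationError,
    annotate_sequence,
    apply_exclusions,
    delta_vs_sham,
    effect_table,
    load_sessions,
)


def _make_trials(congruencies, correct=None, rts=None, participant="p1", condition="sham", phase="main"):
    n = len(congruencies)
    correct = [True] * n if correct is None else correct
    rts = [500.0] * n if rts is None else rts
    word_for = {"congruent": ("red", "red"), "incongruent": ("red", "yellow")}
    rows = []
    for i, (cct, ok, rt) in enumerate(zip(congruencies, correct, rts)):
        w, f = word_for[cct]
        rows.append(
            {"participant": participant, "condition": condition, "trial_idx": i, "phase": phase,
             "word": w, "font_color": f, "congruency": cct, "prev_congruency": "none",
             "response": 1, "correct": ok, "rt_ms": rt, "isi_s": 0.5}
        )
    return pd.DataFrame(rows)


class TestLoadSessions:
    def test_roundtrip_generated_session(self, session_frame, tmp_path):
        path = tmp_path / "session.csv"
        session_frame.to_csv(path, index=False)
        loaded = load_sessions(path)
        assert len(loaded) == len(session_frame)
        assert (loaded["phase"] == "main").sum() == 600

    def test_congruency_mismatch_raises(self, tmp_path):
        frame = _make_trials(["congruent"])
        frame.loc[0, "congruency"] = "incongruent"  # word == font_color says congruent
        path = tmp_path / "bad.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(SessionValidationError):
            load_sessions(path)

    def test_case_insensitive_congruency(self, tmp_path):
        frame = _make_trials(["congruent"])
        frame.loc[0, "word"] = "RED"
        path = tmp_path / "case.csv"
        frame.to_csv(path, index=False)
        assert load_sessions(path)["congruency"].iloc[0] == "congruent"

    def test_rt_out_of_range_raises(self, tmp_path):
        frame = _make_trials(["congruent"], rts=[1600.0])
        path = tmp_path / "rt.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(SessionValidationError):
            load_sessions(path)

    def test_missing_columns_raise(self, tmp_path):
        path = tmp_path / "cols.csv"
        pd.DataFrame({"participant": ["p1"]}).to_csv(path, index=False)
        with pytest.raises(SessionValidationError):
            load_sessions(path)

    def test_practice_rows_retained(self, tmp_path):
        frame = pd.concat(
            [_make_trials(["congruent"] * 3, phase="practice"), _make_trials(["incongruent"] * 3)],
            ignore_index=True,
        )
        frame["trial_idx"] = range(len(frame))
        path = tmp_path / "practice.csv"
        frame.to_csv(path, index=False)
        loaded = load_sessions(path)
        assert (loaded["phase"] == "practice").sum() == 3


class TestAnnotateSequence:
    def test_basic_sequence(self):
        trials = _make_trials(["congruent", "incongruent", "incongruent"])
        out = annotate_sequence(trials)
        assert list(out["prev_congruency"]) == ["none", "congruent", "incongruent"]

    def test_session_boundary_resets(self):
        a = _make_trials(["incongruent", "congruent"], participant="p1")
        b = _make_trials(["congruent", "congruent"], participant="p2")
        out = annotate_sequence(pd.concat([a, b], ignore_index=True))
        assert list(out["prev_congruency"]) == ["none", "incongruent", "none", "congruent"]

    def test_practice_never_feeds_cpt(self):
        practice = _make_trials(["incongruent"] * 2, phase="practice")
        main = _make_trials(["congruent", "incongruent"])
        frame = pd.concat([practice, main], ignore_index=True)
        frame["trial_idx"] = range(len(frame))
        out = annotate_sequence(frame)
        assert list(out["prev_congruency"]) == ["none", "none", "none", "congruent"]

    def test_alternating_sequence_enumeration(self):
        # c I c I c I c I c I: direct enumeration of predecessors
        seq = ["congruent", "incongruent"] * 5
        out = annotate_sequence(_make_trials(seq))
        cpt = list(out["prev_congruency"])
        assert cpt == ["none"] + seq[:-1]
        assert cpt.count("congruent") == 5
        assert cpt.count("incongruent") == 4

    def test_unordered_input_raises(self):
        trials = _make_trials(["congruent", "incongruent"])
        trials["trial_idx"] = [1, 0]
        with pytest.raises(SessionValidationError):
            annotate_sequence(trials)


class TestApplyExclusions:
    def test_error_and_posterror_dropped(self):
        trials = annotate_sequence(_make_trials(["congruent"] * 4, correct=[True, False, True, True]))
        kept = apply_exclusions(trials, for_rt=True)
        assert list(kept["trial_idx"]) == [0, 3]

    def test_accuracy_analysis_keeps_all_main(self):
        trials = annotate_sequence(_make_trials(["congruent"] * 4, correct=[True, False, True, True]))
        assert len(apply_exclusions(trials, for_rt=False)) == 4

    def test_all_correct_session(self, session_frame):
        trials = annotate_sequence(session_frame)
        trials.loc[trials["phase"] == "main", "correct"] = True
        kept = apply_exclusions(trials, for_rt=True)
        assert len(kept) == 600
        assert (kept["prev_congruency"] != "none").sum() == 599

    def test_brute_force_exclusion_count(self, rng):
        n = 400
        correct = rng.random(n) > 0.05
        trials = annotate_sequence(_make_trials(["congruent"] * n, correct=list(correct)))
        kept = apply_exclusions(trials, for_rt=True)
        # brute-force oracle: keep trial i iff correct[i] and (i == 0 or correct[i-1])
        expected = sum(
            bool(correct[i]) and (i == 0 or bool(correct[i - 1])) for i in range(n)
        )
        assert len(kept) == expected

    def test_idempotent(self, session_frame):
        trials = annotate_sequence(session_frame)
        once = apply_exclusions(trials, for_rt=True)
        twice = apply_exclusions(once, for_rt=True)
        pd.testing.assert_frame_equal(once, twice)


class TestEffectTable:
    def test_stroop_effect_from_cells(self):
        # cells engineered to the printed per-condition means
        trials = annotate_sequence(
            _make_trials(
                ["congruent", "congruent", "incongruent", "incongruent"],
                rts=[600.0, 600.0, 639.9, 639.9],
            )
        )
        table = effect_table(trials)["sham"]
        assert table.stroop_effect == pytest.approx(39.9)

    def test_identical_cells_zero_effects(self):
        # covers all four CCT x CPT cells
        seq = ["congruent", "congruent", "incongruent", "incongruent"] * 10
        trials = annotate_sequence(_make_trials(seq, rts=[500.0] * 40))
        table = effect_table(trials)["sham"]
        assert table.stroop_effect == 0.0
        assert table.gratton == 0.0

    def test_gratton_reproduces_from_stratified_stroop(self, session_frame):
        table = effect_table(annotate_sequence(session_frame))["sham"]
        assert table.gratton == pytest.approx(
            table.stroop_by_cpt["congruent"] - table.stroop_by_cpt["incongruent"], abs=1e-9
        )
        assert table.stroop_effect == pytest.approx(
            table.rt_cells["incongruent"] - table.rt_cells["congruent"], abs=1e-9
        )

    def test_grand_mean_conservation(self, session_frame):
        trials = annotate_sequence(session_frame)
        table = effect_table(trials)["sham"]
        kept = apply_exclusions(trials, for_rt=True)
        weighted = sum(
            table.rt_cells[c] * table.n_cells[c] for c in ("congruent", "incongruent")
        ) / sum(table.n_cells[c] for c in ("congruent", "incongruent"))
        assert weighted == pytest.approx(kept["rt_ms"].mean(), abs=1e-9)

    def test_label_permutation_nulls_stroop(self, session_frame, rng):
        trials = annotate_sequence(session_frame)
        effects = []
        for _ in range(50):
            shuffled = trials.copy()
            shuffled["congruency"] = rng.permutation(shuffled["congruency"].to_numpy())
            effects.append(effect_table(shuffled)["sham"].stroop_effect)
        assert abs(np.mean(effects)) < 10.0  # SE of the mean over 50 shuffles ~ 1.7 ms

    def test_empty_cell_flagged(self):
        trials = annotate_sequence(_make_trials(["congruent"] * 4))
        table = effect_table(trials)["sham"]
        assert "incongruent" in table.missing_cells
        assert np.isnan(table.stroop_effect)

    def test_requires_annotation(self, session_frame):
        with pytest.raises(ValueError):
            effect_table(session_frame.drop(columns=["prev_congruency"]))


class TestDeltaVsSham:
    def test_experiment1_printed_values(self):
        effects = {
            "sham": EffectTable.from_summary("sham", 46.2),
            "6hz": EffectTable.from_summary("6hz", 33.8),
        }
        deltas = delta_vs_sham(effects)
        assert deltas["6hz"]["stroop_effect"] == pytest.approx(12.4)

    def test_experiment2_printed_values(self):
        effects = {
            "sham": EffectTable.from_summary("sham", 32.9),
            "6hz": EffectTable.from_summary("6hz", 26.0),
            "9.7hz": EffectTable.from_summary("9.7hz", 35.0),
        }
        deltas = delta_vs_sham(effects)
        assert deltas["6hz"]["stroop_effect"] == pytest.approx(6.9)
        assert deltas["9.7hz"]["stroop_effect"] == pytest.approx(-2.1)

    def test_identical_tables_zero_deltas(self):
        effects = {
            "sham": EffectTable.from_summary("sham", 40.0, {"congruent": 50.0, "incongruent": 30.0}),
            "6hz": EffectTable.from_summary("6hz", 40.0, {"congruent": 50.0, "incongruent": 30.0}),
        }
        deltas = delta_vs_sham(effects)
        assert deltas["6hz"]["stroop_effect"] == 0.0
        assert deltas["6hz"]["gratton"] == 0.0

    def test_missing_sham_raises(self):
        with pytest.raises(KeyError):
            delta_vs_sham({"6hz": EffectTable.from_summary("6hz", 30.0)})


@pytest.fixture(scope="module")
def cohort_tables():
    cfg = synthetic_data.CohortConfig(
        n_subjects=20, kappa=0.4, conditions=("sham", "6hz"),
        n_per_congruency=150, include_practice=False, seed=99,
    )
    cohort = synthetic_data.simulate_cohort(cfg)
    annotated = behavior.annotate_sequence(cohort.sessions)
    return behavior.effect_table(annotated)


class TestCohortLevelEffects:
    def test_positive_gratton_with_adaptation(self, cohort_tables):
        assert cohort_tables["sham"].gratton > 0

    def test_stimulation_reduces_stroop(self, cohort_tables):
        assert cohort_tables["6hz"].stroop_effect < cohort_tables["sham"].stroop_effect
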