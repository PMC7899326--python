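"""End-to-end orchestration: raw trials -> cleaned -> events -> features.

Glues the stage modules together for whole-experiment runs: preprocess
every trial, run session quality control, detect events, extract the
14-feature rows and assemble the analysis tables.
"""

from __future__ import annotations

from collections import defaultdict

import pandas as pd

from .design import ExperimentDesign
from .events import detect_trial_events
from .features import (
    assemble_feature_table,
    day_reference_eye_height,
    extract_trial_features,
)
from .preprocessing import preprocess_trial, session_quality_check
from .simulate import (
    LabelModel,
    OculomotorParams,
    TypingSkill,
    simulate_experiment,
)


def run_experiment_pipeline(
    design: ExperimentDesign,
    seed: int,
    params: OculomotorParams = OculomotorParams(),
    skill: TypingSkill = TypingSkill(),
    label_model: LabelModel = LabelModel(),
    max_trials: int | None = None,
    drop_repeats: bool = True,
):
    """Simulate and fully process an experiment.

    Returns ``(stats_table, model_table, exclusion_log, qc_results)``.
    ``max_trials`` truncates the run (for quick, partial-design passes).
    """
    rows = []
    session_streams = defaultdict(list)
    day_refs: dict = {}
    for trial, label_row in simulate_experiment(
        design, seed, params, skill, label_model, max_trials=max_trials
    ):
        pre = preprocess_trial(trial.stream, drop_repeats=drop_repeats)
        slot = trial.slot
        key = (slot.participant, slot.day)
        if key not in day_refs:
            day_refs[key] = day_reference_eye_height(pre.stream)
        events = detect_trial_events(pre.stream, pre.blinks, pre.losses, seed=seed)
        feats = extract_trial_features(pre, events, trial.log, day_refs[key])
        feats.update(
            participant=slot.participant,
            day=slot.day,
            session=slot.session,
            trial=slot.trial_of_day,
            difficulty=slot.difficulty,
            language=slot.language,
            perceived_effort=label_row["perceived_effort"],
            fatigue_level=label_row["fatigue_level"],
        )
        rows.append(feats)
        session_streams[(slot.participant, slot.day, slot.session)].append(pre.stream)

    qc = [
        session_quality_check(streams, session_id=sid)
        for sid, streams in session_streams.items()
    ]
    trials_df = pd.DataFrame(rows)
    stats_table, model_table, excl = assemble_feature_table(trials_df, qc)
    return stats_table, model_table, excl, qc
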