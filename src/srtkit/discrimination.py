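"""D2 discrimination-ratio scoring of spontaneous-recognition test phases.

The D2 ratio for a target/other duration pair is

    D2 = (t_target - t_other) / (t_target + t_other)

so +1 is pure preference for the target, -1 pure avoidance, 0 indifference,
and the score is undefined when the animal explored neither stimulus.

A test phase holds one stimulus copied from each exposure phase, and the
test can sit in either exposure context, so every trial supports three
framings of the same two durations:

* **context**: target = the stimulus whose exposure context mismatches the
  test context (the context-novel configuration);
* **recency**: target = the exposure-1 stimulus, seen longer ago;
* **side**: target = the left-hand stimulus (a bias control).

In test-in-second trials the context-novel and recency-novel labels land on
the same stimulus (d2_recency = d2_context); in test-in-first trials they
land on opposite stimuli (d2_recency = -d2_context). That sign structure is
what the circular strategy analysis exploits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .trial_data import DesignError, DesignSpec, ExplorationRecord

__all__ = [
    "TrialScores",
    "AnimalSummary",
    "ConfigurationLabels",
    "d2_score",
    "label_configurations",
    "trial_scores",
    "score_cohort",
    "animal_summary",
    "summarize_cohort",
    "flag_outliers",
    "trial_scores_frame",
    "animal_summaries_frame",
]

#: default Tukey-fence multiplier for outlier flagging
OUTLIER_K = 2.07


@dataclass(frozen=True)
class ConfigurationLabels:
    """Which test stimulus plays which role under each framing."""

    context_novel: str
    context_familiar: str
    recency_novel: str
    recency_familiar: str


@dataclass
class TrialScores:
    """Per-trial D2 values under the context, recency and side framings."""

    animal_id: str
    session: int
    trial: int
    trial_type: str
    t_context_novel: float
    t_context_familiar: float
    d2_context: float | None
    d2_recency: float | None
    d2_side: float | None


@dataclass
class AnimalSummary:
    """Per-animal totals and mean D2 scores across test phases."""

    animal_id: str
    sum_context_novel: float
    sum_context_familiar: float
    sum_recency_novel: float
    sum_recency_familiar: float
    mean_d2_context: float | None
    mean_d2_recency: float | None
    mean_d2_side: float | None
    mean_d2_context_first: float | None
    mean_d2_context_second: float | None
    exposure_specifier_present: float
    exposure_specifier_absent: float
    exposure_total_scaled: float
    n_trials_scored: int
    n_trials_defined: int
    excluded: bool


def d2_score(t_target: float, t_other: float) -> float | None:
    """Discrimination ratio (t_target - t_other)/(t_target + t_other).

    Returns None when both durations are zero (no preference observable).
    Negative durations are a domain error, not a scoring outcome.
    """
    if t_target < 0 or t_other < 0:
        raise ValueError(f"durations must be >= 0, got ({t_target}, {t_other})")
    total = t_target + t_other
    if total == 0:
        return None
    return (t_target - t_other) / total


def label_configurations(
    trial_records: Sequence[ExplorationRecord], trial_type: str | None = None
) -> ConfigurationLabels:
    """Assign context/recency novelty roles to the two test stimuli.

    The exposure-2 stimulus mismatches the test context when the test sits
    in the first context, and vice versa; the exposure-1 stimulus is always
    the recency-novel one (seen longer ago).
    """
    test = [
        r for r in trial_records
        if r.phase == "test" and r.stimulus_kind != "context_specifier"
    ]
    if len(test) != 2:
        raise DesignError(f"expected exactly 2 scored test stimuli, got {len(test)}")
    if trial_type is None:
        trial_type = test[0].trial_type
    if trial_type not in ("test_in_first", "test_in_second"):
        raise DesignError(f"trial_type must be a test type, got {trial_type!r}")

    exp1_ids = {
        r.stimulus_id for r in trial_records
        if r.phase == "exposure1" and r.stimulus_kind != "context_specifier"
    }
    exp2_ids = {
        r.stimulus_id for r in trial_records
        if r.phase == "exposure2" and r.stimulus_kind != "context_specifier"
    }

    origin: dict[str, int] = {}
    for r in test:
        in1, in2 = r.stimulus_id in exp1_ids, r.stimulus_id in exp2_ids
        if in1 == in2:
            raise DesignError(
                f"test stimulus {r.stimulus_id!r} must originate from exactly one "
                f"exposure phase (exposure1: {in1}, exposure2: {in2})"
            )
        origin[r.stimulus_id] = 1 if in1 else 2
    if set(origin.values()) != {1, 2}:
        raise DesignError("the two test stimuli must come from different exposure phases")

    from_exp1 = next(s for s, o in origin.items() if o == 1)
    from_exp2 = next(s for s, o in origin.items() if o == 2)

    if trial_type == "test_in_first":
        context_novel, context_familiar = from_exp2, from_exp1
    else:
        context_novel, context_familiar = from_exp1, from_exp2
    return ConfigurationLabels(
        context_novel=context_novel,
        context_familiar=context_familiar,
        recency_novel=from_exp1,
        recency_familiar=from_exp2,
    )


def trial_scores(
    trial_records: Sequence[ExplorationRecord], trial_type: str | None = None
) -> TrialScores:
    """Score one labelled trial under all three framings."""
    labels = label_configurations(trial_records, trial_type)
    test = [
        r for r in trial_records
        if r.phase == "test" and r.stimulus_kind != "context_specifier"
    ]
    tt = trial_type or test[0].trial_type
    by_id = {r.stimulus_id: r for r in test}
    t_cn = by_id[labels.context_novel].duration
    t_cf = by_id[labels.context_familiar].duration
    left = [r for r in test if r.side == "left"]
    right = [r for r in test if r.side == "right"]
    d2_side = None
    if len(left) == 1 and len(right) == 1:
        d2_side = d2_score(left[0].duration, right[0].duration)
    d2_context = d2_score(t_cn, t_cf)
    d2_recency = None
    if d2_context is not None:
        d2_recency = d2_context if tt == "test_in_second" else -d2_context
    r0 = test[0]
    return TrialScores(
        animal_id=r0.animal_id,
        session=r0.session,
        trial=r0.trial,
        trial_type=tt,
        t_context_novel=t_cn,
        t_context_familiar=t_cf,
        d2_context=d2_context,
        d2_recency=d2_recency,
        d2_side=d2_side,
    )


def score_cohort(
    records: Sequence[ExplorationRecord], design: DesignSpec | None = None
) -> list[TrialScores]:
    """Score every complete (animal, session, trial) in the cohort.

    Trials without a test phase or without both exposure phases are skipped
    with a warning; their animals still contribute their other trials.
    """
    out: list[TrialScores] = []
    keys = sorted({(r.animal_id, r.session, r.trial) for r in records})
    for animal, session, trial in keys:
        mine = [
            r for r in records
            if r.animal_id == animal and r.session == session and r.trial == trial
        ]
        phases = {r.phase for r in mine}
        if "test" not in phases or {"exposure1", "exposure2"} - phases:
            warnings.warn(
                f"animal {animal} session {session} trial {trial}: incomplete "
                "phases, trial skipped", stacklevel=2,
            )
            continue
        out.append(trial_scores(mine))
    return out


def _mean_or_none(values: Iterable[float | None]) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


def animal_summary(
    scores: Sequence[TrialScores],
    records: Sequence[ExplorationRecord],
    exposure_phase_count: int = 2,
) -> AnimalSummary:
    """Summarise one animal: configuration totals, mean D2s, exposure splits.

    Undefined trial D2s are excluded from means, never imputed as zero;
    an animal with no defined trials at all is flagged ``excluded``.
    Exposure totals are split by presence of a context-specifier record in
    the phase, and the scaled total divides by the number of exposure
    phases to equate per-phase opportunity with the single test phase.
    """
    if not scores:
        raise ValueError("animal_summary needs at least one scored trial")
    animal = scores[0].animal_id
    if any(s.animal_id != animal for s in scores):
        raise ValueError("scores must all belong to one animal")

    sum_cn = sum(s.t_context_novel for s in scores)
    sum_cf = sum(s.t_context_familiar for s in scores)
    # recency framing re-labels the same two durations
    sum_rn = sum(
        s.t_context_novel if s.trial_type == "test_in_second" else s.t_context_familiar
        for s in scores
    )
    sum_rf = (sum_cn + sum_cf) - sum_rn

    mine = [r for r in records if r.animal_id == animal]
    exposure = [r for r in mine if r.phase in ("exposure1", "exposure2")]
    specifier_phases = {
        (r.session, r.trial, r.phase)
        for r in exposure
        if r.stimulus_kind == "context_specifier"
    }
    present = absent = 0.0
    for r in exposure:
        if r.stimulus_kind == "context_specifier":
            continue
        if (r.session, r.trial, r.phase) in specifier_phases:
            present += r.duration
        else:
            absent += r.duration

    defined = [s for s in scores if s.d2_context is not None]
    return AnimalSummary(
        animal_id=animal,
        sum_context_novel=sum_cn,
        sum_context_familiar=sum_cf,
        sum_recency_novel=sum_rn,
        sum_recency_familiar=sum_rf,
        mean_d2_context=_mean_or_none(s.d2_context for s in scores),
        mean_d2_recency=_mean_or_none(s.d2_recency for s in scores),
        mean_d2_side=_mean_or_none(s.d2_side for s in scores),
        mean_d2_context_first=_mean_or_none(
            s.d2_context for s in scores if s.trial_type == "test_in_first"
        ),
        mean_d2_context_second=_mean_or_none(
            s.d2_context for s in scores if s.trial_type == "test_in_second"
        ),
        exposure_specifier_present=present,
        exposure_specifier_absent=absent,
        exposure_total_scaled=(present + absent) / exposure_phase_count,
        n_trials_scored=len(scores),
        n_trials_defined=len(defined),
        excluded=not defined,
    )


def summarize_cohort(
    scores: Sequence[TrialScores],
    records: Sequence[ExplorationRecord],
    exposure_phase_count: int = 2,
) -> list[AnimalSummary]:
    animals = sorted({s.animal_id for s in scores})
    return [
        animal_summary(
            [s for s in scores if s.animal_id == a], records, exposure_phase_count
        )
        for a in animals
    ]


def flag_outliers(values: Sequence[float], k: float = OUTLIER_K) -> np.ndarray:
    """Flag values outside the Tukey fences [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation between order statistics. With fewer
    than 4 values no fence is meaningful: nothing is flagged and a warning
    is issued.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        warnings.warn("fewer than 4 values: outlier flagging skipped", stacklevel=2)
        return np.zeros(arr.shape, dtype=bool)
    q1, q3 = np.percentile(arr, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return (arr < lo) | (arr > hi)


def trial_scores_frame(scores: Sequence[TrialScores]) -> pd.DataFrame:
    """Tidy per-trial scores table (one row per trial)."""
    return pd.DataFrame(
        [
            {
                "animal_id": s.animal_id,
                "session": s.session,
                "trial": s.trial,
                "trial_type": s.trial_type,
                "t_context_novel": s.t_context_novel,
                "t_context_familiar": s.t_context_familiar,
                "d2_context": s.d2_context,
                "d2_recency": s.d2_recency,
                "d2_side": s.d2_side,
            }
            for s in scores
        ]
    )


def animal_summaries_frame(summaries: Sequence[AnimalSummary]) -> pd.DataFrame:
    from dataclasses import asdict

    return pd.DataFrame([asdict(s) for s in summaries])
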