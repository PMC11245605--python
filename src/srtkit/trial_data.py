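"""Data model, I/O and validation for scored spontaneous-recognition cohorts.

The unit of data is one manually scored exploration duration: one stimulus
(an object or a caged conspecific) in one phase of one trial for one animal.
Durations are pre-aggregated per phase — this module deliberately knows
nothing about bout-level timestamps or video.

Missing data are absent rows. A zero duration means "the stimulus was
present and the animal never explored it", which is a real observation and
must not be conflated with a missing trial.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "PHASES",
    "TRIAL_TYPES",
    "STIMULUS_KINDS",
    "SIDES",
    "SEXES",
    "ExplorationRecord",
    "DesignSpec",
    "ValidationReport",
    "SchemaError",
    "RowError",
    "DesignError",
    "IntegrityError",
    "load_bout_table",
    "write_bout_table",
    "records_to_frame",
    "frame_to_records",
    "validate_cohort",
]

PHASES = ("exposure1", "exposure2", "test")
TRIAL_TYPES = ("test_in_first", "test_in_second", "not_applicable")
STIMULUS_KINDS = ("object", "conspecific", "context_specifier")
SIDES = ("left", "right")
SEXES = ("male", "female")

#: column order of the on-disk bout table (UTF-8 CSV with a header row)
COLUMNS = (
    "experiment_id",
    "animal_id",
    "sex",
    "session",
    "trial",
    "phase",
    "trial_type",
    "stimulus_id",
    "stimulus_kind",
    "side",
    "duration",
)


class SchemaError(ValueError):
    """The table is structurally wrong (e.g. a required column is missing)."""


class RowError(ValueError):
    """A single row failed to parse; carries the zero-based row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class DesignError(ValueError):
    """Trial structure contradicts the experimental design."""


class IntegrityError(ValueError):
    """Duplicate or mutually contradictory records."""


@dataclass(frozen=True)
class ExplorationRecord:
    """One scored exploration duration (seconds) for one stimulus-phase."""

    experiment_id: str
    animal_id: str
    sex: str
    session: int
    trial: int
    phase: str
    trial_type: str
    stimulus_id: str
    stimulus_kind: str
    side: str
    duration: float

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(
                f"trial_type must be one of {TRIAL_TYPES}, got {self.trial_type!r}"
            )
        if self.stimulus_kind not in STIMULUS_KINDS:
            raise ValueError(
                f"stimulus_kind must be one of {STIMULUS_KINDS}, "
                f"got {self.stimulus_kind!r}"
            )
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.session < 1 or self.trial < 1:
            raise ValueError("session and trial are 1-based positive integers")
        d = float(self.duration)
        if not (d >= 0.0) or d != d or d == float("inf"):
            raise ValueError(f"duration must be finite and >= 0, got {self.duration}")
        if self.phase == "test" and self.trial_type == "not_applicable":
            raise ValueError("test-phase records must carry a real trial_type")


def _default_counterbalancing() -> dict[int, str]:
    # interleaved so each consecutive pair {1,2} and {3,4} holds one of each type
    return {1: "test_in_first", 2: "test_in_second", 3: "test_in_second", 4: "test_in_first"}


@dataclass
class DesignSpec:
    """Structure of one experimental session.

    The object-in-context default is four trials of three phases (two
    exposures then a test), with test-in-first and test-in-second trials
    interleaved so that every consecutive trial pair contains one of each —
    the property the circular pairing step relies on.
    """

    trials_per_session: int = 4
    phases_per_trial: int = 3
    counterbalancing: dict[int, str] = field(default_factory=_default_counterbalancing)
    expected_animals: list[str] | None = None
    exposure_phase_count: int = 2

    def __post_init__(self):
        for t, tt in self.counterbalancing.items():
            if tt not in ("test_in_first", "test_in_second"):
                raise DesignError(f"trial {t}: unknown trial_type {tt!r}")
        self.validate_interleaving()

    def validate_interleaving(self) -> None:
        """Each consecutive pair {2i-1, 2i} must hold one trial of each type."""
        trials = sorted(self.counterbalancing)
        for a, b in zip(trials[::2], trials[1::2]):
            pair = {self.counterbalancing[a], self.counterbalancing[b]}
            if pair != {"test_in_first", "test_in_second"}:
                raise DesignError(
                    f"trials {a} and {b} are both {self.counterbalancing[a]}; "
                    "consecutive pairs must interleave test types"
                )

    def trial_pairs(self) -> list[tuple[int, int]]:
        trials = sorted(self.counterbalancing)
        return list(zip(trials[::2], trials[1::2]))

    @classmethod
    def from_file(cls, path: str | Path) -> "DesignSpec":
        """Read a design from a YAML or JSON document mirroring the fields."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if "counterbalancing" in doc:
            doc["counterbalancing"] = {int(k): v for k, v in doc["counterbalancing"].items()}
        return cls(**doc)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        doc = asdict(self)
        if path.suffix == ".json":
            path.write_text(json.dumps(doc, indent=2), encoding="utf-8")
        else:
            path.write_text(yaml.safe_dump(doc), encoding="utf-8")


@dataclass
class ValidationReport:
    """Outcome of cohort validation: hard errors, advisory warnings, coverage."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    completeness: dict[str, dict] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_on_error(self) -> None:
        if self.errors:
            raise IntegrityError("; ".join(self.errors))


def records_to_frame(records: Iterable[ExplorationRecord]) -> pd.DataFrame:
    rows = [asdict(r) for r in records]
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[ExplorationRecord]:
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    records = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        try:
            duration = float(getattr(row, "duration"))
        except (TypeError, ValueError) as exc:
            raise RowError(idx, f"non-numeric duration {getattr(row, 'duration')!r}") from exc
        if not duration >= 0:
            raise RowError(idx, f"negative or non-finite duration {duration}")
        try:
            records.append(
                ExplorationRecord(
                    experiment_id=str(getattr(row, "experiment_id")),
                    animal_id=str(getattr(row, "animal_id")),
                    sex=str(getattr(row, "sex")),
                    session=int(getattr(row, "session")),
                    trial=int(getattr(row, "trial")),
                    phase=str(getattr(row, "phase")),
                    trial_type=str(getattr(row, "trial_type")),
                    stimulus_id=str(getattr(row, "stimulus_id")),
                    stimulus_kind=str(getattr(row, "stimulus_kind")),
                    side=str(getattr(row, "side")),
                    duration=duration,
                )
            )
        except ValueError as exc:
            raise RowError(idx, str(exc)) from exc
    return records


def load_bout_table(
    path: str | Path, design: DesignSpec | None = None
) -> list[ExplorationRecord]:
    """Load a scored bout table (CSV, one row per stimulus-phase).

    Raises :class:`SchemaError` when a required column is absent and
    :class:`RowError` (with the offending zero-based row index) when a
    duration fails to parse as a non-negative real.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return frame_to_records(frame)


def write_bout_table(records: Iterable[ExplorationRecord], path: str | Path) -> None:
    """Write records as UTF-8 CSV; durations at full repr precision."""
    frame = records_to_frame(records)
    frame["duration"] = [repr(float(d)) for d in frame["duration"]]
    frame.to_csv(path, index=False, encoding="utf-8")


def load_osf_deposit(path: str | Path, design: DesignSpec | None = None):
    """Convertor stub for the study's public data deposit.

    The deposit's table layout is not published alongside the deposit
    itself, so no mapping is shipped; adapt the file to the bout-table
    schema of :data:`COLUMNS` and use :func:`load_bout_table`.
    """
    raise NotImplementedError(
        "the deposit schema is unknown; convert to the bout-table CSV dialect "
        "and use load_bout_table()"
    )


def validate_cohort(
    records: Sequence[ExplorationRecord], design: DesignSpec | None = None
) -> ValidationReport:
    """Check a loaded cohort against the session design.

    Duplicated (animal, session, trial, phase, side) among to-be-recognised
    stimuli are hard errors; missing trials or phases are warnings with a
    per-animal completeness map (the analysis tolerates unequal n).
    Validation is order-independent: permuting the records changes nothing.
    """
    design = design or DesignSpec()
    report = ValidationReport()

    keyed = Counter(
        (r.animal_id, r.session, r.trial, r.phase, r.side)
        for r in records
        if r.stimulus_kind != "context_specifier"
    )
    for key, count in sorted(keyed.items()):
        if count > 1:
            report.errors.append(
                f"duplicate scored side: animal {key[0]} session {key[1]} "
                f"trial {key[2]} phase {key[3]} side {key[4]} appears {count} times"
            )

    animals = sorted({r.animal_id for r in records})
    if design.expected_animals:
        for a in design.expected_animals:
            if a not in animals:
                report.warnings.append(f"expected animal {a} contributed no records")

    expected_trials = sorted(design.counterbalancing)
    for animal in animals:
        mine = [r for r in records if r.animal_id == animal]
        sessions = sorted({r.session for r in mine})
        missing: list[tuple[int, int, str]] = []
        n_complete = 0
        for session in sessions:
            for trial in expected_trials:
                present = {
                    r.phase for r in mine if r.session == session and r.trial == trial
                }
                if not present:
                    missing.append((session, trial, "all phases"))
                    report.warnings.append(
                        f"animal {animal}: session {session} trial {trial} missing entirely"
                    )
                    continue
                absent = [p for p in PHASES if p not in present]
                if absent:
                    for p in absent:
                        missing.append((session, trial, p))
                        report.warnings.append(
                            f"animal {animal}: session {session} trial {trial} "
                            f"missing phase {p}"
                        )
                else:
                    n_complete += 1
        report.completeness[animal] = {
            "sessions": sessions,
            "complete_trials": n_complete,
            "missing": missing,
        }
    return report
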