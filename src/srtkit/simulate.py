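"""Synthetic spontaneous-recognition cohorts with known generative structure.

The generator emulates the statistical shape the analysis assumes: per-phase
total exploration times drawn from a positively skewed gamma law, a
preference split of each test phase's total between the two stimuli driven
by a latent mnemonic strategy, conspecific-presence facilitation of
exposure exploration, and elevated exploration of opposite-sex conspecifics.

The split model is chosen so that the expected D2 toward the
strategy-predicted stimulus equals the strategy strength delta exactly: the
predicted stimulus receives a fraction f of the phase total with
f ~ Beta(mu*kappa, (1-mu)*kappa), mu = (1+delta)/2, and D2 = 2f - 1, so
E[D2] = delta and Var shrinks as the concentration kappa grows
(kappa = inf gives f = mu deterministically). This makes parameter-recovery
targets analytic rather than calibrated.

All draws flow from a single numpy Generator seeded by the config, in a
fixed documented order (animal by animal, trial by trial, phase by phase),
so identical configs reproduce identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .trial_data import DesignSpec, ExplorationRecord

__all__ = [
    "STRATEGIES",
    "SimulationConfig",
    "simulate_object_in_context",
    "simulate_conspecific_in_context",
    "simulate_raters",
]

STRATEGIES = (
    "context_novel",
    "recency_novel",
    "context_familiar",
    "recency_familiar",
    "none",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic cohort.

    Defaults mirror the study conditions: 10 animals (half male), four
    interleaved object-in-context trials per session, a context-novel
    strategy of strength 0.6 at split concentration 20, gamma-distributed
    phase totals of order 20 s (objects), conspecific-presence facilitation
    of exposure exploration ~1.33x, and a 4x opposite-sex multiplier for
    conspecific test sessions.
    """

    n_animals: int = 10
    trials_per_animal: int = 4
    strategy: str = "context_novel"
    delta: float = 0.6
    kappa: float = 20.0
    total_shape: float = 4.0
    total_scale: float = 5.0
    facilitation: float = 1.33
    opposite_sex_multiplier: float = 4.0
    rater_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if min(self.total_shape, self.total_scale) <= 0:
            raise ValueError("gamma total-time parameters must be positive")
        if min(self.facilitation, self.opposite_sex_multiplier) <= 0:
            raise ValueError("multipliers must be positive")
        if self.n_animals < 1 or self.trials_per_animal < 1:
            raise ValueError("cohort sizes must be positive")
        if self.trials_per_animal % 2:
            raise ValueError("trials_per_animal must be even (paired trial types)")


def _split_fraction(rng: np.random.Generator, mu: float, kappa: float) -> float:
    """Fraction of the phase total assigned to the predicted stimulus."""
    if math.isinf(kappa):
        return mu
    if mu <= 0.0 or mu >= 1.0:
        # degenerate preference (delta = 1): all exploration on the target
        return float(mu > 0.5)
    return float(rng.beta(mu * kappa, (1.0 - mu) * kappa))


def _strategy_mu(delta: float, strategy: str) -> float:
    return 0.5 if strategy == "none" else (1.0 + delta) / 2.0


def _predicted_stimulus(strategy: str, trial_type: str,
                        from_exp1: str, from_exp2: str) -> str:
    """Which test stimulus the latent strategy predicts more exploration of.

    Context strategies track the stimulus whose exposure context mismatches
    the test context; recency strategies track exposure order. They agree
    in test-in-second trials and disagree in test-in-first trials.
    """
    context_novel = from_exp2 if trial_type == "test_in_first" else from_exp1
    context_familiar = from_exp1 if trial_type == "test_in_first" else from_exp2
    return {
        "context_novel": context_novel,
        "context_familiar": context_familiar,
        "recency_novel": from_exp1,
        "recency_familiar": from_exp2,
        "none": context_novel,  # mu = 0.5; orientation irrelevant
    }[strategy]


def _animal_design(index: int) -> DesignSpec:
    """Counterbalanced trial-type maps: animals alternate the pair order."""
    if index % 2 == 0:
        cb = {1: "test_in_first", 2: "test_in_second",
              3: "test_in_second", 4: "test_in_first"}
    else:
        cb = {1: "test_in_second", 2: "test_in_first",
              3: "test_in_first", 4: "test_in_second"}
    return DesignSpec(counterbalancing=cb)


def simulate_object_in_context(config: SimulationConfig) -> list[ExplorationRecord]:
    """Simulate an object-in-context cohort (the two-object-pair design).

    Each trial emits two exposure phases (one object pair each, identical
    duplicates left and right) and a test phase holding one copy from each
    exposure. The context specifier (a conspecific partner) is present in
    whichever exposure context is *not* revisited at test — the subject is
    always alone at test — and boosts that phase's object exploration by
    the facilitation multiplier, alongside a scored conspecific bout.
    """
    rng = np.random.default_rng(config.seed)
    mu = _strategy_mu(config.delta, config.strategy)
    records: list[ExplorationRecord] = []
    for ai in range(config.n_animals):
        animal = f"m{ai + 1:02d}"
        sex = "male" if ai < (config.n_animals + 1) // 2 else "female"
        design = _animal_design(ai)
        for trial in range(1, config.trials_per_animal + 1):
            tt = design.counterbalancing[(trial - 1) % 4 + 1]
            sid1, sid2 = f"t{trial}_x", f"t{trial}_y"
            # conspecific accompanies the exposure context not used at test
            specifier_phase = "exposure2" if tt == "test_in_first" else "exposure1"
            for phase, sid in (("exposure1", sid1), ("exposure2", sid2)):
                total = rng.gamma(config.total_shape, config.total_scale)
                frac = _split_fraction(rng, 0.5, config.kappa)
                boost = config.facilitation if phase == specifier_phase else 1.0
                for side, dur in (("left", total * frac), ("right", total * (1 - frac))):
                    records.append(ExplorationRecord(
                        experiment_id="exp_object_in_context", animal_id=animal,
                        sex=sex, session=1, trial=trial, phase=phase,
                        trial_type="not_applicable", stimulus_id=sid,
                        stimulus_kind="object", side=side, duration=dur * boost,
                    ))
                if phase == specifier_phase:
                    records.append(ExplorationRecord(
                        experiment_id="exp_object_in_context", animal_id=animal,
                        sex=sex, session=1, trial=trial, phase=phase,
                        trial_type="not_applicable", stimulus_id="partner",
                        stimulus_kind="context_specifier", side="left",
                        duration=float(rng.gamma(2.0, 2.0)),
                    ))
            total = rng.gamma(config.total_shape, config.total_scale)
            frac = _split_fraction(rng, mu, config.kappa)
            target = _predicted_stimulus(config.strategy, tt, sid1, sid2)
            target_side = "left" if rng.random() < 0.5 else "right"
            for sid in (sid1, sid2):
                dur = total * frac if sid == target else total * (1 - frac)
                side = target_side if sid == target else (
                    "right" if target_side == "left" else "left"
                )
                records.append(ExplorationRecord(
                    experiment_id="exp_object_in_context", animal_id=animal,
                    sex=sex, session=1, trial=trial, phase="test",
                    trial_type=tt, stimulus_id=sid, stimulus_kind="object",
                    side=side, duration=dur,
                ))
    return records


def simulate_conspecific_in_context(config: SimulationConfig) -> list[ExplorationRecord]:
    """Simulate a conspecific-in-context cohort (three sessions, one trial).

    Each session's trial: exposure 1 presents conspecifics A and B in the
    first context; exposure 2 presents B and a newly introduced C in the
    second context; the test returns to the first context with A (same
    context, seen longer ago) and C (contextual mismatch, seen more
    recently) — structurally a test-in-first trial, so a context-novel
    strategy predicts exploration of C and a recency-novel strategy of A.
    The third session uses opposite-sex conspecifics: all its durations
    scale by the opposite-sex multiplier.
    """
    rng = np.random.default_rng(config.seed)
    mu = _strategy_mu(config.delta, config.strategy)
    records: list[ExplorationRecord] = []
    for ai in range(config.n_animals):
        animal = f"m{ai + 1:02d}"
        sex = "male" if ai < (config.n_animals + 1) // 2 else "female"
        for session in (1, 2, 3):
            sex_mult = config.opposite_sex_multiplier if session == 3 else 1.0
            ids = {c: f"s{session}_{c}" for c in "ABC"}
            for phase, pair in (("exposure1", ("A", "B")), ("exposure2", ("B", "C"))):
                total = rng.gamma(config.total_shape, config.total_scale) * sex_mult
                frac = _split_fraction(rng, 0.5, config.kappa)
                for c, dur in zip(pair, (total * frac, total * (1 - frac))):
                    records.append(ExplorationRecord(
                        experiment_id="exp_conspecific_in_context", animal_id=animal,
                        sex=sex, session=session, trial=1, phase=phase,
                        trial_type="not_applicable", stimulus_id=ids[c],
                        stimulus_kind="conspecific",
                        side="left" if c == pair[0] else "right", duration=dur,
                    ))
            total = rng.gamma(config.total_shape, config.total_scale) * sex_mult
            frac = _split_fraction(rng, mu, config.kappa)
            target = _predicted_stimulus(
                config.strategy, "test_in_first", ids["A"], ids["C"]
            )
            target_side = "left" if rng.random() < 0.5 else "right"
            for c in ("A", "C"):
                sid = ids[c]
                dur = total * frac if sid == target else total * (1 - frac)
                side = target_side if sid == target else (
                    "right" if target_side == "left" else "left"
                )
                records.append(ExplorationRecord(
                    experiment_id="exp_conspecific_in_context", animal_id=animal,
                    sex=sex, session=session, trial=1, phase="test",
                    trial_type="test_in_first", stimulus_id=sid,
                    stimulus_kind="conspecific", side=side, duration=dur,
                ))
    return records


def simulate_raters(
    true_durations: Sequence[float],
    k: int = 3,
    noise_sd: float = 0.5,
    bias_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate k raters rescoring the same bouts (items x raters matrix).

    Rater r's score of item i is truth_i + bias_r + noise_ir, with the
    per-rater bias drawn once and the noise independently per cell;
    scores truncate at zero (a scored duration cannot be negative).
    """
    if noise_sd < 0 or bias_sd < 0:
        raise ValueError("noise_sd and bias_sd must be >= 0")
    rng = np.random.default_rng(seed)
    truth = np.asarray(true_durations, dtype=float)
    bias = rng.normal(0.0, bias_sd, size=k) if bias_sd > 0 else np.zeros(k)
    noise = rng.normal(0.0, noise_sd, size=(truth.size, k)) if noise_sd > 0 else 0.0
    return np.maximum(truth[:, None] + bias[None, :] + noise, 0.0)
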