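"""Circular strategy analysis for paired-trial spontaneous recognition data.

A pair of consecutive trials — one test-in-first-context, one
test-in-second-context — yields a point (D2_second, D2_first) in the plane.
Its polar angle

    theta = atan2(D2_first, D2_second)            (degrees, in (-180, 180])

places coherent mnemonic strategies on the diagonals:

* +45 deg: context-novel (novelty preference driven by contextual mismatch),
* -45 deg: recency-novel (novelty preference for the longer-ago stimulus),
* +135 deg: recency-familiar,
* -135 deg: context-familiar,

while the axes (0, +/-90, 180 deg) indicate preference expressed in only one
of the two trial types. A cohort using a coherent strategy produces angles
clustered on one diagonal; strategy-free behaviour produces no directional
structure, which Rao's spacing test assesses against circular uniformity.

Note on the arctangent: the vertical component is always the
test-in-first-context D2 and the horizontal component the
test-in-second-context D2. Spreadsheet-style ATAN2 notation lists the
horizontal argument first; the standard math convention lists the vertical
first. This module takes (d2_first, d2_second) in named order, so the
convention cannot be misapplied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .discrimination import TrialScores
from .trial_data import DesignError, DesignSpec

__all__ = [
    "AngularPoint",
    "CircularSummary",
    "RaoTestResult",
    "StrategyClassification",
    "IDEAL_ANGLES",
    "normalize_angle",
    "strategy_angle",
    "session_angles",
    "circular_mean",
    "circular_median",
    "circular_summary",
    "rao_spacing_statistic",
    "rao_null_sample",
    "rao_spacing_test",
    "angular_histogram",
    "classify_strategy",
]

#: ideal directions (degrees) of the four perfectly coherent strategies
IDEAL_ANGLES = {
    "context_novel": 45.0,
    "recency_novel": -45.0,
    "recency_familiar": 135.0,
    "context_familiar": -135.0,
}

#: axis directions indicating preference in only one trial type
AXIS_NOTES = {
    0.0: "second_context_trials_only",
    180.0: "second_context_trials_only",
    90.0: "first_context_trials_only",
    -90.0: "first_context_trials_only",
}


@dataclass(frozen=True)
class AngularPoint:
    """One paired-trial circular data point for one animal."""

    animal_id: str
    pair_index: int
    d2_first: float
    d2_second: float
    angle: float


@dataclass
class CircularSummary:
    """Descriptive and (optionally) inferential circular statistics.

    ``secondary_direction`` is the circular median — the angle minimising
    mean absolute circular deviation, with a midpoint tie rule. That is a
    convention of this package, recorded in ``secondary_definition``.
    """

    n: int
    mean_direction: float | None
    secondary_direction: float | None
    resultant_length: float
    rao_u: float | None = None
    rao_p: float | None = None
    alpha: float | None = None
    secondary_definition: str = "circular median (min mean absolute deviation, midpoint ties)"


@dataclass
class RaoTestResult:
    """Rao's spacing test of circular uniformity with a Monte-Carlo p."""

    n: int
    statistic: float
    p: float
    critical_value: float
    alpha: float
    reject: bool
    n_mc: int
    seed: int


@dataclass
class StrategyClassification:
    """Nearest coherent strategy for one angle.

    ``label`` is None for exact axis cases (two strategies equidistant);
    ``axis_note`` then says which single trial type carried the preference.
    """

    label: str | None
    distance: float
    axis_note: str | None


def normalize_angle(deg: float) -> float:
    """Map any angle in degrees to the interval (-180, 180]."""
    a = math.fmod(deg, 360.0)
    if a > 180.0:
        a -= 360.0
    elif a <= -180.0:
        a += 360.0
    return a


def strategy_angle(d2_first: float, d2_second: float) -> float | None:
    """Angle (degrees) of the paired-D2 point; None when both D2s are zero.

    The vertical component is the test-in-first-context D2 and the
    horizontal component the test-in-second-context D2, so equal positive
    preference in both trial types maps to exactly +45 deg.
    """
    if d2_first == 0.0 and d2_second == 0.0:
        return None
    return normalize_angle(math.degrees(math.atan2(d2_first, d2_second)))


def session_angles(
    scores: Sequence[TrialScores], design: DesignSpec | None = None
) -> list[AngularPoint]:
    """Build paired-trial circular points from one or more animals' scores.

    Consecutive trial pairs ({1,2}, {3,4}, ...) must each contain one
    test-in-first and one test-in-second trial. A complete 4-trial session
    yields two points per animal (n = 20 for a 10-animal cohort). Pairs
    with a missing trial, an undefined member D2, or a zero-zero angle are
    dropped with a warning.
    """
    design = design or DesignSpec()
    points: list[AngularPoint] = []
    for animal in sorted({s.animal_id for s in scores}):
        for session in sorted({s.session for s in scores if s.animal_id == animal}):
            mine = {
                s.trial: s
                for s in scores
                if s.animal_id == animal and s.session == session
            }
            for pair_index, (a, b) in enumerate(design.trial_pairs(), start=1):
                got = [mine[t] for t in (a, b) if t in mine]
                if len(got) < 2:
                    warnings.warn(
                        f"animal {animal} session {session}: trial pair ({a},{b}) "
                        "incomplete, circular point dropped", stacklevel=2,
                    )
                    continue
                types = {s.trial_type for s in got}
                if types != {"test_in_first", "test_in_second"}:
                    raise DesignError(
                        f"animal {animal} session {session}: pair ({a},{b}) holds "
                        f"trial types {sorted(types)}; one of each type required"
                    )
                first = next(s for s in got if s.trial_type == "test_in_first")
                second = next(s for s in got if s.trial_type == "test_in_second")
                if first.d2_context is None or second.d2_context is None:
                    warnings.warn(
                        f"animal {animal} session {session}: pair ({a},{b}) has an "
                        "undefined D2, circular point dropped", stacklevel=2,
                    )
                    continue
                angle = strategy_angle(first.d2_context, second.d2_context)
                if angle is None:
                    warnings.warn(
                        f"animal {animal} session {session}: pair ({a},{b}) is "
                        "(0, 0), angle undefined, point dropped", stacklevel=2,
                    )
                    continue
                points.append(
                    AngularPoint(
                        animal_id=animal,
                        pair_index=pair_index,
                        d2_first=first.d2_context,
                        d2_second=second.d2_context,
                        angle=angle,
                    )
                )
    return points


def circular_mean(angles_deg: Sequence[float]) -> tuple[float | None, float]:
    """Mean direction (deg) and resultant length of unit vectors.

    Returns (None, 0.0)-like output when the resultant vanishes (antipodal
    data): the direction of a zero vector is undefined.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("need at least one angle")
    c, s = np.cos(a).mean(), np.sin(a).mean()
    r = float(np.hypot(c, s))
    if r < 1e-12:
        return None, 0.0
    return normalize_angle(math.degrees(math.atan2(s, c))), r


def _mean_abs_deviation(angles: np.ndarray, phi: float) -> float:
    d = np.abs(np.vectorize(normalize_angle)(angles - phi))
    return float(d.mean())


def circular_median(angles_deg: Sequence[float]) -> float:
    """Angle minimising the mean absolute circular deviation.

    Candidates are the data points themselves; exact ties are resolved by
    the circular mean of the tied candidates (midpoint rule for even n).
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one angle")
    devs = np.array([_mean_abs_deviation(a, phi) for phi in a])
    best = devs.min()
    tied = a[np.isclose(devs, best, rtol=0, atol=1e-9)]
    med, r = circular_mean(tied)
    if med is None:  # antipodal tie: fall back to the first candidate
        med = normalize_angle(float(tied[0]))
    return med


def circular_summary(angles_deg: Sequence[float]) -> CircularSummary:
    """Descriptive circular summary: mean direction, R-bar, circular median."""
    a = [normalize_angle(x) for x in angles_deg]
    mean_dir, r = circular_mean(a)
    return CircularSummary(
        n=len(a),
        mean_direction=mean_dir,
        secondary_direction=circular_median(a),
        resultant_length=r,
    )


def rao_spacing_statistic(angles_deg: Sequence[float]) -> float:
    """Rao's spacing statistic U (degrees).

    Sort the angles on the circle; the n successive gaps T_i (including the
    wrap-around) sum to 360. U = 1/2 * sum(|T_i - 360/n|). U = 0 for
    perfectly even spacing and 360(1 - 1/n) when all angles coincide.
    """
    a = np.sort(np.mod(np.asarray(angles_deg, dtype=float), 360.0))
    n = a.size
    if n < 2:
        raise ValueError("Rao's spacing statistic needs at least 2 angles")
    gaps = np.diff(a, append=a[0] + 360.0)
    lam = 360.0 / n
    return float(0.5 * np.abs(gaps - lam).sum())


def rao_null_sample(n: int, n_mc: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate n_mc values of U under circular uniformity (vectorised)."""
    u = np.sort(rng.uniform(0.0, 360.0, size=(n_mc, n)), axis=1)
    gaps = np.diff(u, axis=1)
    wrap = (u[:, 0] + 360.0 - u[:, -1])[:, None]
    gaps = np.concatenate([gaps, wrap], axis=1)
    lam = 360.0 / n
    return 0.5 * np.abs(gaps - lam).sum(axis=1)


def rao_spacing_test(
    angles_deg: Sequence[float],
    alpha: float = 0.05,
    n_mc: int = 100_000,
    seed: int = 0,
) -> RaoTestResult:
    """Test circular uniformity by Rao's spacing statistic.

    The p-value is the Monte-Carlo proportion of null U values at the same
    n that reach the observed U, with the +1 continuity correction
    p = (1 + #{U_null >= U_obs}) / (n_mc + 1); the alpha-level critical
    value is the empirical (1 - alpha) null quantile. Deterministic given
    the seed. Below n = 4 the calibration is unreliable and the test
    refuses to run.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size < 4:
        raise ValueError("rao_spacing_test needs n >= 4 angles")
    u_obs = rao_spacing_statistic(a)
    rng = np.random.default_rng(seed)
    null = rao_null_sample(a.size, n_mc, rng)
    p = (1.0 + float((null >= u_obs).sum())) / (n_mc + 1.0)
    crit = float(np.quantile(null, 1.0 - alpha))
    return RaoTestResult(
        n=int(a.size),
        statistic=u_obs,
        p=p,
        critical_value=crit,
        alpha=alpha,
        reject=u_obs > crit,
        n_mc=n_mc,
        seed=seed,
    )


def angular_histogram(
    angles_deg: Sequence[float], bin_width: float = 22.5
) -> tuple[np.ndarray, np.ndarray]:
    """Counts over half-open bins [edge, edge + width) starting at -180 deg.

    With the default width of 22.5 deg this is the 16-bin rose-plot layout.
    Angles are normalised to (-180, 180] first; +180 wraps into the bin at
    -180 by the half-open rule. Returns (counts, edges) with len(edges) =
    len(counts) + 1 and counts summing to n.
    """
    if bin_width <= 0 or 360.0 % bin_width != 0:
        raise ValueError(f"bin width must divide 360, got {bin_width}")
    nbins = int(round(360.0 / bin_width))
    a = np.array([normalize_angle(x) for x in np.asarray(angles_deg, dtype=float)])
    idx = np.floor((a + 180.0) / bin_width).astype(int) % nbins
    counts = np.bincount(idx, minlength=nbins)
    edges = -180.0 + bin_width * np.arange(nbins + 1)
    return counts, edges


def _circ_dist(a: float, b: float) -> float:
    return abs(normalize_angle(a - b))


def classify_strategy(angle_deg: float) -> StrategyClassification:
    """Nearest coherent strategy (by circular distance) for one angle.

    Angles equidistant from two ideals — exactly the axis directions 0,
    +/-90 and 180 deg — are reported as axis cases: preference expressed in
    only one of the two trial types, with no strategy label assigned.
    """
    a = normalize_angle(angle_deg)
    dists = {lbl: _circ_dist(a, ideal) for lbl, ideal in IDEAL_ANGLES.items()}
    best = min(dists.values())
    winners = sorted(lbl for lbl, d in dists.items() if abs(d - best) < 1e-9)
    if len(winners) == 1:
        return StrategyClassification(label=winners[0], distance=best, axis_note=None)
    axis = min(AXIS_NOTES, key=lambda ax: _circ_dist(a, ax))
    return StrategyClassification(label=None, distance=best, axis_note=AXIS_NOTES[axis])
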