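"""End-to-end analysis runs: validate, score, summarise, test, report.

``run_full_report`` reproduces the full analysis sequence for a cohort:
configuration totals with paired t tests, per-framing and per-trial-type
one-sample t tests of D2 against zero, a side-bias check, quartile-based
outlier flags, the circular strategy construction with Rao's spacing test
and the 16-bin angular histogram, and — for the conspecific-in-context
design — repeated-measures ANOVAs with post-hocs. Outputs are tidy CSVs,
a versioned JSON summary and a plain-text log; everything is deterministic
given the input table and the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import circular as circ
from . import discrimination as disc
from . import inferential as infer
from .simulate import (
    SimulationConfig,
    simulate_conspecific_in_context,
    simulate_object_in_context,
)
from .trial_data import (
    DesignSpec,
    ExplorationRecord,
    load_bout_table,
    records_to_frame,
    validate_cohort,
)

__all__ = ["RunConfig", "run_full_report", "SUMMARY_SCHEMA_VERSION"]

SUMMARY_SCHEMA_VERSION = "1.0"

EXPERIMENTS = (
    "exp1_object_conspecific_context",
    "exp2_object_object_context",
    "exp3_conspecific_in_context",
)

CONVENTION_NOTES = {
    "arctangent": (
        "strategy angle = atan2(vertical = test-in-1st-context D2, "
        "horizontal = test-in-2nd-context D2), degrees in (-180, 180]"
    ),
    "secondary_direction": (
        "v is the circular median (minimum mean absolute deviation, "
        "midpoint tie rule); it is a package convention"
    ),
    "exposure_scaling": (
        "summed exposure exploration divided by the number of exposure "
        "phases when compared with test-phase exploration"
    ),
}


@dataclass
class RunConfig:
    """One analysis run: either a bout-table path or a simulation config."""

    experiment: str
    input_path: str | Path | None = None
    sim_config: SimulationConfig | None = None
    design: DesignSpec | None = None
    alpha: float = 0.05
    mc_reps: int = 100_000
    seed: int = 0
    out_dir: str | Path | None = None
    outlier_k: float = disc.OUTLIER_K

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {EXPERIMENTS}")
        if (self.input_path is None) == (self.sim_config is None):
            raise ValueError("provide exactly one of input_path / sim_config")


def _test_result_dict(r: infer.TestResult) -> dict:
    return {
        "label": r.label,
        "statistic": r.statistic,
        "df": r.df,
        "p": r.p,
        "effect": r.effect,
        "effect_name": r.effect_name,
        "ci": list(r.ci) if r.ci else None,
        "tails": r.tails,
        "degenerate": r.degenerate,
        "note": r.note,
    }


def _anova_dict(effects: dict[str, infer.AnovaEffect]) -> dict:
    return {name: dataclasses.asdict(e) for name, e in effects.items()}


def _one_sample_block(values: Sequence[float | None], label: str) -> dict:
    vals = [v for v in values if v is not None]
    block = {"label": label, "n": len(vals), "mean": None, "sd": None, "test": None}
    if vals:
        block["mean"] = float(np.mean(vals))
        block["sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
    if len(vals) >= 2:
        r = infer.one_sample_t(vals, 0.0)
        r.label = label
        block["test"] = _test_result_dict(r)
    return block


def _outlier_block(values: list[float], animals: list[str], k: float) -> dict:
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        flags = disc.flag_outliers(values, k=k) if values else np.array([], dtype=bool)
    return {
        "k": k,
        "flagged": [a for a, f in zip(animals, flags) if f],
    }


def _excluding(values: list[float], animals: list[str], flagged: list[str]):
    return [v for v, a in zip(values, animals) if a not in flagged]


def run_full_report(config: RunConfig) -> dict:
    """Run the full analysis and return (and optionally write) the summary.

    When ``config.out_dir`` is set, writes records.csv (simulated runs),
    trial_scores.csv, animal_summary.csv, angles.csv, histogram.csv,
    summary.json and run.log. The JSON summary is byte-identical across
    repeated runs with the same input and seed.
    """
    log: list[str] = []
    if config.sim_config is not None:
        sim = config.sim_config
        if config.experiment == "exp3_conspecific_in_context":
            records = simulate_conspecific_in_context(sim)
        else:
            records = simulate_object_in_context(sim)
        log.append(f"simulated cohort: {dataclasses.asdict(sim)}")
    else:
        records = load_bout_table(config.input_path, config.design)
        log.append(f"loaded {len(records)} records from {config.input_path}")
    if not records:
        raise ValueError("empty input: no exploration records")

    design = config.design or DesignSpec()
    report = validate_cohort(records, design)
    for w in report.warnings:
        log.append(f"validation warning: {w}")
    if not report.ok:
        raise ValueError("validation failed: " + "; ".join(report.errors))

    import warnings as _w

    with _w.catch_warnings(record=True) as caught:
        _w.simplefilter("always")
        scores = disc.score_cohort(records, design)
        summaries = disc.summarize_cohort(scores, records, design.exposure_phase_count)
        for c in caught:
            log.append(f"scoring warning: {c.message}")

    animals = [s.animal_id for s in summaries]
    excluded_animals = [s.animal_id for s in summaries if s.excluded]
    usable = [s for s in summaries if not s.excluded]
    for a in excluded_animals:
        log.append(f"excluded animal {a}: no trial with a defined D2")

    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "experiment": config.experiment,
        "seed": config.seed,
        "alpha": config.alpha,
        "conventions": CONVENTION_NOTES,
        "validation": {
            "n_animals": len(animals),
            "warnings": report.warnings,
            "completeness": {
                a: report.completeness[a]["complete_trials"]
                for a in report.completeness
            },
            "excluded_animals": excluded_animals,
        },
    }

    # ---- configuration totals and paired tests -------------------------
    cn = [s.sum_context_novel for s in usable]
    cf = [s.sum_context_familiar for s in usable]
    rn = [s.sum_recency_novel for s in usable]
    rf = [s.sum_recency_familiar for s in usable]
    ids = [s.animal_id for s in usable]

    out_cn = _outlier_block([a - b for a, b in zip(cn, cf)], ids, config.outlier_k)
    out_rn = _outlier_block([a - b for a, b in zip(rn, rf)], ids, config.outlier_k)
    for name, blk in (("context totals", out_cn), ("recency totals", out_rn)):
        for a in blk["flagged"]:
            log.append(f"outlier ({name}, k={config.outlier_k}): animal {a} excluded "
                       "from that comparison only")

    def paired_block(x, y, flagged, label):
        xk = _excluding(x, ids, flagged)
        yk = _excluding(y, ids, flagged)
        blk = {
            "label": label,
            "n": len(xk),
            "mean_a": float(np.mean(xk)) if xk else None,
            "mean_b": float(np.mean(yk)) if yk else None,
            "sd_a": float(np.std(xk, ddof=1)) if len(xk) > 1 else None,
            "sd_b": float(np.std(yk, ddof=1)) if len(yk) > 1 else None,
            "test": None,
            "outliers_excluded": flagged,
        }
        if len(xk) >= 2:
            r = infer.paired_t(xk, yk)
            r.label = label
            blk["test"] = _test_result_dict(r)
        return blk

    summary["configuration_totals"] = {
        "context": paired_block(cn, cf, out_cn["flagged"],
                                "context_novel vs context_familiar totals"),
        "recency": paired_block(rn, rf, out_rn["flagged"],
                                "recency_novel vs recency_familiar totals"),
    }

    # ---- D2 one-sample tests -------------------------------------------
    summary["d2_tests"] = {
        "context_overall": _one_sample_block(
            [s.mean_d2_context for s in usable], "mean context D2 vs 0"),
        "recency_overall": _one_sample_block(
            [s.mean_d2_recency for s in usable], "mean recency D2 vs 0"),
        "context_test_in_first": _one_sample_block(
            [s.mean_d2_context_first for s in usable],
            "context D2 (test-in-1st trials) vs 0"),
        "context_test_in_second": _one_sample_block(
            [s.mean_d2_context_second for s in usable],
            "context D2 (test-in-2nd trials) vs 0"),
        "side_bias": _one_sample_block(
            [s.mean_d2_side for s in usable], "mean side D2 vs 0"),
    }

    # ---- exposure control ----------------------------------------------
    test_totals = [s.sum_context_novel + s.sum_context_familiar for s in usable]
    exposure_scaled = [s.exposure_total_scaled for s in usable]
    exposure_block = {
        "scaled_exposure_mean": float(np.mean(exposure_scaled)) if usable else None,
        "test_mean": float(np.mean(test_totals)) if usable else None,
        "note": CONVENTION_NOTES["exposure_scaling"],
        "test": None,
        "specifier_presence": None,
    }
    if len(usable) >= 2 and any(exposure_scaled):
        r = infer.paired_t(exposure_scaled, test_totals)
        r.label = "scaled exposure vs test totals"
        exposure_block["test"] = _test_result_dict(r)
    pres = [s.exposure_specifier_present for s in usable]
    absn = [s.exposure_specifier_absent for s in usable]
    if any(pres):
        blk = {
            "present_mean": float(np.mean(pres)),
            "absent_mean": float(np.mean(absn)),
            "test": None,
        }
        if len(usable) >= 2:
            r = infer.paired_t(pres, absn)
            r.label = "exposure exploration: specifier present vs absent"
            blk["test"] = _test_result_dict(r)
        exposure_block["specifier_presence"] = blk
    summary["exposure_control"] = exposure_block

    # ---- circular strategy analysis (paired-trial designs) -------------
    angles_frame = None
    hist_frame = None
    if config.experiment != "exp3_conspecific_in_context":
        with _w.catch_warnings(record=True) as caught:
            _w.simplefilter("always")
            points = circ.session_angles(scores, design)
            for c in caught:
                log.append(f"circular warning: {c.message}")
        angles = [p.angle for p in points]
        block: dict = {"n": len(angles), "points_per_animal": None}
        if angles:
            desc = circ.circular_summary(angles)
            counts, edges = circ.angular_histogram(angles)
            block.update({
                "mean_direction": desc.mean_direction,
                "secondary_direction": desc.secondary_direction,
                "resultant_length": desc.resultant_length,
                "histogram_bin_width": 22.5,
            })
            hist_frame = pd.DataFrame({
                "bin_start": edges[:-1], "bin_end": edges[1:], "count": counts,
            })
            if desc.mean_direction is not None:
                cls = circ.classify_strategy(desc.mean_direction)
                block["mean_strategy"] = cls.label
                block["mean_strategy_distance"] = cls.distance
                block["mean_strategy_axis_note"] = cls.axis_note
            if len(angles) >= 4:
                rao = circ.rao_spacing_test(
                    angles, alpha=config.alpha, n_mc=config.mc_reps, seed=config.seed
                )
                block["rao"] = dataclasses.asdict(rao)
        angles_frame = pd.DataFrame([
            {
                "animal_id": p.animal_id, "pair_index": p.pair_index,
                "d2_first": p.d2_first, "d2_second": p.d2_second,
                "angle": p.angle,
                "strategy": circ.classify_strategy(p.angle).label,
            }
            for p in points
        ])
        summary["circular"] = block

    # ---- conspecific-in-context ANOVAs ---------------------------------
    if config.experiment == "exp3_conspecific_in_context":
        rows = []
        d2_rows = []
        for s in scores:
            # conspecific C = context-novel configuration, A = same-context
            rows.append({"subject": s.animal_id, "session": s.session,
                         "conspecific": "C", "value": s.t_context_novel})
            rows.append({"subject": s.animal_id, "session": s.session,
                         "conspecific": "A", "value": s.t_context_familiar})
            if s.d2_context is not None:
                d2_rows.append({"subject": s.animal_id, "session": s.session,
                                "value": s.d2_context})
        long = pd.DataFrame(rows)
        with _w.catch_warnings(record=True) as caught:
            _w.simplefilter("always")
            effects = infer.rm_anova_within(long, ["session", "conspecific"])
            posthoc_session = infer.pairwise_posthoc(
                long, "session", "bonferroni", factors=["session", "conspecific"])
            posthoc_consp = infer.pairwise_posthoc(
                long, "conspecific", "fisher_lsd", factors=["session", "conspecific"])
            d2_long = pd.DataFrame(d2_rows)
            d2_effects = infer.rm_anova_within(d2_long, ["session"])
            d2_posthoc = infer.pairwise_posthoc(d2_long, "session", "bonferroni")
            for c in caught:
                log.append(f"anova warning: {c.message}")
        summary["anova"] = {
            "exploration": _anova_dict(effects),
            "posthoc_session_bonferroni": [
                _test_result_dict(r) for r in posthoc_session],
            "posthoc_conspecific_lsd": [
                _test_result_dict(r) for r in posthoc_consp],
            "d2_by_session": _anova_dict(d2_effects),
            "d2_posthoc_bonferroni": [_test_result_dict(r) for r in d2_posthoc],
        }

    summary["log"] = log

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if config.sim_config is not None:
            records_to_frame(records).to_csv(out / "records.csv", index=False)
        disc.trial_scores_frame(scores).to_csv(out / "trial_scores.csv", index=False)
        disc.animal_summaries_frame(summaries).to_csv(
            out / "animal_summary.csv", index=False)
        if angles_frame is not None:
            angles_frame.to_csv(out / "angles.csv", index=False)
        if hist_frame is not None:
            hist_frame.to_csv(out / "histogram.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8")
        (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")
    return summary
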