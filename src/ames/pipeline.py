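"""Orchestration: traces -> unit errors -> summaries -> curves -> tests.

``run_pipeline`` ties the whole analysis together and is deterministic:
re-running with the same configuration and data reproduces every output
table bitwise. A run log records the configuration hash, every unit
exclusion with its reason, and every degenerate-case warning; unit counts
reconcile as ``units_detected = units_analyzed + units_excluded``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from .config import RunConfig
from .curves import ResponseCurve, fit_group_curve, fit_participant_curve
from .metrics import (
    DegenerateUnitError,
    rescale_unit,
    resample_unit,
    magnitude_error,
    shape_error,
    summarize_participants,
)
from .preprocess import bandpass
from .segment import NoCompleteUnitError, segment_trace
from .simulate import SESSION_RATIOS, StudyDataset
from .stats import DegenerateDataError, PairedComparison, TestResult, compare_pre_post
from .templates import make_template
from .trace_io import read_dataset

TEST_PHASES = ("pre_test", "post_test")


@dataclass
class PipelineResult:
    """Tidy output tables of one pipeline run."""

    units: pd.DataFrame  # one row per analyzed motion unit
    participants: pd.DataFrame  # per participant x session x phase means
    curves: pd.DataFrame  # fitted response curves, long format
    tests: pd.DataFrame  # paired pre/post test results
    log: List[str] = field(default_factory=list)
    n_units_detected: int = 0
    n_units_excluded: int = 0

    @property
    def n_units_analyzed(self) -> int:
        return len(self.units)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.units.to_csv(out / "unit_errors.csv", index=False)
        self.participants.to_csv(out / "participant_summary.csv", index=False)
        self.curves.to_csv(out / "response_curves.csv", index=False)
        self.tests.to_csv(out / "test_results.csv", index=False)
        self.tests.to_json(out / "test_results.json", orient="records", indent=2)
        (out / "run_log.txt").write_text("\n".join(self.log) + "\n")


def analyze_dataset(dataset: StudyDataset, config: RunConfig | None = None) -> PipelineResult:
    """Run preprocessing, segmentation, metrics, curves and stats on a dataset."""
    config = config or RunConfig()
    log: List[str] = [f"config_hash: {config.config_hash()}"]
    spec = config.filter.to_spec()
    seg = config.segmentation
    templates = {
        s: make_template(config.amplitude_mm, config.frequency_hz, r)
        for s, r in SESSION_RATIOS.items()
    }

    unit_rows = []
    curves_by_key: Dict[tuple, ResponseCurve] = {}
    n_detected = 0
    n_excluded = 0
    for rec in dataset:
        label = f"{rec.participant}/{rec.session}/{rec.phase}"
        template = templates[rec.session]
        filtered = bandpass(rec.trace, spec)
        try:
            segres = segment_trace(
                filtered,
                expected_freq_hz=config.frequency_hz,
                prominence_frac=seg.prominence_frac,
                min_sep_frac=seg.min_sep_frac,
                duration_bounds_frac=seg.duration_bounds_frac,
            )
        except NoCompleteUnitError as exc:
            log.append(f"WARNING {label}: no complete unit ({exc})")
            continue
        n_detected += segres.n_detected
        n_excluded += segres.n_excluded
        for s, e, reason in segres.excluded:
            log.append(f"EXCLUDED {label}: unit [{s},{e}) reason={reason}")
        rescaled_units = []
        for i, unit in enumerate(segres.units):
            mag = magnitude_error(
                unit, config.target_mm, method=config.magnitude_method, template=template
            )
            try:
                nu = rescale_unit(
                    resample_unit(unit, config.n_resample, interp=config.interp)
                )
            except DegenerateUnitError:
                n_excluded += 1
                n_detected += 1  # the unit was detected but cannot be analyzed
                log.append(
                    f"EXCLUDED {label}: unit [{unit.start_index},{unit.end_index}) "
                    "reason=degenerate_rescale"
                )
                continue
            rescaled_units.append(nu)
            unit_rows.append(
                {
                    "participant": rec.participant,
                    "group": rec.group,
                    "session": rec.session,
                    "phase": rec.phase,
                    "unit": i,
                    "start_s": unit.start_index / filtered.sampling_rate_hz,
                    "duration_s": unit.duration_s,
                    "magnitude_error_mm": mag,
                    "shape_error": shape_error(nu, template),
                }
            )
        if rec.phase in TEST_PHASES and len(rescaled_units) >= 2:
            curves_by_key[(rec.group, rec.participant, rec.session, rec.phase)] = (
                fit_participant_curve(rescaled_units, n_grid=config.n_resample)
            )

    units = pd.DataFrame(unit_rows)
    if units.empty:
        raise NoCompleteUnitError("no motion units survived in the whole dataset")
    participants = summarize_participants(units)
    log.append(
        f"units_detected={n_detected} units_analyzed={len(units)} "
        f"units_excluded={n_excluded}"
    )

    curve_rows = []
    for (group, pid, session, phase), curve in sorted(curves_by_key.items()):
        for g, v in zip(curve.grid, curve.fitted):
            curve_rows.append(
                {
                    "level": "participant",
                    "group": group,
                    "id": pid,
                    "session": session,
                    "phase": phase,
                    "grid": g,
                    "fitted": v,
                }
            )
    groups = sorted({k[0] for k in curves_by_key})
    sessions = sorted({k[2] for k in curves_by_key})
    for group in groups:
        for session in sessions:
            for phase in TEST_PHASES:
                pcs = [
                    c
                    for (g, _, s, ph), c in sorted(curves_by_key.items())
                    if g == group and s == session and ph == phase
                ]
                if len(pcs) < 2:
                    log.append(
                        f"WARNING {group}/{session}/{phase}: "
                        f"{len(pcs)} participant curve(s); group curve skipped"
                    )
                    continue
                gc = fit_group_curve(pcs)
                for g, v in zip(gc.grid, gc.fitted):
                    curve_rows.append(
                        {
                            "level": "group",
                            "group": group,
                            "id": group,
                            "session": session,
                            "phase": phase,
                            "grid": g,
                            "fitted": v,
                        }
                    )
    curves = pd.DataFrame(curve_rows)

    test_rows = []
    for group in sorted(participants["group"].unique()):
        for session in sorted(participants["session"].unique()):
            cell = participants[
                (participants["group"] == group) & (participants["session"] == session)
            ]
            pre = cell[cell["phase"] == "pre_test"].set_index("participant")
            post = cell[cell["phase"] == "post_test"].set_index("participant")
            shared = sorted(set(pre.index) & set(post.index))
            for metric, col in [
                ("magnitude_error", "mean_magnitude_error_mm"),
                ("shape_error", "mean_shape_error"),
            ]:
                row = {"group": group, "session": session, "metric": metric, "n": len(shared)}
                if len(shared) < 3:
                    log.append(
                        f"WARNING {group}/{session}/{metric}: only {len(shared)} "
                        "matched participants; test skipped"
                    )
                    continue
                try:
                    res: TestResult = compare_pre_post(
                        PairedComparison(
                            pre=pre.loc[shared, col].to_numpy(),
                            post=post.loc[shared, col].to_numpy(),
                            metric=metric,
                            alpha=config.alpha,
                        )
                    )
                except DegenerateDataError as exc:
                    log.append(f"WARNING {group}/{session}/{metric}: degenerate ({exc})")
                    continue
                row.update(
                    {
                        "test_used": res.test_used,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "normality_p": res.normality_p,
                        "direction": res.direction,
                        "significant": bool(res.p_value < config.alpha),
                    }
                )
                test_rows.append(row)
    tests = pd.DataFrame(test_rows)

    return PipelineResult(
        units=units,
        participants=participants,
        curves=curves,
        tests=tests,
        log=log,
        n_units_detected=n_detected,
        n_units_excluded=n_excluded,
    )


def run_pipeline(
    config: RunConfig, data_dir: str | Path, out_dir: str | Path | None = None
) -> PipelineResult:
    """Load a trace tree by its manifest, analyze it, optionally write tables."""
    dataset = read_dataset(data_dir)
    result = analyze_dataset(dataset, config)
    if out_dir is not None:
        result.write(out_dir)
    return result


def learning_curve_table(participants: pd.DataFrame) -> pd.DataFrame:
    """Group-mean magnitude error per training trial (the trial-wise view).

    One row per group x session x trial with the across-participant mean
    of the per-participant mean magnitude error.
    """
    trials = participants[participants["phase"].str.startswith("trial_")].copy()
    trials["trial"] = trials["phase"].str.split("_").str[1].astype(int)
    out = (
        trials.groupby(["group", "session", "trial"], sort=True)[
            ["mean_magnitude_error_mm", "mean_shape_error"]
        ]
        .mean()
        .reset_index()
    )
    return out


def trial_slope(learning: pd.DataFrame, group: str, session: str) -> tuple[float, float]:
    """OLS slope (mm/trial) and its p-value of the group's trial-wise
    magnitude-error curve."""
    from scipy import stats as sps

    cell = learning[(learning["group"] == group) & (learning["session"] == session)]
    res = sps.linregress(cell["trial"], cell["mean_magnitude_error_mm"])
    return float(res.slope), float(res.pvalue)
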