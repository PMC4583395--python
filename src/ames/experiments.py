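"""Study-level Monte-Carlo experiments on the simulated design.

These drivers answer design-level questions about the whole chain
(simulate -> filter -> segment -> score -> paired test): the type-I error
of the routed pre/post comparison under a no-change learner, its power
under the default post-trial-feedback learning dynamics, and the
trial-wise learning-curve contrast between the feedback groups.

Each replicate study simulates the pre- and post-test trace of every
participant, runs the full per-trace pipeline, reduces to per-participant
mean errors, and applies the normality-routed paired comparison. Shorter
traces than the 20 s default can be requested to keep large replicate
counts cheap; the trace length only sets how many motion units average
into each participant mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import unit_errors
from .preprocess import FilterSpec, bandpass
from .segment import segment_trace
from .simulate import SimulationParams, simulate_trial
from .stats import DegenerateDataError, PairedComparison, compare_pre_post
from .templates import MotionTemplate


def participant_phase_errors(
    template: MotionTemplate,
    params: SimulationParams,
    phase: str,
    seed,
    duration_s: float = 20.0,
    sampling_rate_hz: float = 80.3,
    skill: tuple = (1.0, 1.0),
    spec: FilterSpec | None = None,
) -> tuple[float, float]:
    """(mean magnitude error mm, mean shape error) of one simulated trace,
    through the full filter/segment/score chain."""
    trace = simulate_trial(
        template, params, phase, seed, duration_s=duration_s,
        sampling_rate_hz=sampling_rate_hz, skill=skill,
    )
    seg = segment_trace(bandpass(trace, spec or FilterSpec()), template.frequency_hz)
    mags, shapes, _ = unit_errors(seg.units, template, target_mm=template.amplitude_mm)
    return float(mags.mean()), float(shapes.mean())


def simulate_pre_post_study(
    template: MotionTemplate,
    params: SimulationParams,
    n_participants: int,
    seed,
    duration_s: float = 20.0,
    metric: str = "magnitude",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-participant pre/post mean errors for one replicate study."""
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    pick = 0 if metric == "magnitude" else 1
    pre, post = [], []
    for pi, child in enumerate(root.spawn(n_participants)):
        skill_rng = np.random.default_rng(child)
        skill = tuple(np.exp(skill_rng.normal(0.0, params.participant_sd, size=2)))
        pre_seed, post_seed = child.spawn(2)
        pre.append(
            participant_phase_errors(
                template, params, "pre_test", pre_seed, duration_s, skill=skill
            )[pick]
        )
        post.append(
            participant_phase_errors(
                template, params, "post_test", post_seed, duration_s, skill=skill
            )[pick]
        )
    return np.asarray(pre), np.asarray(post)


@dataclass(frozen=True)
class RejectionSummary:
    n_replicates: int
    rejection_rate: float  # fraction of replicates with p < alpha
    correct_direction_rate: float  # rejected AND pre > post (error reduced)
    t_test_fraction: float  # how often normality routed to the paired t


def pre_post_rejection_rate(
    template: MotionTemplate,
    params: SimulationParams,
    n_participants: int,
    n_replicates: int,
    seed: int,
    duration_s: float = 20.0,
    alpha: float = 0.05,
    metric: str = "magnitude",
) -> RejectionSummary:
    """Rejection rate of the routed paired comparison over replicate studies.

    With a no-change ``params`` (equal learning-curve endpoints) this
    estimates the type-I error; with decaying defaults it estimates power
    and the rate of detecting the reduction with the correct sign.
    """
    rng_root = np.random.SeedSequence(seed)
    n_rej = 0
    n_correct = 0
    n_t = 0
    n_run = 0
    for rep_seed in rng_root.spawn(n_replicates):
        pre, post = simulate_pre_post_study(
            template, params, n_participants, rep_seed, duration_s, metric
        )
        try:
            res = compare_pre_post(PairedComparison(pre=pre, post=post, alpha=alpha))
        except DegenerateDataError:
            continue
        n_run += 1
        if res.test_used == "paired_t":
            n_t += 1
        if res.p_value < alpha:
            n_rej += 1
            if res.direction > 0:
                n_correct += 1
    return RejectionSummary(
        n_replicates=n_run,
        rejection_rate=n_rej / n_run,
        correct_direction_rate=n_correct / n_run,
        t_test_fraction=n_t / n_run,
    )


def trial_error_curve(
    template: MotionTemplate,
    params: SimulationParams,
    n_participants: int,
    n_seeds: int,
    seed: int,
    duration_s: float = 20.0,
) -> np.ndarray:
    """Seed-averaged group-mean magnitude error per training trial (1..8)."""
    from .simulate import N_TRIALS

    root = np.random.SeedSequence(seed)
    curves = []
    for rep in root.spawn(n_seeds):
        per_trial = np.zeros(N_TRIALS)
        for pi, child in enumerate(rep.spawn(n_participants)):
            skill_rng = np.random.default_rng(child)
            skill = tuple(np.exp(skill_rng.normal(0.0, params.participant_sd, size=2)))
            for k, tseed in enumerate(child.spawn(N_TRIALS)):
                per_trial[k] += participant_phase_errors(
                    template, params, f"trial_{k + 1}", tseed, duration_s, skill=skill
                )[0]
        curves.append(per_trial / n_participants)
    return np.mean(curves, axis=0)
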