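"""Synthetic learner-motion generator for the two-group training study.

Emulates the study's data tree: two groups (concurrent visual feedback vs
post-trial visual feedback), two sessions (simple 1:1 and complicated 2:1
lifting/thrusting), and per session a pre-training test, eight training
trials and a post-training test, one trace per participant x session x
phase.

A simulated trace is ``distorted template + low-frequency drift +
high-frequency jitter``:

* **amplitude error** — each cycle's peak-to-trough is ``A + d_k`` with
  ``d_k ~ N(0, s_mag)``; the per-unit magnitude error is then ``|d_k|``
  with expectation ``s_mag * sqrt(2/pi)``.
* **shape distortion** — a smooth monotone time-warp of each cycle
  (``u -> u + c_k sin(2 pi u) / (2 pi)``, ``c_k ~ N(0, 0.8 s_shape)``
  clipped to +/-0.9) plus a small second-harmonic admixture windowed to
  vanish at the cycle ends. Shape MSE grows continuously from 0 with
  ``s_shape``.
* **drift** — a sinusoid below the 0.2 Hz filter cut (default 0.05 Hz).
* **jitter** — three sinusoids with random frequencies above the 5 Hz cut
  (default 10-30 Hz band). Both nuisance terms are strictly band-limited,
  so the band-pass preprocessing removes them by construction.

The error scales follow an exponential learning curve per group and error
kind, ``E_t = E_inf + (E0 - E_inf) * exp(-t / tau)`` with trial index
t = 1..8; the pre-test uses the naive level (t = 0) and the post-test the
level reached after trial 8. The concurrent-feedback defaults are flat and
low, the post-trial-feedback defaults start high and decay — the
qualitative trial-wise contrast the study reports. Participants differ by
a lognormal skill multiplier applied to both error scales.

Every trace is seeded reproducibly from (seed, group, participant,
session, phase), so any subset of the dataset can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Tuple

import numpy as np

from .templates import MotionTemplate, make_template
from .trace import DomainError, MotionTrace

GROUPS = ("concurrent_vf", "post_trial_vf")
SESSIONS = ("simple", "complicated")
SESSION_RATIOS: Dict[str, Tuple[float, float]] = {"simple": (1.0, 1.0), "complicated": (2.0, 1.0)}
N_TRIALS = 8
PHASES = ("pre_test",) + tuple(f"trial_{k}" for k in range(1, N_TRIALS + 1)) + ("post_test",)


def phase_time(phase: str) -> int:
    """Learning-curve time of a phase: 0 for the naive pre-test, the trial
    number during training, and 8 (the level after the last trial) for the
    post-test."""
    if phase == "pre_test":
        return 0
    if phase == "post_test":
        return N_TRIALS
    if phase.startswith("trial_"):
        k = int(phase.split("_", 1)[1])
        if 1 <= k <= N_TRIALS:
            return k
    raise DomainError(f"unknown phase: {phase!r}")


@dataclass(frozen=True)
class LearningCurve:
    """Exponential decay of an error scale across trials."""

    initial: float  # E0, the naive level
    asymptote: float  # E_inf, the trained level
    tau: float = 2.5  # trials to decay by 1/e

    def __post_init__(self) -> None:
        if not self.initial >= self.asymptote >= 0:
            raise DomainError("need initial >= asymptote >= 0")
        if self.tau <= 0:
            raise DomainError("tau must be positive")

    def value(self, t: float) -> float:
        return self.asymptote + (self.initial - self.asymptote) * np.exp(-t / self.tau)


@dataclass(frozen=True)
class SimulationParams:
    """Error structure of one group's simulated learners.

    ``magnitude`` is in mm (peak-to-trough deviation scale); ``shape`` is
    the dimensionless scale of the within-cycle distortion. Drift must sit
    below the 0.2 Hz high-pass cut and jitter above the 5 Hz low-pass cut,
    so preprocessing can remove them.
    """

    magnitude: LearningCurve
    shape: LearningCurve
    drift_amp_mm: float = 0.3
    drift_freq_hz: float = 0.05
    noise_amp_mm: float = 0.1
    noise_band_hz: Tuple[float, float] = (10.0, 30.0)
    participant_sd: float = 0.25  # lognormal sigma of the skill multiplier

    def __post_init__(self) -> None:
        if self.drift_amp_mm < 0 or self.noise_amp_mm < 0 or self.participant_sd < 0:
            raise DomainError("scales must be non-negative")
        if not self.drift_freq_hz < 0.2:
            raise DomainError("drift frequency must be below the 0.2 Hz filter cut")
        if not 5.0 < self.noise_band_hz[0] < self.noise_band_hz[1]:
            raise DomainError("noise band must lie above the 5 Hz filter cut")


def concurrent_vf_params() -> SimulationParams:
    """Concurrent visual feedback: low, roughly flat error across trials."""
    return SimulationParams(
        magnitude=LearningCurve(initial=0.35, asymptote=0.30, tau=2.0),
        shape=LearningCurve(initial=0.12, asymptote=0.10, tau=2.0),
    )


def post_trial_vf_params() -> SimulationParams:
    """Post-trial visual feedback: high initial error decaying across trials."""
    return SimulationParams(
        magnitude=LearningCurve(initial=1.2, asymptote=0.25, tau=2.5),
        shape=LearningCurve(initial=0.8, asymptote=0.15, tau=2.5),
    )


def default_params_by_group() -> Dict[str, SimulationParams]:
    return {"concurrent_vf": concurrent_vf_params(), "post_trial_vf": post_trial_vf_params()}


def no_change_params(magnitude_scale: float = 0.5, shape_scale: float = 0.3) -> SimulationParams:
    """Constant error scales across all phases (null learning model)."""
    return SimulationParams(
        magnitude=LearningCurve(initial=magnitude_scale, asymptote=magnitude_scale, tau=1.0),
        shape=LearningCurve(initial=shape_scale, asymptote=shape_scale, tau=1.0),
    )


def simulate_trial(
    template: MotionTemplate,
    params: SimulationParams,
    phase: str,
    seed,
    duration_s: float = 20.0,
    sampling_rate_hz: float = 80.3,
    skill: Tuple[float, float] = (1.0, 1.0),
    meta: dict | None = None,
) -> MotionTrace:
    """One simulated trace for one phase; deterministic given the seed.

    ``skill`` is the participant's (magnitude, shape) error multiplier.
    With all error scales, drift and noise at zero the output equals
    ``sample_template`` exactly.
    """
    f = template.frequency_hz
    n_cycles = int(np.floor(duration_s * f))
    if n_cycles < 3:
        raise DomainError(
            f"{duration_s} s at {f} Hz gives {n_cycles} cycles; need >= 3 for an "
            "interior motion unit"
        )
    t_learn = phase_time(phase)
    s_mag = params.magnitude.value(t_learn) * skill[0]
    s_shape = params.shape.value(t_learn) * skill[1]

    rng = np.random.default_rng(seed)
    n = int(np.floor(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    cyc = np.floor(t * f).astype(int)
    u = t * f - cyc
    n_cyc_total = cyc[-1] + 1

    a = template.amplitude_mm
    d = rng.normal(0.0, s_mag, n_cyc_total) if s_mag > 0 else np.zeros(n_cyc_total)
    np.clip(d, -(a - 0.2), None, out=d)  # keep every cycle's excursion positive
    c = rng.normal(0.0, 0.8 * s_shape, n_cyc_total) if s_shape > 0 else np.zeros(n_cyc_total)
    np.clip(c, -0.9, 0.9, out=c)  # keep the time-warp monotone
    h = rng.normal(0.0, 0.12 * s_shape, n_cyc_total) if s_shape > 0 else np.zeros(n_cyc_total)

    w = u + c[cyc] * np.sin(2 * np.pi * u) / (2 * np.pi)
    base = template.cycle(w)
    admix = a * h[cyc] * np.sin(4 * np.pi * u) * np.sin(np.pi * u)
    y = (1.0 + d[cyc] / a) * (base + admix)

    drift_phase = rng.uniform(0.0, 2 * np.pi)
    if params.drift_amp_mm > 0:
        y = y + params.drift_amp_mm * np.sin(2 * np.pi * params.drift_freq_hz * t + drift_phase)
    noise_f = rng.uniform(*params.noise_band_hz, size=3)
    noise_phase = rng.uniform(0.0, 2 * np.pi, size=3)
    if params.noise_amp_mm > 0:
        for fj, pj in zip(noise_f, noise_phase):
            y = y + params.noise_amp_mm / np.sqrt(3) * np.sin(2 * np.pi * fj * t + pj)

    m = {"phase": phase, "role": "recording"}
    if meta:
        m.update(meta)
    return MotionTrace(y, sampling_rate_hz, m)


@dataclass(frozen=True)
class StudyDesign:
    """Structure of the training study."""

    groups: Tuple[str, ...] = GROUPS
    n_per_group: Dict[str, int] = field(
        default_factory=lambda: {"concurrent_vf": 10, "post_trial_vf": 11}
    )
    sessions: Tuple[str, ...] = SESSIONS
    phases: Tuple[str, ...] = PHASES
    trial_duration_s: float = 20.0
    sampling_rate_hz: float = 80.3
    amplitude_mm: float = 4.0
    frequency_hz: float = 1.0
    session2_pre_carryover: float = 0.0  # optional aftereffect: fraction of the
    # complicated-session pre-test error scale removed by session-1 training

    def template_for(self, session: str) -> MotionTemplate:
        return make_template(self.amplitude_mm, self.frequency_hz, SESSION_RATIOS[session])

    def participant_ids(self, group: str) -> List[str]:
        prefix = "c" if group == "concurrent_vf" else "p"
        return [f"{prefix}{i + 1:02d}" for i in range(self.n_per_group[group])]


@dataclass(frozen=True)
class TraceRecord:
    participant: str
    group: str
    session: str
    phase: str
    trace: MotionTrace


@dataclass
class StudyDataset:
    records: List[TraceRecord]

    def __iter__(self) -> Iterator[TraceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def select(self, **labels) -> List[TraceRecord]:
        out = self.records
        for key, val in labels.items():
            out = [r for r in out if getattr(r, key) == val]
        return out


def _trace_seed(seed: int, gi: int, pi: int, si: int, phi: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), gi, pi, si, phi])


def simulate_study(
    design: StudyDesign,
    params_by_group: Dict[str, SimulationParams] | None = None,
    seed: int = 0,
) -> StudyDataset:
    """The full data tree: one trace per participant x session x phase.

    Per-trace seeds are derived from (seed, group, participant, session,
    phase), so the same seed reproduces the dataset bitwise and any subset
    can be regenerated on its own.
    """
    params_by_group = params_by_group or default_params_by_group()
    for g in design.groups:
        if g not in params_by_group:
            raise DomainError(f"no simulation parameters for group {g!r}")
    records: List[TraceRecord] = []
    for gi, group in enumerate(design.groups):
        params = params_by_group[group]
        for pi, pid in enumerate(design.participant_ids(group)):
            skill_rng = np.random.default_rng(np.random.SeedSequence([int(seed), gi, pi]))
            skill = tuple(np.exp(skill_rng.normal(0.0, params.participant_sd, size=2)))
            for si, session in enumerate(design.sessions):
                template = design.template_for(session)
                sess_params = params
                if session == "complicated" and design.session2_pre_carryover > 0:
                    co = design.session2_pre_carryover
                    sess_params = replace(
                        params,
                        magnitude=replace(
                            params.magnitude,
                            initial=params.magnitude.asymptote
                            + (params.magnitude.initial - params.magnitude.asymptote) * (1 - co),
                        ),
                        shape=replace(
                            params.shape,
                            initial=params.shape.asymptote
                            + (params.shape.initial - params.shape.asymptote) * (1 - co),
                        ),
                    )
                for phi, phase in enumerate(design.phases):
                    trace = simulate_trial(
                        template,
                        sess_params,
                        phase,
                        _trace_seed(seed, gi, pi, si, phi),
                        duration_s=design.trial_duration_s,
                        sampling_rate_hz=design.sampling_rate_hz,
                        skill=skill,
                        meta={
                            "participant": pid,
                            "group": group,
                            "session": session,
                            "phase": phase,
                        },
                    )
                    records.append(TraceRecord(pid, group, session, phase, trace))
    return StudyDataset(records)
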