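"""Ideal lifting/thrusting motion templates.

The training target is a 4-mm, 1-Hz cyclic displacement. With equal lifting
and thrusting time (ratio 1:1) the waveform is a pure sinusoid. With unequal
timing (e.g. lifting:thrusting = 2:1) it is realised as a *warped sine*:
``A/2 * (1 - cos(2*pi*w(u)))`` where the monotone phase map ``w`` runs fast
through the thrust and slow through the lift, with smooth (C1) cosine
transitions of half-width ``warp_delta`` centred on the trough and the peak.
Because the phase speed is locally symmetric about both extrema, the
waveform's curvature there is symmetric, so band-limiting the signal (as the
0.2-5 Hz preprocessing filter does) leaves the trough and peak positions in
place — which keeps filtered motion units comparable to the template under
the shared trough-anchored phase convention. For ratio 1:1 the phase map is
the identity and the waveform is the pure sine exactly.

Phase convention: every cycle starts at the trough (the most-lifted, i.e.
shallowest, needle position), rises through the thrust to the single peak,
and falls back through the lift. This matches the segmentation convention
of delimiting motion units at the relatively lower points of a recording,
so template and segmented units are comparable without any phase search.
The template minimum is 0 mm; displacement is depth relative to the most
lifted position, and all downstream error metrics are offset-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .trace import DomainError, MotionTrace


@dataclass(frozen=True)
class MotionTemplate:
    """Parametric one-cycle lifting/thrusting waveform.

    Parameters
    ----------
    amplitude_mm :
        Peak-to-trough displacement (the study target is 4 mm).
    frequency_hz :
        Cycles per second (study target 1 Hz).
    lift_thrust_ratio :
        ``(lift_time, thrust_time)`` proportions within one cycle;
        (1, 1) gives the simple pure-sine template, (2, 1) the
        complicated one.
    """

    amplitude_mm: float
    frequency_hz: float
    lift_thrust_ratio: Tuple[float, float]
    warp_delta: float = 0.125  # half-width (cycle fraction) of the speed ramps

    def __post_init__(self) -> None:
        if self.amplitude_mm <= 0:
            raise DomainError("amplitude_mm must be positive")
        if self.frequency_hz <= 0:
            raise DomainError("frequency_hz must be positive")
        rl, rt = self.lift_thrust_ratio
        if rl <= 0 or rt <= 0:
            raise DomainError("both lift_thrust_ratio components must be positive")
        if not 0 < self.warp_delta <= 0.25:
            raise DomainError("warp_delta must be in (0, 0.25]")
        # the phase map must stay monotone for this ratio
        _, q, low = self._warp_coeffs()
        if low <= 0 or low + q <= 0:
            raise DomainError(
                f"lift:thrust ratio {rl}:{rt} is too extreme for a monotone waveform"
            )

    @property
    def period_s(self) -> float:
        return 1.0 / self.frequency_hz

    @property
    def thrust_fraction(self) -> float:
        """Fraction of the cycle spent thrusting (rising from trough to peak)."""
        rl, rt = self.lift_thrust_ratio
        return rt / (rl + rt)

    def _delta(self) -> float:
        """Ramp half-width, clipped so the trough and peak ramps never overlap."""
        ft = self.thrust_fraction
        return min(self.warp_delta, 0.5 * ft, 0.5 * (1.0 - ft))

    def _warp_coeffs(self) -> Tuple[float, float, float]:
        """(delta, q, l): phase speed is ``l`` in the lift, ``l + q`` in the
        thrust, with cosine ramps of half-width ``delta`` between them.

        Solves ``w(1) = 1`` and ``w(thrust_fraction) = 1/2`` so the peak sits
        exactly at the stated thrust fraction of the cycle. For ratio 1:1,
        q = 0 and the map is the identity.
        """
        ft = self.thrust_fraction
        d = self._delta()
        c = 1.0 - 2.0 / np.pi  # integral asymmetry of a half cosine ramp
        denom = ft * (1.0 - ft) - c * d
        if denom <= 0:
            return d, np.inf, -np.inf
        q = (0.5 - ft) / denom
        return d, q, 1.0 - q * ft

    def phase_map(self, u) -> np.ndarray:
        """Monotone warp ``w(u)`` on [0, 1): fast thrust, slow lift, smooth
        joins; identity for ratio 1:1."""
        u = np.asarray(u, dtype=float) % 1.0
        ft = self.thrust_fraction
        d, q, low = self._warp_coeffs()
        # S(u) = integral of the ramp profile (1 in the thrust, 0 in the lift,
        # half-cosine transitions centred on u=0 and u=ft)
        s = np.empty_like(u)
        m = u <= d
        s[m] = 0.5 * u[m] + (d / np.pi) * (1.0 - np.cos(np.pi * u[m] / (2 * d)))
        m = (u > d) & (u <= ft - d)
        s[m] = 0.5 * d + d / np.pi + (u[m] - d)
        m = (u > ft - d) & (u <= ft + d)
        s[m] = (
            ft
            - 1.5 * d
            + d / np.pi
            + 0.5 * (u[m] - ft + d)
            + (d / np.pi) * np.cos(np.pi * (u[m] - ft) / (2 * d))
        )
        m = (u > ft + d) & (u <= 1.0 - d)
        s[m] = ft - 0.5 * d + d / np.pi
        m = u > 1.0 - d
        s[m] = (
            ft
            - 0.5 * d
            + d / np.pi
            + 0.5 * (u[m] - 1.0 + d)
            - (d / np.pi) * np.cos(np.pi * (u[m] - 1.0) / (2 * d))
        )
        return low * u + q * s

    def cycle(self, u) -> np.ndarray:
        """Waveform on normalised cycle time ``u`` (cycle fraction, any real).

        ``u`` is taken modulo 1; the trough (value 0) sits at u = 0 and the
        single peak (value ``amplitude_mm``) at ``u = thrust_fraction``.
        For ratio 1:1 this is ``A/2 * (1 - cos(2*pi*u))`` exactly.
        """
        w = self.phase_map(u)
        return 0.5 * self.amplitude_mm * (1.0 - np.cos(2.0 * np.pi * w))

    def waveform(self, t) -> np.ndarray:
        """Displacement (mm) at time ``t`` seconds; periodic, trough at t=0."""
        return self.cycle(np.asarray(t, dtype=float) * self.frequency_hz)


def make_template(
    amplitude_mm: float,
    frequency_hz: float,
    lift_thrust_ratio: Tuple[float, float] = (1.0, 1.0),
) -> MotionTemplate:
    """Construct a lifting/thrusting template; arguments must be positive."""
    return MotionTemplate(
        amplitude_mm=float(amplitude_mm),
        frequency_hz=float(frequency_hz),
        lift_thrust_ratio=(float(lift_thrust_ratio[0]), float(lift_thrust_ratio[1])),
    )


def simple_template(amplitude_mm: float = 4.0, frequency_hz: float = 1.0) -> MotionTemplate:
    """Session-1 template: pure sine, equal lift and thrust time."""
    return make_template(amplitude_mm, frequency_hz, (1.0, 1.0))


def complicated_template(amplitude_mm: float = 4.0, frequency_hz: float = 1.0) -> MotionTemplate:
    """Session-2 template: lifting twice as slow as thrusting (2:1)."""
    return make_template(amplitude_mm, frequency_hz, (2.0, 1.0))


def sample_template(
    template: MotionTemplate,
    sampling_rate_hz: float,
    duration_s: float,
    meta: dict | None = None,
) -> MotionTrace:
    """Uniformly sample a template into a trace.

    ``floor(duration_s * sampling_rate_hz)`` samples; sample k holds the
    waveform value at ``k / sampling_rate_hz``. The rate must resolve the
    cycle (at least 4 samples per cycle).
    """
    if duration_s <= 0:
        raise DomainError("duration_s must be positive")
    if sampling_rate_hz < 4.0 * template.frequency_hz:
        raise DomainError(
            f"sampling rate {sampling_rate_hz} Hz undersamples a "
            f"{template.frequency_hz} Hz template (need >= 4x)"
        )
    n = int(np.floor(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    m = {"role": "template"}
    if meta:
        m.update(meta)
    return MotionTrace(template.waveform(t), sampling_rate_hz, m)


def template_profile(template: MotionTemplate, n_points: int = 50, rescaled: bool = True) -> np.ndarray:
    """One template cycle on the shared normalised-time grid.

    The grid is ``n_points`` equally spaced points on [0, 1] inclusive of
    both endpoints (both endpoints are the trough). With ``rescaled`` the
    profile is min-max mapped to [0, 1], matching how segmented motion
    units are normalised before the shape-error comparison.
    """
    u = np.linspace(0.0, 1.0, n_points)
    v = template.cycle(u)
    if rescaled:
        v = (v - v.min()) / (v.max() - v.min())
    return v
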