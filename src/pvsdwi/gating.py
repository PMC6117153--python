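"""Cardiac-gating timing: r-wave delays, diffusion-weighting windows, phase labels.

All times are in ms after the r-wave.  The diffusion weighting of a spin-echo
readout triggered ``rwave_delay`` ms after the r-wave is centred at the first
refocusing pulse, i.e. half the first echo time into the readout; its
temporal extent equals the gradient-pair separation (delta_big).  The window
is labelled *pulsation* when it overlaps the arterial pulse-wave arrival
interval at the imaging location, otherwise *diastole*.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import Tuple

from .signal_model import ParameterError

__all__ = [
    "GatingPlan",
    "weighting_centre",
    "weighting_window",
    "pulse_arrival",
    "classify_phase",
    "make_plan",
]

DEFAULT_RR_MS = 150.0          # rat r-r interval
DEFAULT_PWV_M_PER_S = 2.69     # cerebral pulse wave velocity
DEFAULT_HEART_DISTANCE_M = 0.10
DEFAULT_SYSTOLIC_WIDTH_MS = 40.0


def weighting_centre(rwave_delay: float, first_echo_time: float) -> float:
    """Delay from the r-wave to the centre of diffusion weighting (ms).

    The weighting straddles the first refocusing pulse at half the first
    echo time: ``rwave_delay + first_echo_time / 2``.
    """
    if rwave_delay < 0 or first_echo_time < 0:
        raise ParameterError("delays must be non-negative")
    return rwave_delay + first_echo_time / 2.0


def weighting_window(centre: float, delta_big: float) -> Tuple[float, float]:
    """Diffusion-weighting interval ``(centre - delta/2, centre + delta/2)``."""
    if delta_big < 0:
        raise ParameterError("delta_big must be non-negative")
    start = centre - delta_big / 2.0
    if start < 0:
        raise ParameterError(
            f"weighting window starts before the r-wave (start = {start} ms)"
        )
    return (start, centre + delta_big / 2.0)


def pulse_arrival(distance_m: float, pwv_m_per_s: float) -> float:
    """Pulse-wave transit time (ms) from the heart over ``distance_m`` metres."""
    if distance_m <= 0 or pwv_m_per_s <= 0:
        raise ParameterError("distance and pulse wave velocity must be positive")
    return 1000.0 * distance_m / pwv_m_per_s


def classify_phase(
    window: Tuple[float, float],
    arrival: float,
    systolic_width: float = DEFAULT_SYSTOLIC_WIDTH_MS,
    rr_interval: float = DEFAULT_RR_MS,
) -> str:
    """Label a weighting window as ``'pulsation'`` or ``'diastole'``.

    The window is pulsation when it overlaps (boundary-inclusive) the
    interval ``[arrival, arrival + systolic_width]`` on the circular cardiac
    timeline of period ``rr_interval``; the classification is therefore
    invariant to shifting window and arrival together modulo the r-r
    interval.
    """
    if rr_interval <= 0:
        raise ParameterError("rr_interval must be positive")
    start, end = window
    if end < start:
        raise ParameterError("window end precedes window start")
    w_len = end - start
    if w_len > rr_interval:
        warnings.warn(
            f"weighting window ({w_len} ms) is wider than the r-r interval "
            f"({rr_interval} ms)",
            stacklevel=2,
        )
    if w_len + systolic_width >= rr_interval:
        return "pulsation"
    # circular interval overlap: offset of systole start relative to window start
    d = (arrival - start) % rr_interval
    overlap = (d <= w_len) or (d >= rr_interval - systolic_width)
    return "pulsation" if overlap else "diastole"


@dataclass(frozen=True)
class GatingPlan:
    """Complete timing plan for one r-wave-triggered acquisition."""

    rwave_delay: float
    weighting_centre: float
    window_start: float
    window_end: float
    phase_label: str
    pulse_arrival: float
    rr_interval: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def format_text(self) -> str:
        rows = [
            ("r-wave delay", f"{self.rwave_delay:g} ms"),
            ("weighting centre", f"{self.weighting_centre:g} ms"),
            ("weighting window", f"{self.window_start:g} - {self.window_end:g} ms"),
            ("pulse arrival", f"{self.pulse_arrival:.1f} ms"),
            ("r-r interval", f"{self.rr_interval:g} ms"),
            ("cardiac phase", self.phase_label),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k.ljust(width)}  {v}" for k, v in rows)


def make_plan(
    rwave_delay: float,
    first_echo_time: float,
    delta_big: float,
    distance_m: float = DEFAULT_HEART_DISTANCE_M,
    pwv_m_per_s: float = DEFAULT_PWV_M_PER_S,
    systolic_width: float = DEFAULT_SYSTOLIC_WIDTH_MS,
    rr_interval: float = DEFAULT_RR_MS,
) -> GatingPlan:
    """Assemble a :class:`GatingPlan` from acquisition timing and physiology."""
    centre = weighting_centre(rwave_delay, first_echo_time)
    start, end = weighting_window(centre, delta_big)
    arrival = pulse_arrival(distance_m, pwv_m_per_s)
    if end > rr_interval:
        warnings.warn(
            f"weighting window ends after the r-r interval ({end} > {rr_interval} ms)",
            stacklevel=2,
        )
    phase = classify_phase((start, end), arrival, systolic_width, rr_interval)
    return GatingPlan(rwave_delay, centre, start, end, phase, arrival, rr_interval)
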