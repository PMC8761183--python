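"""Acquisition dynamics: equal-count frame planning and decay correction.

Times are minutes internally; frame durations cross the interface in seconds
(the units of scan-protocol tables).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .isotopes import IsotopeModel, decay_factor

__all__ = [
    "FrameSchedule",
    "lesion_to_background_ratio",
    "plan_equal_count_frames",
    "interframe_decay_correct",
    "frame_average_concentration",
]


@dataclass(frozen=True)
class FrameSchedule:
    """A list of (start [min], duration [s]) acquisition frames."""

    frames: tuple[tuple[float, float], ...]
    target_counts: float | None = None

    def __post_init__(self):
        frames = tuple((float(s), float(d)) for s, d in self.frames)
        object.__setattr__(self, "frames", frames)
        prev_end = -math.inf
        for start, dur in frames:
            if dur <= 0:
                raise ValueError("frame durations must be positive")
            if start < prev_end - 1e-9:
                raise ValueError("frames must be non-overlapping and time-ordered")
            prev_end = start + dur / 60.0

    @property
    def durations_s(self) -> np.ndarray:
        return np.array([d for _, d in self.frames])

    @property
    def starts_min(self) -> np.ndarray:
        return np.array([s for s, _ in self.frames])


def lesion_to_background_ratio(lesion_conc: float, bkg_conc: float) -> float:
    """Lesion-to-background activity concentration ratio."""
    if bkg_conc <= 0:
        raise ValueError(f"background concentration must be positive, got {bkg_conc}")
    return lesion_conc / bkg_conc


def _integrated_decay(isotope: IsotopeModel, t1_min: float, t2_min: float) -> float:
    """∫ 2^(−t/t½) dt over [t1, t2] in minutes (per unit initial activity)."""
    lam = isotope.decay_constant
    if lam == 0.0:
        return t2_min - t1_min
    return (math.exp(-lam * t1_min) - math.exp(-lam * t2_min)) / lam


def plan_equal_count_frames(
    start_conc: float,
    isotope: IsotopeModel,
    n_frames: int,
    first_duration: float,
) -> FrameSchedule:
    """Plan contiguous frames with equal time-integrated (decayed) activity.

    For a decaying isotope the frame durations stretch so that every frame
    collects the same expected counts as the first; solved in closed form from
    the exponential integral.  ``first_duration`` is in seconds.

    Raises
    ------
    ValueError
        If the schedule would extend past 20 half-lives (the tail no longer
        contains one frame's worth of counts).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if first_duration <= 0:
        raise ValueError("first_duration must be positive")
    lam = isotope.decay_constant
    d1_min = first_duration / 60.0
    if lam == 0.0:
        frames = tuple((k * d1_min, first_duration) for k in range(n_frames))
        counts = start_conc * d1_min
        return FrameSchedule(frames=frames, target_counts=counts)

    # u_k = exp(−λ t_k); each frame removes the same Δu = λ·I₁ of remaining decay
    target_integral = _integrated_decay(isotope, 0.0, d1_min)
    du = lam * target_integral
    limit = 20.0 * isotope.half_life
    frames = []
    t = 0.0
    u = 1.0
    for _ in range(n_frames):
        u_next = u - du
        if u_next <= 0.0:
            raise ValueError(
                "equal-count schedule infeasible: remaining activity cannot "
                "supply another frame of the requested counts"
            )
        t_next = -math.log(u_next) / lam
        if t_next > limit:
            raise ValueError("equal-count schedule exceeds 20 half-lives")
        frames.append((t, (t_next - t) * 60.0))
        t, u = t_next, u_next
    counts = start_conc * target_integral
    return FrameSchedule(frames=tuple(frames), target_counts=counts)


def interframe_decay_correct(
    measured_conc: float,
    isotope: IsotopeModel,
    frame_start: float,
    frame_duration: float,
    reference_time: float = 0.0,
) -> float:
    """Reference a frame-averaged concentration back to ``reference_time``.

    Divides out the within-frame decay average and back-decays the frame start
    to the reference:  corrected = measured · λΔt/(1−e^(−λΔt)) · e^(λ(t₀−t_ref))
    with Δt the frame duration.  ``frame_start``/``reference_time`` in minutes,
    ``frame_duration`` in seconds.  For a stable isotope this is the identity.
    """
    if frame_duration <= 0:
        raise ValueError("frame_duration must be positive")
    lam = isotope.decay_constant
    if lam == 0.0:
        return measured_conc
    dt_min = frame_duration / 60.0
    within = lam * dt_min / (1.0 - math.exp(-lam * dt_min))
    back = math.exp(lam * (frame_start - reference_time))
    return measured_conc * within * back


def frame_average_concentration(
    conc_at_reference: float,
    isotope: IsotopeModel,
    frame_start: float,
    frame_duration: float,
    reference_time: float = 0.0,
) -> float:
    """Time-averaged decayed concentration over one frame (the quantity a
    sinogram frame actually measures); inverse of :func:`interframe_decay_correct`.
    """
    if frame_duration <= 0:
        raise ValueError("frame_duration must be positive")
    dt_min = frame_duration / 60.0
    t1 = frame_start - reference_time
    avg = _integrated_decay(isotope, t1, t1 + dt_min) / dt_min
    return conc_at_reference * avg
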