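"""Phase-contrast MR angiography (PC-MRA) and cardiac-frame selection.

The PC-MRA combines signal magnitude and blood speed into a static 3D image
in which vessels are bright::

    PC_MRA(x) = M(x) * sqrt(Vx(x)^2 + Vy(x)^2 + Vz(x)^2)

where M, Vx, Vy, Vz are arithmetic means over the systolic frames — the
component averages are taken *before* the norm, so opposing velocities
cancel, and the magnitude factor suppresses noise in low-signal regions such
as the lungs.

Systole is identified from a per-frame scalar signal curve (volume mean of
M * |v|, the single-frame analogue of the PC-MRA); the frame with the highest
signal is the peak frame used to anchor temporal segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Flow4D

__all__ = [
    "FrameSignalCurve",
    "frame_signal_curve",
    "select_frames",
    "compute_pcmra",
]


@dataclass
class FrameSignalCurve:
    """Per-frame angiographic signal with the detected systolic window."""

    values: np.ndarray
    systolic_set: tuple
    peak_frame: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.systolic_set = tuple(int(t) for t in self.systolic_set)
        if self.peak_frame not in self.systolic_set:
            raise ValueError("peak_frame must belong to the systolic set")


def frame_signal_curve(flow: Flow4D) -> np.ndarray:
    """Volume-mean of magnitude * speed per frame; shape (n_frames,)."""
    signal = flow.magnitude * flow.speed()
    return signal.mean(axis=(0, 1, 2))


def select_frames(curve, systolic_frac: float = 0.7):
    """Detect the systolic frame set and the peak frame from a signal curve.

    Frames whose signal reaches ``systolic_frac`` of the curve maximum form
    the systolic set; the peak frame is the argmax (lowest index on ties).

    Raises
    ------
    ValueError
        On an empty or all-zero curve (no systole detectable).
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty signal curve")
    peak_value = curve.max()
    if peak_value <= 0:
        raise ValueError("all-zero signal curve: no systole detectable")
    systolic = tuple(int(t) for t in np.flatnonzero(curve >= systolic_frac * peak_value))
    peak_frame = int(np.argmax(curve))  # argmax takes the lowest index on ties
    return systolic, peak_frame


def detect_systole(flow: Flow4D, systolic_frac: float = 0.7) -> FrameSignalCurve:
    """Convenience wrapper: signal curve + systolic window in one call."""
    values = frame_signal_curve(flow)
    systolic, peak = select_frames(values, systolic_frac)
    return FrameSignalCurve(values=values, systolic_set=systolic, peak_frame=peak)


def compute_pcmra(flow: Flow4D, frames) -> np.ndarray:
    """Compute the PC-MRA over the given frame set.

    Velocity components and magnitude are averaged over ``frames`` first;
    the output is ``mean(M) * |mean(v)|``, nonnegative, and exactly zero
    wherever the mean magnitude vanishes.
    """
    frames = np.asarray(sorted(set(int(t) for t in np.atleast_1d(frames))))
    if frames.size == 0:
        raise ValueError("empty frame set")
    if frames.min() < 0 or frames.max() >= flow.n_frames:
        raise ValueError("frame index out of range")
    mean_mag = flow.magnitude[..., frames].mean(axis=3)
    mean_vel = flow.velocity[..., frames, :].mean(axis=3)
    return mean_mag * np.sqrt(np.sum(mean_vel ** 2, axis=-1))
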