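"""Raw segment → per-beat normalized pulses.

The stage mirrors the standard PPG preprocessing chain: Savitzky–Golay
smoothing (4th order, 19-sample window by default), beat delineation
(systolic peaks plus diastolic feet), respiratory baseline-wander removal by
subtracting the piecewise-linear interpolant through the pulse feet, and
two-dimensional normalization of each beat to unit duration and unit
amplitude on a fixed grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import savgol_filter

#: Default Savitzky–Golay polynomial order.
DEFAULT_ORDER = 4
#: Default Savitzky–Golay window length (samples).
DEFAULT_WINDOW = 19
#: Default normalized-pulse grid length.
DEFAULT_N = 100
#: Refractory period between systolic peaks, seconds.
REFRACTORY_S = 0.3
#: A candidate peak must reach this fraction of the local rolling amplitude.
PEAK_FRACTION = 0.5
#: Rolling window for the adaptive threshold, seconds.
ROLLING_S = 1.5


class NoBeatsDetected(ValueError):
    """Beat delineation found no usable pulse."""


@dataclass(frozen=True)
class BeatAnnotation:
    """Pulse feet (diastolic onsets) and systolic peaks, as sample indices.

    Feet and peaks strictly alternate starting with a foot; every peak lies
    between its flanking feet, so ``len(foot_indices) == len(peak_indices)+1``.
    """

    foot_indices: np.ndarray
    peak_indices: np.ndarray

    def __post_init__(self) -> None:
        feet = np.asarray(self.foot_indices, dtype=int)
        peaks = np.asarray(self.peak_indices, dtype=int)
        object.__setattr__(self, "foot_indices", feet)
        object.__setattr__(self, "peak_indices", peaks)
        if len(feet) != len(peaks) + 1:
            raise ValueError("need exactly one more foot than peaks")
        if np.any(np.diff(feet) <= 0) or (len(peaks) > 1 and np.any(np.diff(peaks) <= 0)):
            raise ValueError("indices must be strictly increasing")
        if len(peaks) and not np.all((feet[:-1] < peaks) & (peaks < feet[1:])):
            raise ValueError("each peak must lie strictly between its flanking feet")

    @property
    def n_beats(self) -> int:
        return len(self.peak_indices)

    def complete_beats(self, n_samples: int) -> list[tuple[int, int]]:
        """(start_foot, end_foot) pairs whose feet are interior minima.

        Beats whose bounding foot touches the segment edge are partial (the
        true diastolic onset fell outside the window) and are excluded.
        """
        out = []
        feet = self.foot_indices
        for i in range(self.n_beats):
            if feet[i] > 0 and feet[i + 1] < n_samples - 1:
                out.append((int(feet[i]), int(feet[i + 1])))
        return out


@dataclass(frozen=True)
class NormalizedPulse:
    """A single beat resampled to the unit square.

    ``values`` sit on a uniform grid over normalized time [0, 1] with
    ``min(values) == 0`` and ``max(values) == 1`` exactly.
    """

    values: np.ndarray
    source: tuple[str, int] = ("", 0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, len(self.values))


def smooth(
    samples: np.ndarray,
    order: int = DEFAULT_ORDER,
    window: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """Savitzky–Golay smoothing; length preserving.

    Interior samples equal the centre value of the least-squares polynomial of
    ``order`` fitted to each ``window``-sample neighbourhood; near the edges
    the boundary polynomial is evaluated at the boundary positions.
    """
    samples = np.asarray(samples, dtype=float)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= order:
        raise ValueError(f"window ({window}) must exceed order ({order})")
    if len(samples) < window:
        raise ValueError(f"signal length {len(samples)} shorter than window {window}")
    return savgol_filter(samples, window_length=window, polyorder=order, mode="interp")


def detect_beats(samples: np.ndarray, rate: float) -> BeatAnnotation:
    """Delineate systolic peaks and diastolic feet on a smoothed signal.

    Peaks are local maxima exceeding an adaptive threshold (a fraction of the
    rolling amplitude envelope), separated by a 0.3 s refractory period; each
    foot is the minimum between successive peaks, with the leading/trailing
    feet taken as the minima before the first and after the last peak.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 3:
        raise NoBeatsDetected("signal too short")
    rng = float(x.max() - x.min())
    if rng <= 0 or np.std(x) < 1e-12 * max(1.0, abs(x).max()):
        raise NoBeatsDetected("flat signal")

    w = max(3, int(round(ROLLING_S * rate)) | 1)
    roll_max = maximum_filter1d(x, size=w, mode="nearest")
    roll_min = minimum_filter1d(x, size=w, mode="nearest")
    threshold = roll_min + PEAK_FRACTION * (roll_max - roll_min)

    interior = (x[1:-1] >= x[:-2]) & (x[1:-1] > x[2:]) & (x[1:-1] >= threshold[1:-1])
    candidates = np.flatnonzero(interior) + 1
    if len(candidates) == 0:
        raise NoBeatsDetected("no peaks above the adaptive threshold")

    # enforce refractory period, keeping the taller peak of close pairs
    refractory = int(round(REFRACTORY_S * rate))
    peaks: list[int] = []
    for idx in candidates:
        if peaks and idx - peaks[-1] < refractory:
            if x[idx] > x[peaks[-1]]:
                peaks[-1] = int(idx)
        else:
            peaks.append(int(idx))

    # drop peaks with no room for a foot on either side
    while peaks and peaks[0] == 0:
        peaks.pop(0)
    while peaks and peaks[-1] == n - 1:
        peaks.pop()
    if not peaks:
        raise NoBeatsDetected("no interior peaks")

    feet = [int(np.argmin(x[: peaks[0]])) if peaks[0] > 0 else 0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        feet.append(int(a + 1 + np.argmin(x[a + 1 : b])))
    feet.append(int(peaks[-1] + 1 + np.argmin(x[peaks[-1] + 1 :])))
    return BeatAnnotation(foot_indices=np.array(feet), peak_indices=np.array(peaks))


def remove_baseline(samples: np.ndarray, annotation: BeatAnnotation) -> np.ndarray:
    """Subtract the piecewise-linear interpolant through the pulse feet.

    Pins every foot to zero, removing sub-heart-rate (respiratory) wander
    without touching within-beat morphology; the baseline extends flat beyond
    the first and last foot.
    """
    x = np.asarray(samples, dtype=float)
    feet = annotation.foot_indices
    if len(feet) < 2:
        raise ValueError("need at least 2 feet to interpolate a baseline")
    baseline = np.interp(np.arange(len(x)), feet, x[feet])
    return x - baseline


def normalize_pulse(
    beat: np.ndarray,
    N: int = DEFAULT_N,
    source: tuple[str, int] = ("", 0),
) -> NormalizedPulse:
    """Two-dimensional normalization of one beat.

    The beat is linearly resampled onto a uniform ``N``-point grid over
    normalized time [0, 1], then shifted and scaled so its minimum is 0 and
    its maximum is 1 exactly.
    """
    beat = np.asarray(beat, dtype=float)
    if len(beat) < 4:
        raise ValueError(f"beat needs >= 4 samples, got {len(beat)}")
    rng = beat.max() - beat.min()
    if rng <= 0:
        raise ValueError("beat has zero amplitude range")
    t_old = np.linspace(0.0, 1.0, len(beat))
    t_new = np.linspace(0.0, 1.0, N)
    v = np.interp(t_new, t_old, beat)
    v = (v - v.min()) / (v.max() - v.min())
    return NormalizedPulse(values=v, source=source)


def segment_pulses(
    samples: np.ndarray,
    rate: float,
    *,
    order: int = DEFAULT_ORDER,
    window: int = DEFAULT_WINDOW,
    N: int = DEFAULT_N,
    segment_id: str = "",
) -> tuple[list[NormalizedPulse], BeatAnnotation]:
    """Full chain: smooth → delineate → de-trend → normalize each complete beat."""
    smoothed = smooth(samples, order=order, window=window)
    annotation = detect_beats(smoothed, rate)
    detrended = remove_baseline(smoothed, annotation)
    beats = annotation.complete_beats(len(samples))
    # guard against mis-placed feet at the segment edges: the first and last
    # beat are kept only when their duration matches the segment median
    if len(beats) >= 3:
        durations = np.array([b - a for a, b in beats], dtype=float)
        med = float(np.median(durations))
        keep = []
        for i, (ab, d) in enumerate(zip(beats, durations)):
            if i in (0, len(beats) - 1) and abs(d - med) > 0.08 * med:
                continue
            keep.append(ab)
        beats = keep
    pulses = []
    for k, (a, b) in enumerate(beats):
        pulses.append(normalize_pulse(detrended[a : b + 1], N=N, source=(segment_id, k)))
    if not pulses:
        raise NoBeatsDetected(f"segment {segment_id!r}: no complete beat between interior feet")
    return pulses, annotation
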