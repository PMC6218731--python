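"""Pulse-morphology features and variance-inflation-factor selection.

Five features are measured on each normalized pulse: the pulse area (integral
over normalized time), the rising time (normalized time from foot to systolic
peak, also called crest time), and the pulse widths at 25%, 50% and 75% of
the normalized amplitude.  Widths use the outermost level crossings (first
up-crossing to last down-crossing) so that a dicrotic wave re-crossing a
level never shrinks the width.

Feature selection follows standard multicollinearity practice: the variance
inflation factor VIF_j = 1/(1-R²_j) of each feature regressed (with
intercept) on the rest, eliminating the worst offender until all VIFs fall
at or below a threshold of 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .preprocess import BeatAnnotation, NormalizedPulse, segment_pulses
from .signal_io import PPGSegment

#: Names of the five morphology features, in canonical column order.
FEATURE_NAMES = ["area", "rising_time", "width_25", "width_50", "width_75"]
#: Features conventionally retained after multicollinearity screening.
SELECTED_FEATURES = ["area", "rising_time", "width_25"]
#: Default VIF elimination threshold.
VIF_THRESHOLD = 10.0


@dataclass
class FeatureRecord:
    """Per-segment morphology features with reference pressures."""

    segment_id: str
    case_id: str
    area: float
    rising_time: float
    width_25: float
    width_50: float
    width_75: float
    ref_sbp: float | None = None
    ref_dbp: float | None = None

    def as_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "segment_id": self.segment_id,
            "area": self.area,
            "rising_time": self.rising_time,
            "width_25": self.width_25,
            "width_50": self.width_50,
            "width_75": self.width_75,
            "ref_sbp": np.nan if self.ref_sbp is None else self.ref_sbp,
            "ref_dbp": np.nan if self.ref_dbp is None else self.ref_dbp,
        }


@dataclass
class VIFReport:
    """Variance inflation factors plus the outcome of iterative elimination.

    ``vifs`` holds the VIFs computed on the full input feature set;
    ``elimination_order`` lists dropped features in drop order and
    ``retained`` the surviving ones (input order preserved).
    """

    vifs: dict[str, float]
    elimination_order: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)


def pulse_area(pulse: NormalizedPulse | np.ndarray) -> float:
    """Trapezoidal integral of the normalized pulse over normalized time."""
    v = pulse.values if isinstance(pulse, NormalizedPulse) else np.asarray(pulse, float)
    return float(np.trapezoid(v, dx=1.0 / (len(v) - 1)))


def rising_time(pulse: NormalizedPulse | np.ndarray) -> float:
    """Normalized time of the systolic peak (first sample attaining the max)."""
    v = pulse.values if isinstance(pulse, NormalizedPulse) else np.asarray(pulse, float)
    return float(np.argmax(v)) / (len(v) - 1)


def width_at(pulse: NormalizedPulse | np.ndarray, fraction: float) -> float:
    """Outermost pulse width at ``fraction`` of the normalized amplitude.

    The width spans from the first up-crossing to the last down-crossing of
    the level, each located by linear interpolation between adjacent samples.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    v = pulse.values if isinstance(pulse, NormalizedPulse) else np.asarray(pulse, float)
    n = len(v)
    dx = 1.0 / (n - 1)
    above = v >= fraction
    if not above.any():
        return 0.0
    first = int(np.argmax(above))
    last = n - 1 - int(np.argmax(above[::-1]))
    if first == 0:
        t_up = 0.0
    else:
        t_up = (first - 1 + (fraction - v[first - 1]) / (v[first] - v[first - 1])) * dx
    if last == n - 1:
        t_down = 1.0
    else:
        t_down = (last + (v[last] - fraction) / (v[last] - v[last + 1])) * dx
    return float(t_down - t_up)


def pulse_features(pulse: NormalizedPulse | np.ndarray) -> dict[str, float]:
    """All five morphology features of one normalized pulse."""
    return {
        "area": pulse_area(pulse),
        "rising_time": rising_time(pulse),
        "width_25": width_at(pulse, 0.25),
        "width_50": width_at(pulse, 0.50),
        "width_75": width_at(pulse, 0.75),
    }


def extract_segment_features(
    segment: PPGSegment,
    *,
    order: int = 4,
    window: int = 19,
    N: int = 100,
) -> FeatureRecord:
    """Mean per-beat features over the complete beats of one segment.

    The reference cuff pressure is constant over a 5 s segment, so a single
    feature vector per segment (the arithmetic mean across beats) is the
    natural aggregation.
    """
    pulses, _ = segment_pulses(
        segment.samples, segment.rate, order=order, window=window, N=N,
        segment_id=segment.segment_id,
    )
    per_beat = [pulse_features(p) for p in pulses]
    means = {k: float(np.mean([f[k] for f in per_beat])) for k in FEATURE_NAMES}
    return FeatureRecord(
        segment_id=segment.segment_id,
        case_id=segment.case_id,
        ref_sbp=segment.ref_sbp,
        ref_dbp=segment.ref_dbp,
        **means,
    )


def extract_feature_table(
    segments,
    *,
    order: int = 4,
    window: int = 19,
    N: int = 100,
) -> pd.DataFrame:
    """Feature table (one row per segment) for a sequence of segments."""
    rows = [
        extract_segment_features(s, order=order, window=window, N=N).as_dict()
        for s in segments
    ]
    from .signal_io import FEATURE_COLUMNS

    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def compute_vif(X) -> VIFReport:
    """Variance inflation factor of every column of ``X``.

    VIF_j = 1/(1-R²_j) with R²_j from the ordinary-least-squares regression of
    column j on all remaining columns plus an intercept; exact collinearity is
    reported as ``inf``.
    """
    M, names = _as_matrix(X)
    n, k = M.shape
    if k < 2:
        raise ValueError("need at least 2 features for VIF")
    if n <= k:
        raise ValueError(f"need more rows ({n}) than features ({k})")
    for j in range(k):
        if np.ptp(M[:, j]) == 0.0:
            raise ValueError(f"constant column: {names[j]!r}")
    vifs: dict[str, float] = {}
    for j in range(k):
        others = sm.add_constant(np.delete(M, j, axis=1))
        r2 = sm.OLS(M[:, j], others).fit().rsquared
        vifs[names[j]] = float("inf") if r2 >= 1.0 - 1e-14 else float(1.0 / (1.0 - r2))
    return VIFReport(vifs=vifs, retained=list(names))


def select_features(X, threshold: float = VIF_THRESHOLD) -> VIFReport:
    """Iterative VIF elimination.

    While any VIF exceeds ``threshold``, drop the feature with the largest
    VIF (ties broken toward the later input column) and recompute.  Returns
    the VIFs of the full input set plus elimination order and retained names.
    """
    M, names = _as_matrix(X)
    initial = compute_vif(pd.DataFrame(M, columns=names)).vifs
    current = list(names)
    eliminated: list[str] = []
    while len(current) >= 2:
        cols = [names.index(c) for c in current]
        vifs = compute_vif(pd.DataFrame(M[:, cols], columns=current)).vifs
        worst = max(vifs.values())
        if worst <= threshold:
            break
        # ties -> later input column
        drop = max(
            (c for c in current if vifs[c] == worst),
            key=lambda c: names.index(c),
        )
        eliminated.append(drop)
        current.remove(drop)
    if len(current) < 2 and len(names) >= 2:
        # a single survivor has no VIF; treat full elimination as degenerate
        if not current:
            raise ValueError("all features eliminated: degenerate design matrix")
    return VIFReport(vifs=initial, elimination_order=eliminated, retained=current)
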