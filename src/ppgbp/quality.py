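"""Rule-based segment screening.

An automated stand-in for visual quality control: a segment is accepted only
when it carries both reference pressures, is not flat, shows no saturation
plateaus or dropouts (long runs pinned at the extremes), a physiologically
plausible beat count, and an amplitude range inside configured bounds.  All
violated rules are reported, not just the first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import NoBeatsDetected, detect_beats, smooth
from .signal_io import PPGSegment

#: Reason codes, in report order.
REASONS = (
    "missing_reference",
    "flatline",
    "clipping",
    "implausible_beat_count",
    "out_of_range_amplitude",
)


@dataclass(frozen=True)
class QualityRules:
    """Configurable acceptance thresholds.

    ``clip_run`` is the minimum number of consecutive samples sitting exactly
    at the segment maximum or minimum that counts as saturation/dropout;
    beat-count bounds correspond to 36–180 bpm over 5 s.
    """

    flatline_rel_sd: float = 1e-6
    clip_run: int = 25
    min_beats: int = 3
    max_beats: int = 15
    min_amplitude: float = 1e-9
    max_amplitude: float = math.inf
    smooth_order: int = 4
    smooth_window: int = 19


@dataclass
class QualityReport:
    """Outcome of screening one segment; accepted ⇔ no reasons."""

    segment_id: str
    accepted: bool
    reasons: list[str] = field(default_factory=list)


def _longest_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate([[0], mask.view(np.int8), [0]])
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return int((ends - starts).max())


def assess(segment: PPGSegment, rules: QualityRules | None = None) -> QualityReport:
    """Screen one segment; always returns a report with exhaustive reasons."""
    rules = rules or QualityRules()
    reasons: list[str] = []
    x = segment.samples
    rng = float(x.max() - x.min()) if len(x) else 0.0

    if not segment.has_reference:
        reasons.append("missing_reference")

    flat = rng == 0.0 or float(np.std(x)) < rules.flatline_rel_sd * rng
    if flat:
        reasons.append("flatline")

    if not flat and rng > 0:
        run_hi = _longest_run(x == x.max())
        run_lo = _longest_run(x == x.min())
        if max(run_hi, run_lo) >= rules.clip_run:
            reasons.append("clipping")

    beats_ok = False
    if not flat:
        try:
            ann = detect_beats(
                smooth(x, order=rules.smooth_order, window=rules.smooth_window),
                segment.rate,
            )
            beats_ok = rules.min_beats <= ann.n_beats <= rules.max_beats
        except (NoBeatsDetected, ValueError):
            beats_ok = False
    if not beats_ok:
        reasons.append("implausible_beat_count")

    if not (rules.min_amplitude <= rng <= rules.max_amplitude):
        reasons.append("out_of_range_amplitude")

    return QualityReport(
        segment_id=segment.segment_id,
        accepted=not reasons,
        reasons=reasons,
    )


def filter_dataset(
    segments, rules: QualityRules | None = None
) -> tuple[list[PPGSegment], list[QualityReport]]:
    """Screen every segment; order preserved, one report per input."""
    rules = rules or QualityRules()
    accepted: list[PPGSegment] = []
    reports: list[QualityReport] = []
    for seg in segments:
        report = assess(seg, rules)
        reports.append(report)
        if report.accepted:
            accepted.append(seg)
    return accepted, reports


def reports_frame(reports: list[QualityReport]) -> pd.DataFrame:
    """CSV-ready view of screening reports."""
    return pd.DataFrame(
        {
            "segment_id": [r.segment_id for r in reports],
            "accepted": [r.accepted for r in reports],
            "reasons": [";".join(r.reasons) for r in reports],
        }
    )
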