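"""Packaged reference tables of a published regression-tree PPG study.

Four CSV fixtures transcribe the per-case results that a cuffless
blood-pressure study reported for its regression-tree estimator on a
32-case hospital dataset:

* ``reference_segment_counts.csv`` — per-case segment counts by category,
  plus discarded (bad-quality / missing-reference) counts;
* ``reference_case_agreement.csv`` — per-case mean reference and estimated
  SBP/DBP with their differences (reference − estimated), pooled over all
  of a case's segments;
* ``reference_sbp_by_category.csv`` / ``reference_dbp_by_category.csv`` —
  the same quantities stratified by reference BP category (empty cells
  where a case has no segments in a category).

The summary (mean / SD) rows of the published tables are deliberately not
stored: :func:`summarise_agreement` recomputes them from the per-case rows,
which is what the package's own evaluation arithmetic is checked against.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .evaluation import bland_altman, difference_stats, iso_check, round_half_away

_DATA = resources.files("ppgbp") / "data"


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path)


def segment_counts() -> pd.DataFrame:
    """Per-case segment counts by category and exclusion reason."""
    return _read("reference_segment_counts.csv")


def case_agreement() -> pd.DataFrame:
    """Per-case reference/estimated SBP and DBP with differences."""
    return _read("reference_case_agreement.csv")


def category_agreement(target: str) -> pd.DataFrame:
    """Per-case agreement stratified by BP category; target 'sbp' or 'dbp'."""
    if target not in ("sbp", "dbp"):
        raise ValueError(f"target must be 'sbp' or 'dbp', got {target!r}")
    return _read(f"reference_{target}_by_category.csv")


def summarise_agreement(differences) -> dict:
    """Mean, SD, Bland–Altman limits and ISO verdict of per-case differences.

    Values are rounded to one decimal (half away from zero), the display
    convention of the published tables.
    """
    d = np.asarray(differences, dtype=float)
    d = d[np.isfinite(d)]
    mean, sd = difference_stats(d)
    bias, lo, hi = bland_altman(d)
    return {
        "n_cases": int(len(d)),
        "mean": round_half_away(mean, 1),
        "sd": round_half_away(sd, 1),
        "loa_lower": round_half_away(lo, 1),
        "loa_upper": round_half_away(hi, 1),
        "iso_pass": iso_check(mean, sd),
    }


def recompute_summary_rows() -> dict:
    """Recompute every summary statistic the reference tables print.

    Returns a nested dict: overall SBP/DBP agreement from the pooled
    per-case table, per-category SBP/DBP agreement, and the dataset-level
    segment counts.
    """
    out: dict = {}
    overall = case_agreement()
    for target in ("sbp", "dbp"):
        out[f"overall_{target}"] = summarise_agreement(overall[f"{target}_diff"])
        # mean reference / estimated BP across cases, as printed
        out[f"overall_{target}"]["mean_reference"] = round_half_away(
            float(overall[f"{target}_ref"].mean()), 1
        )
        out[f"overall_{target}"]["mean_estimated"] = round_half_away(
            float(overall[f"{target}_est"].mean()), 1
        )
    for target in ("sbp", "dbp"):
        table = category_agreement(target)
        for cat in ("normo", "hyper", "hypo"):
            summary = summarise_agreement(table[f"{cat}_diff"])
            summary["mean_reference"] = round_half_away(
                float(table[f"{cat}_ref"].mean()), 1
            )
            out[f"{cat}_{target}"] = summary
    counts = segment_counts()
    out["counts"] = {
        "normotensive": int(counts["normotensive"].sum()),
        "hypertensive": int(counts["hypertensive"].sum()),
        "hypotensive": int(counts["hypotensive"].sum()),
        "bad_quality": int(counts["bad_quality"].sum()),
        "missing_reference": int(counts["missing_reference"].sum()),
        "total": int(counts["total"].sum()),
    }
    out["counts"]["good_quality"] = (
        out["counts"]["normotensive"]
        + out["counts"]["hypertensive"]
        + out["counts"]["hypotensive"]
    )
    return out
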