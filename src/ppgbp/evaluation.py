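"""Cross-validated evaluation with per-case, per-category agreement statistics.

The protocol: pool all accepted segments, assign them to k folds (default 10)
at the segment level, obtain one held-out SBP and DBP estimate per segment,
average reference and estimated pressures per case (optionally within one
blood-pressure category), and summarise the per-case differences
(reference − estimated) with their mean, sample SD, Bland–Altman limits of
agreement (bias ± 1.96·SD) and an ISO-style verdict: a device passes when the
absolute mean difference is at most 5 mmHg and the SD at most 8 mmHg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models as _models
from .features import SELECTED_FEATURES

CATEGORIES = ("normotensive", "hypertensive", "hypotensive")

#: ISO-style accuracy limits for noninvasive BP devices, mmHg.
ISO_MEAN_LIMIT = 5.0
ISO_SD_LIMIT = 8.0


@dataclass(frozen=True)
class CategoryThresholds:
    """Blood-pressure category rule.

    Hypertensive when SBP ≥ ``hyper_sbp`` or DBP ≥ ``hyper_dbp``; otherwise
    hypotensive when SBP < ``hypo_sbp``; otherwise normotensive.  Diastolic
    pressure is deliberately not part of the hypotensive rule: normotensive
    subjects routinely show DBP in the low 40s.
    """

    hyper_sbp: float = 140.0
    hyper_dbp: float = 90.0
    hypo_sbp: float = 90.0


def classify_category(
    sbp: float, dbp: float, thresholds: CategoryThresholds | None = None
) -> str:
    """Assign one of normotensive / hypertensive / hypotensive."""
    th = thresholds or CategoryThresholds()
    if not (math.isfinite(sbp) and math.isfinite(dbp)):
        raise ValueError(f"non-finite blood pressure ({sbp}, {dbp})")
    if sbp >= th.hyper_sbp or dbp >= th.hyper_dbp:
        return "hypertensive"
    if sbp < th.hypo_sbp:
        return "hypotensive"
    return "normotensive"


@dataclass(frozen=True)
class FoldAssignment:
    """Fold label (1..k) per row, from a seeded permutation + round robin."""

    labels: np.ndarray
    k: int
    seed: int


def kfold_assign(n: int, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Partition ``n`` rows into ``k`` folds whose sizes differ by at most 1."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    labels[order] = np.arange(n) % k + 1
    return FoldAssignment(labels=labels, k=k, seed=seed)


@dataclass(frozen=True)
class ModelSpec:
    """Which regressor to use, with hyperparameters."""

    name: str  # "mlr" | "svr" | "tree"
    params: dict = field(default_factory=dict)

    def fit(self, X: np.ndarray, y: np.ndarray):
        if self.name == "mlr":
            return _models.fit_mlr(_models.TrainingSet(X, y))
        if self.name == "svr":
            return _models.fit_svr(_models.TrainingSet(X, y), **self.params)
        if self.name == "tree":
            return _models.fit_tree(_models.TrainingSet(X, y), **self.params)
        raise ValueError(f"unknown model {self.name!r}; expected mlr, svr or tree")


def cross_validate(
    features: pd.DataFrame,
    model: ModelSpec,
    k: int = 10,
    seed: int = 0,
    thresholds: CategoryThresholds | None = None,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """One held-out SBP and DBP estimate per segment.

    SBP and DBP are fitted as separate targets on the same selected features.
    Returns an estimate-record table with columns case_id, segment_id,
    ref_sbp, ref_dbp, est_sbp, est_dbp, fold, category (category from the
    reference pressures).
    """
    feature_names = feature_names or SELECTED_FEATURES
    needed = set(feature_names) | {"case_id", "segment_id", "ref_sbp", "ref_dbp"}
    missing = needed - set(features.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    if features[["ref_sbp", "ref_dbp"]].isna().any().any():
        raise ValueError("feature table contains rows without reference BPs")
    n = len(features)
    assignment = kfold_assign(n, k=k, seed=seed)
    X = features[feature_names].to_numpy(dtype=float)
    y_sbp = features["ref_sbp"].to_numpy(dtype=float)
    y_dbp = features["ref_dbp"].to_numpy(dtype=float)
    est_sbp = np.full(n, np.nan)
    est_dbp = np.full(n, np.nan)
    for fold in range(1, k + 1):
        test = assignment.labels == fold
        train = ~test
        try:
            m_s = model.fit(X[train], y_sbp[train])
            m_d = model.fit(X[train], y_dbp[train])
        except Exception as exc:
            raise RuntimeError(f"model fit failed on fold {fold}: {exc}") from exc
        est_sbp[test] = _models.predict(m_s, X[test])
        est_dbp[test] = _models.predict(m_d, X[test])
    th = thresholds or CategoryThresholds()
    return pd.DataFrame(
        {
            "case_id": features["case_id"].to_numpy(),
            "segment_id": features["segment_id"].to_numpy(),
            "ref_sbp": y_sbp,
            "ref_dbp": y_dbp,
            "est_sbp": est_sbp,
            "est_dbp": est_dbp,
            "fold": assignment.labels,
            "category": [classify_category(s, d, th) for s, d in zip(y_sbp, y_dbp)],
        }
    )


def per_case_summary(records: pd.DataFrame, category: str | None = None) -> pd.DataFrame:
    """Per-case mean reference/estimated pressures and their difference.

    With ``category`` given, only segments whose reference pressures fall in
    that category contribute; cases without qualifying segments are omitted.
    Differences are reference − estimated.
    """
    if len(records) == 0:
        raise ValueError("no estimate records")
    sub = records if category is None else records[records["category"] == category]
    rows = []
    for case_id, grp in sub.groupby("case_id", sort=True):
        row = {"case_id": case_id, "n_segments": len(grp)}
        for tgt in ("sbp", "dbp"):
            ref = grp[f"ref_{tgt}"].mean()
            est = grp[f"est_{tgt}"].mean()
            row[f"ref_{tgt}"] = ref
            row[f"est_{tgt}"] = est
            row[f"diff_{tgt}"] = ref - est
        rows.append(row)
    return pd.DataFrame(rows)


def difference_stats(differences) -> tuple[float, float]:
    """Mean and sample (n−1) SD of per-case differences."""
    d = np.asarray(differences, dtype=float)
    if len(d) < 2:
        raise ValueError(f"need >= 2 summaries, got {len(d)}")
    return float(d.mean()), float(d.std(ddof=1))


def bland_altman(differences) -> tuple[float, float, float]:
    """Bland–Altman bias and limits of agreement (bias ± 1.96·SD)."""
    bias, sd = difference_stats(differences)
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def iso_check(mean_difference: float, sd: float) -> bool:
    """ISO-style verdict: |mean| ≤ 5 mmHg and SD ≤ 8 mmHg, inclusive."""
    if not (math.isfinite(mean_difference) and math.isfinite(sd)):
        raise ValueError("non-finite agreement statistics")
    return abs(mean_difference) <= ISO_MEAN_LIMIT and sd <= ISO_SD_LIMIT


@dataclass
class CategoryReport:
    """Agreement summary for one BP target within one category (or overall)."""

    category: str  # one of CATEGORIES or "overall"
    target: str  # "sbp" | "dbp"
    n_cases: int
    mean_difference: float
    sd_difference: float  # nan when < 2 cases
    bias: float
    loa_lower: float
    loa_upper: float
    iso_pass: bool | None  # None when SD unavailable


def _summarise(diffs: np.ndarray, category: str, target: str) -> CategoryReport:
    n = len(diffs)
    if n >= 2:
        mean, sd = difference_stats(diffs)
        bias, lo, hi = bland_altman(diffs)
        verdict = iso_check(mean, sd)
    else:
        mean = float(diffs.mean()) if n else float("nan")
        sd = float("nan")
        bias, lo, hi = mean, float("nan"), float("nan")
        verdict = None
    return CategoryReport(
        category=category,
        target=target,
        n_cases=n,
        mean_difference=mean,
        sd_difference=sd,
        bias=bias,
        loa_lower=lo,
        loa_upper=hi,
        iso_pass=verdict,
    )


def category_report(
    records: pd.DataFrame, thresholds: CategoryThresholds | None = None
) -> list[CategoryReport]:
    """Overall and per-category agreement reports for SBP and DBP.

    Stratification uses the reference-pressure category of each segment; the
    overall report pools all segments per case.
    """
    if len(records) == 0:
        raise ValueError("no estimate records")
    reports: list[CategoryReport] = []
    for target in ("sbp", "dbp"):
        overall = per_case_summary(records)
        reports.append(_summarise(overall[f"diff_{target}"].to_numpy(), "overall", target))
        for cat in CATEGORIES:
            summaries = per_case_summary(records, category=cat)
            diffs = (
                summaries[f"diff_{target}"].to_numpy()
                if len(summaries)
                else np.empty(0)
            )
            reports.append(_summarise(diffs, cat, target))
    return reports


def reports_frame(reports: list[CategoryReport]) -> pd.DataFrame:
    """Tabular view of :func:`category_report` output."""
    return pd.DataFrame([r.__dict__ for r in reports])


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (display convention for agreement tables)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
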