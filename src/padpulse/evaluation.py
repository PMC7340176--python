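"""Detection and severity-assessment evaluation protocols.

Two protocols, applied identically to the CNN and the calibrated-ABI
baseline:

* detection — for each labeling threshold, draw a balanced cohort
  (equal numbers of patients strictly below and at-or-above the threshold),
  classify every waveform sample of those patients by thresholding the
  predicted severity, and aggregate sensitivity, specificity, accuracy and
  rank-based AUC over all samples;
* severity — draw a severity-uniform cohort (a fixed number of patients at
  every 1% severity level) and summarise predicted-vs-true severity with
  Bland-Altman statistics (bias and 1.96-sd limits of agreement).

Both protocols are repeated with independent cohort draws and the
across-repeat mean and coefficient of variation are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .cohort import VirtualPatient

__all__ = [
    "DetectionResult",
    "BlandAltmanResult",
    "EvaluationReport",
    "sample_detection_cohort",
    "sample_severity_cohort",
    "run_detection",
    "bland_altman",
    "run_full_evaluation",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.1, 0.71, 0.1), 10))


@dataclass
class DetectionResult:
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    n_positive_samples: int
    n_negative_samples: int
    method: str  # "DL" | "ABI"


@dataclass
class BlandAltmanResult:
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    n: int
    method: str = ""


@dataclass
class EvaluationReport:
    detection: pd.DataFrame  # method x threshold rows, across-repeat mean + cv
    bland_altman: pd.DataFrame
    repeats: int
    seeds: list[int] = field(default_factory=list)

    def to_csv(self, detection_path, bland_altman_path) -> None:
        self.detection.to_csv(detection_path, index=False)
        self.bland_altman.to_csv(bland_altman_path, index=False)


def sample_detection_cohort(
    test_basis: list[VirtualPatient],
    threshold: float,
    seed: int,
    n_per_class: int = 1000,
) -> list[VirtualPatient]:
    """Balanced cohort: n_per_class patients below and at/above the threshold.

    Sampling is without replacement and reproducible for a given seed.
    """
    rng = np.random.default_rng(seed)
    below = [p for p in test_basis if p.severity < threshold]
    above = [p for p in test_basis if p.severity >= threshold]
    for name, pool in (("healthy", below), ("PAD", above)):
        if len(pool) < n_per_class:
            raise ValueError(
                f"only {len(pool)} {name} patients available, need {n_per_class}"
            )
    picked_below = rng.choice(len(below), size=n_per_class, replace=False)
    picked_above = rng.choice(len(above), size=n_per_class, replace=False)
    return [below[i] for i in picked_below] + [above[i] for i in picked_above]


def sample_severity_cohort(
    test_basis: list[VirtualPatient],
    seed: int,
    per_level: int = 25,
    levels=None,
) -> list[VirtualPatient]:
    """Severity-uniform cohort: per_level patients at every 1% level 1-80%."""
    rng = np.random.default_rng(seed)
    if levels is None:
        levels = np.round(np.arange(0.01, 0.801, 0.01), 10)
    by_level: dict[float, list[VirtualPatient]] = {}
    for p in test_basis:
        by_level.setdefault(round(p.severity, 10), []).append(p)
    out = []
    for lev in levels:
        pool = by_level.get(round(float(lev), 10), [])
        if len(pool) < per_level:
            raise ValueError(
                f"only {len(pool)} patients at severity {lev}, need {per_level}"
            )
        picked = rng.choice(len(pool), size=per_level, replace=False)
        out.extend(pool[i] for i in picked)
    return out


def mann_whitney_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Rank-statistic AUC; ties contribute half a concordance."""
    scores = np.concatenate([scores_pos, scores_neg])
    labels = np.concatenate([np.ones(len(scores_pos)), np.zeros(len(scores_neg))])
    return float(roc_auc_score(labels, scores))


def run_detection(
    predicted: np.ndarray,
    true_severity: np.ndarray,
    threshold: float,
    method: str = "DL",
) -> DetectionResult:
    """Aggregate the confusion matrix over all samples of a detection cohort.

    ``predicted`` are continuous severity estimates per waveform sample;
    a sample is called PAD when its prediction is at or above the
    threshold, and its true label is PAD when its true severity is at or
    above the threshold.
    """
    predicted = np.asarray(predicted, dtype=float)
    true_severity = np.asarray(true_severity, dtype=float)
    if predicted.shape != true_severity.shape:
        raise ValueError("prediction/label length mismatch")
    is_pad = true_severity >= threshold
    called_pad = predicted >= threshold
    n_pos = int(is_pad.sum())
    n_neg = int((~is_pad).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("detection cohort must contain both classes")
    sensitivity = float((called_pad & is_pad).sum() / n_pos)
    specificity = float((~called_pad & ~is_pad).sum() / n_neg)
    accuracy = float((called_pad == is_pad).mean())
    auc = mann_whitney_auc(predicted[is_pad], predicted[~is_pad])
    return DetectionResult(
        threshold=float(threshold),
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        auc=auc,
        n_positive_samples=n_pos,
        n_negative_samples=n_neg,
        method=method,
    )


def bland_altman(
    true_severities: np.ndarray, predicted_severities: np.ndarray, method: str = ""
) -> BlandAltmanResult:
    """Bias and 1.96-sd limits of agreement of (predicted - true)."""
    t = np.asarray(true_severities, dtype=float)
    p = np.asarray(predicted_severities, dtype=float)
    if t.shape != p.shape:
        raise ValueError("length mismatch")
    if t.size < 2:
        raise ValueError("need at least two pairs")
    diff = p - t
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        n=t.size,
        method=method,
    )


def _cv(values: np.ndarray) -> float:
    m = np.mean(values)
    return float(np.std(values, ddof=0) / abs(m)) if m != 0 else 0.0


def run_full_evaluation(
    predictors: dict,
    test_basis: list[VirtualPatient],
    repeats: int = 10,
    seed: int = 0,
    thresholds=DEFAULT_THRESHOLDS,
    n_per_class: int = 1000,
    per_level: int = 25,
) -> EvaluationReport:
    """Run both protocols for every method over repeated cohort draws.

    ``predictors`` maps a method name ("DL", "ABI", ...) to a callable that,
    given a list of cohort patients, returns (predicted, true) severity
    arrays over all stored waveform samples of those patients.
    """
    det_rows = []
    ba_rows = []
    seeds = [seed * 1000 + r for r in range(repeats)]
    for r, rep_seed in enumerate(seeds):
        for ti, thr in enumerate(thresholds):
            cohort = sample_detection_cohort(
                test_basis, float(thr), rep_seed * 100 + ti, n_per_class
            )
            for method, predict in predictors.items():
                pred, true = predict(cohort)
                res = run_detection(pred, true, float(thr), method)
                det_rows.append(dict(repeat=r, **res.__dict__))
        sev_cohort = sample_severity_cohort(
            test_basis, rep_seed * 100 + 99, per_level
        )
        for method, predict in predictors.items():
            pred, true = predict(sev_cohort)
            res = bland_altman(true, pred, method)
            ba_rows.append(dict(repeat=r, **res.__dict__))

    det = pd.DataFrame(det_rows)
    ba = pd.DataFrame(ba_rows)

    def summarise(df: pd.DataFrame, keys: list[str], metrics: list[str]) -> pd.DataFrame:
        rows = []
        for key_vals, grp in df.groupby(keys):
            if not isinstance(key_vals, tuple):
                key_vals = (key_vals,)
            row = dict(zip(keys, key_vals))
            for m in metrics:
                row[f"{m}_mean"] = float(grp[m].mean())
                row[f"{m}_cv"] = _cv(grp[m].to_numpy())
            rows.append(row)
        return pd.DataFrame(rows)

    det_summary = summarise(
        det, ["method", "threshold"], ["sensitivity", "specificity", "accuracy", "auc"]
    )
    ba_summary = summarise(ba, ["method"], ["bias", "sd", "loa_lower", "loa_upper"])
    return EvaluationReport(
        detection=det_summary, bland_altman=ba_summary, repeats=repeats, seeds=seeds
    )
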