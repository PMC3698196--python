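"""Cohort measurements and statistics: tumor volume, B-mode gray intensity,
two-sample tests, assumption checks, Pearson correlation, and leave-one-out
cross-validated (LOOCV) two-feature classification.

The LOOCV classifier is a two-class linear discriminant with pooled
covariance and equal priors — the default discriminant procedure of common
statistics packages.  Treated is the positive class throughout: sensitivity
is the fraction of treated samples predicted treated, specificity the
fraction of control samples predicted control, and decision ties are broken
toward control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal import hilbert

__all__ = [
    "SampleRecord",
    "StatsReport",
    "LoocvResult",
    "tumor_volume",
    "bmode_image",
    "mean_gray_intensity",
    "two_sample_ttest",
    "assumption_checks",
    "pearson_correlation",
    "loocv_classify",
    "loocv_replicates",
    "cohort_report",
]

GROUP_LABELS = ("control", "treated")
_MEASURES = ("volume", "gray_intensity", "slope", "midband", "nuclei_density")


def tumor_volume(length: float, width: float, depth: float) -> float:
    """Prolate-ellipsoid calliper volume: pi/6 * length * width * depth (cm^3)."""
    if length <= 0 or width <= 0 or depth <= 0:
        raise ValueError("all calliper dimensions must be > 0")
    return math.pi / 6.0 * length * width * depth


@dataclass(frozen=True)
class SampleRecord:
    """Per-tumor measurements; missing measures are None."""

    sample_id: str
    group: str
    length_cm: float | None = None
    width_cm: float | None = None
    depth_cm: float | None = None
    volume: float | None = None
    gray_intensity: float | None = None
    slope: float | None = None
    midband: float | None = None
    nuclei_density: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(f"group must be one of {GROUP_LABELS}")
        dims = (self.length_cm, self.width_cm, self.depth_cm)
        if all(d is not None for d in dims):
            expected = tumor_volume(*dims)
            if self.volume is None:
                object.__setattr__(self, "volume", expected)
            elif abs(self.volume - expected) > 1e-9:
                raise ValueError("volume inconsistent with pi/6 * length * width * depth")


def bmode_image(
    frame, dynamic_range_db: float = 60.0, gain_db: float = 25.0
) -> np.ndarray:
    """B-mode proxy from RF: analytic-signal envelope, log compression, 8 bit.

    The dB-to-gray mapping is fixed (full scale = 32768 counts at
    ``-gain_db``), never normalized per image, so intensity comparisons
    between frames are meaningful.
    """
    lines = np.asarray(frame.lines, dtype=float)
    envelope = np.abs(hilbert(lines, axis=1))
    with np.errstate(divide="ignore"):
        env_db = 20.0 * np.log10(np.maximum(envelope, 1e-12) / 32768.0)
    scaled = (env_db + gain_db + dynamic_range_db) / dynamic_range_db
    return np.clip(np.rint(255.0 * scaled), 0, 255).astype(np.uint8)


def mean_gray_intensity(image, roi_rectangle: tuple[int, int, int, int] | None = None) -> float:
    """Mean pixel value inside a rectangular ROI of a gray-scale image.

    ``roi_rectangle`` is (top, left, height, width) in pixels; None means the
    whole image.  RF frames are accepted directly and converted through the
    B-mode proxy first.
    """
    if hasattr(image, "lines"):
        image = bmode_image(image)
    img = np.asarray(image, dtype=float)
    if roi_rectangle is None:
        roi = img
    else:
        top, left, height, width = roi_rectangle
        if height <= 0 or width <= 0:
            raise ValueError("ROI must have positive height and width")
        if top < 0 or left < 0 or top + height > img.shape[0] or left + width > img.shape[1]:
            raise ValueError("ROI extends outside the image")
        roi = img[top : top + height, left : left + width]
    if roi.size == 0:
        raise ValueError("empty ROI")
    return float(roi.mean())


def two_sample_ttest(x, y, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided Student's t-test (pooled variance by default).

    Degenerate zero-variance input: equal means give (0, 1); unequal means
    raise, since t is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means: t is undefined")
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def assumption_checks(x, y) -> dict:
    """Normality (one-sample KS against the fitted normal) and Levene's test.

    Returns {'ks_p': (p_x, p_y), 'levene_p': p}; a constant sample makes its
    KS p undefined (reported as nan).  The KS test uses estimated mean/SD,
    which is the common software default and conservative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each sample needs n >= 3")

    def _ks(sample: np.ndarray) -> float:
        sd = sample.std(ddof=1)
        if sd == 0:
            return float("nan")
        return float(sps.kstest(sample, "norm", args=(sample.mean(), sd)).pvalue)

    levene_p = float(sps.levene(x, y, center="mean").pvalue)
    return {"ks_p": (_ks(x), _ks(y)), "levene_p": levene_p}


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with its two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("samples must have equal length >= 3")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("Pearson correlation is undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class LoocvResult:
    accuracy: float
    sensitivity: float
    specificity: float
    predictions: tuple[str, ...]


def _lda_direction(x0: np.ndarray, x1: np.ndarray) -> tuple[np.ndarray, float]:
    """Pooled-covariance linear discriminant: weight vector and threshold.

    Falls back to a diagonal covariance (with a warning) when the pooled
    covariance is singular.
    """
    m0 = x0.mean(axis=0)
    m1 = x1.mean(axis=0)
    n0, n1 = x0.shape[0], x1.shape[0]
    pooled = ((n0 - 1) * np.cov(x0, rowvar=False) + (n1 - 1) * np.cov(x1, rowvar=False)) / (
        n0 + n1 - 2
    )
    pooled = np.atleast_2d(pooled)
    try:
        if np.linalg.cond(pooled) > 1e12:
            raise np.linalg.LinAlgError
        weights = np.linalg.solve(pooled, m1 - m0)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular pooled covariance; falling back to its diagonal",
            RuntimeWarning,
            stacklevel=3,
        )
        diag = np.diag(pooled).copy()
        diag[diag <= 0] = max(1e-12, float(diag[diag > 0].mean()) if np.any(diag > 0) else 1e-12)
        weights = (m1 - m0) / diag
    threshold = float(weights @ (m0 + m1) / 2.0)  # equal priors
    return weights, threshold


def loocv_classify(features, labels) -> LoocvResult:
    """Leave-one-out cross-validated two-class linear discriminant.

    Each sample is predicted by a pooled-covariance, equal-prior linear
    discriminant trained on the other n-1; treated is the positive class and
    ties go to control.  Requires n >= 4 with both labels present.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(labels)
    y = labels == "treated" if labels.dtype.kind in "UO" else labels.astype(bool)
    n = x.shape[0]
    if n < 4 or y.sum() == 0 or y.sum() == n:
        raise ValueError("LOOCV needs n >= 4 with both labels present")
    predictions = np.zeros(n, dtype=bool)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        weights, threshold = _lda_direction(x[mask & ~y], x[mask & y])
        predictions[i] = float(weights @ x[i]) > threshold  # tie -> control
    tp = int(np.sum(predictions & y))
    tn = int(np.sum(~predictions & ~y))
    return LoocvResult(
        accuracy=(tp + tn) / n,
        sensitivity=tp / int(y.sum()),
        specificity=tn / int((~y).sum()),
        predictions=tuple("treated" if p else "control" for p in predictions),
    )


def loocv_replicates(
    control_means: Sequence[float],
    control_sds: Sequence[float],
    treated_means: Sequence[float],
    treated_sds: Sequence[float],
    n_per_group: int = 12,
    n_replicates: int = 1000,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Monte-Carlo LOOCV over cohorts drawn from per-group feature normals.

    Features are drawn independently within each group (the within-group
    feature correlation defaults to zero).  Returns per-replicate arrays of
    accuracy, sensitivity and specificity.
    """
    rng = np.random.default_rng(seed)
    cm = np.asarray(control_means, dtype=float)
    cs = np.asarray(control_sds, dtype=float)
    tm = np.asarray(treated_means, dtype=float)
    ts = np.asarray(treated_sds, dtype=float)
    labels = np.concatenate([np.zeros(n_per_group, bool), np.ones(n_per_group, bool)])
    acc = np.empty(n_replicates)
    sen = np.empty(n_replicates)
    spe = np.empty(n_replicates)
    for k in range(n_replicates):
        control = rng.normal(cm, cs, size=(n_per_group, cm.size))
        treated = rng.normal(tm, ts, size=(n_per_group, tm.size))
        result = loocv_classify(np.vstack([control, treated]), labels)
        acc[k], sen[k], spe[k] = result.accuracy, result.sensitivity, result.specificity
    return {"accuracy": acc, "sensitivity": sen, "specificity": spe}


@dataclass(frozen=True)
class StatsReport:
    """Cohort-level statistics assembled from per-sample records."""

    n_control: int
    n_treated: int
    group_stats: dict
    tests: dict
    correlations: dict
    loocv: dict
    percent_changes: dict
    missing_measures: tuple[str, ...]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_text(self) -> str:
        lines = [f"Cohort: {self.n_control} control vs {self.n_treated} treated", ""]
        for measure, stats in self.group_stats.items():
            c, t = stats["control"], stats["treated"]
            test = self.tests.get(measure, {})
            lines.append(
                f"{measure:>15}: control {c['mean']:9.3f} +/- {c['sd']:7.3f}   "
                f"treated {t['mean']:9.3f} +/- {t['sd']:7.3f}   "
                f"t={test.get('t', float('nan')):7.3f} p={test.get('p', float('nan')):.4g}"
            )
        for measure, pc in self.percent_changes.items():
            lines.append(f"percent change ({measure}): {pc:+.1f}%")
        for pair, corr in self.correlations.items():
            lines.append(f"Pearson {pair}: r={corr['r']:.3f} p={corr['p']:.4g}")
        if self.loocv:
            lines.append(
                f"LOOCV (slope, midband): accuracy {self.loocv['accuracy']:.3f}, "
                f"sensitivity {self.loocv['sensitivity']:.3f}, "
                f"specificity {self.loocv['specificity']:.3f}"
            )
        if self.missing_measures:
            lines.append(f"absent measures: {', '.join(self.missing_measures)}")
        return "\n".join(lines)


def cohort_report(records: Sequence[SampleRecord]) -> StatsReport:
    """Assemble the full cohort statistics from per-sample records.

    Group means/SDs, pooled t-tests with assumption checks, percent changes
    of slope and midband, Pearson correlations of each spectral parameter
    against nuclei density, and two-feature LOOCV.  Measures absent from the
    records are marked absent rather than failing.
    """
    df = pd.DataFrame([asdict(r) for r in records])
    for label in GROUP_LABELS:
        if (df["group"] == label).sum() < 2:
            raise ValueError(f"need at least 2 records in group '{label}'")
    control = df[df["group"] == "control"]
    treated = df[df["group"] == "treated"]

    group_stats: dict = {}
    tests: dict = {}
    missing: list[str] = []
    for measure in _MEASURES:
        cx = control[measure].dropna().to_numpy(dtype=float)
        tx = treated[measure].dropna().to_numpy(dtype=float)
        if cx.size < 2 or tx.size < 2:
            missing.append(measure)
            continue
        group_stats[measure] = {
            "control": {"mean": float(cx.mean()), "sd": float(cx.std(ddof=1))},
            "treated": {"mean": float(tx.mean()), "sd": float(tx.std(ddof=1))},
        }
        t, p = two_sample_ttest(cx, tx)
        entry = {"t": t, "p": p}
        if cx.size >= 3 and tx.size >= 3:
            entry.update(assumption_checks(cx, tx))
        tests[measure] = entry

    percent_changes = {}
    from .spectral import percent_change  # local import: avoid a hard dependency cycle

    for measure in ("slope", "midband"):
        if measure in group_stats:
            percent_changes[measure] = percent_change(
                group_stats[measure]["control"]["mean"],
                group_stats[measure]["treated"]["mean"],
            )

    correlations = {}
    if "nuclei_density" not in missing:
        for measure in ("slope", "midband"):
            if measure in missing:
                continue
            sub = df[[measure, "nuclei_density"]].dropna()
            if len(sub) >= 3:
                r, p = pearson_correlation(sub[measure], sub["nuclei_density"])
                correlations[f"{measure}_vs_nuclei_density"] = {"r": r, "p": p}

    loocv: dict = {}
    if "slope" not in missing and "midband" not in missing:
        sub = df[["slope", "midband", "group"]].dropna()
        if len(sub) >= 4 and sub["group"].nunique() == 2:
            result = loocv_classify(
                sub[["slope", "midband"]].to_numpy(dtype=float), sub["group"].to_numpy()
            )
            loocv = {
                "accuracy": result.accuracy,
                "sensitivity": result.sensitivity,
                "specificity": result.specificity,
                "predictions": dict(zip(sub.index.map(lambda i: df.loc[i, "sample_id"]), result.predictions)),
            }

    return StatsReport(
        n_control=int(len(control)),
        n_treated=int(len(treated)),
        group_stats=group_stats,
        tests=tests,
        correlations=correlations,
        loocv=loocv,
        percent_changes=percent_changes,
        missing_measures=tuple(missing),
    )
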