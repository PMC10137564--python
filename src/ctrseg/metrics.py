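"""Segmentation-overlap, agreement, and diagnostic-performance metrics.

Covers the full evaluation suite for an automated CTR pipeline:

* pixel confusion counts (one-vs-rest per class) and the derived
  IoU = TP/(TP+FP+FN) and Dice = 2·PPV·TPR/(PPV+TPR) per class, with
  mIoU/ADC as unweighted class averages (foreground classes lung+heart
  by default; background can be included with a flag);
* method-agreement statistics on CTR values: OLS R², mean ± SD absolute
  difference in percentage points, the count of images with absolute CTR
  bias ≥ 2 percentage points, Bland–Altman bias and 95% limits of
  agreement, and a paired two-sided t-test;
* diagnostic performance of the cardiomegaly call (CTR > 50%):
  accuracy / sensitivity / specificity and a threshold-sweep ROC curve
  with trapezoidal AUC (tie handling equivalent to the pairwise rule
  P(score+ > score−) + ½·P(equal)).

Standard statistics (t-test, OLS) are delegated to :mod:`scipy.stats`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import io
from .errors import DegenerateInputError

FOREGROUND_CLASSES = (io.LUNG, io.HEART)


# ---------------------------------------------------------------------------
# pixel confusion and overlap metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest pixel tallies per class (arrays indexed by class code)."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n_pixels(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


def confusion(pred: np.ndarray, ref: np.ndarray) -> ConfusionCounts:
    """Per-class one-vs-rest pixel confusion between two label masks."""
    pred = io.validate_mask(pred)
    ref = io.validate_mask(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs ref {ref.shape}")
    k = io.N_CLASSES
    m = np.bincount(
        ref.ravel().astype(np.int64) * k + pred.ravel(), minlength=k * k
    ).reshape(k, k)  # rows: reference class, cols: predicted class
    tp = np.diag(m).astype(np.int64)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    tn = m.sum() - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class SegMetrics:
    iou_per_class: dict
    dice_per_class: dict
    miou: float
    adc: float
    class_set_averaged: tuple


def seg_metrics(
    counts: ConfusionCounts,
    classes_to_average: tuple = FOREGROUND_CLASSES,
) -> SegMetrics:
    """IoU/Dice per class and their unweighted averages (mIoU, ADC).

    A class with TP+FP+FN = 0 (absent from both masks) is excluded from
    the averages; the classes actually averaged are recorded.
    """
    if not classes_to_average:
        raise ValueError("classes_to_average must not be empty")
    iou, dice = {}, {}
    for c in range(io.N_CLASSES):
        tp, fp, fn = int(counts.tp[c]), int(counts.fp[c]), int(counts.fn[c])
        if tp + fp + fn == 0:
            continue
        iou[c] = tp / (tp + fp + fn)
        # algebraically 2*PPV*TPR/(PPV+TPR); this form is defined even
        # when one of PPV/TPR has an empty denominator
        dice[c] = 2 * tp / (2 * tp + fp + fn)
    averaged = tuple(c for c in classes_to_average if c in iou)
    if not averaged:
        raise ValueError("no class in classes_to_average has any pixels")
    return SegMetrics(
        iou_per_class=iou,
        dice_per_class=dice,
        miou=float(np.mean([iou[c] for c in averaged])),
        adc=float(np.mean([dice[c] for c in averaged])),
        class_set_averaged=averaged,
    )


# ---------------------------------------------------------------------------
# CTR agreement statistics
# ---------------------------------------------------------------------------

def regression_r2(reference_ctrs, test_ctrs) -> float:
    """R² of the OLS regression of the test CTRs on the reference CTRs."""
    ref = np.asarray(reference_ctrs, dtype=float)
    test = np.asarray(test_ctrs, dtype=float)
    if ref.shape != test.shape:
        raise ValueError("length mismatch between reference and test CTRs")
    if ref.size < 3:
        raise ValueError(f"need n >= 3 pairs, got {ref.size}")
    if np.ptp(ref) == 0:
        raise DegenerateInputError("reference CTRs are constant; R² undefined")
    res = sps.linregress(ref, test)
    return float(res.rvalue ** 2)


def difference_stats(
    reference_ctrs, test_ctrs, bias_threshold: float = 0.02
) -> tuple[float, float, int]:
    """Mean and SD (n−1) of |test − reference| in CTR percentage points,
    plus the count of pairs at or above ``bias_threshold`` (CTR units)."""
    ref = np.asarray(reference_ctrs, dtype=float)
    test = np.asarray(test_ctrs, dtype=float)
    if ref.shape != test.shape:
        raise ValueError("length mismatch between reference and test CTRs")
    if ref.size < 2:
        raise ValueError(f"need n >= 2 pairs, got {ref.size}")
    d = np.abs(test - ref)
    return (
        float(d.mean() * 100.0),
        float(d.std(ddof=1) * 100.0),
        int(np.count_nonzero(d >= bias_threshold)),
    )


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    lower_loa: float
    upper_loa: float
    means: np.ndarray = field(repr=False)
    diffs: np.ndarray = field(repr=False)


def bland_altman(reference_ctrs, test_ctrs) -> BlandAltman:
    """Bland–Altman agreement: bias ± 1.96·SD limits plus plot payload."""
    ref = np.asarray(reference_ctrs, dtype=float)
    test = np.asarray(test_ctrs, dtype=float)
    if ref.shape != test.shape:
        raise ValueError("length mismatch between reference and test CTRs")
    if ref.size < 2:
        raise ValueError(f"need n >= 2 pairs, got {ref.size}")
    d = test - ref
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        bias=bias,
        lower_loa=bias - 1.96 * sd,
        upper_loa=bias + 1.96 * sd,
        means=(test + ref) / 2.0,
        diffs=d,
    )


def paired_t_test(abs_diffs_a, abs_diffs_b) -> tuple[float, float]:
    """Paired two-sided t-test on per-image differences (df = n − 1)."""
    a = np.asarray(abs_diffs_a, dtype=float)
    b = np.asarray(abs_diffs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 3:
        raise ValueError(f"need n >= 3 pairs, got {a.size}")
    if np.ptp(a - b) == 0:
        raise DegenerateInputError("pairwise differences have zero variance")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# diagnostic performance of the cardiomegaly call
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiagnosticReport:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc_points: np.ndarray = field(repr=False)  # ordered (FPR, TPR) pairs
    threshold: float = 0.50
    n: int = 0


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points by sweeping all distinct score thresholds + trapezoid AUC.

    Returns (roc_points, auc) with roc_points an (m, 2) array of (FPR, TPR)
    running from (0, 0) to (1, 1).  Grouping tied scores makes the
    trapezoidal AUC equal the pairwise rule P(s+ > s−) + ½·P(s+ = s−).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("ROC undefined: labels contain a single class")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # cut after the last element of each tied-score group
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), s_sorted.size - 1]
    cum_tp = np.cumsum(y_sorted)[distinct]
    cum_fp = (distinct + 1) - cum_tp
    tpr = np.r_[0.0, cum_tp / n_pos]
    fpr = np.r_[0.0, cum_fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def diagnostic_performance(
    test_ctrs, reference_ctrs, threshold: float = 0.50
) -> DiagnosticReport:
    """Cardiomegaly detection performance of the thresholded test CTRs
    against the reference truth (reference CTR strictly > threshold)."""
    test = np.asarray(test_ctrs, dtype=float)
    ref = np.asarray(reference_ctrs, dtype=float)
    if test.shape != ref.shape:
        raise ValueError("length mismatch between reference and test CTRs")
    truth = ref > threshold
    pred = test > threshold
    tp = int(np.count_nonzero(pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    roc_points, auc = roc_auc(test, truth)
    return DiagnosticReport(
        accuracy=(tp + tn) / truth.size,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        auc=auc,
        roc_points=roc_points,
        threshold=threshold,
        n=int(truth.size),
    )


@dataclass(frozen=True)
class AgreementReport:
    r2: float
    mean_abs_diff: float       # CTR percentage points
    sd_abs_diff: float         # CTR percentage points
    n_bias_ge_2pct: int
    bland_altman: tuple        # (bias, lower_loa, upper_loa) in CTR units
    t_stat: float
    p_value: float
    n: int


def agreement_report(reference_ctrs, test_ctrs) -> AgreementReport:
    """Full CTR agreement summary between a test method and the reference.

    The t-test is the paired two-sided test of test vs reference CTRs.
    """
    mean_d, sd_d, n_ge = difference_stats(reference_ctrs, test_ctrs)
    ba = bland_altman(reference_ctrs, test_ctrs)
    try:
        t, p = paired_t_test(test_ctrs, reference_ctrs)
    except DegenerateInputError:
        t, p = float("nan"), float("nan")
    return AgreementReport(
        r2=regression_r2(reference_ctrs, test_ctrs),
        mean_abs_diff=mean_d,
        sd_abs_diff=sd_d,
        n_bias_ge_2pct=n_ge,
        bland_altman=(ba.bias, ba.lower_loa, ba.upper_loa),
        t_stat=t,
        p_value=p,
        n=len(np.asarray(reference_ctrs)),
    )


# ---------------------------------------------------------------------------
# dataset-level evaluation
# ---------------------------------------------------------------------------

def evaluate_run(
    manifest_path,
    predictions: dict,
    out_dir=None,
    classes_to_average: tuple = FOREGROUND_CLASSES,
    aggregate: str = "micro",
) -> dict:
    """Evaluate predicted masks against a manifest with reference masks/CTRs.

    ``predictions`` maps each manifest ``image_path`` to a predicted label
    mask (array or path).  Confusions are summed over images before metric
    computation (micro-average; ``aggregate='macro'`` averages per-image
    metrics instead).  Images whose CTR extraction fails (missing heart or
    lung) get an ``error_note`` and are excluded from the agreement and
    diagnostic statistics — the automated pipeline's hand-off to human
    review.  Returns a report bundle; CSV/JSON files are written when
    ``out_dir`` is given.
    """
    from .ctr import compute_ctr
    from .errors import MissingStructureError

    manifest = io.read_manifest(manifest_path)
    base = Path(manifest_path).parent
    missing = [r for r in manifest["image_path"] if r not in predictions]
    if missing:
        raise ValueError(f"missing predictions for {len(missing)} image(s): "
                         f"{missing[:5]}{'...' if len(missing) > 5 else ''}")

    total = None
    per_image_metrics = []
    rows = []
    for rec in manifest.itertuples():
        pred = predictions[rec.image_path]
        if not isinstance(pred, np.ndarray):
            pred = io.read_mask(pred)
        ref_mask = io.read_mask(base / rec.mask_path)
        cc = confusion(pred, ref_mask)
        total = cc if total is None else total + cc
        per_image_metrics.append(seg_metrics(cc, classes_to_average))

        row = dict(image_path=rec.image_path, error_note="")
        ref_ctr = getattr(rec, "true_ctr", None)
        if ref_ctr is None or not np.isfinite(ref_ctr):
            try:
                ref_ctr = compute_ctr(ref_mask).ctr
            except MissingStructureError as exc:
                ref_ctr = np.nan
                row["error_note"] = f"reference: {exc}"
        row["reference_ctr"] = ref_ctr
        try:
            res = compute_ctr(pred)
            row.update(
                predicted_ctr=res.ctr,
                cardiac_width_px=res.cardiac_width_px,
                thoracic_width_px=res.thoracic_width_px,
                cardiomegaly_flag=res.ctr > 0.5,
            )
        except MissingStructureError as exc:
            row.update(predicted_ctr=np.nan, cardiac_width_px=np.nan,
                       thoracic_width_px=np.nan, cardiomegaly_flag=None,
                       error_note=(row["error_note"] + "; " if row["error_note"]
                                   else "") + str(exc))
        rows.append(row)

    per_image = pd.DataFrame(rows)
    if aggregate == "micro":
        seg = seg_metrics(total, classes_to_average)
    elif aggregate == "macro":
        seg = SegMetrics(
            iou_per_class={}, dice_per_class={},
            miou=float(np.mean([m.miou for m in per_image_metrics])),
            adc=float(np.mean([m.adc for m in per_image_metrics])),
            class_set_averaged=classes_to_average,
        )
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")

    ok = per_image["predicted_ctr"].notna() & per_image["reference_ctr"].notna()
    ref_ok = per_image.loc[ok, "reference_ctr"].to_numpy()
    test_ok = per_image.loc[ok, "predicted_ctr"].to_numpy()
    # degenerate at tiny n or single-class truth: report what is computable
    try:
        agreement = agreement_report(ref_ok, test_ok)
    except (ValueError, DegenerateInputError):
        agreement = None
    try:
        diagnostic = diagnostic_performance(test_ok, ref_ok)
    except (ValueError, DegenerateInputError):
        diagnostic = None

    bundle = dict(
        seg=seg,
        agreement=agreement,
        diagnostic=diagnostic,
        per_image=per_image,
        n_images=len(per_image),
        n_excluded=int((~ok).sum()),
        aggregate=aggregate,
        classes_averaged=[io.CLASS_NAMES[c] for c in seg.class_set_averaged],
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def bundle_summary(bundle: dict) -> dict:
    """Flatten a report bundle into JSON-serialisable scalars."""
    seg, agr, diag = bundle["seg"], bundle["agreement"], bundle["diagnostic"]
    out = dict(
        n_images=bundle["n_images"],
        n_excluded=bundle["n_excluded"],
        aggregate=bundle["aggregate"],
        classes_averaged=bundle["classes_averaged"],
        miou=seg.miou,
        adc=seg.adc,
        iou_per_class={io.CLASS_NAMES[c]: v for c, v in seg.iou_per_class.items()},
        dice_per_class={io.CLASS_NAMES[c]: v for c, v in seg.dice_per_class.items()},
    )
    if agr is not None:
        out.update(
            r2=agr.r2,
            mean_abs_diff_pct=agr.mean_abs_diff,
            sd_abs_diff_pct=agr.sd_abs_diff,
            n_bias_ge_2pct=agr.n_bias_ge_2pct,
            bland_altman_bias=agr.bland_altman[0],
            bland_altman_lower_loa=agr.bland_altman[1],
            bland_altman_upper_loa=agr.bland_altman[2],
            t_stat=agr.t_stat,
            p_value=agr.p_value,
        )
    if diag is not None:
        out.update(
            accuracy=diag.accuracy,
            sensitivity=diag.sensitivity,
            specificity=diag.specificity,
            auc=diag.auc,
        )
    return out


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["per_image"].to_csv(out_dir / "per_image.csv", index=False)
    diag = bundle["diagnostic"]
    roc = diag.roc_points if diag is not None else np.empty((0, 2))
    pd.DataFrame(roc, columns=["fpr", "tpr"]).to_csv(
        out_dir / "roc_points.csv", index=False
    )
    ok = bundle["per_image"]["predicted_ctr"].notna() & \
        bundle["per_image"]["reference_ctr"].notna()
    sub = bundle["per_image"].loc[ok]
    pd.DataFrame({
        "mean_ctr": (sub["predicted_ctr"] + sub["reference_ctr"]) / 2.0,
        "diff_ctr": sub["predicted_ctr"] - sub["reference_ctr"],
    }).to_csv(out_dir / "bland_altman_points.csv", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(bundle_summary(bundle), fh, indent=2)
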