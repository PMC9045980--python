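"""Segmentation metric suite and per-case aggregation.

Ratio metrics come from per-pixel confusion counts:

    Jaccard = TP / (TP + FN + FP)          DSC = 2TP / (2TP + FP + FN)
    SEN = TP / (TP + FN)                   SPE = TN / (FP + TN)
    PPV = TP / (TP + FP)                   ACC = (TP + TN) / total

The Hausdorff distance is the symmetric max-of-directed-max Euclidean
distance between the two foreground pixel sets (full sets, not boundaries),
computed with exact distance transforms.  Per-case aggregation pools counts
over a case's slices (micro), takes the max of per-slice HDs, then averages
unweighted over cases (macro); a per-slice macro mode is also available.

Empty-foreground convention: if prediction and ground truth are both empty
the overlap metrics are 1 and HD is 0; if exactly one is empty the ratios
are 0 and HD is undefined (NaN, excluded from means with a logged count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "compute_metrics",
    "confusion_counts",
    "evaluate_cases",
    "hausdorff_distance",
]

RATIO_METRICS = ("jaccard", "dsc", "sen", "spe", "ppv", "acc")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self):
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other):
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass
class MetricsReport:
    jaccard: float = np.nan
    dsc: float = np.nan
    sen: float = np.nan
    spe: float = np.nan
    ppv: float = np.nan
    acc: float = np.nan
    hd: float = np.nan
    n_cases: int = 0
    n_hd_excluded: int = 0

    def as_dict(self):
        return {
            k: getattr(self, k)
            for k in (*RATIO_METRICS, "hd", "n_cases", "n_hd_excluded")
        }


def _check_binary(mask, name):
    mask = np.asarray(mask)
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ValueError(f"{name} mask must be binary {{0,1}}")
    return mask.astype(bool)


def confusion_counts(pred, gt) -> ConfusionCounts:
    """Exhaustive per-pixel tally of TP/FP/TN/FN for two binary masks."""
    pred = _check_binary(pred, "pred")
    gt = _check_binary(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num, den):
    return num / den if den > 0 else np.nan


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Evaluate the ratio metrics from confusion counts.

    Division-by-zero cases return NaN sentinels, except the fully empty
    prediction/ground-truth pair where the overlap metrics are 1 by
    convention.
    """
    if c.total == 0:
        return MetricsReport()
    r = MetricsReport(
        jaccard=_ratio(c.tp, c.tp + c.fn + c.fp),
        dsc=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        sen=_ratio(c.tp, c.tp + c.fn),
        spe=_ratio(c.tn, c.fp + c.tn),
        ppv=_ratio(c.tp, c.tp + c.fp),
        acc=_ratio(c.tp + c.tn, c.total),
    )
    if c.tp + c.fp + c.fn == 0:  # both foregrounds empty
        r.jaccard = r.dsc = r.sen = r.ppv = 1.0
        r.hd = 0.0
    return r


def hausdorff_distance(pred, gt) -> float:
    """Symmetric Hausdorff distance between two foreground pixel sets.

    Directed distances are read off exact Euclidean distance transforms of
    each mask's complement; the result is in pixel units.  Both masks empty
    -> 0; exactly one empty -> NaN with a warning.
    """
    pred = _check_binary(pred, "pred")
    gt = _check_binary(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    p_any, g_any = pred.any(), gt.any()
    if not p_any and not g_any:
        return 0.0
    if p_any != g_any:
        warnings.warn("Hausdorff distance undefined: one mask is empty", stacklevel=2)
        return float("nan")
    d_to_gt = distance_transform_edt(~gt)
    d_to_pred = distance_transform_edt(~pred)
    return float(max(d_to_gt[pred].max(), d_to_pred[gt].max()))


def _case_masks(case):
    # Accept CaseRecord-like objects or plain lists of masks.
    return case.tumor_masks if hasattr(case, "tumor_masks") else list(case)


def evaluate_cases(preds: list, gts: list, mode: str = "case", target: str = "tumor") -> MetricsReport:
    """Aggregate metrics over aligned predicted and ground-truth cases.

    ``preds`` holds per-case lists of predicted binary masks (or CaseRecords),
    ``gts`` the matching ground-truth cases.  mode="case" pools confusion
    counts within each case and takes the per-case max slice HD, then averages
    unweighted over cases; mode="slice" macro-averages per slice.
    """
    if mode not in ("case", "slice"):
        raise ValueError(f"mode must be 'case' or 'slice', got {mode!r}")
    if len(preds) != len(gts):
        raise ValueError(f"case lists differ in length: {len(preds)} vs {len(gts)}")

    units = []  # (counts, hd) per aggregation unit
    for pred_case, gt_case in zip(preds, gts):
        pmasks = _case_masks(pred_case)
        if target == "roi" and hasattr(gt_case, "roi_masks"):
            gmasks = gt_case.roi_masks
        else:
            gmasks = _case_masks(gt_case)
        if len(pmasks) != len(gmasks):
            raise ValueError("slice counts differ between prediction and ground truth")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_slice = [
                (confusion_counts(p, g), hausdorff_distance(p, g))
                for p, g in zip(pmasks, gmasks)
            ]
        if mode == "case":
            counts = ConfusionCounts()
            for c, _ in per_slice:
                counts = counts + c
            hds = [h for _, h in per_slice]
            hd = np.nan if np.any(np.isnan(hds)) else (max(hds) if hds else np.nan)
            units.append((counts, hd))
        else:
            units.extend(per_slice)

    reports = []
    for counts, hd in units:
        r = compute_metrics(counts)
        if not (counts.tp + counts.fp + counts.fn == 0):
            r.hd = hd
        reports.append(r)

    out = MetricsReport(n_cases=len(units))
    for name in RATIO_METRICS:
        vals = [getattr(r, name) for r in reports if np.isfinite(getattr(r, name))]
        setattr(out, name, float(np.mean(vals)) if vals else np.nan)
    hds = [r.hd for r in reports]
    finite = [h for h in hds if np.isfinite(h)]
    out.n_hd_excluded = int(sum(1 for h in hds if not np.isfinite(h)))
    out.hd = float(np.mean(finite)) if finite else np.nan
    return out
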