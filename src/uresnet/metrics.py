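"""Segmentation agreement statistics.

Per-case measures (Dice overlap, lesion volume as a percentage of the
intracranial volume) and cohort-level agreement between automatic and
reference volumetry: ordinary least-squares trend with R^2 and RMSE,
Bland-Altman bias / reproducibility coefficient (RPC = 1.96 sigma of the
paired differences) / coefficient of variation (CV = 100 sigma / mean of
the paired measurements), and the Wilcoxon signed-rank paired test with the
effect size |z| / sqrt(n1 + n2).

Conventions (documented because reference texts leave them open): standard
deviations are sample (n-1) estimates; Dice of two empty masks is 1
(perfect agreement on absence); the Bland-Altman bias is tested against
zero with a two-sided one-sample t-test; the Wilcoxon z is the normal
approximation with zero-differences discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .volume_io import LabelMap


def dice_score(pred: LabelMap | np.ndarray, ref: LabelMap | np.ndarray,
               class_id: int) -> float:
    """Dice overlap 2|A^B| / (|A|+|B|) of one class; 1 if both masks empty."""
    a = (pred.labels if isinstance(pred, LabelMap) else np.asarray(pred)) == class_id
    b = (ref.labels if isinstance(ref, LabelMap) else np.asarray(ref)) == class_id
    if a.shape != b.shape:
        raise ValueError(f"label grids differ in shape: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def lesion_volume_icv(labels: LabelMap, spacing, brain_mask: np.ndarray,
                      class_id: int) -> float:
    """Lesion volume of one class as a percentage of the intracranial volume."""
    brain_mask = np.asarray(brain_mask, dtype=bool)
    n_icv = int(brain_mask.sum())
    if n_icv == 0:
        raise ValueError("brain mask is empty: ICV undefined")
    lab = labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)
    # identical voxel volume cancels from the ratio but is kept for clarity
    vox = float(np.prod(spacing))
    return 100.0 * (int((lab == class_id).sum()) * vox) / (n_icv * vox)


def volume_agreement(auto, ref) -> dict[str, float]:
    """OLS trend of automatic volumes against reference volumes.

    Returns slope/intercept of ``auto = slope * ref + intercept``, the R^2
    of that fit, and the RMSE of the paired differences (auto - ref).
    """
    auto = np.asarray(auto, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if auto.shape != ref.shape:
        raise ValueError("auto and ref must have equal lengths")
    if auto.size < 3:
        raise ValueError("need at least 3 cases for a trend fit")
    fit = stats.linregress(ref, auto)
    rmse = float(np.sqrt(np.mean((auto - ref) ** 2)))
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue**2),
        "rmse": rmse,
    }


def bland_altman(auto, ref) -> dict[str, float]:
    """Bland-Altman agreement between paired volume measurements."""
    auto = np.asarray(auto, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if auto.shape != ref.shape:
        raise ValueError("auto and ref must have equal lengths")
    if auto.size < 2:
        raise ValueError("need at least 2 cases")
    d = auto - ref
    sigma = float(np.std(d, ddof=1))
    mean_of_pairs = float(np.mean((auto + ref) / 2.0))
    if mean_of_pairs == 0:
        raise ZeroDivisionError("mean measurement is zero: CV undefined")
    if np.allclose(d, d[0]):
        bias_p = 1.0 if d[0] == 0 else 0.0
    else:
        bias_p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return {
        "bias": float(np.mean(d)),
        "rpc": 1.96 * sigma,
        "cv": 100.0 * sigma / mean_of_pairs,
        "bias_p": bias_p,
    }


def paired_effect_size(metric_a, metric_b) -> dict[str, float]:
    """Wilcoxon signed-rank test plus effect size |z| / sqrt(n1 + n2).

    ``n1 = n2 =`` number of cases; z is the normal approximation of the
    signed-rank statistic.  If all paired differences are zero the test is
    degenerate: p = 1 and effect size 0 by convention.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal lengths")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    if np.all(a == b):
        return {"p": 1.0, "z": 0.0, "effect_size": 0.0}
    res = stats.wilcoxon(a, b, zero_method="wilcox", method="approx")
    z = float(res.zstatistic)
    return {
        "p": float(res.pvalue),
        "z": z,
        "effect_size": effect_size_from_z(z, a.size, b.size),
    }


def effect_size_from_z(z: float, n1: int, n2: int) -> float:
    """r = |z| / sqrt(n1 + n2)."""
    return abs(z) / np.sqrt(n1 + n2)


def evaluate_cohort(
    predictions: list[LabelMap],
    references: list[LabelMap],
    spacings: list[tuple[float, float, float]],
    brain_masks: list[np.ndarray],
    class_ids: tuple[int, ...] = (1, 2),
    class_names: tuple[str, ...] = ("WMH", "stroke"),
) -> dict:
    """Per-case Dice and ICV-% volumes plus cohort agreement statistics.

    Returns ``{"per_case": DataFrame, "summary": DataFrame}``.  Cohort Dice
    means are taken over the cases where the class is present in the
    reference; agreement statistics use all cases.
    """
    rows = []
    for i, (pred, ref) in enumerate(zip(predictions, references)):
        row = {"case": i}
        for cid, name in zip(class_ids, class_names):
            row[f"dice_{name}"] = dice_score(pred, ref, cid)
            row[f"auto_vol_{name}"] = lesion_volume_icv(
                pred, spacings[i], brain_masks[i], cid
            )
            row[f"ref_vol_{name}"] = lesion_volume_icv(
                ref, spacings[i], brain_masks[i], cid
            )
            row[f"present_{name}"] = bool((ref.labels == cid).any())
        rows.append(row)
    per_case = pd.DataFrame(rows)
    summary_rows = []
    for cid, name in zip(class_ids, class_names):
        present = per_case[f"present_{name}"]
        dice = per_case.loc[present, f"dice_{name}"]
        auto = per_case[f"auto_vol_{name}"].to_numpy()
        ref = per_case[f"ref_vol_{name}"].to_numpy()
        entry = {
            "class": name,
            "dice_mean": float(dice.mean()) if len(dice) else np.nan,
            "dice_std": float(dice.std(ddof=1)) if len(dice) > 1 else np.nan,
            "n_cases_present": int(present.sum()),
        }
        if len(per_case) >= 3 and np.ptp(ref) > 0:
            entry.update(volume_agreement(auto, ref))
        if len(per_case) >= 2 and np.mean((auto + ref) / 2) != 0:
            ba = bland_altman(auto, ref)
            entry.update({f"ba_{k}": v for k, v in ba.items()})
        summary_rows.append(entry)
    return {"per_case": per_case, "summary": pd.DataFrame(summary_rows)}


def write_report(report: dict, out_dir) -> None:
    """Serialize an evaluation report as delimited text."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    report["per_case"].to_csv(os.path.join(out_dir, "per_case.tsv"), sep="\t",
                              index=False)
    report["summary"].to_csv(os.path.join(out_dir, "summary.tsv"), sep="\t",
                             index=False)
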