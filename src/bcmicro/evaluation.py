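"""Evaluation protocols: ROC with partial score coverage, stratified
5-fold cross-validation, and ranked cumulative protein down-fold curves.

Two quirks distinguish these from textbook ROC/gain curves:

* tools only report scores above their internal cutoffs, so a record with
  a missing score can never be "called" — the realized ROC stops at the
  tool's maximum reachable FPR (fraction of negatives with any score) and
  is optionally extrapolated to (1, 1) by a straight segment, mirroring
  the dashed interpolation used when plotting such curves;
* ranked-list quality against proteomics is measured by the area A(n)
  under the running cumulative sum c(t) of protein log fold changes over
  the top-n predictions — more negative means the ranking concentrates
  repressed proteins at the top.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import BcmicroError, InsufficientDataError
from .fusion import posterior_batch
from .score_io import FoldChangeTable, ScoreTable
from .training import TrainingConfig, train_model

#: Ranking orientation of the six tools' raw scores: True when a larger
#: score means a stronger predicted target.  TargetScan context scores
#: and PITA ddG energies rank the other way.
DEFAULT_DIRECTIONS: dict[str, bool] = {
    "TargetScan": False,
    "miRanda": True,
    "PicTar": True,
    "mirTarget": True,
    "PITA": False,
    "Diana-microT": True,
}


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    max_reachable_fpr: float
    extrapolated: bool


@dataclass
class CumulativeCurve:
    """c(t): cumulative fold-change sums; a_n: area A(n) per requested n."""

    c: np.ndarray
    a_n: dict[int, float]


@dataclass
class CVResult:
    posteriors: np.ndarray
    roc: ROCResult
    fold_of: np.ndarray  # test-fold index per record


def roc_curve(
    scores,
    labels,
    extrapolate: bool = False,
    higher_is_better: bool = True,
) -> ROCResult:
    """ROC over present scores; missing scores are never called.

    Thresholds sweep the unique present scores (ties enter the called set
    together).  Records with missing scores still count in the TPR/FPR
    denominators, so the realized curve ends at the coverage limit
    (max reachable FPR); with ``extrapolate`` a straight segment continues
    to (1, 1) and is included in the trapezoidal AUC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise InsufficientDataError("need at least one positive and one negative")
    if not higher_is_better:
        s = -s
    present = ~np.isnan(s)
    sp = s[present]
    yp = y[present]
    order = np.argsort(-sp, kind="stable")
    sp, yp = sp[order], yp[order]
    tps = np.cumsum(yp == 1)
    fps = np.cumsum(yp == 0)
    # last index of each tie group = points of the threshold sweep
    if len(sp):
        last = np.r_[np.nonzero(np.diff(sp))[0], len(sp) - 1]
        tpr_pts = tps[last] / n_pos
        fpr_pts = fps[last] / n_neg
    else:
        tpr_pts = np.empty(0)
        fpr_pts = np.empty(0)
    fpr = np.r_[0.0, fpr_pts]
    tpr = np.r_[0.0, tpr_pts]
    max_reachable_fpr = float((present & (y == 0)).sum() / n_neg)
    did_extrapolate = False
    if extrapolate and (fpr[-1] < 1.0 or tpr[-1] < 1.0):
        fpr = np.r_[fpr, 1.0]
        tpr = np.r_[tpr, 1.0]
        did_extrapolate = True
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr, tpr, auc, max_reachable_fpr, did_extrapolate)


def five_fold_cv(
    table: ScoreTable, cfg: TrainingConfig | None = None, seed: int = 0
) -> CVResult:
    """Stratified 5-fold CV: train on 4 folds, score the held-out fold.

    Out-of-fold posteriors are pooled into a single ROC (extrapolated,
    although fused posteriors are always present so the realized curve
    already reaches (1, 1)).
    """
    labels = table.labels
    if np.isnan(labels).any():
        raise BcmicroError("cross-validation requires a fully labeled table")
    if (labels == 1).sum() < 5 or (labels == 0).sum() < 5:
        raise InsufficientDataError("need at least 5 records of each class")
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    n = len(table)
    posteriors = np.empty(n)
    fold_of = np.empty(n, dtype=int)
    for k, (train_idx, test_idx) in enumerate(
        skf.split(np.zeros(n), labels.astype(int))
    ):
        model = train_model(table.subset(train_idx), cfg, seed=seed)
        posteriors[test_idx] = posterior_batch(model, table.subset(test_idx))
        fold_of[test_idx] = k
    roc = roc_curve(posteriors, labels, extrapolate=True)
    return CVResult(posteriors, roc, fold_of)


def cumulative_downfold(
    ranked_genes, fc: FoldChangeTable, n_list
) -> CumulativeCurve:
    """Cumulative fold-change curve c(t) and areas A(n) for a ranked list.

    ``ranked_genes`` must be ordered by descending prediction confidence.
    Genes absent from the fold-change table are skipped without consuming
    rank positions.  A(n) = sum_{t<=n} c(t) with c(t) = sum_{j<=t} fc_j.
    """
    values = [float(fc.entries[g]) for g in ranked_genes if g in fc.entries]
    # plain left-fold accumulation so A(n) matches a literal double sum
    # bit-for-bit
    c: list[float] = []
    running = 0.0
    for v in values:
        running += v
        c.append(running)
    a_of_c: list[float] = []
    area = 0.0
    for v in c:
        area += v
        a_of_c.append(area)
    a_n: dict[int, float] = {}
    for n in n_list:
        n = int(n)
        if n < 1 or n > len(c):
            raise ValueError(
                f"n={n} outside usable ranked-list length {len(c)}"
            )
        a_n[n] = a_of_c[n - 1]
    return CumulativeCurve(c=np.array(c), a_n=a_n)


def average_downfold(
    curves, n: int, table6_convention: bool = False
) -> float:
    """F(n): the mean of A_i(n) across per-miRNA curves.

    ``table6_convention`` divides by 2M instead of M, matching one
    published summary table whose printed values equal half the plain
    mean.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one curve")
    values = []
    for curve in curves:
        if n not in curve.a_n:
            raise ValueError(f"A({n}) not computed for one of the curves")
        values.append(curve.a_n[n])
    denom = 2 * len(values) if table6_convention else len(values)
    return float(sum(values) / denom)
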