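"""Screen quality control.

Non-targeting controls are known negatives: a good screen ranks them as
non-essential. QC here is (i) a ROC/AUC of an essentiality score against
known-nonessential labels, (ii) the fraction of control units left
uncalled, and (iii) correlation of ER against external per-gene
viability measurements (e.g. siRNA knockdown assays).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .errors import ValidationError
from .scoring import CALL_NONE


@dataclass(frozen=True)
class RocResult:
    """ROC curve points (thresholds descending) and its area.

    The AUC equals both the trapezoidal area under the curve and the
    tie-corrected Mann-Whitney concordance U / (n+ * n-).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    p: float
    n: int


def roc_controls(scores, labels) -> RocResult:
    """ROC of an essentiality score (default convention: -ER) against labels.

    ``labels`` are truth flags with True = essential (positive class);
    known-nonessential controls are the negatives. Ties contribute half a
    concordant pair, so the AUC equals the Mann-Whitney statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    if not np.isfinite(scores).all():
        raise ValidationError("scores must be finite")
    if labels.all() or not labels.any():
        raise ValidationError("ROC requires both label classes")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    # rank-based AUC: ties counted 1/2 (equals the trapezoid under the tie-grouped curve)
    ranks = stats.rankdata(scores, method="average")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(u / (n_pos * n_neg)))


def control_nonessential_rate(table: pd.DataFrame) -> float:
    """Fraction of control pseudo-genes with no depletion call.

    Expects a gene table with boolean ``is_control`` and a ``call``
    column; a well-behaved screen leaves most controls uncalled.
    """
    if "is_control" not in table.columns or "call" not in table.columns:
        raise ValidationError("gene table must carry 'is_control' and 'call' columns")
    ctrl = table[table["is_control"].astype(bool)]
    if ctrl.empty:
        raise ValidationError("no control units in the gene table")
    return float((ctrl["call"] == CALL_NONE).mean())


def correlate_external(
    er: pd.Series, viability: pd.Series, method: str = "spearman"
) -> CorrelationResult:
    """Correlate per-gene ER with an external viability table.

    Series are joined on gene symbol (case-folded, whitespace-stripped);
    unmatched genes are dropped. Returns the coefficient and two-sided
    p-value for ``method`` in {"pearson", "spearman"}.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")

    def _norm(s: pd.Series) -> pd.Series:
        s = s.copy()
        s.index = s.index.astype(str).str.strip().str.upper()
        return s[~s.index.duplicated()]

    er_n, via_n = _norm(er), _norm(viability)
    common = er_n.index.intersection(via_n.index)
    if len(common) < 3:
        raise ValidationError(
            f"need at least 3 matched genes for a correlation; matched {len(common)} "
            f"of {len(er_n)} ER and {len(via_n)} viability genes"
        )
    x = er_n.loc[common].astype(float)
    y = via_n.loc[common].astype(float)
    if method == "pearson":
        res = stats.pearsonr(x, y)
    else:
        res = stats.spearmanr(x, y)
    return CorrelationResult(method=method, r=float(res.statistic), p=float(res.pvalue), n=len(common))


def write_roc(roc: RocResult, path) -> None:
    pd.DataFrame(
        {"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
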