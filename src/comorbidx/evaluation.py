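"""Discrimination and calibration statistics for fitted risk models.

* ``auc_delong`` — AUC as the Mann-Whitney two-sample statistic (ties
  count one half) with the DeLong structural-components variance and a
  normal-approximation 95% CI truncated to [0, 1].
* ``compare_auc`` — paired DeLong test for two prediction vectors on
  the same records; chi-square with 1 degree of freedom.
* ``hosmer_lemeshow`` — the H-L goodness-of-fit chi-square over risk-
  ordered bins (default 10 groups, df = groups - 2); higher values and
  small p-values mean poorer calibration.
* ``calibration_curve`` — per-quantile-bin mean predicted probability
  versus observed event proportion (the 45-degree line is perfect
  calibration).

Records with identical predictions always share a bin, so bins can be
unequal; this keeps the statistics independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "auc_delong",
    "compare_auc",
    "hosmer_lemeshow",
    "calibration_curve",
    "EvaluationReport",
    "evaluate_predictions",
]


def _check_inputs(predictions, outcomes):
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("predictions and outcomes must be equal-length 1-d vectors")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary")
    return p, y.astype(bool)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(p: np.ndarray, y: np.ndarray):
    """AUC and per-case / per-control structural components (V10, V01)."""
    pos, neg = p[y], p[~y]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r, neg_r = _midrank(pos), _midrank(neg)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    auc = float(v10.mean())
    return auc, v10, v01


def auc_delong(predictions, outcomes, level: float = 0.95):
    """AUC with DeLong 95% confidence interval.

    Returns ``(auc, (ci_low, ci_high))`` with the CI truncated to
    [0, 1].  Requires both classes present.
    """
    p, y = _check_inputs(predictions, outcomes)
    auc, v10, v01 = _delong_components(p, y)
    m, n = len(v10), len(v01)
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return auc, (lo, hi)


def compare_auc(pred_a, pred_b, outcomes):
    """Paired DeLong test of two correlated AUCs on the same records.

    Returns ``(chi2 statistic, df=1, p)``; the statistic is
    ``(AUC_a - AUC_b)^2 / Var(AUC_a - AUC_b)`` with the covariance
    estimated from shared structural components.  Symmetric in its
    first two arguments.
    """
    pa, ya = _check_inputs(pred_a, outcomes)
    pb, yb = _check_inputs(pred_b, outcomes)
    auc_a, v10a, v01a = _delong_components(pa, ya)
    auc_b, v10b, v01b = _delong_components(pb, yb)
    m, n = len(v10a), len(v01a)
    var = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2.0 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2.0 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0.0 or np.isclose(diff, 0.0) and var < 1e-16:
        return 0.0, 1, 1.0
    chi2 = diff * diff / var
    return float(chi2), 1, float(stats.chi2.sf(chi2, 1))


def _quantile_bins(p: np.ndarray, groups: int) -> np.ndarray:
    """Bin index per record; ties share a bin, empty bins are dropped."""
    edges = np.quantile(p, np.linspace(0, 1, groups + 1)[1:-1])
    idx = np.searchsorted(edges, p, side="right")
    # relabel to consecutive bin ids (duplicated edges empty some bins)
    _, idx = np.unique(idx, return_inverse=True)
    return idx


def hosmer_lemeshow(predictions, outcomes, groups: int = 10):
    """Hosmer-Lemeshow chi-square over risk-ordered bins.

    Returns ``(statistic, df, p)`` with ``df = bins - 2`` (the number
    of realised bins, which equals ``groups`` unless prediction ties
    merge bins).  A bin with zero expected count in either class
    raises, suggesting fewer groups.
    """
    p, y = _check_inputs(predictions, outcomes)
    if len(p) < 2 * groups:
        raise ValueError(f"need at least {2 * groups} records for {groups} groups")
    if not (y.any() and (~y).any()):
        raise ValueError("both outcome classes must be present")
    idx = _quantile_bins(p, groups)
    stat = 0.0
    nbins = idx.max() + 1
    for b in range(nbins):
        sel = idx == b
        e1 = p[sel].sum()
        e0 = (1.0 - p[sel]).sum()
        if e1 <= 0.0 or e0 <= 0.0:
            raise ValueError(
                f"bin {b} has zero expected count; use fewer groups"
            )
        o1 = float(y[sel].sum())
        o0 = float((~y[sel]).sum())
        stat += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
    df = int(max(1, nbins - 2))
    return float(stat), df, float(stats.chi2.sf(stat, df))


def calibration_curve(predictions, outcomes, bins: int = 10):
    """Quantile-binned calibration points.

    Returns a list of ``(mean predicted, observed proportion, size)``
    tuples sorted by mean predicted probability.
    """
    p, y = _check_inputs(predictions, outcomes)
    if len(p) < bins:
        raise ValueError("need at least one record per bin")
    idx = _quantile_bins(p, bins)
    pts = []
    for b in range(idx.max() + 1):
        sel = idx == b
        pts.append((float(p[sel].mean()), float(y[sel].mean()), int(sel.sum())))
    pts.sort(key=lambda t: t[0])
    return pts


@dataclass
class EvaluationReport:
    """Discrimination and calibration summary for one model."""

    model: str
    auc: float
    auc_ci: tuple[float, float]
    hl_stat: float
    hl_df: int
    hl_p: float
    calibration: list[tuple[float, float, int]]
    lr_stat: float | None = None
    lr_df: int | None = None
    lr_p: float | None = None

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "hl_stat": self.hl_stat,
            "hl_df": self.hl_df,
            "hl_p": self.hl_p,
            "calibration": [
                {"mean_predicted": a, "observed": b, "size": c}
                for a, b, c in self.calibration
            ],
        }
        if self.lr_stat is not None:
            d.update({"lr_stat": self.lr_stat, "lr_df": self.lr_df, "lr_p": self.lr_p})
        return d


def evaluate_predictions(
    model: str, predictions, outcomes, hl_groups: int = 10, cal_bins: int = 10
) -> EvaluationReport:
    """Compute the full report (AUC + CI, H-L, calibration points)."""
    auc, ci = auc_delong(predictions, outcomes)
    hl, df, p = hosmer_lemeshow(predictions, outcomes, groups=hl_groups)
    cal = calibration_curve(predictions, outcomes, bins=cal_bins)
    return EvaluationReport(model, auc, ci, hl, df, p, cal)
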