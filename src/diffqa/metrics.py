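"""Evaluation of quality predictions: ranking loss, correlation, KS, skewness.

A predictor is judged per target on how well it ranks that target's decoy
pool: the ranking loss is the true-score gap between the genuinely best
decoy and the decoy the predictor puts first (0 means the best decoy was
selected), and the per-target Pearson correlation measures score agreement
across the pool.  Distribution-level agreement is probed with the two-sample
Kolmogorov-Smirnov statistic D = sup_x |F1(x) - F2(x)| on (1) all true vs
all predicted scores and (2) per-target best vs per-target selected true
scores, and the asymmetry of the ranking-loss distribution is summarized by
its population skewness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


class MetricError(ValueError):
    """Invalid input to an evaluation metric."""


@dataclass
class PoolModel:
    model_id: str
    true_gdtts: float
    predicted_gdtts: Optional[float] = None


@dataclass
class TargetPool:
    """All scored decoys of one target."""

    target_id: str
    models: list[PoolModel]

    def __post_init__(self) -> None:
        if not self.models:
            raise MetricError(f"target {self.target_id}: empty pool")
        for m in self.models:
            if not 0.0 <= m.true_gdtts <= 1.0:
                raise MetricError(
                    f"target {self.target_id}, model {m.model_id}: true score "
                    f"{m.true_gdtts} outside [0, 1]"
                )

    @property
    def best_true(self) -> float:
        return max(m.true_gdtts for m in self.models)

    def selected(self) -> PoolModel:
        """The model put first by predicted score (ties: smallest model_id)."""
        missing = [m.model_id for m in self.models if m.predicted_gdtts is None]
        if missing:
            raise MetricError(
                f"target {self.target_id}: missing predictions for {missing}"
            )
        return min(self.models,
                   key=lambda m: (-m.predicted_gdtts, m.model_id))


@dataclass
class EvalReport:
    per_target: list[dict] = field(default_factory=list)
    mean_ranking_loss: float = float("nan")
    mean_pcc: float = float("nan")
    pooled_pcc: float = float("nan")
    best_vs_selected_pcc: float = float("nan")
    loss_skewness: float = float("nan")
    n_undefined_pcc: int = 0
    ks_results: list[dict] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_targets": len(self.per_target),
            "mean_ranking_loss": self.mean_ranking_loss,
            "mean_pcc": self.mean_pcc,
            "pooled_pcc": self.pooled_pcc,
            "best_vs_selected_pcc": self.best_vs_selected_pcc,
            "loss_skewness": self.loss_skewness,
            "n_undefined_pcc": self.n_undefined_pcc,
            "ks_results": self.ks_results,
        }


# ---------------------------------------------------------------------------
# Individual metrics
# ---------------------------------------------------------------------------

def ranking_loss(pool: TargetPool) -> float:
    """|best true score - true score of the top-predicted model|, in [0, 1]."""
    return abs(pool.best_true - pool.selected().true_gdtts)


def per_target_pcc(pool: TargetPool) -> float:
    """Pearson correlation of (predicted, true); NaN when undefined.

    Undefined means fewer than two models or a constant score sequence; such
    targets are excluded from averaged correlations.
    """
    if len(pool.models) < 2:
        return float("nan")
    pred = np.array([m.predicted_gdtts for m in pool.models], dtype=float)
    true = np.array([m.true_gdtts for m in pool.models], dtype=float)
    if np.any(np.isnan(pred)):
        raise MetricError(f"target {pool.target_id}: missing predictions")
    if np.ptp(pred) == 0 or np.ptp(true) == 0:
        return float("nan")
    return float(stats.pearsonr(pred, true).statistic)


def ks_two_sample(sample1: Sequence[float],
                  sample2: Sequence[float]) -> tuple[float, float]:
    """Two-sample KS statistic D(n,m) with its asymptotic p-value.

    D is the exact supremum of |F1,n - F2,m| over the pooled data points
    (evaluated from both sides of each step); the p-value comes from the
    asymptotic two-sample Kolmogorov distribution.
    """
    s1 = np.asarray(sample1, dtype=float)
    s2 = np.asarray(sample2, dtype=float)
    if s1.size == 0 or s2.size == 0:
        raise MetricError("KS test requires two non-empty samples")
    res = stats.ks_2samp(s1, s2, method="asymp")
    return float(res.statistic), float(res.pvalue)


def skewness(sample: Sequence[float]) -> float:
    """Population (biased) sample skewness: m3 / m2^(3/2) with 1/n moments."""
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise MetricError("skewness requires at least 2 values")
    if np.ptp(x) == 0:
        raise MetricError("skewness undefined for a zero-variance sample")
    return float(stats.skew(x, bias=True))


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

def _safe_pcc(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def evaluate(pools: Sequence[TargetPool]) -> EvalReport:
    """Per-target metrics plus the aggregate statistics of the full suite.

    KS test "all_scores" compares the pooled true vs pooled predicted score
    distributions over every model; KS test "best_vs_selected" compares the
    per-target best true scores against the true scores of the selected
    models.  The skewness summarizes the ranking-loss distribution (NaN when
    the losses are constant, e.g. for a perfect predictor).
    """
    if not pools:
        raise MetricError("evaluate needs at least one target pool")
    report = EvalReport()
    losses, pccs = [], []
    all_true, all_pred, best_true, selected_true = [], [], [], []
    for pool in pools:
        loss = ranking_loss(pool)
        pcc = per_target_pcc(pool)
        losses.append(loss)
        if math.isnan(pcc):
            report.n_undefined_pcc += 1
        else:
            pccs.append(pcc)
        report.per_target.append(
            {"target_id": pool.target_id, "n_models": len(pool.models),
             "ranking_loss": loss, "pcc": pcc}
        )
        all_true.extend(m.true_gdtts for m in pool.models)
        all_pred.extend(m.predicted_gdtts for m in pool.models)
        best_true.append(pool.best_true)
        selected_true.append(pool.selected().true_gdtts)

    report.mean_ranking_loss = float(np.mean(losses))
    report.mean_pcc = float(np.mean(pccs)) if pccs else float("nan")
    if report.n_undefined_pcc:
        logger.info("%d target(s) had undefined per-target correlation and "
                    "were excluded from mean_pcc", report.n_undefined_pcc)
    report.pooled_pcc = _safe_pcc(np.asarray(all_pred), np.asarray(all_true))
    report.best_vs_selected_pcc = _safe_pcc(np.asarray(best_true),
                                            np.asarray(selected_true))
    loss_arr = np.asarray(losses)
    report.loss_skewness = (
        skewness(loss_arr) if loss_arr.size >= 2 and np.ptp(loss_arr) > 0
        else float("nan")
    )
    for label, s1, s2 in (
        ("all_scores", all_true, all_pred),
        ("best_vs_selected", best_true, selected_true),
    ):
        if np.ptp(np.concatenate([s1, s2])) == 0:
            d, p = 0.0, 1.0
        else:
            d, p = ks_two_sample(s1, s2)
        report.ks_results.append({"label": label, "d_statistic": d, "p_value": p})
    return report


def random_selector_loss(pools: Sequence[TargetPool]) -> float:
    """Expected mean ranking loss of a uniform-random model selector.

    Exact by enumeration: for each pool, the mean over its models of
    (best true score - model true score), averaged over pools.
    """
    if not pools:
        raise MetricError("needs at least one pool")
    per_pool = []
    for pool in pools:
        best = pool.best_true
        per_pool.append(
            float(np.mean([best - m.true_gdtts for m in pool.models]))
        )
    return float(np.mean(per_pool))
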