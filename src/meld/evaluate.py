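"""Detection metrics (TPR, PPV, MCC, FWER) and between-method comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ConfusionCounts", "confusion", "mcc", "fwer", "compare_methods"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(truth: np.ndarray, found: np.ndarray) -> ConfusionCounts:
    """Exact confusion counts between two equal-length boolean masks."""
    truth = np.asarray(truth, dtype=bool).ravel()
    found = np.asarray(found, dtype=bool).ravel()
    if truth.shape != found.shape:
        raise ValueError("mask lengths differ")
    return ConfusionCounts(
        TP=int(np.sum(truth & found)),
        FP=int(np.sum(~truth & found)),
        TN=int(np.sum(~truth & ~found)),
        FN=int(np.sum(truth & ~found)),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 (by convention) when any
    denominator factor is zero, e.g. an all-negative prediction."""
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / np.sqrt(float(denom))


def fwer(any_positive: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """Family-wise error rate over null simulations plus an exact binomial
    test of rate == alpha.

    ``any_positive`` is a boolean vector: did simulation i flag any feature?
    Returns (rate, two-sided binomial p-value).
    """
    any_positive = np.asarray(any_positive, dtype=bool)
    n = len(any_positive)
    if n < 1:
        raise ValueError("need at least one null simulation")
    k = int(any_positive.sum())
    test = stats.binomtest(k, n, alpha)
    return k / n, test.pvalue


def compare_methods(
    metrics_a: np.ndarray,
    metrics_b: np.ndarray,
    n_boot: int = 10000,
    seed: int = 0,
) -> dict:
    """Paired percentile-t bootstrap comparison of per-simulation metrics.

    Resamples simulations with replacement, studentizes the recentred mean
    difference, and reports the two-sided bootstrap p together with
    win/loss/tie counts for method A versus B.  Pairs where either metric
    is undefined (NaN, e.g. PPV with no detections) are dropped.
    """
    a = np.asarray(metrics_a, dtype=np.float64)
    b = np.asarray(metrics_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("metric vectors must be paired")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    d = a - b
    n = len(d)
    if n < 2:
        raise ValueError("need at least two paired simulations")
    mean_d = d.mean()
    se_d = d.std(ddof=1) / np.sqrt(n)
    t_obs = mean_d / se_d if se_d > 0 else 0.0
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    reps = d[idx]
    rep_means = reps.mean(axis=1)
    rep_ses = reps.std(axis=1, ddof=1) / np.sqrt(n)
    ok = rep_ses > 0
    t_star = np.zeros(n_boot)
    t_star[ok] = (rep_means[ok] - mean_d) / rep_ses[ok]
    p = (1.0 + np.sum(np.abs(t_star) >= abs(t_obs))) / (n_boot + 1.0)
    return {
        "t": t_obs,
        "p": p,
        "mean_diff": mean_d,
        "wins": int(np.sum(d > 0)),
        "losses": int(np.sum(d < 0)),
        "ties": int(np.sum(d == 0)),
        "n": n,
    }
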