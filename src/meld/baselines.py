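"""Mass-univariate comparators: paired t-test across subjects, with or
without TFCE, under a max-statistic sign-flip permutation test.

Trial-level signals are averaged per condition within subject; the paired
t statistic of the per-subject condition differences is computed at every
feature.  The permutation null flips the sign of each subject's whole
difference map independently (the exact scheme for a paired design),
optionally enhances the resulting map with TFCE, and keeps the most
extreme |statistic| across features from each permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FeatureSpace, TfceParams
from .inference import empirical_p
from .tfce import ClusterLabeler, tfce_enhance

__all__ = ["PairedTMap", "paired_t_map", "baseline_inference", "run_baseline"]


@dataclass
class PairedTMap:
    diffs: np.ndarray  # n_subjects x n_features condition-mean differences
    t: np.ndarray  # n_features
    enhanced: np.ndarray | None = None
    null_max: np.ndarray | None = None  # n_perms
    p: np.ndarray | None = None
    mask: np.ndarray | None = None
    alpha: float | None = None


def _finite_t(mean_d: np.ndarray, se_d: np.ndarray) -> np.ndarray:
    """t = mean/SE with zero-SD features mapped to (map max + 1), signed.

    A constant nonzero difference has an infinite t; it is represented by a
    value that dominates every finite statistic in the map while keeping
    TFCE integration bounded.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_d > 0, mean_d / np.where(se_d > 0, se_d, 1.0), 0.0)
    degen = (se_d == 0) & (mean_d != 0)
    if degen.any():
        cap = (np.abs(t).max() if np.any(~degen) else 0.0) + 1.0
        t = np.where(degen, np.sign(mean_d) * cap, t)
    return t


def paired_t_map(
    Y: np.ndarray, conditions: np.ndarray, subject_slices: list[slice]
) -> PairedTMap:
    """Within-subject condition-mean differences and the across-subject t map.

    ``conditions`` must have exactly two levels, both present in every
    subject block; the difference is first-level-minus-second in sorted
    level order.
    """
    conditions = np.asarray(conditions).astype(str)
    levels = np.unique(conditions)
    if len(levels) != 2:
        raise ValueError(f"expected exactly two condition levels, got {levels}")
    diffs = []
    for i, sl in enumerate(subject_slices):
        c = conditions[sl]
        block = Y[sl]
        if not (np.any(c == levels[0]) and np.any(c == levels[1])):
            raise ValueError(f"subject block {i} is missing a condition")
        diffs.append(block[c == levels[0]].mean(axis=0) - block[c == levels[1]].mean(axis=0))
    D = np.stack(diffs)
    n = D.shape[0]
    mean_d = D.mean(axis=0)
    se_d = D.std(axis=0, ddof=1) / np.sqrt(n)
    return PairedTMap(diffs=D, t=_finite_t(mean_d, se_d))


def baseline_inference(
    tmap: PairedTMap,
    feature_space: FeatureSpace,
    use_tfce: bool,
    params: TfceParams,
    n_perms: int,
    seed: int,
    alpha: float = 0.05,
) -> PairedTMap:
    """Max-statistic sign-flip permutation inference on a paired t map."""
    D = tmap.diffs
    n_subj = D.shape[0]
    labeler = ClusterLabeler(feature_space) if use_tfce else None

    def statistic(diffs: np.ndarray) -> np.ndarray:
        m = diffs.mean(axis=0)
        se = diffs.std(axis=0, ddof=1) / np.sqrt(n_subj)
        t = _finite_t(m, se)
        if use_tfce:
            t = tfce_enhance(t, params, labeler=labeler)
        return t

    true_stat = statistic(D)
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    null = np.empty(n_perms)
    for i in range(n_perms):
        signs = rng.choice([-1.0, 1.0], size=n_subj)
        null[i] = np.abs(statistic(D * signs[:, None])).max()
    p = empirical_p(true_stat, null)
    return PairedTMap(
        diffs=D,
        t=tmap.t,
        enhanced=true_stat if use_tfce else None,
        null_max=null,
        p=p,
        mask=p < alpha,
        alpha=alpha,
    )


def run_baseline(
    dataset,
    condition_col: str,
    use_tfce: bool,
    params: TfceParams | None = None,
    n_perms: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> PairedTMap:
    """Convenience wrapper: paired t map plus permutation inference on a dataset."""
    params = params or TfceParams()
    tmap = paired_t_map(
        dataset.Y,
        dataset.design[condition_col].to_numpy(),
        dataset.subject_slices(),
    )
    return baseline_inference(
        tmap, dataset.feature_space, use_tfce, params, n_perms, seed, alpha
    )
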