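"""Bootstrap stability selection of feature correlations across subjects.

Each (term, feature) element of the enhanced correlation stack is tested
against zero with an across-subject t statistic whose standard error is the
standard deviation of a subject-level bootstrap (resampling subjects with
replacement).  Elements that fail the test at the selection threshold are
zeroed in every subject's row, producing the stable stack fed to the SVD.
No multiple-comparisons correction is applied here: this is feature
selection, and the selection step is repeated inside every permutation so
final significance fully accounts for it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import CorrelationStack

__all__ = ["StabilityResult", "bootstrap_se", "stability_mask"]


@dataclass
class StabilityResult:
    terms: list[str]
    mean: np.ndarray  # n_terms x n_features, across-subject mean of R_e
    se: np.ndarray  # bootstrap SE of that mean
    t: np.ndarray
    p: np.ndarray
    stable: np.ndarray  # boolean n_terms x n_features
    stack: CorrelationStack  # stage "stable": masked R_e


def bootstrap_se(
    stack: CorrelationStack, n_boot: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Bootstrap SE of the across-subject mean for every (term, feature).

    One subject resample per replicate is shared across all terms and
    features (the resampling unit is the subject).  Implemented through
    resample count vectors, so each replicate mean is a weighted average of
    subject rows.  SD uses the n_boot - 1 denominator.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(rng)
    subjects = np.unique(stack.subjects)
    n_subj = len(subjects)
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    terms = _ordered_terms(stack)
    draws = rng.integers(0, n_subj, size=(n_boot, n_subj))
    counts = np.zeros((n_boot, n_subj))
    for i in range(n_boot):
        counts[i] = np.bincount(draws[i], minlength=n_subj)
    weights = counts / n_subj
    se = np.empty((len(terms), stack.values.shape[1]))
    for t_i, term in enumerate(terms):
        block = stack.term_block(term)  # n_subj x n_features, subject-sorted
        rep_means = weights @ block
        se[t_i] = rep_means.std(axis=0, ddof=1)
        # columns constant across subjects resample to themselves exactly
        constant = block.max(axis=0) == block.min(axis=0)
        se[t_i, constant] = 0.0
    return se


def _ordered_terms(stack: CorrelationStack) -> list[str]:
    seen: dict[str, None] = {}
    for t in stack.terms:
        seen.setdefault(t, None)
    return list(seen)


def stability_mask(
    stack: CorrelationStack,
    se: np.ndarray,
    stability_alpha: float,
    reference: str = "normal",
) -> StabilityResult:
    """Mask unstable elements of the enhanced stack.

    t = mean / SE, two-sided p against the chosen reference.  The default
    treats the bootstrap ratio as a standard-normal deviate (the
    convention for bootstrap-SE saliences in the PLS neuroimaging
    literature); ``reference="t"`` uses Student's t on n_subjects - 1
    degrees of freedom, the more conservative choice at small n.
    Zero-SE elements: p = 0 (retained) when the mean is nonzero (the
    statistic is effectively infinite), p = 1 (dropped) when the mean is
    also zero.  The stable/unstable decision for a (term, feature) element
    applies to all subject rows of that term.
    """
    terms = _ordered_terms(stack)
    n_subj = len(np.unique(stack.subjects))
    mean = np.stack([stack.term_block(t).mean(axis=0) for t in terms])
    if se.shape != mean.shape:
        raise ValueError("SE shape does not match the stack's (terms, features)")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / np.where(se > 0, se, 1.0), 0.0)
        if reference == "normal":
            p = 2.0 * stats.norm.sf(np.abs(t))
        elif reference == "t":
            p = 2.0 * stats.t.sf(np.abs(t), n_subj - 1)
        else:
            raise ValueError(f"unknown reference {reference!r}")
    zero_se = se == 0
    p = np.where(zero_se & (mean != 0), 0.0, p)
    p = np.where(zero_se & (mean == 0), 1.0, p)
    with np.errstate(invalid="ignore"):
        t = np.where(zero_se & (mean != 0), np.inf * np.sign(mean), t)
    stable = p < stability_alpha
    masked = stack.values.copy()
    for t_i, term in enumerate(terms):
        rows = stack.terms == term
        masked[rows] = np.where(stable[t_i], masked[rows], 0.0)
    return StabilityResult(
        terms=terms,
        mean=mean,
        se=se,
        t=t,
        p=p,
        stable=stable,
        stack=stack.with_values(masked, "stable"),
    )
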