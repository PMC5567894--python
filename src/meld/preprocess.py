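"""Within-subject normalization and the stacked predictor-feature correlation matrix.

For each subject, every column of the coded predictors X and of the data Y
is centered to mean 0 and scaled to unit sum of squares; the per-subject
cross product X_norm' Y_norm is then exactly the matrix of Pearson
correlations between each predictor and each feature.  Stacking subjects
gives R with (n_subjects * n_terms) rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CorrelationStack", "normalize_within_subject", "correlate", "fisher_z"]

_Z_CLAMP = 1.0 - 1e-12


@dataclass
class CorrelationStack:
    """Per-subject, per-term feature maps, stacked subject-major, term-minor.

    ``stage`` tags the processing state: "raw" (correlations in [-1, 1]),
    "z" (Fisher-transformed), "enhanced" (after TFCE) or "stable"
    (after stability masking).
    """

    values: np.ndarray  # (n_subjects * n_terms) x n_features
    subjects: np.ndarray  # subject label per row
    terms: np.ndarray  # term name per row
    stage: str = "raw"

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def term_block(self, term: str) -> np.ndarray:
        """Rows for one term across subjects: n_subjects x n_features."""
        return self.values[self.terms == term]

    def with_values(self, values: np.ndarray, stage: str) -> "CorrelationStack":
        return CorrelationStack(values, self.subjects, self.terms, stage)


def normalize_within_subject(
    M: np.ndarray, subject_slices: list[slice]
) -> tuple[np.ndarray, np.ndarray]:
    """Center and unit-SSQ-scale each column within each subject block.

    Returns (normalized matrix, degenerate flags) where the flags mark
    (block, column) combinations with zero variance; those columns are set
    to all-zeros so resampled or permuted data never raises.
    """
    M = np.asarray(M, dtype=np.float64)
    out = np.empty_like(M)
    degenerate = np.zeros((len(subject_slices), M.shape[1]), dtype=bool)
    for b, sl in enumerate(subject_slices):
        block = M[sl]
        if block.shape[0] < 2:
            raise ValueError(f"subject block {b} has fewer than 2 trials")
        centered = block - block.mean(axis=0)
        ssq = np.einsum("ij,ij->j", centered, centered)
        zero = ssq <= 0
        degenerate[b] = zero
        scale = np.sqrt(np.where(zero, 1.0, ssq))
        out[sl] = np.where(zero, 0.0, centered / scale)
    return out, degenerate


def correlate(
    X_norm: np.ndarray,
    Y_norm: np.ndarray,
    subject_slices: list[slice],
    subjects: np.ndarray,
    terms: list[str],
) -> CorrelationStack:
    """Per-subject correlations R_subject = X_norm' Y_norm, stacked.

    Rows are ordered subject-major, term-minor: all terms for subject 1,
    then all terms for subject 2, and so on.
    """
    if X_norm.shape[0] != Y_norm.shape[0]:
        raise ValueError("X and Y row counts differ")
    n_terms = X_norm.shape[1]
    blocks = []
    for sl in subject_slices:
        blocks.append(X_norm[sl].T @ Y_norm[sl])
    values = np.concatenate(blocks, axis=0)
    # numerical guard: normalized cross products are correlations
    np.clip(values, -1.0, 1.0, out=values)
    row_subjects = np.repeat(np.asarray(subjects), n_terms)
    row_terms = np.tile(np.asarray(terms, dtype=object), len(subject_slices))
    return CorrelationStack(values, row_subjects, row_terms, stage="raw")


def fisher_z(stack: CorrelationStack) -> CorrelationStack:
    """Fisher z-transform (atanh) of a raw correlation stack.

    |r| is clamped just below 1 so perfect correlations map to a large
    finite z rather than infinity.
    """
    if stack.stage != "raw":
        raise ValueError("fisher_z expects a raw correlation stack")
    z = np.arctanh(np.clip(stack.values, -_Z_CLAMP, _Z_CLAMP))
    return stack.with_values(z, "z")
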