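"""Compact SVD of the stable correlation stack, projection and back-projection.

The compact SVD of the stable stack R_s (rank k <= n_subjects * n_terms
regardless of the number of features) supplies the right singular vectors
V' used to reduce the dependent data: Y_w = Y V'.  After per-component
model fits produce t-values T_s, the map is returned to feature space as a
variance-weighted combination of component maps,

    T_f[term, j] = sum_c T_s[c, term] * S_norm[c] * V'[c, j],

where S_norm is S divided by the sum of singular values of the *unpermuted*
data, so permutation maps are scaled relative to the variance the true data
explained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SvdComponents", "compact_svd", "project", "backproject"]


@dataclass
class SvdComponents:
    U: np.ndarray  # rows x k
    S: np.ndarray  # k, descending, > 0
    Vt: np.ndarray  # k x n_features
    sum_S: float  # sum of S (of the unpermuted data when reused)

    @property
    def k(self) -> int:
        return len(self.S)

    def s_norm(self, sum_S: float | None = None) -> np.ndarray:
        """S / sum(S); pass the true-data sum for permutation stacks."""
        denom = self.sum_S if sum_S is None else sum_S
        return self.S / denom


def compact_svd(R_s: np.ndarray) -> SvdComponents | None:
    """Compact SVD with a tolerance-based rank cut.

    Singular values <= max(m, n) * eps * S_1 are dropped.  Returns None for
    an all-zero (degenerate) input; callers treat that as "no stable
    features survived" rather than as an error.  Component signs are fixed
    by making the largest-magnitude entry of each right singular vector
    positive, for deterministic output across platforms.
    """
    R_s = np.asarray(R_s, dtype=np.float64)
    if not np.any(R_s):
        return None
    U, S, Vt = np.linalg.svd(R_s, full_matrices=False)
    tol = max(R_s.shape) * np.finfo(np.float64).eps * S[0]
    k = int(np.sum(S > tol))
    if k == 0:
        return None
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    flip = np.sign(Vt[np.arange(k), np.argmax(np.abs(Vt), axis=1)])
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    return SvdComponents(U=U, S=S, Vt=Vt, sum_S=float(S.sum()))


def project(Y: np.ndarray, Vt: np.ndarray) -> np.ndarray:
    """Component scores Y_w = Y V' (computed on the unnormalized data)."""
    Y = np.asarray(Y, dtype=np.float64)
    if Y.shape[1] != Vt.shape[1]:
        raise ValueError(
            f"Y has {Y.shape[1]} features but Vt has {Vt.shape[1]}"
        )
    return Y @ Vt.T


def backproject(T_s: np.ndarray, s_norm: np.ndarray, Vt: np.ndarray) -> np.ndarray:
    """Variance-weighted return of component t-values to feature space.

    T_s is k x n_terms; the result is n_terms x n_features.
    """
    T_s = np.atleast_2d(np.asarray(T_s, dtype=np.float64))
    s_norm = np.asarray(s_norm, dtype=np.float64)
    if len(s_norm) != T_s.shape[0] or len(s_norm) != Vt.shape[0]:
        raise ValueError("component counts of T_s, s_norm and Vt differ")
    return (T_s * s_norm[:, None]).T @ Vt
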