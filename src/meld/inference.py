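"""Permutation engine and full-pipeline orchestration.

The complete chain (normalize -> correlate -> Fisher z -> TFCE ->
stability selection -> compact SVD -> projection -> per-component mixed
models -> back-projection) is run once on the true data and then re-run,
feature selection included, on every permutation.  A permutation shuffles
the dependent data relative to the independent variables within each
subject: the fixed-covariate rows are permuted within subject blocks
while Y stays aligned with its subject and item labels.  Subject- and
item-level random structure is therefore intact under the null (only the
pairing of condition/covariate with trial is broken), which is what makes
the condition labels exchangeable when the fixed effect is absent.

Family-wise error control is by max statistic: each permutation
contributes, per term, the largest |t| across features; a second stage
takes the minimum p across terms and features per permutation to correct
across terms as well.  Empirical p-values use the add-one estimator
(p >= 1/(n_perms+1)) and ties count against the hypothesis.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from joblib import Parallel, delayed

from .core import MeldConfig, MeldDataset, MeldResult
from .formula import ModelFormula, code_design, parse_formula
from .lmm import LmerEngine, fit_components
from .preprocess import correlate, fisher_z, normalize_within_subject
from .reduction import backproject, compact_svd, project
from .stability import bootstrap_se, stability_mask
from .tfce import ClusterLabeler, tfce_enhance

__all__ = ["permute_within_subject", "empirical_p", "run_meld"]

logger = logging.getLogger("meld")


def permute_within_subject(
    subject_slices: list[slice], n_trials: int, seed: int, perm_index: int
) -> np.ndarray:
    """Trial permutation restricted to subject blocks.

    The returned index array is applied to the fixed-covariate rows, which
    shuffles the dependent data relative to the independent variables while
    Y keeps its subject and item alignment.  Deterministic given
    (seed, perm_index); perm_index 0 is reserved for the unpermuted data by
    convention of the caller.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, perm_index]))
    perm = np.arange(n_trials)
    for sl in subject_slices:
        block = perm[sl]
        rng.shuffle(block)
        perm[sl] = block
    return perm


def empirical_p(true_stats: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Add-one empirical p of |stat| against a 1-D max-statistic null."""
    true_stats = np.abs(np.asarray(true_stats, dtype=np.float64))
    null = np.asarray(null, dtype=np.float64)
    n = len(null)
    counts = (null[:, None] >= true_stats[None, :]).sum(axis=0)
    return (1.0 + counts) / (n + 1.0)


def _boot_rng(seed: int, perm_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, perm_index, 1]))


class _Pipeline:
    """Precomputed state shared by the true pass and every permutation."""

    def __init__(self, dataset: MeldDataset, formula: ModelFormula, config: MeldConfig):
        self.dataset = dataset
        self.config = config
        self.formula = formula
        coded = code_design(formula, dataset.design)
        self.term_names = coded.term_names
        self.slices = dataset.subject_slices()
        self.X_norm, x_degen = normalize_within_subject(coded.matrix, self.slices)
        if x_degen.any():
            raise ValueError("a predictor is constant within some subject block")
        self.Y_norm, y_degen = normalize_within_subject(dataset.Y, self.slices)
        if y_degen.any():
            logger.info(
                "%d constant feature/subject combinations set to zero correlation",
                int(y_degen.sum()),
            )
        self.labeler = ClusterLabeler(dataset.feature_space)
        self.engine = LmerEngine(formula, dataset.design)

    def single_pass(
        self,
        perm: np.ndarray | None,
        boot_rng: np.random.Generator,
        sum_S_true: float | None,
    ):
        """Run steps 1-6 on (optionally permuted) data.

        ``perm`` permutes the covariate rows within subject; Y is left in
        place.  Returns (T_f, sum_S, statuses) or None when no stable
        feature correlations survive (a degenerate pass).
        """
        ds, cfg = self.dataset, self.config
        if perm is None:
            X_norm, design, engine = self.X_norm, ds.design, self.engine
        else:
            X_norm = self.X_norm[perm]
            design = ds.design.copy()
            for col in self.formula.fixed:
                design[col] = design[col].to_numpy()[perm]
            engine = LmerEngine(self.formula, design)
        stack = correlate(
            X_norm, self.Y_norm, self.slices, ds.subjects, self.term_names
        )
        stack = fisher_z(stack)
        if cfg.tfce_enabled:
            enhanced = np.stack(
                [
                    tfce_enhance(row, cfg.tfce, labeler=self.labeler)
                    for row in stack.values
                ]
            )
            stack = stack.with_values(enhanced, "enhanced")
        se = bootstrap_se(stack, cfg.n_bootstraps, boot_rng)
        stab = stability_mask(
            stack, se, cfg.stability_alpha, reference=cfg.stability_reference
        )
        svd = compact_svd(stab.stack.values)
        if svd is None:
            return None
        Y_w = project(ds.Y, svd.Vt)
        comps = fit_components(Y_w, design, self.formula, engine=engine)
        s_norm = svd.s_norm(sum_S_true)
        T_f = backproject(comps.T_s, s_norm, svd.Vt)
        return T_f, svd.sum_S, comps.statuses


def _perm_worker(pipeline: _Pipeline, perm_index: int, sum_S_true: float):
    ds, cfg = pipeline.dataset, pipeline.config
    perm = permute_within_subject(
        pipeline.slices, ds.n_trials, cfg.seed, perm_index
    )
    out = pipeline.single_pass(perm, _boot_rng(cfg.seed, perm_index), sum_S_true)
    n_terms = len(pipeline.term_names)
    if out is None:
        return np.zeros(n_terms), True
    T_f, _, _ = out
    return np.abs(T_f).max(axis=1), False


def run_meld(
    dataset: MeldDataset,
    formula: ModelFormula | str,
    config: MeldConfig | None = None,
) -> MeldResult:
    """Full MELD analysis of a dataset: true-data maps plus permutation inference."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    config = config or MeldConfig()
    pipeline = _Pipeline(dataset, formula, config)
    n_terms = len(pipeline.term_names)
    n_feat = dataset.n_features
    n_perms = config.n_permutations

    true_out = pipeline.single_pass(None, _boot_rng(config.seed, 0), None)
    if true_out is None:
        warnings.warn(
            "no stable feature correlations in the true data; empty result",
            stacklevel=2,
        )
        ones = np.ones((n_terms, n_feat))
        return MeldResult(
            terms=pipeline.term_names,
            t_map=np.zeros((n_terms, n_feat)),
            perm_max_t=np.zeros((n_perms, n_terms)),
            p_term=ones,
            min_p_null=np.ones(n_perms),
            p=ones.copy(),
            mask=np.zeros((n_terms, n_feat), dtype=bool),
            feature_shape=dataset.feature_space.shape,
            alpha=config.alpha,
            seed=config.seed,
            n_permutations=n_perms,
            degenerate_perms=np.zeros(n_perms, dtype=bool),
            degenerate_true=True,
        )
    T_f_true, sum_S_true, statuses = true_out
    n_fallback = sum(s != "converged" for s in statuses)
    if n_fallback:
        logger.info("%d component fits used a fallback model", n_fallback)

    if config.n_jobs == 1:
        results = [
            _perm_worker(pipeline, i, sum_S_true) for i in range(1, n_perms + 1)
        ]
    else:
        results = Parallel(n_jobs=config.n_jobs)(
            delayed(_perm_worker)(pipeline, i, sum_S_true)
            for i in range(1, n_perms + 1)
        )
    perm_max_t = np.stack([r[0] for r in results])  # n_perms x n_terms
    degenerate = np.array([r[1] for r in results])
    if degenerate.any():
        logger.info("%d degenerate permutations", int(degenerate.sum()))

    # term-level empirical p per feature from the per-term max-|t| null
    p_term = np.stack(
        [empirical_p(T_f_true[t], perm_max_t[:, t]) for t in range(n_terms)]
    )
    # each permutation's smallest attainable p over terms and features equals
    # the rank-based p of its own per-term maximum within the null
    counts = (perm_max_t[:, None, :] >= perm_max_t[None, :, :]).sum(axis=0)
    p_of_null = (counts + 0.0) / (n_perms + 1.0)  # self-comparison supplies the +1
    min_p_null = p_of_null.min(axis=1)
    min_p_null[degenerate] = 1.0
    # final p: how often a permutation attains a p at least as small
    final_counts = (min_p_null[:, None, None] <= p_term[None, :, :]).sum(axis=0)
    p_final = (1.0 + final_counts) / (n_perms + 1.0)
    mask = p_final < config.alpha

    return MeldResult(
        terms=pipeline.term_names,
        t_map=T_f_true,
        perm_max_t=perm_max_t,
        p_term=p_term,
        min_p_null=min_p_null,
        p=p_final,
        mask=mask,
        feature_shape=dataset.feature_space.shape,
        alpha=config.alpha,
        seed=config.seed,
        n_permutations=n_perms,
        degenerate_perms=degenerate,
        degenerate_true=False,
    )
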