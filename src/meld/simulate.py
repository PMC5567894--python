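"""Synthetic trial-level datasets with known signal geometry.

Each simulated experiment embeds a scalar trial signal, generated from a
crossed-random-effects model, into a binary spatial pattern on a 2-D noise
field:

    s_ij = (slope + u_i^slope) * x_ij + u_i^int + w_j
    Y[trial ij] = s_ij * pattern + noise,  noise ~ N(0, 1) iid per feature

where x_ij is the +/-0.5 condition code (A -> +0.5, B -> -0.5) of item j
for subject i, u_i are subject deviations (SD 0.1 on intercept and slope)
and w_j is a standard-normal item intercept shared across subjects, so the
item factor is crossed with subject.  Every subject sees every item once;
the balanced condition assignment of items is randomized per subject (as
in a counterbalanced recognition-memory design, where a given word is
"old" for some subjects and "new" for others), which is what makes the
item intercept estimable rather than confounded with condition.
Defaults: 9 subjects, 50 trials each (25 per condition), a 100 x 100
field with exactly 100 signal features.  The noise is deliberately
unsmoothed so the true-positive set is unambiguous.

Signal patterns are deterministic.  "central" is one 10 x 10 block;
"split" four 5 x 5 blocks; "dispersed" twenty-five 2 x 2 blocks;
"centrality:C" places C percent of the 100 signal features in one central
near-square cluster and the rest in small satellite blocks on a regular
grid, with at least two empty cells between clusters so nothing merges
under orthogonal adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FeatureSpace, MeldDataset
from .tfce import label_clusters

__all__ = ["SignalPattern", "SimulationSpec", "make_pattern", "simulate_dataset", "run_experiment"]


@dataclass
class SignalPattern:
    mask: np.ndarray  # boolean, field shape
    descriptor: str
    cluster_sizes: list[int]

    @property
    def n_signal(self) -> int:
        return int(self.mask.sum())


def _near_square_block(c: int) -> tuple[int, int, int]:
    """(height, width, n_cells) of a near-square row-major block of c cells."""
    h = int(np.floor(np.sqrt(c)))
    w = int(np.ceil(c / h))
    return h, w, c


def _place_block(mask: np.ndarray, r0: int, c0: int, h: int, w: int, n: int):
    """Fill the first n cells (row-major) of an h x w block at (r0, c0)."""
    filled = 0
    for i in range(h):
        for j in range(w):
            if filled == n:
                return
            mask[r0 + i, c0 + j] = True
            filled += 1


def make_pattern(
    descriptor: str, shape: tuple[int, int] = (100, 100), n_signal: int = 100
) -> SignalPattern:
    """Build a deterministic signal pattern from its descriptor string."""
    rows, cols = shape
    mask = np.zeros(shape, dtype=bool)
    if descriptor == "central":
        _build_centrality(mask, n_signal, n_signal)
    elif descriptor == "dispersed":
        _build_centrality(mask, 4, n_signal)
    elif descriptor == "split":
        side = int(np.sqrt(n_signal // 4))
        if 4 * side * side != n_signal:
            raise ValueError("split pattern needs n_signal divisible into 4 squares")
        q_r, q_c = rows // 4, cols // 4
        for r0 in (q_r, 3 * q_r):
            for c0 in (q_c, 3 * q_c):
                _place_block(mask, r0 - side // 2, c0 - side // 2, side, side, side * side)
    elif descriptor.startswith("centrality:") or descriptor.startswith("centrality("):
        num = descriptor.split(":")[-1].rstrip(")").split("(")[-1].rstrip("%")
        pct = float(num)
        c = int(round(pct / 100.0 * n_signal))
        if not (4 <= c <= n_signal):
            raise ValueError(f"centrality {pct}% not realizable with {n_signal} features")
        _build_centrality(mask, c, n_signal)
    else:
        raise ValueError(f"unknown pattern descriptor {descriptor!r}")
    if int(mask.sum()) != n_signal:
        raise ValueError(
            f"could not realize pattern {descriptor!r} with {n_signal} features on {shape}"
        )
    labels, n = label_clusters(mask.ravel(), FeatureSpace(shape))
    sizes = sorted(
        np.unique(labels[labels > 0], return_counts=True)[1].tolist(), reverse=True
    )
    return SignalPattern(mask=mask, descriptor=descriptor, cluster_sizes=sizes)


def _build_centrality(mask: np.ndarray, c: int, n_signal: int) -> None:
    """One central c-cell near-square cluster plus 2x2 satellites."""
    rows, cols = mask.shape
    h, w, _ = _near_square_block(c)
    r0, c0 = (rows - h) // 2, (cols - w) // 2
    _place_block(mask, r0, c0, h, w, c)
    remaining = n_signal - c
    if remaining == 0:
        return
    # satellite anchors on a regular grid, scanned row-major, skipping any
    # position within 2 cells of the central block or the field edge
    spacing = 8
    anchors = []
    for ar in range(2, rows - 3, spacing):
        for ac in range(2, cols - 3, spacing):
            if ar + 1 >= r0 - 2 and ar <= r0 + h + 1 and ac + 1 >= c0 - 2 and ac <= c0 + w + 1:
                continue
            anchors.append((ar, ac))
    need_blocks = (remaining + 3) // 4
    if need_blocks > len(anchors):
        raise ValueError("field too small for the requested satellite blocks")
    for b in range(need_blocks):
        ar, ac = anchors[b]
        n = min(4, remaining)
        if n >= 3:
            _place_block(mask, ar, ac, 2, 2, n)
        else:
            _place_block(mask, ar, ac, 1, n, n)
        remaining -= n


@dataclass
class SimulationSpec:
    """Generative settings for one simulated experiment."""

    slope: float = 0.5
    pattern: SignalPattern = field(default_factory=lambda: make_pattern("central"))
    n_subjects: int = 9
    n_trials: int = 50  # per subject, split evenly across the two conditions
    sigma_item: float = 1.0
    sigma_subj_intercept: float = 0.1
    sigma_subj_slope: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.slope < 0:
            raise ValueError("slope must be >= 0")
        if self.n_trials % 2:
            raise ValueError("n_trials must be even (balanced conditions)")


def simulate_dataset(spec: SimulationSpec) -> tuple[MeldDataset, np.ndarray]:
    """Generate one dataset; returns (dataset, flat truth mask)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed]))
    n_items = spec.n_trials
    half = n_items // 2
    base_codes = np.array([0.5] * half + [-0.5] * half)
    item_ids = np.array([f"i{j:03d}" for j in range(n_items)])
    w = rng.normal(0.0, spec.sigma_item, size=n_items)  # item intercepts, shared

    pattern_flat = spec.pattern.mask.ravel().astype(np.float64)
    n_feat = pattern_flat.size
    rows_design = []
    Y = np.empty((spec.n_subjects * n_items, n_feat))
    u_int = rng.normal(0.0, spec.sigma_subj_intercept, size=spec.n_subjects)
    u_slope = rng.normal(0.0, spec.sigma_subj_slope, size=spec.n_subjects)
    for i in range(spec.n_subjects):
        x = rng.permutation(base_codes)  # per-subject counterbalancing
        s = (spec.slope + u_slope[i]) * x + u_int[i] + w
        noise = rng.standard_normal((n_items, n_feat))
        Y[i * n_items : (i + 1) * n_items] = s[:, None] * pattern_flat[None, :] + noise
        for j in range(n_items):
            rows_design.append((f"s{i:02d}", item_ids[j], "A" if x[j] > 0 else "B"))
    design = pd.DataFrame(rows_design, columns=["subject", "item", "beh"])
    dataset = MeldDataset(design, Y, FeatureSpace(spec.pattern.mask.shape))
    return dataset, spec.pattern.mask.ravel()


def run_experiment(
    slopes,
    patterns,
    n_sims: int,
    methods=("meld", "t_tfce", "t"),
    config=None,
    n_perms_baseline: int = 500,
    seed: int = 0,
    shape: tuple[int, int] = (100, 100),
    n_signal: int = 100,
) -> pd.DataFrame:
    """Grid runner: every method on every simulated dataset; one row per
    (simulation, method) with confusion counts and metrics."""
    from .baselines import run_baseline
    from .core import MeldConfig
    from .evaluate import confusion, mcc
    from .inference import run_meld

    config = config or MeldConfig()
    records = []
    sim_id = 0
    for pattern_desc in patterns:
        pattern = make_pattern(pattern_desc, shape=shape, n_signal=n_signal)
        for slope in slopes:
            for rep in range(n_sims):
                sim_seed = int(
                    np.random.default_rng(
                        np.random.SeedSequence([seed, sim_id])
                    ).integers(2**31)
                )
                spec = SimulationSpec(slope=slope, pattern=pattern, seed=sim_seed)
                dataset, truth = simulate_dataset(spec)
                masks = {}
                if "meld" in methods:
                    cfg = MeldConfig(
                        n_permutations=config.n_permutations,
                        n_bootstraps=config.n_bootstraps,
                        stability_alpha=config.stability_alpha,
                        alpha=config.alpha,
                        seed=sim_seed,
                        tfce=config.tfce,
                        tfce_enabled=config.tfce_enabled,
                        n_jobs=config.n_jobs,
                    )
                    res = run_meld(dataset, "signal~beh+(beh|subject)+(1|item)", cfg)
                    masks["meld"] = res.mask.any(axis=0)
                if "t_tfce" in methods:
                    masks["t_tfce"] = run_baseline(
                        dataset, "beh", True, config.tfce,
                        n_perms_baseline, sim_seed, config.alpha,
                    ).mask
                if "t" in methods:
                    masks["t"] = run_baseline(
                        dataset, "beh", False, config.tfce,
                        n_perms_baseline, sim_seed, config.alpha,
                    ).mask
                for method, found in masks.items():
                    c = confusion(truth, found)
                    tpr = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else np.nan
                    ppv = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else np.nan
                    records.append(
                        dict(
                            sim_id=sim_id,
                            method=method,
                            slope=slope,
                            pattern=pattern_desc,
                            TP=c.TP,
                            FP=c.FP,
                            TN=c.TN,
                            FN=c.FN,
                            TPR=tpr,
                            PPV=ppv,
                            MCC=mcc(c),
                            any_positive=bool(found.any()),
                        )
                    )
                sim_id += 1
    return pd.DataFrame.from_records(records)
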