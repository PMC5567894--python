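"""Walk the pipeline stage by stage on a demo-scale dataset.

Three subjects complete 10 trials each; every trial has a two-level
condition and a continuous covariate, and the recorded response is a
3 x 5 feature grid (think: 3 channels x 5 timepoints).  This mirrors the
smallest configuration the method is usually explained with, so every
matrix is small enough to print.
"""

import numpy as np
import pandas as pd

import meld

rng = np.random.default_rng(42)
rows = []
for s in range(3):
    for t in range(10):
        rows.append((f"s{s}", f"i{t:02d}", "A" if t % 2 else "B", rng.normal()))
design = pd.DataFrame(rows, columns=["subject", "item", "beh", "cont"])
Y = rng.standard_normal((30, 15))
dataset = meld.MeldDataset(design, Y, meld.FeatureSpace((3, 5)))

formula = meld.parse_formula("neural~beh+cont+(beh+cont|subject)+(1|item)")
coded = meld.code_design(formula, dataset.design)
print("fixed terms:", coded.term_names, "| coding: A ->",
      coded.coding["beh"]["map"]["A"])

slices = dataset.subject_slices()
X_norm, _ = meld.normalize_within_subject(coded.matrix, slices)
Y_norm, _ = meld.normalize_within_subject(dataset.Y, slices)
R = meld.correlate(X_norm, Y_norm, slices, dataset.subjects, coded.term_names)
print("R:", R.values.shape, "rows = 2 terms x 3 subjects; entries are "
      "Pearson correlations in [-1, 1]")

z = meld.fisher_z(R)
enhanced = np.stack([
    meld.tfce_enhance(row, meld.TfceParams(), dataset.feature_space)
    for row in z.values
])
stack = z.with_values(enhanced, "enhanced")
se = meld.bootstrap_se(stack, n_boot=500, rng=0)
stab = meld.stability_mask(stack, se, stability_alpha=0.05)
print("stable elements:", int(stab.stable.sum()), "of", stab.stable.size,
      "(pure noise here, so roughly the selection rate)")

svd = meld.compact_svd(stab.stack.values)
if svd is None:
    print("no stable correlations survived -> a real run would report an "
          "empty significance mask")
else:
    Y_w = meld.project(dataset.Y, svd.Vt)
    print("compact SVD kept", svd.k, "components (at most 6 here); "
          "Y_w:", Y_w.shape)
    comps = meld.fit_components(Y_w, dataset.design, formula)
    T_f = meld.backproject(comps.T_s, svd.s_norm(), svd.Vt)
    print("T_s:", comps.T_s.shape, "-> back-projected T_f:", T_f.shape)
    print("max |T_f|: %.3f (noise data: small t-values expected)"
          % np.abs(T_f).max())
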