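"""Compare the mixed-effects pipeline against the t-test baselines.

Runs all three methods (MELD, paired t with TFCE, plain paired t) on the
same small simulated datasets and tabulates TPR / PPV / MCC per method,
then tests whether MELD's MCC differs from t+TFCE's with a paired
bootstrap.  Dispersed signal is where the multivariate reduction helps
most and cluster enhancement helps least.
"""

import meld

table = meld.run_experiment(
    slopes=[0.9],
    patterns=["centrality:25"],  # 1/4 of the signal in the main cluster
    n_sims=3,
    methods=("meld", "t_tfce", "t"),
    config=meld.MeldConfig(n_permutations=60, n_bootstraps=300, seed=1),
    n_perms_baseline=200,
    seed=1,
    shape=(40, 40),
    n_signal=36,
)
print(table.groupby("method")[["TPR", "PPV", "MCC"]].mean().round(3))

wide = table.pivot(index="sim_id", columns="method", values="MCC")
cmp = meld.compare_methods(wide["meld"], wide["t_tfce"], n_boot=2000, seed=0)
print(f"\nMELD vs t+TFCE on MCC: mean diff {cmp['mean_diff']:+.3f}, "
      f"bootstrap t {cmp['t']:.2f}, p {cmp['p']:.3f} "
      f"(wins {cmp['wins']}/losses {cmp['losses']}/ties {cmp['ties']})")
print("positive diff = the mixed-effects pipeline agreed better with the "
      "true signal mask")
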