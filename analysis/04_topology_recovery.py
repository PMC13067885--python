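"""Recovery of injected network-topology differences.

Replicates cohorts whose eyes-open recordings follow each participant's
small-world template and whose eyes-closed recordings use its full
degree-preserving randomization, then asks how often the cohort-mean
small-worldness AUC is ordered open > closed.
"""

from pathlib import Path

import pandas as pd

from swaynet import experiments

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)

rate = experiments.sigma_auc_ordering_rate(n_reps=20, n_per_group=17,
                                           n_rand=100, master_seed=41000)
pd.DataFrame([{"experiment": "sigma_auc_ordering", "replicates": 20,
               "correct_ordering_rate": rate}]).to_csv(
    RESULTS / "topology_recovery.csv", index=False)
print(f"sigma-AUC ordered correctly (open > closed) in {rate:.0%} "
      "of 20 replicate cohorts")
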