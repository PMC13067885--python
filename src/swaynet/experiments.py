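"""Monte-Carlo validation experiments on synthetic cohorts.

Three cohort-level checks that the generator and the analysis stack jointly
behave as designed:

* **power** — a diffusion multiplier injected into one group-by-condition
  cell must surface as a significant sway-area interaction in most
  replicate cohorts;
* **type-I calibration** — with no injected effects the interaction test
  must reject at its nominal rate;
* **topology recovery** — cohorts whose eyes-open recordings follow each
  participant's small-world template and whose eyes-closed recordings use
  its full degree-preserving randomization must show the cohort-mean
  small-worldness AUC ordered open > closed.

Replicates derive their seeds as ``master_seed + replicate``; all results
are deterministic for a fixed master seed.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .group_stats import mixed_anova_2x2
from .pipeline import RunConfig, run_pipeline
from .posturography import aggregate_trials, cop_metrics
from .synthetic_cohort import (CellEffect, CohortDesign, CopGenParams,
                               generate_cohort, null_cell_effects)

__all__ = [
    "cop_area_long",
    "area_interaction_power",
    "interaction_type1_rate",
    "sigma_auc_ordering_rate",
]

#: short trials used where only the fNIRS arm matters
_FAST_COP = CopGenParams(duration=5.0, sampling_rate=200.0)


def cop_area_long(design: CohortDesign) -> pd.DataFrame:
    """Per-participant trial-averaged sway area in long format."""
    ds = generate_cohort(design)
    group_of = dict(zip(ds.participants["participant"],
                        ds.participants["group"]))
    rows = []
    for (pid, cond), trials in ds.cop_trials.items():
        agg = aggregate_trials([cop_metrics(t) for t in trials])
        rows.append({"participant": pid, "group": group_of[pid],
                     "condition": cond, "value": agg.AREA})
    return pd.DataFrame(rows)


def _area_design(n_per_group: int, seed: int, mci_closed_diffusion: float
                 ) -> CohortDesign:
    effects = null_cell_effects()
    effects[("MCI", "closed")] = CellEffect(mci_closed_diffusion, 0.0)
    return CohortDesign(n_per_group=n_per_group, with_fnirs=False,
                        cell_effects=effects, master_seed=seed)


def area_interaction_power(n_reps: int = 20, n_per_group: int = 17,
                           diffusion: float = 1.5, alpha: float = 0.05,
                           master_seed: int = 1000) -> float:
    """Fraction of replicate cohorts whose AREA interaction is significant
    after injecting ``diffusion`` into the MCI eyes-closed cell."""
    hits = 0
    for rep in range(n_reps):
        table = cop_area_long(_area_design(n_per_group, master_seed + rep,
                                           diffusion))
        hits += mixed_anova_2x2(table).loc["interaction", "p"] < alpha
    return hits / n_reps


def interaction_type1_rate(n_reps: int = 200, n_per_group: int = 17,
                           alpha: float = 0.05,
                           master_seed: int = 20000) -> float:
    """Null rejection rate of the AREA interaction over replicate cohorts
    with no injected effects."""
    hits = 0
    for rep in range(n_reps):
        table = cop_area_long(_area_design(n_per_group, master_seed + rep, 1.0))
        hits += mixed_anova_2x2(table).loc["interaction", "p"] < alpha
    return hits / n_reps


def sigma_auc_ordering_rate(n_reps: int = 20, n_per_group: int = 17,
                            n_rand: int = 100,
                            master_seed: int = 41000) -> float:
    """Fraction of replicate cohorts whose mean small-worldness AUC is
    larger for the small-world (open) than the randomized (closed) arm."""
    effects = {(g, c): CellEffect(1.0, 0.0 if c == "open" else 1.0)
               for g in ("MCI", "CN") for c in ("open", "closed")}
    wins = 0
    for rep in range(n_reps):
        design = CohortDesign(n_per_group=n_per_group, cell_effects=effects,
                              cop_params=_FAST_COP,
                              master_seed=master_seed + rep)
        config = RunConfig(design=design, n_rand=n_rand,
                           seed=master_seed + rep)
        bundle = run_pipeline(config)
        means = bundle.network_table.groupby("condition")["sigma"].mean()
        wins += means["open"] > means["closed"]
    return wins / n_reps
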