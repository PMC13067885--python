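"""Generate a synthetic study cohort and write it to disk.

Demonstrates the on-disk cohort layout (per-trial COP CSVs, long-format
two-wavelength intensity CSVs, participant table, manifest) on a small
cohort — full-length fNIRS recordings are ~25 MB of CSV each, so the
full-scale analyses (02-04) generate their cohorts in memory instead.
Raw files land in scratch/cohort; the participant table is copied to
results/.
"""

import dataclasses
from pathlib import Path

from swaynet.synthetic_cohort import CohortDesign, generate_cohort, write_cohort

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

design = CohortDesign(n_per_group=3, fnirs_duration_s=60.0, master_seed=7)
dataset = generate_cohort(design)
write_cohort(dataset, SCRATCH)
RESULTS.mkdir(exist_ok=True)
dataset.participants.to_csv(RESULTS / "participants.csv", index=False)

print(f"cohort: {len(dataset.participants)} participants, "
      f"{dataset.n_trials} COP trials, "
      f"{sum(v is not None for v in dataset.fnirs.values())} fNIRS recordings")
print(f"raw data in {SCRATCH}")
print(f"participant table in {RESULTS / 'participants.csv'}")
print("full-scale design used by the later steps: "
      f"{dataclasses.replace(design, n_per_group=17, fnirs_duration_s=600.0)}")
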