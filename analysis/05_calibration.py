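#!/usr/bin/env python
"""Statistical calibration on effect-free data.

Finding to check here: with no injected effects, the cluster test's
family-wise false-positive rate and the behavioral paired t-test's
rejection rate both sit near the nominal 5 %.
"""

import json
from pathlib import Path

from mupulse.behavior import detection_stats
from mupulse.behavior_sim import simulate_behavior_session
from mupulse.params import SubjectParams
from mupulse.pipeline import run_null_experiment

OUT = Path("results/calibration")
OUT.mkdir(parents=True, exist_ok=True)

n_eeg = 100
eeg_hits = sum(run_null_experiment(n_subjects=20, seed=s, n_iter=300)
               for s in range(n_eeg))
print(f"cluster-test type-I rate: {eeg_hits / n_eeg:.3f} "
      f"({eeg_hits}/{n_eeg} null experiments with a significant cluster)")

n_cohorts = 200
beh_hits = 0
for c in range(n_cohorts):
    sessions = [simulate_behavior_session("A2", SubjectParams(), 3,
                                          seed=c * 29 + s, subject_id=s)
                for s in range(21)]
    beh_hits += detection_stats(sessions).p < 0.05
print(f"behavioral null rejection rate: {beh_hits / n_cohorts:.3f} "
      f"({beh_hits}/{n_cohorts} cohorts)")

(OUT / "calibration.json").write_text(json.dumps({
    "cluster_type_i_rate": eeg_hits / n_eeg,
    "n_eeg_experiments": n_eeg,
    "behavior_null_rejection_rate": beh_hits / n_cohorts,
    "n_behavior_cohorts": n_cohorts}, indent=1))
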