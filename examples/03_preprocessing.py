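"""Preprocess a small synthetic study: filter, flag artifacts, exclude.

Streams a 3-subject study through the cleaning cascade and prints the
exclusion report: which trials lost too many cycles to artifact and whether
any subject fell below three retained trials in a condition.
"""

import flowssvep as fs
from flowssvep import preprocess as pp

spec = fs.StimulusSpec()
cm = fs.hydrocel_like_layout()
topo = fs.demo_topography(cm)  # artifact_rate 0.05 per cycle by default
design = fs.StudyDesign(n_subjects=3, trials_per_condition=4)

subject_comp, trial_comp, report = fs.extract_study_components(
    fs.iter_study(design, topo, spec, seed=5), spec
)

n_trials = len(report.trials)
n_excluded = (report.trials.status == "excluded").sum()
print(f"{n_trials} trials processed; {n_excluded} excluded "
      f"(>= 15% of their 10 cycles exceeded the 60 uV rule)")
print(report.trials[report.trials.status == "excluded"]
      [["subject", "pattern", "speed", "trial", "n_flagged"]].to_string(index=False))
print()
print("subject verdicts (excluded = some condition kept < 3 trials):")
print(report.subjects.to_string(index=False))
print()
retained = report.retained_trials()
print(f"subject-level components built from {len(retained)} retained trials; "
      f"{subject_comp.subject.nunique()} subjects enter the statistics")
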