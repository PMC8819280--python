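"""Trial schedules and synthetic behavioral data.

Builds the randomized two-session schedule for a 20-participant cohort
(4 camera + 24 CED-SPV + 8 boundary-SPV trials each), verifies the
matching constraints, then draws synthetic trial records and prints
descriptive statistics in the style of a results table.
"""

from spvsim import behavior, design

slots = design.build_study_schedule(n_participants=20, seed=11)
report = design.verify_schedule(slots)
df = design.schedule_to_frame(slots)
print(f"{len(slots)} scheduled trials; constraints "
      f"{'all pass' if report.passed else report.failures()}")
print("per participant:", df[df.participant_id == 'P01']["vision"].value_counts().to_dict())

trials = behavior.sample_trials(slots, seed=11)
overall = trials[["duration_s", "collisions", "rating"]]
camera = trials.loc[trials["vision"] == "camera", ["duration_s", "collisions", "rating"]]
print("\n                    overall          camera control")
for col, label in (("duration_s", "trial duration (s)"),
                   ("collisions", "no. of collisions "),
                   ("rating", "subjective rating ")):
    print(f"{label}:  {overall[col].mean():6.2f} +- {overall[col].std():5.2f}   "
          f"{camera[col].mean():6.2f} +- {camera[col].std():5.2f}")
# Camera-vision collisions are pinned at zero and its mean duration is
# anchored near 16.7 s; SPV conditions average around 31 s with large
# between-participant spread (sd 7.7 s), mirroring the study's structure.
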