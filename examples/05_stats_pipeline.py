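"""The full behavioral statistics pipeline on synthetic data.

Standardizes endpoints within participants, runs the two planned-
comparison families (scene complexity with CED, m=6, threshold 0.0083;
boundary vs CED, m=4, threshold 0.0125) with Wilcoxon signed-rank tests,
and reports the practice effect and restoration percentages.
"""

from spvsim import behavior, design, stats

slots = design.build_study_schedule(20, seed=11)
trials = behavior.sample_trials(slots, seed=11)
z = stats.standardize_within_participant(trials)

print("Shapiro-Wilk screen (advisory):")
for ep, (w, p) in stats.shapiro_wilk_screen(z).items():
    print(f"  {ep:12s} W={w:.3f} p={p:.4f}")

for ep in ("duration_s", "collisions", "rating"):
    report = stats.run_planned_comparisons(z, stats.complexity_family(ep))
    print(f"\ncomplexity family, {ep} (significant if p < "
          f"{report.displayed_thresholds[6]}):")
    for r in report.results:
        flag = "*" if r.significant else " "
        print(f"  {r.comparison.label:32s} W={r.w_statistic:6.1f} p={r.p_value:.4f} {flag}")

r, p, shift = stats.learning_effect(trials)
print(f"\npractice effect: r(trial number, z-duration) = {r:+.3f} (p={p:.3f}); "
      f"session-2 SPV trials {shift:.2f} s faster")

# Restoration: how much of normal-vision performance a condition recovers,
# floor = 10x10 complex (worst condition), ceiling = camera vision.
data = trials


def cond_mean(endpoint, vision, res=None, cpx=None):
    sub = data[data["vision"] == vision]
    if res is not None:
        sub = sub[sub["resolution"] == res]
    if cpx is not None:
        sub = sub[sub["complexity"] == cpx]
    return sub[endpoint].mean()


for ep, direction in (("duration_s", "lower_is_better"),
                      ("collisions", "lower_is_better"),
                      ("rating", "higher_is_better")):
    pct = stats.restoration_percentage(
        cond_mean(ep, "ced_spv", 26, "plain"),
        floor=cond_mean(ep, "ced_spv", 10, "complex"),
        ceiling=cond_mean(ep, "camera"),
        direction=direction,
    )
    print(f"restoration at 26x26 plain, {ep:12s}: {pct:5.1f}%")
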