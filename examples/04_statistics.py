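"""Split-plot ANOVA and post-hoc contrasts on a simulated cohort.

Simulates the full four-group study (sham, L5, L6, L5+L6; n = 5/5/9/6)
over six assessment days, then tests the right-hindlimb toe spread with
a mixed (split-plot) ANOVA — group as the between-subjects factor, day
as the within-subjects factor — followed by Fisher's LSD contrasts at
day 1.  The interaction carries 15 numerator degrees of freedom
((4-1) x (6-1)), and the combined lesion separates from every other
group on day 1.
"""

import ratgait as rg

recordings = rg.simulate_cohort(rg.CohortDesign(), seed=0)
gait, _ = rg.summarize_recordings(recordings)
ts = gait[(gait.limb == "right") & (gait.metric == "toe_spread_mm") & gait.valid]

table = rg.mixed_anova(ts, dv="value", within="day", between="group")
print("mixed ANOVA, right toe spread (mm):")
print(table.to_frame().round(3).to_string(index=False))

day1 = ts[ts.day == "d1"]
lsd = rg.lsd_posthoc(day1, dv="value", between="group", require_significant_omnibus=False)
print("\nFisher LSD at day 1 (unadjusted p):")
print(lsd[["group1", "group2", "mean_diff", "t", "p"]].round(4).to_string(index=False))

bonf = rg.oneway_bonferroni(ts[ts.group == "L5L6"], dv="value", within="day")
print("\nBonferroni time contrasts within L5+L6 (first rows):")
print(bonf[["time1", "time2", "mean_diff", "p_bonf"]].head(5).round(4).to_string(index=False))
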