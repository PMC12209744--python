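"""Clinical x serologic stratification and relative risks vs the cohort.

Subjects are classed by clinical involvement (acral: mRSS > 4 or DU disease;
cardiopulmonary: baseline PAH or ILD; dual; none) and crossed with the IFN
class into eight strata.  High risk = at least one involvement AND IFN-high.
Relative risks compare each group's KM cumulative incidence with the whole
cohort's at 24/36/48 months.
"""

from ifnstrat import (SimConfig, adjudicate_cohort, assign_strata,
                      classify_panels, derive_threshold, generate_cohort,
                      generate_controls, rr_vs_overall, score_panels,
                      upset_counts)

config = SimConfig(seed=1)
controls = generate_controls(config)
baseline, panels, visits, _ = generate_cohort(config)
model = derive_threshold(score_panels(controls)["ifn_score"])
scores = classify_panels(panels, model)
outcomes = adjudicate_cohort(baseline, visits)

strata = assign_strata(baseline, scores)
counts = upset_counts(strata, outcomes)
print("per-stratum event rates (upset-plot data):")
print(counts.to_string(index=False))

aligned = outcomes.merge(strata, on="subject_id")
hi = (aligned["risk_group"] == "high_risk").to_numpy()
rr_hi = rr_vs_overall(aligned, hi, ci="bootstrap", n_bootstrap=500, seed=1)
rr_lo = rr_vs_overall(aligned, ~hi, ci="bootstrap", n_bootstrap=500, seed=1)
for name, rr in (("high risk", rr_hi), ("low risk", rr_lo)):
    for _, r in rr.iterrows():
        print(f"{name:<10} RR at {r['horizon']:.0f} months: {r['rr']:.2f} "
              f"(95% CI {r['ci_lo']:.2f}-{r['ci_hi']:.2f})")
# Only strata combining clinical involvement with a high IFN score approach
# or exceed 50% event rates; the pooled high-risk group runs at roughly
# twice the cohort-average risk while its complement sits below 1.
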