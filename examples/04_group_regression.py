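"""MI-pooled multinomial regression of substance-group membership.

Derives the four substance groups (none / alcohol-tobacco-other /
cannabis-without-ATS / ATS) from a synthetic cohort with ~5% missing data,
imputes covariates by chained equations (m = 5 here for speed), fits a
multinomial logistic regression per completed dataset and pools with
Rubin's rules.  Effects are reported as relative risk ratios against the
no-substance-use group.
"""

from assistnet import (
    assign_group,
    build_analysis_table,
    dichotomize_items,
    generate_cohort,
    paper_like_config,
    pooled_regression,
)

cohort = generate_cohort(paper_like_config(n=1107, seed=7))
group = assign_group(dichotomize_items(cohort))
print("group sizes:", group.value_counts(dropna=False).to_dict())

analysis = build_analysis_table(cohort, group)
table = pooled_regression(analysis, m=5, seed=7, n_iter=5)

show = table[table["term"].isin(["age", "region[regional]", "cas"])]
print("\npooled effects (RRR vs no substance use):")
print(
    show[["outcome", "term", "rrr", "ci_low", "ci_high", "p"]]
    .round(3).to_string(index=False)
)
# Age increases the relative risk of every use group; the regional-centre
# effect is largest for the ATS group; clinical anger (CAS, per SD) is
# associated specifically with the cannabis group — the generator plants
# these effects and the pooled fit recovers them.
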