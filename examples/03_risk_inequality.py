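"""Quantify how a binary health risk concentrates across the index gradient.

The Wagstaff concentration index ranks individuals by their community's
restrictiveness category (least restrictive = rank 0, most restrictive =
rank 1) and measures the covariance between risk and rank.  A positive
value means the risk is concentrated in the most restrictive communities;
the binary correction divides by (1 - mu) so the bound is +-1.
"""

from gcci import (
    SyntheticConfig,
    generate_survey,
    community_prevalence,
    fit_one_factor,
    score_communities,
    select_k,
    risk_gradient_table,
)

df = generate_survey(SyntheticConfig())
cp = community_prevalence(df)
scores = score_communities(fit_one_factor(cp), cp)
gccs = select_k(scores.score, scores.community_id)

table, results = risk_gradient_table(df, gccs, ["multiparity"])
print("Weighted prevalence (%) of multiparity (5+ children) by category,")
print("and the corrected concentration index:")
print(table.round(2).to_string())

res = results["multiparity"]
print(f"\nOverall prevalence mu = {res.mu:.3f}")
print(f"Raw CI = {res.raw_ci:.3f}; corrected CI = raw / (1 - mu) = {res.corrected_ci:.3f}")
print(
    "\nThe positive index confirms the risk burden falls on women in the"
    "\nmost restrictive communities; |CI| > 0.10 is conventionally read as"
    "\nhigh inequality."
)
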