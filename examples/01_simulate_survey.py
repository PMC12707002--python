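"""Generate a synthetic family-health survey and inspect its structure.

The generator draws a latent restrictiveness factor per community and
produces individual-level questionnaire responses, survey weights, the
domestic-violence subsample design, and a multiparity outcome.
"""

from gcci import SyntheticConfig, generate_survey, community_prevalence, describe_communities

cfg = SyntheticConfig()  # 47 communities, 435 women each, seed 20210
df = generate_survey(cfg)

print(f"{len(df)} respondents in {df.community_id.nunique()} communities")
print(f"DV subsample: {df.dv_flag.mean():.0%} of respondents")

cp = community_prevalence(df)
print("\nCommunity-level indicator prevalences (mean/SD/min/max across communities):")
print(describe_communities(cp).round(3))
print(
    "\nEach row is one of the five restrictive-context indicators; the spread"
    "\nacross communities is what the index will summarize."
)
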