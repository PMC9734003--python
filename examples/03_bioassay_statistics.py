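"""Significance statistics of the organ-bath antispasmodic assay.

For one batch: Welch tests reconstructed from the printed group summaries
(mean +/- SEM, n = 6), the one-way ANOVA across the five groups, and the
inhibition rate implied by the group means.  '##' marks p < 0.01 vs control;
'**' marks p < 0.01 vs the acetylcholine model group.
"""

from specfx import (
    anova_oneway_from_summary,
    bioassay_record,
    bioassay_stats,
    inhibition_rate,
)

rec = bioassay_record("S1")
print(f"batch {rec.batch_id} group summaries:")
print(rec.summaries.round(4).to_string(index=False))

stats = bioassay_stats(rec)
print("\nWelch tests (model vs control; each dose vs model):")
print(stats.round(4).to_string(index=False))

groups = [rec.group(g) for g in rec.summaries["group"]]
f, dfb, dfw, p = anova_oneway_from_summary(groups)
print(f"\none-way ANOVA: F({dfb},{dfw}) = {f:.2f}, p = {p:.2e}")

c, m, d = (rec.group(g).mean for g in ("control", "model", "dose_35"))
print(f"\ninhibition at 35 mg/mL from group means: {inhibition_rate(c, m, d):.1f}% "
      "(0% = model tension, 100% = control tone)")
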