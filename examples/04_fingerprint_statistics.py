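"""Extract subtype fingerprints and run the comparison statistics.

Uses the planted-territory atlas (the oracle ROI path) so the statistics are
shown on cleanly labelled subtypes: paired t-tests between subtypes, the
Cohen's-d contribution ledger, and the subtype x age/gender repeated-
measures GLM that recovers the planted age interactions.
"""

from wmfp import (PhantomSpec, cohens_d_contributions,
                  extract_fingerprint_table, generate_phantom_cohort,
                  glm_subtype_age_gender, paired_subtype_tests)

records, truth = generate_phantom_cohort(PhantomSpec(seed=0))
table = extract_fingerprint_table(truth.atlas(), records)

print("mean fingerprints (subjects averaged):")
print(table.groupby("subtype")[["R1", "R2", "AD", "RD", "chi_m",
                                "R2star", "MPF"]].mean().round(2))

tests = paired_subtype_tests(table)
sig = tests[tests.significant]
print(f"\npaired t-tests: {len(sig)}/{len(tests)} significant after "
      f"Bonferroni (threshold {tests.attrs['corrected_threshold']:.2e})")

d = cohens_d_contributions(table)
for pair, grp in d.groupby("pair"):
    top = grp.loc[grp.contribution.idxmax()]
    print(f"  {pair}: distance {grp.distance.iloc[0]:.1f} cumulative |d|, "
          f"largest contributor {top.param} ({100 * top.contribution:.0f}%)")

glm = glm_subtype_age_gender(table, omnibus=False)
glm = glm.set_index(["analysis", "term"])
print("\nGLM highlights:")
print(f"  MPF age main effect:      F({glm.loc[('MPF', 'age'), 'df1']:.0f},"
      f"{glm.loc[('MPF', 'age'), 'df2']:.0f}) = "
      f"{glm.loc[('MPF', 'age'), 'F']:.1f}, p = {glm.loc[('MPF', 'age'), 'p']:.2e}")
print(f"  R1 subtype x age:         F({glm.loc[('R1', 'type_x_age'), 'df1']:.0f},"
      f"{glm.loc[('R1', 'type_x_age'), 'df2']:.0f}) = "
      f"{glm.loc[('R1', 'type_x_age'), 'F']:.1f}, "
      f"p = {glm.loc[('R1', 'type_x_age'), 'p']:.2e}")
print("\nAD separates the track subtype from both subcortical ones (largest "
      "d contribution); the global MPF decline with age and the opposite "
      "R1 age slopes planted in the phantom are both recovered.")
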