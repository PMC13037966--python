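"""Classify every gene pair of one treatment group as S / NS / NA / EXCLUDED.

A pair is significant (S) only when the parametric P and the 200-permutation
empirical P are both < 0.005 — at n = 5 the empirical gate means no permuted
pairing of the replicates may beat the observed one. Pairs with P > 0.05 are
non-significant (NS), pairs touching an all-zero gene are NA, and everything
else (the intermediate band, failed empirical confirmation, fewer than three
distinct expression tuples) is excluded.
"""

from phenocoex import SyntheticSpec, classify_group, generate_study, subset_group

matrix, design, truth = generate_study(SyntheticSpec(
    n_background_genes=40, n_ds1_pairs=5, n_ds2_pairs=5, n_nondiff_pairs=4,
    n_na_genes=4, planted_cluster_sizes=(6,), hub_degree=4, seed=42,
))

group = subset_group(matrix, design, ("A1", "GL24"))  # treated group, A line
stats = classify_group(group, seed=7)

print(f"group A1/GL24: {stats.shape[0]} pairs "
      f"(= C({group.values.shape[0]}, 2))")
print("label counts:", stats["label"].value_counts().to_dict())

planted = truth.pairs[(truth.pairs["kind"] == "pair")
                      & (truth.pairs["scenario"] == "DS1")].iloc[0]
row = stats[(stats["gene_a"] == planted["gene_a"])
            & (stats["gene_b"] == planted["gene_b"])].iloc[0]
print(f"planted DS1 pair {row['gene_a']}-{row['gene_b']}: r={row['r']:+.3f}, "
      f"p={row['p']:.2e}, empirical p={row['emp_p']:.3f} -> {row['label']}")
# In this treated group the planted pair is S; in the A-line control groups
# and in the non-responsive B line the same pair classifies NS.
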