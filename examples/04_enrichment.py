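"""Expand a cluster with high-confidence interactors and run ORA.

The interaction table is STRING-format (protein1, protein2, combined_score);
records are kept when the score is strictly above 950 (confidence > 0.95).
Enrichment is the one-sided hypergeometric tail with Benjamini-Hochberg FDR,
run on cluster genes, their interactors, or the combination.
"""

from pathlib import Path

import phenocoex.annotation as anno

# toy inputs, written here so the example is self-contained
Path("scratch_string.tsv").write_text(
    "protein1\tprotein2\tcombined_score\n"
    "CL1_A\tPARTNER1\t990\n"
    "CL1_B\tPARTNER2\t975\n"
    "CL1_B\tWEAK\t900\n"      # dropped: 900 <= 950
    "CL1_A\tCL1_B\t999\n"     # internal edge, not an interactor
)
Path("scratch_sets.gmt").write_text(
    "PATH_UP\tresponse pathway\tCL1_A\tCL1_B\tPARTNER1\tPARTNER2\n"
    "PATH_BG\thousekeeping\tH1\tH2\tH3\tH4\tH5\tH6\n"
)

table = anno.load_interactions("scratch_string.tsv", min_score=950)
collection = anno.read_gmt("scratch_sets.gmt")
cluster = ["CL1_A", "CL1_B"]

interactors = anno.expand_cluster(cluster, table)
print(f"cluster {cluster} -> interactors {sorted(interactors)}")

universe = sorted(collection.all_genes)
combined = set(cluster) | interactors
result = anno.ora(combined, collection, universe)
print(result.to_string(index=False))
# PATH_UP holds all 4 query genes out of its 4 members (k = K = 4) in a
# 10-gene universe: p = C(6,0)/C(10,4) vs the housekeeping set at p = 1.
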