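# phenocoex

Phenotype-filtered differential gene co-expression analysis for small-n
RNA-seq designs.

## The problem

A compound suppresses some cell lines (the responsive phenotype, "A") and
leaves others untouched ("B"). Differential-expression analysis finds genes
that individually change under treatment; it misses coordinated changes where
*relationships between genes* are rewired. `phenocoex` targets exactly that:
gene pairs whose co-expression is gained, lost, or reshaped by treatment in
every responsive line while remaining unchanged in the non-responsive
line(s), so that the rewiring is attributable to the phenotype and not to the
treatment per se.

The typical input is small: a genes × samples TPM matrix with ~5 replicates
per (cell line, treatment) group. At n = 5 correlation estimates are noisy,
|r| thresholds are uninformative (anything significant has |r| ≥ 0.97
anyway), and genome-wide FDR correction is hopelessly conservative. The
method instead uses strict P-value bands backed by permutation.

## The method

For each unordered gene pair within each treatment group, with expression
vectors x, y over the replicates:

* **r, P** — sample Pearson correlation and its two-sided P from the t
  distribution with n − 2 df.
* **empirical P** — relative orderings of one vector are permuted (200 draws
  by default, or all n! exactly); `emp_p = #{i : P_i < P_obs} / n_perm`. With
  the default thresholds, significance requires that *no* permuted pairing
  beats the observed one.
* **label** — `S` if P < 0.005 and emp_p < 0.005 (and ≥ 3 distinct (x, y)
  tuples); `NS` if P > 0.05; `NA` if either gene is all-zero across the
  group's replicates; `EXCLUDED` otherwise (the ambiguous middle band).

Per cell line, the (control, treated) label pair maps to a transition;
transitions combine into differential scenarios:

* **DS1** (gain): {NS, NA} → S in every A line;
* **DS2** (loss): S → {NS, NA} in every A line;
* **DS3** (strength change): S → S with a significant Fisher r-to-z
  difference in every A line.

The **phenotype filter** then keeps a differential pair only if every B line
shows a non-differential pattern (NS→NS, NA→NA, or S→S unchanged). Passing
pairs become edges of undirected, unweighted per-scenario networks; clusters
are connected components, hubs are nodes with degree ≥ 10. Top clusters are
expanded with STRING-format interactors (combined score > 950) and tested for
gene-set over-representation (hypergeometric tail, Benjamini–Hochberg FDR at
0.05 and a strict 1e-5 tier for terms shared between DS1 and DS2).

Because real studies of this shape rarely ship public raw data, the package
includes a synthetic-study generator that plants DS1/DS2/DS3 pairs, clusters,
hub stars and NA genes with certified ground truth, plus a scoring harness.

## Worked example

`examples/03_scenarios_and_network.py` generates a small study (40 background
genes, 5 DS1 + 5 DS2 pairs, 4 non-differential pairs, 4 NA genes, a 6-gene
cluster and a degree-4 hub star), classifies every pair in all six groups,
calls scenarios, and scores recovery:

```
scenario calls: {'none': 3051, 'DS1': 25, 'DS2': 5}
phenotype filter: 29 passing of 30 differential pairs (+1 without the filter, 3.4% increase)
DS1: 21 nodes, 24 edges, 7 clusters (largest 6), hubs ['CL1_001', ..., 'HUB_C']
DS2: 10 nodes, 5 edges, 5 clusters (largest 2), hubs []
DS1 precision 1.00 / recall 1.00; cluster recovered: True; hub detected: True
```

Reading this: 30 pairs were differential in both A lines; 29 of them were
also non-differential in the B line and passed the filter — the one extra
pair that a filter-free analysis would have added (+3.4%) is noise unrelated
to the phenotype. The DS1 network contains the planted 6-gene cluster as a
single connected component and the planted hub; every planted pair was
recovered (recall 1.00) and nothing spurious was called (precision 1.00).

The other examples show the generator (`01`), the per-group pair
classification with its empirical-P gate (`02`), and interactor expansion
plus enrichment on toy STRING/GMT inputs (`04`). There is also a thin CLI:

```sh
phenocoex simulate --out-dir sim --seed 9
phenocoex run --matrix sim/matrix.tsv --design sim/design.yaml --out-dir out --seed 3
phenocoex score --calls out/scenario_calls.tsv --truth sim/truth.tsv
```

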