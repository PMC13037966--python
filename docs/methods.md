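# Methods

## Model and procedure

`phenocoex` identifies treatment-induced rewiring of pairwise gene
co-expression that is specific to a phenotype. The unit of analysis is the
*treatment pair*: a (control, treated) pair of sample groups within one cell
line. Each cell line carries a phenotype role — `A` (shows the phenotype of
interest, e.g. drug-responsive) or `B` (reference, non-responsive). A valid
design has ≥ 1 A-role treatment pair and ≥ 0 B-role pairs; with zero B pairs
the phenotype filter degenerates to an A-line consistency requirement.

### Pair statistics and labels

Within each group, every unordered gene pair receives:

* the sample Pearson r and a two-sided parametric P from the t distribution
  with n − 2 df (n = replicates per group, default 5);
* for candidate significant pairs only, a permutation empirical P: one
  vector's replicate order is permuted (default 200 draws with replacement
  from the n! relative orderings; an exact mode enumerates all of them, 120
  at n = 5), each permutation yields a parametric P_i, and
  `emp_p = #{i : P_i < P_obs} / n_perm` with a strict `<`.

Labels, evaluated in order:

1. `NA` — at least one gene is identically zero across the group's
   replicates (the relationship is unevaluable, not absent). NA is decided
   before the distinct-points test: an all-zero gene has a single distinct
   tuple, so a universal gate would make NA unreachable.
2. `EXCLUDED` if fewer than 3 distinct (x, y) value tuples. "Distinct" is
   read as distinct value pairs; repeated zeros are the motivating case.
3. `NS` if P > 0.05.
4. `S` if P < 0.005 **and** emp_p < 0.005. With 200 permutations this means
   *zero* permuted P values beat the observed one.
5. `EXCLUDED` otherwise — the intermediate band and failed empirical
   confirmations. A constant-but-nonzero vector (undefined r) is likewise
   EXCLUDED, not NA.

r is never used as a selection criterion; at n = 5 any pair passing the P
bands has |r| ≥ 0.974 regardless. Only the sign of r is stored. An optional
log2(TPM+1) transform before correlation exists and is off by default.

### Scenarios and the phenotype filter

Per cell line, the (control label, treated label) combination maps to a
transition code; S→S pairs split on a two-sided Fisher r-to-z test
(`z = (atanh r₁ − atanh r₂)/√(1/(n₁−3)+1/(n₂−3))`, α = 0.05) into *changed*
vs *unchanged*. Any combination involving EXCLUDED, and (by default) mixed
NS/NA across treatments, is `OTHER` — neither differential nor
non-differential; a lenient option folds the NS/NA mixtures into the
both-uncorrelated pattern. The r-to-z test uses the not-both-zero replicate
count as its effective n (equal to the group size except when zeros are
present; fewer than 4 effective points ⇒ unchanged).

A pair is **DS1** when every A-line transition is a gain ({NS, NA} → S),
**DS2** when every one is a loss, **DS3** when every one is S→S-changed;
identical patterns across A lines are not required. It **passes the
phenotype filter** when it has a scenario and every B-line transition is
non-differential (NS→NS, NA→NA, or S→S-unchanged). For the canonical
2-A/1-B design the per-scenario tally spans 4 A-combinations × 3 B-patterns
= 12 conditions; other designs tally by sorted transition multisets.

At n = 5 the Fisher test has essentially no power (0.99 vs 0.90 gives
|z| ≈ 1.18, p ≈ 0.24), so DS3 calls are expected to be rare — the package
treats this as a property of the small-n regime, not a defect.

### Networks, clusters, hubs

Passing pairs of a scenario are edges of an undirected, unweighted graph
(edge kinds: formed / dissolved / changed for DS1/DS2/DS3). |r| is
deliberately not an edge weight. Clusters are connected components, ordered
by size descending with ties broken by the lexicographically smallest member
(a deterministic, platform-independent order; the ordering itself is a
package choice). Hubs are nodes with degree ≥ 10. "Top k" cluster selection
is tie-inclusive by default: every cluster matching the k-th size is kept.
Percent figures are rounded half-up to one decimal by default (an integer
style is available via the digits option).

### Interactors and enrichment

A STRING-format table (protein1, protein2, combined_score 0–1000) is
filtered at combined_score **strictly greater than** 950 (confidence > 0.95)
and symmetrized. Cluster expansion takes first neighbors of the members,
minus the members. Over-representation uses the one-sided hypergeometric
tail `p = Σ_{j≥k} C(K,j)C(N−K,n−j)/C(N,n)` with Benjamini–Hochberg FDR over
all tested sets, at two tiers: 0.05 for breadth and 1e-5 for the strict
DS1 ∩ DS2 intersection. The default universe is the intersection of the
expression matrix's genes with the gene-set members (configurable).
Interaction identifiers are assumed pre-mapped to the expression namespace;
a two-column mapping file is supported. Depletion is not tested.

## Synthetic studies and what they certify

The generator emulates the canonical layout: cell lines A1, A2 (role A) and
B1 (role B), treatments DMSO/GL24, 5 replicates per group, non-negative
TPM-like values. Background genes are independent log-normal: a per-gene
baseline with log-mean 3.0 and log-sd 1.5 (across-gene spread) times
per-replicate log-normal noise with log-sd 0.4 (≈ 40 % replicate CV).

Planted correlated pairs are built with an **exact sample correlation** of
`r_target` (default 0.99): the partner is `r·x̃ + √(1−r²)·z̃` with z̃ confined
to the orthogonal complement of the standardized latent x̃, then affinely
mapped onto a TPM-like non-negative range (affine maps preserve r exactly).
Two further guarantees are enforced by redraw of the noise component:

* **rank comonotonicity** with the latent — Pearson r is maximized over
  pairings by the rank-aligned order, so a pair whose ranks are *not*
  aligned is beaten by some alternative pairing of its own points and fails
  the strict empirical gate; a blind draw at r = 0.99, n = 5 satisfies
  alignment only about half the time;
* **zero beats under exact enumeration** of all 120 orderings, which
  transfers to any sampled subset of them.

Without these, a "population r = 0.99" construction would miss the
P < 0.005 boundary (sample r < 0.974) roughly a quarter of the time and the
empirical gate half the time, i.e. the emitted truth labels would be false
and recovery scores would measure generator noise instead of the pipeline.
`r_target ≥ 0.98` is enforced because the significance boundary at n = 5
sits at |r| = 0.9737. Groups where a plant is intended uncorrelated are
redrawn until the parametric p exceeds 0.1, a margin above the NS threshold.

Structures: DS1 pairs are correlated (certified) in the A-line treated
groups and enforced-uncorrelated elsewhere; DS2 mirrors them; DS3 pairs are
correlated in all A groups with sample r 0.99 (control) vs 0.90 (treated,
uncertified — it cannot clear the S band); non-differential pairs are either
correlated everywhere at equal strength or uncorrelated everywhere; NA genes
are background genes zeroed across all replicates of designated groups
(alternating: all groups / all control groups). Clusters are planted as a
**certified chain** — each member is a certified partner of the previous one
in the designated groups and enforced-uncorrelated against it elsewhere — so
the chain edges alone guarantee a single connected component; non-adjacent
members correlate at ≈ `r_target^distance` and add edges opportunistically.
The hub is a star of certified spokes, so its degree is guaranteed. Signs
alternate between plants (negative correlations are planted and recovered;
the sign is recorded but unused downstream).

Scoring convention: *precision* counts any planted differential structure
(explicit pairs, within-cluster pairs, hub spokes, leaf–leaf pairs) as a
true positive; *recall* is computed over construction-certified plants only
(`guaranteed` in the truth manifest). Within-cluster non-adjacent pairs are
statistically borderline by design, so connectivity — not per-edge recall —
is the cluster criterion.

Features of real RNA-seq deliberately not emulated: count noise, library
size and compositionality, batch effects, gene-length bias, and realistic
correlation spectra among background genes. Passing recovery tests therefore
demonstrates correctness of the statistical machinery on data satisfying the
model's assumptions, not end-to-end performance on real libraries.

## Determinism and numerics

* One master seed fans out to per-pair permutation seeds through a stable
  BLAKE2 hash of (seed, sorted gene ids), so results are independent of
  evaluation order, parallelism and platform.
* The identity permutation is analytically tied with the observed statistic
  and must not count as a beat under the strict `<`. Observed and permuted
  P values are computed through one floating-point path (elementwise dots,
  no BLAS matmul), and the comparison carries a 1e-9 relative tie guard so a
  caller-supplied P_obs from any other correct formula (e.g. the beta form)
  cannot produce a one-ulp spurious beat. Genuine orderings of continuous
  data are separated by far more.
* Degenerate permutations yielding a constant vector (impossible under pure
  reordering, but guarded) contribute P_i = 1, a conservative convention.
* Fisher z clamps |r| at 1 − 1e-12; exactly equal correlations are always
  "unchanged".
* Matrix text round-trips exactly (`%.17g` on write, correctly-rounded
  strtod on read).
* Reported percentages round half-up (ties away from zero), not banker's.

## Problem sizes

The default benchmark (≈ 490 genes, ≈ 119k pairs per group, 6 groups,
200 permutations for candidate pairs) classifies in a few seconds on one
CPU; the full acceptance run, including the strength-shift study and the
worked arithmetic, takes ~10 s. These sizes were chosen to exercise all
planted structure classes at the canonical replicate count while staying
desk-scale.

## Open design choices and limitations

* The permutation null is per-pair (each pair draws its own orderings); a
  matrix-wide scheme (one shuffle per gene per round, shared across pairs)
  is available via `perm_scheme="matrix"`. The two differ only in the joint
  distribution across pairs, not per-pair marginals.
* The strength-change test for DS3 is a package choice (Fisher r-to-z); the
  scenario taxonomy itself does not prescribe one.
* Strict mode treats mixed NS/NA across treatments as ambiguous (`OTHER`);
  the lenient flag reclassifies it as both-uncorrelated.
* The enrichment universe and gene-set parameters are explicit knobs, not
  inferred; enrichment results depend on the supplied GMT and interaction
  files and are only as current as those inputs.
* No community detection, centralities beyond degree, weighted graphs,
  multi-arm (> 2 treatment) contrasts, or live database retrieval.
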