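# Methods

This note documents the models, estimators and design choices behind
`invadiv`, what the synthetic-data generator does and does not emulate,
and the numerical conventions a user should know before trusting (or
extending) the results.

## Input handling and trimming

Sequences are assumed aligned (or trivially alignable, i.e. equal-length)
within each species; the package never builds alignments.  Records are
padded with trailing gaps to the longest aligned length L.  A record whose
covered span (first to last non-gap symbol) is shorter than
`min_coverage` (default 90%) of L is dropped with a logged reason;
the common analysis window is the intersection of the retained records'
spans, so a slightly short sequence shrinks the window and a badly
truncated one is discarded instead.  Populations left with fewer than
`min_n` (default 5) sequences are excluded — frequency-based statistics on
smaller samples are dominated by noise, and the smallest sample retained in
the bundled study table is 5.  Trimming is idempotent.

Metadata are tab-separated (names with commas and diacritics survive
round-trips), coordinates are decimal-degree WGS84, and every writer in the
package has a reader that restores the object field-for-field.

## Diversity indices

Complete deletion is the default site filter: any column containing a gap
or non-ACGT symbol in any sequence of the population is removed before
*S*, *nHap*, Hd and π are computed (this matches the common default of
the classical diversity calculators; a pairwise-deletion variant of *S*
exists behind a flag).  Haplotypes are exact string classes over the
retained sites — no ambiguity-aware merging — which keeps the counts
reproducible and order-independent.

Hd uses Nei's unbiased estimator; π uses the n/(n−1) form, which equals
the plain average of pairwise differences over all C(n,2) sequence pairs.
The biased and unbiased forms agree at the 3-decimal reporting precision
for every bundled worked example, so the choice does not affect the
reference checks.  Tables round Hd and π to 3 decimals; full precision is
available with `decimals=None`.

## Haplotype-frequency F_ST and permutation inference

Differentiation is measured on haplotype identity only:
`F_ST = (H_b − H_w)/H_b`, with H_w pooled over the two populations with
weights n(n−1)/2 (configurable to an unweighted mean) and the pair
compared on the complete-deletion columns of the pooled alignment.  This
estimator is exactly computable from haplotype counts, so the test suite
checks it against brute-force enumeration of every sequence pair.  Raw
estimates may be slightly negative; they are preserved internally and
clamped to zero only in range summaries, so a reported minimum of 0 may be
a clamped negative.  Two populations fixed for the same haplotype give 0
by convention.

Permutation tests pool individual sequences and re-partition them into the
original sample sizes (default 10,000 permutations); the add-one rule
keeps p strictly positive, and an exhaustive enumeration over all
re-partitions serves as the oracle at tiny n.  Note that the smallest
attainable p is 1/(n_perm+1), so the fixed p < .01 reporting criterion
needs at least 199 permutations to be able to fire at all.  The
alternative significance rule is Benjamini–Yekutieli FDR control, the
correction recommended for tables of pairwise F_ST tests.

`fst_components`/`global_fst` expose the pooled diversity components
(H_w, H_b) of a whole multi-deme dataset.  Summing components across
replicate datasets before taking the ratio (the multilocus form) is the
right way to compare simulations with analytic F_ST expectations: the
per-replicate ratio estimator is biased downward at low mutation rates,
where many pairs are monomorphic.

## Evolutionary distances, trees and model selection

Pairwise distances use the closed forms of JC69, K2P and TN93; the
gamma-corrected variants replace each −ln(x) by a(x^(−1/a)−1).  HKY85 has
no closed-form distance and is routed through TN93, in which it nests.
Saturation (a non-positive log argument) raises an explicit error rather
than returning NaN; inside bootstrap replicates saturated pairs are capped
at 10 substitutions/site so a rare degenerate resample cannot abort a run.
Mean between-population distance is the arithmetic mean over all inter-
population pairs (saturated pairs excluded with a warning); the "net"
variant that subtracts the within-population means is available behind a
flag, since either convention is found in the field's tooling.

Neighbor joining follows Saitou–Nei with the Studier–Keppler Q criterion,
deterministic tie-breaking (lowest label-index pair) and negative
branch-length estimates clamped to zero (they arise only on non-additive
input; on additive matrices the tree reproduces every path length to
machine precision, which is tested up to 8 taxa).  Bootstrap supports
resample alignment columns, rebuild the tree, and count each original
internal bipartition; edges below the condensation threshold (default
75%) — and zero-length internal edges, which only exist by tie-breaking —
are collapsed into polytomies.

Model selection fixes the topology to the K2P neighbor-joining tree and,
for each of JC69/K2P/HKY85/TN93 with and without Γ₄ (median-rate discrete
categories), maximises the pruning-algorithm likelihood jointly over
branch lengths and substitution parameters (L-BFGS-B on log-transformed
parameters; gamma shape bounded to [0.05, 10]; base frequencies empirical
for HKY/TN93 and counted as parameters).  The winner minimises
BIC = −2lnL + k·ln(sites), with sites = complete-deletion columns.  With
fewer than three distinct haplotypes there is nothing to fit and JC69 is
returned with a warning.  The candidate family is deliberately the nested
set whose distances have closed forms used downstream, not a full 24-model
scan.

## Geography

Distances are haversine great circles on a sphere of radius 6371.0 km
(≈0.5% from an ellipsoidal geodesic — negligible next to the arbitrariness
of assigning one coordinate to a shoreline sample, and far from the
waterway distance a drifting amphipod actually experiences; treat the
geographic predictor accordingly).  Log10 of the km matrix is the
regression predictor.  Co-located distinct populations would make it
undefined; such pairs get log10(min positive distance / 10) and a warning,
a policy invented for robustness since real sampling designs rarely repeat
coordinates exactly.

## Group comparisons and distance models

Mann–Whitney tests use midranks for ties; the exact null distribution when
n₁·n₂ ≤ 400 with no ties, otherwise the normal approximation with
tie-corrected variance and continuity correction.  The reported W is the
rank-based U of the invasive (first) group; the z statistic is reported
alongside because a U can never be negative and published summaries
sometimes print z under the name W.

The structure contrast divides every pairwise F_ST of a species by that
species' mean upper-triangle log10 distance (each species normalised
independently), then pools the per-pair normalised values within the
invasive and non-invasive groups (pooling by per-species means is also
computed, since group averages can be read either way).

Regressions are ordinary least squares of pairwise F_ST on mean
evolutionary distance and log10 geographic distance, with per-term t and
two-sided p, R² and the overall F-test.  Pairwise observations share
populations and a single genealogy, so OLS p-values are anti-conservative;
a Mantel permutation p-value is available for honest inference.  Species
spanning a major geographic break are split by region label first
(species flagged as stepping-stone-contiguous stay whole), and subsets
with fewer than 4 populations (6 pairs) are flagged non-regressable —
three points cannot support an intercept plus two slopes.

For spatially explicit simulations the isolation-by-distance power check
uses the geography-only regression `F_ST ~ log10(km)`.  This is a
deliberate choice: the evolutionary-distance covariate is computed from
the same realized genealogy as F_ST itself, so in a two-predictor model it
absorbs essentially all the signal and the partial geographic slope has
power near the test's size for any stepping-stone configuration.  The
two-predictor model remains the analysis tool for real data, where deep
lineage structure and geography are distinct processes.

## The synthetic-data generator

The generator is a direct structured-coalescent implementation: haploid
lineages (one mtDNA sequence per individual), within-deme pairwise
coalescence at rate 1 (time in units of the deme size), migration as a
per-deme rate matrix, mutations laid on branches as Poisson(θ·length)
events under Jukes–Cantor with multiple hits allowed.  Identical seed and
configuration give byte-identical FASTA output.

* **Island model** — every lineage leaves its deme at total rate
  M(d−1)/d toward a uniform other deme.  This finite-deme calibration
  makes the classical haploid expectation F_ST = 1/(1+2M) hold exactly in
  the low-mutation limit for any deme count (the uncorrected rate would
  give 1/(1+2Md/(d−1))).  Above M = 1000 the strong-migration (panmictic)
  limit is simulated directly to keep the event count bounded.  The
  generator is cross-checked against an independent coalescent simulator
  (msprime) and against the exact island-model coalescence times.
* **Stepping stone** — demes on a line with nearest-neighbour migration
  and coordinates spaced `deme_spacing_km` apart, generating isolation by
  distance.
* **Deep splits** — demes are partitioned among `n_lineages` clades with
  independent genealogies whose ancestral sequences are mutated from a
  common backbone; the realized inter-ancestor divergence is recorded,
  and tests use realized rather than nominal values because multiple hits
  make the two differ at high divergence.

Defaults (6 demes × 10 sequences, 509 bp, θ = 0.5, M = 1) emulate the
scale of the study data: 3–25 localities per species, 5–42 sequences per
locality, and within-population diversity in the observed range
(Hd 0–1, π up to ≈0.05).  Property tests use conditions chosen by design-
time power analysis: parameter recovery runs at θ = 0.05 because
1/(1+2M) is a low-mutation-limit result; the isolation-by-distance power
check uses a 10-deme line with neighbour rate 2, where the single-locus
F_ST gradient is strong enough for ≥80% power.

What the generator does **not** emulate: recombination (absent in mtDNA),
selection, demographic change, sequencing error, alignment uncertainty,
and the real species' uneven sampling designs.  Passing tests therefore
demonstrate that the estimators and the inference chain behave correctly
under the stated neutral models — not that any biological conclusion about
real gammarids is robust to the processes the models omit.

## The bundled study table and its rank statistics

The package ships the published per-population index table (59
populations across seven species) and recomputes the invasive vs
non-invasive Mann–Whitney comparisons from it.  Two *G. tigrinus*
populations (St.John and Neuse) carry a "non-native" range label in the
printed table although both sites lie on the Atlantic coast of North
America, inside the species' documented native range; the comparison stage
treats them as native (the raw labels are available via
`study_table(apply_range_corrections=False)`).  With this correction the
recomputed statistics for segregating sites (U = 214, p = .970) and
haplotype diversity (U = 271.5, p = .166) match the published values
exactly, which no labelling consistent with the printed 25/16 group sizes
does.  The published nucleotide-diversity statistic (W = 90.5, p = .307)
cannot be reproduced from the printed table under any grouping or
orientation — the recomputed value is U = 228.5 (p = .762), and resolving
every rounding tie can move U by at most about ±10 — so it appears to be
an erratum; the corresponding acceptance test records the discrepancy by
failing, and the qualitative conclusion (no group difference) is
unchanged.

## Numerical conventions and limitations

* RNG: a single root seed is fanned out to stages by CRC-hashing the
  stage name into a `SeedSequence`; per-stage seeds stay below 2³¹.
* Degenerate inputs: fixed-same pairs give F_ST = 0; H_b = 0 likewise;
  all-saturated population pairs are an error; fewer than 3 taxa cannot
  be treed; fewer than 4 pairs cannot be regressed.
* The ML optimiser uses finite-difference gradients with at most 200
  L-BFGS-B iterations and ftol 1e-7; likelihoods are pattern-compressed
  and duplicate haplotypes are collapsed before fitting.
* Reproducing the original study's sequence-level numbers (per-species
  F_ST ranges, Table-2 coefficients, tree figures) requires downloading
  the archived sequences and supplying coordinates, neither of which is
  bundled; `invadiv reproduce` runs the protocol once those are provided
  and cross-checks computed indices against the bundled table.
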