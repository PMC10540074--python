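# Methods

This note documents the models and procedures implemented in `pangevo`,
the defaults and why they were chosen, the numerical and tie-breaking
conventions, what the synthetic-data generators do and do not emulate, and
known limitations.

## Genomic-species delineation

Genomes are nodes of an undirected graph; an edge joins two genomes when
their average nucleotide identity (ANI) reaches the threshold, 95% by
default — the conventional intra-species boundary for microbial genomes.
ANI programs report each direction of a comparison separately and the two
values differ slightly; we keep the edge when **either** direction passes
and weight it by the mean of the available directions. This is the most
inclusive deterministic rule; it is stamped into the run manifest.
Self-comparisons are dropped; genomes with no surviving comparison remain
as isolated nodes (singleton species).

Clusters are computed with the Markov Cluster algorithm (MCL),
re-implemented: the column-stochastic transition matrix built from edge
weights (self-loop on each node equal to its largest incident weight,
guaranteeing aperiodicity; 1 for isolated nodes) is alternately expanded
(matrix power, default 2) and inflated (elementwise power, default 2.0,
followed by column renormalization), pruning entries below 1e-6, until the
largest column change falls under 1e-6 or 200 iterations elapse
(non-convergence returns the current clustering with a warning). Clusters
are the connected components of the converged matrix's nonzero structure —
the attractor basins — which makes the partition overlap-free and
guarantees that nodes in different components of the thresholded graph are
never merged. Nodes are sorted before matrix construction, and cluster
labels are assigned by descending size then lexicographically smallest
member, so the output is invariant to input order. Whether the original
analyses ran MCL on weights or on a binarized pass/fail graph is not
knowable from the published record; both are supported (`binary_edges`),
weighted being the default.

## Pangenome partitioning and openness

A family present in k of N genomes (fraction f = k/N) is classed by the
first matching rule: k = 1 → *unique*; f = 1 → *core*; f ≥ 0.90 →
*soft-core*; f ≥ 0.15 → *shell*; k ≥ 2 → *cloud*. The published boundary
phrasings ("between 99.999 and 90%", "between 89 and 15%", "14% down to
two strains") are interpreted as half-open fraction intervals [0.90, 1.0)
and [0.15, 0.90) plus the two count rules; the unique→core→soft-core→
shell→cloud precedence makes the classes exhaustive and mutually exclusive
for every N, including small panels where two genomes already exceed 15%.
This is verified exhaustively for all (N, k) with N ≤ 30 against an
independently coded rule set.

The accumulation curve draws, for each of 1,000 permutations (the default)
of the genome order, the number of distinct families among the first k
genomes; the mean curve is the fit target for the Heaps-law model
y = a·x^γ, estimated by nonlinear least squares (`scipy.optimize.curve_fit`,
initialization a = y(1), γ = 0.3, tolerances 1e-10). Fitting the mean
cumulative curve — rather than per-permutation curves or the new-genes
curve — matches the upstream permutation-plot convention. γ in (0, 1)
is reported as an open pangenome; a clonal matrix fits γ ≈ 0 and a fully
disjoint one γ = 1 exactly, which the tests use as analytic limits.

COG enrichment compares the percentage of core families carrying each
category against the pooled accessory fraction (soft-core + shell + cloud
+ unique). An orthogroup's categories are the union of its member genes'
letters (a multi-letter family counts once per category); families with no
annotated gene carry the `@` pseudo-category and stay in the denominators.
Calls: *core-enriched* when log₂(core%/accessory%) ≥ 1, *core-depleted*
when ≤ −1, *undefined* when either percentage is zero. Percentages can be
computed per family (default) or per gene (`unit="gene"`, weighting each
family by its total gene count); the published convention is not stated,
so the choice is stamped into the output.

## Ancestral gene content (Wagner parsimony)

Each family's presence/absence is reconstructed on the fixed rooted
species tree by Sankoff dynamic programming over states {0, 1} with gain
and loss penalties both 1 by default (configurable). Bottom-up:
cost(node, s) = Σ_children min_t [cost(child, t) + penalty(s→t)];
multifurcations are handled natively by the sum. Top-down: the root takes
the cheaper state, ties broken toward absence by default — with equal
penalties many patterns are genuinely ambiguous, and preferring absence
avoids inflating ancestral genome sizes (the alternative is available as
`root_tie_break="presence"`). Traceback ties prefer the parent's state,
which avoids spurious gain/loss pairs on sibling edges; both policies are
deterministic and recorded in the output. Per-edge gains (present here,
absent in parent) and losses (the converse) satisfy the identity
present(child) = (present(parent) ∖ lost) ∪ gained, asserted in tests
along with exact agreement of the reconstructed cost with a brute-force
minimum over all internal labelings on every small tree. The probabilistic
birth–death rate machinery sometimes used to pre-estimate rates before a
parsimony pass is intentionally out of scope; the reconstruction here is
the parsimony step itself.

## Tajima's D

S (segregating sites) and π (mean pairwise difference count) are computed
after complete-column deletion: any column containing a character outside
{A, C, G, T} in any sequence is removed before either statistic, so both
estimators see exactly the same sites. This is the conservative
gap/ambiguity convention; it is recorded in output metadata. D =
(π − S/a₁)/√(e₁S + e₂S(S−1)) with the standard n-dependent constants
(a₁ = Σ 1/i, etc.). D is undefined when S = 0 or n < 4; undefined rows are
emitted with a flag rather than dropped, keeping downstream denominator
choices explicit. Within-species D is computed per orthogroup on
within-cluster sequences only.

Group comparisons use the Mann–Whitney U test. U and the common-language
effect size CLES = U/(n₁n₂) are computed by direct pair scoring (1 per
win, 0.5 per tie); the p-value comes from `scipy.stats.mannwhitneyu` —
the exact null distribution when n₁·n₂ ≤ 400 and the data are tie-free,
otherwise the tie-corrected normal approximation. The two paths agree to
well under 0.01 near the switch point.

## Pairwise dN/dS and distances

The dN/dS engine is the Nei–Gojobori (1986) counting method with
Jukes–Cantor correction, chosen because it is fully specifiable and has an
exact brute-force oracle (explicit pathway enumeration), and it supports
the downstream screen unchanged; the engine name is stamped into all
outputs. Conventions: synonymous site opportunity at each codon position
is (synonymous non-stop changes)/3 — a mutation creating a stop codon
counts toward the nonsynonymous opportunity; site counts are averaged over
the two sequences; difference counts average over all single-step
substitution pathways, excluding pathways through stop codons (falling
back to all pathways in the rare case every pathway is blocked); codons
containing a gap, N, or a stop in either sequence are skipped pairwise.
dX = −(3/4)·ln(1 − (4/3)p_X); a proportion at or beyond 3/4 is saturation
and flags the pair unusable. ω = dN/dS is defined only when dS > 0. NG86
is biased under transition/transversion asymmetry (it ignores κ), so
recovery tests use κ = 1; with κ > 1 expect dS inflation and downward ω
bias relative to maximum-likelihood engines.

The companion nucleotide distance is Tajima–Nei (1984), which corrects for
unequal base composition: d = −b·ln(1 − p/b) with b = ½(1 − Σgᵢ² + p²/c)
and c = Σ_{i<j} x_ij²/(2gᵢgⱼ); it reduces to Jukes–Cantor for balanced
composition, asserted in tests. Records are filtered before any median or
test: Tajima–Nei distance equal to zero ("distance" in the discard rule is
read as the Tajima–Nei quantity, the one introduced in the same breath as
the rule), ω > 5, dS > 10, and — in cross-cluster mode — same-cluster
pairs. Removal reasons are tallied in the run report.

Codon-aware back-translation expands each aligned amino acid to its source
codon (protein gaps become `---`), after verifying that the CDS translates
exactly to the ungapped protein under the bacterial code (GTG/TTG starts
read as Met); a retained trailing stop codon is trimmed and internal stops
are errors naming the sequence and position.

## The differential-selection screen

For one orthogroup and two species clusters, every cluster member is
paired with one common outgroup sequence (when outgroup paralogs exist,
the one with the smallest median Tajima–Nei distance to the ingroup, ties
to alignment order); the two resulting ω multisets are compared by
Mann–Whitney, and the orthogroup is flagged `higher_in_A`/`higher_in_B`
iff |log₂(median_A/median_B)| > 1 **and** p < 0.05, else `ns`. Whether
published pairwise sets were outgroup-only or also ingroup-vs-ingroup
across clusters is ambiguous; the default is outgroup mode, with
`mode="cross-cluster"` available. Equal per-cluster genome sampling
(e.g. n = 19 per cluster) is supported and used by the validation runs.

## Synthetic-data generators

All generators are seed-deterministic (same config + seed ⇒ identical
bytes).

* **Gene content**: root family count ~ Poisson(λ₀); along each branch of
  length t every present family survives with probability exp(−μt) and
  Poisson(σt) new families are born, each born once globally
  (infinitely-many-genes). This keeps the true event log unambiguous for
  recovery tests but deliberately omits re-gain, transfer between
  lineages, and copy-number dynamics — passing recovery tests therefore
  shows the reconstruction recovers birth/death histories, not that real
  histories are birth/death.
* **Coalescent**: waiting times Exp(k(k−1)/2) in scaled units, mutations
  ~ Poisson(θ·T_total/2) placed uniformly on branches, each mutation on
  its own site among L positions (infinite sites mapped to finite L; a
  warning fires when E[S] > 0.1·L). No recombination, structure, or
  demography. Calibrated against E[S] = θa₁ and E[π] = θ, and
  cross-checked against msprime in one test.
* **Codon evolution**: exact event-by-event (Gillespie) simulation of a
  GY94-style chain — single-nucleotide codon moves among sense codons,
  ×κ for transitions, ×ω for nonsynonymous moves, uniform codon
  frequencies — with time scaled so one unit is one expected substitution
  per codon at the uniform composition. Event-by-event simulation (rather
  than matrix exponentials) makes realized substitution counts available
  as ground truth.
* **Planted ANI tables**: within-cluster values truncated-normal
  (default 97.5 ± 0.8, truncated ≥ 95.5), between-cluster 82 ± 3 truncated
  ≤ 92, independent direction jitter (0.05); the truncation bounds bracket
  the 95% threshold, so exact recovery is guaranteed by construction and
  any failure indicates a clustering defect.
* **End-to-end fixture**: 4 clusters × 5 genomes, ~300 gene families,
  8 orthogroup alignments of 200 codons (one with genuinely differential
  ω: 1.0 in one cluster vs 0.2 elsewhere), with a ground-truth JSON.
  Dimensions chosen so the full test suite runs in minutes on one CPU.

For the screen validation, synthetic orthogroups use a divergence budget
of 0.02 expected substitutions/codon on the outgroup stem, 0.15 on each
cluster stem, and 0.10 on each member tip, concentrating divergence on the
cluster-specific branches so member-vs-outgroup ω̂ reflects the cluster's
ω. Members of a cluster share their stem and are therefore positively
correlated — a realistic property that makes the null flag-rate check a
joint test of the rule, not of Mann–Whitney alone.

## Numerical and formatting conventions

Every table is written with fixed column order and 6-decimal floats, and
JSON with sorted keys, so reruns under the same configuration are
byte-identical. Internal tree nodes without labels are auto-named by
preorder index (`N0`, `N1`, …) so ancestral reports are stable. The
trailing `Total` column of gene-count tables is always recomputed, never
trusted. Orthofinder "unassigned genes" merged into a matrix are accepted
as singleton orthogroup rows.

## Limitations

Reproducing the absolute published numbers for any particular genus
(pangenome sizes, ancestral gene counts, per-orthogroup CLES values)
requires the corresponding genome dataset and its upstream annotation/
orthology runs, which are outside this package's scope — the pipeline
starts from the intermediate artifacts. NG86 is a counting method, not an
ML estimator; the screen's decision rule transfers unchanged, but absolute
ω values from ML engines will differ, most under strong transition bias.
MCL parameter defaults (inflation 2.0) follow the classic recommendation;
very weakly separated species complexes may need tuning.
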