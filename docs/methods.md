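# Methods

## The network model

A regulatory network is a directed graph over three node classes — TF, miRNA,
gene — with typed, signed edges: `TF-gene` (TF → gene or TF → TF; TF–TF
regulation and autoregulatory self-loops ride on this relation type, which is
what lets TF cascades exist at all), `TF-miRNA` (TF → miRNA) and
`miRNA-target` (miRNA → gene or TF, always repression). Node classes are
inferred from edge context because curated source tables are relation lists,
not node lists; an id whose implied classes conflict is a hard error, as is a
duplicate (source, target, relation) triple or one with conflicting signs —
sign drives every downstream stratification, so silently keeping one record
would corrupt the analyses. Components are weakly connected (direction
ignored), matching the "single interconnected network" reading of component
counts in this literature.

## Evolutionary rates

Protein-coding rates are dN (nonsynonymous substitutions per site), consumed
as a 2-column TSV. miRNA rates are sequence divergence against an outgroup:
over alignment columns whose reference coordinate falls inside the miRNA's
interval, divergence = substituted columns / both-ungapped columns. Gap
columns leave both numerator and denominator — divergence is a per-aligned-
site substitution proportion. No multiple-hit correction is applied by
default (primate-scale distances are small; a Jukes–Cantor switch exists).
Intervals with no aligned column are flagged `no_alignment`; intervals whose
aligned fraction falls below `min_aligned_fraction` (default 0.5 — a partial
alignment of less than half the hairpin says little) are flagged
`low_coverage`; both are excluded from rate tables by default and reported in
the QC output. Coordinates are 0-based half-open internally; AXT input
(1-based inclusive) is converted on read; strand does not affect the count
because complementing both rows of an alignment column preserves
match/mismatch. Where blocks overlap on the reference the first block wins
with a warning (best-in-genome pairwise chains are normally disjoint).

## Statistics

All tests are two-sided and nonparametric, with conventions pinned so results
are environment-independent:

* **Spearman** — mid-ranks for ties; p from the exact permutation
  distribution for n ≤ 10 (enumeration over permutations of one rank vector),
  else the t approximation t = ρ√((n−2)/(1−ρ²)). Constant input yields an
  explicitly undefined result rather than a silent 0.
* **Wilcoxon rank-sum** — exact enumeration when n₁+n₂ ≤ 12 without ties
  (two-sided as 2·min(P(U≤u), P(U≥u)), capped at 1); otherwise the
  tie-corrected normal approximation with continuity correction. Two
  identical constant groups carry no evidence: p = 1.
* **Fisher's exact test** — probability-mass two-sided definition (sum of
  hypergeometric probabilities ≤ that of the observed table). The reported
  odds ratio is the sample OR (a·d)/(b·c): +∞ when b·c = 0 with a·d > 0, NaN
  when both cross-products vanish.

p-value computation delegates to scipy where scipy implements the pinned
convention; every convention is enforced by enumeration-oracle tests
regardless of the backing implementation.

## Coevolution analyses

Edges of one relation type are stratified by sign; edges missing either rate
are dropped and counted. Each *edge* is one observation — a hub regulator
with k partners contributes k pairs. This matches the per-pair framing of the
question but pseudo-replicates hub rates; the permutation null of the
correlation is therefore slightly anti-conservative on hub-heavy networks (a
known caveat, visible in the null-calibration tests).

Median splits sort pairs by the splitting member's rate, breaking ties by
lexicographic edge id, and assign the middle pair of an odd count to the low
half — deterministic by construction. The signal-preference contrast uses the
same halving convention on TF rate and tests the half × sign 2×2 table.

Expression-based sign inference assigns activation/repression to TF-gene
edges by the sign of the Spearman correlation of the endpoint expression
profiles (Pearson available as a switch); exactly zero, undefined (constant
profile), below a configurable |ρ| threshold (default 0, i.e. no filter), or
a missing endpoint gives `unknown`.

## Cascade ordering

A is upstream of B (same class) when a directed path A ⇝ B exists over edges
of any type and no path B ⇝ A exists. Mutually reachable pairs are excluded
rather than counted twice — the conservative choice where no cycle rule is
given. Rate ties are excluded from the fraction's denominator because
"lower" is strict. Shortest paths use unit weights, where Dijkstra reduces
to breadth-first search; the implementation is tested for equivalence against
a BFS oracle, and pair enumeration against a transitive-closure oracle.

## Pathway co-regulation

A TF–miRNA pair regulates a common pathway when at least one membership set
contains both ids; membership is annotation input, not computed. Because the
counting unit of such contingency tables is ambiguous in the literature (pair
counts can exceed link counts when pairs are crossed with pathways), both
units are implemented: `pair` (default; one observation per signed pair) and
`pair_pathway` (one observation per pair × pathway-regulated-by-either-member
combination). Printed-table checks feed published counts directly through
the Fisher machinery, independent of the counting unit.

## Sensitivity analysis

`perturb_network` removes round(remove_frac·|E|) edges uniformly (round half
up) and adds round(add_frac·|E|) edges sampled uniformly over class-
compatible (source, target) pairs absent from the original network, typed by
endpoint classes; added TF edges draw signs from the original per-type sign
frequencies, added miRNA-target edges are repressive. Node sets never change
and every replicate is re-validated. Replicates are seeded from
(seed, replicate index) so execution order and parallelism cannot affect
results; replicate counts default to 100. The report carries per-replicate
statistics plus, per analysis, the median and the share of replicates
preserving the baseline's sign and (where a p-value exists) its significance
verdict at α = 0.05.

## The synthetic-data generator

The generator emulates the statistical structure of the curated human
TF–miRNA network the method was designed for; defaults are the study
conditions:

| parameter | default | why |
|---|---|---|
| composition | 425 TF / 150 miRNA / 1700 gene; 2655 / 210 / 1433 edges | curated network's composition |
| `p_activation` | 0.78 | activating share of signed TF-miRNA links (158/203) |
| `degree_skew` | 1.0 | rank-weight exponent; reproduces the observed hub scale (top TF ≈ 26/210 links). Steeper skews concentrate edges on one regulator, whose massively tied rate attenuates rank correlations |
| `rho_activating` / `rho_repressing` | 0.6 / 0.0 | planted Spearman between regulator and partner rates per sign |
| `rho_mirna_target` | −0.3 | planted negative miRNA–target association |
| `cascade_gradient_tf` / `_mirna` | +0.006 / −0.006 per depth, saturating at depth 6 | positive = deeper regulators evolve faster; defaults produce upstream-lower fractions of ~0.65 (TF) and ~0.33 (miRNA), the order of magnitude reported for real cascades. The cap keeps deep dense networks from letting the gradient dwarf the dN-scale rate variance |
| `pathway_or` / `common_pathway_base` | 2.0 / 0.12 | planted co-membership odds ratio over the repressing-pair baseline |
| `subst_prob`, `gap_prob` | 0.05, 0.02 | per-site substitution / gap probabilities for alignment blocks |

Rates use a Gaussian copula: each node carries a standard-normal latent,
partner latents are blended toward the normalized sum of their regulators'
latents with weight 2·sin(πρ/6)·√k (capped at 1, k = regulator count), and
latents map through gamma quantiles (dN-like scale for proteins,
divergence-like for miRNAs). Rank blending induces the target Spearman
without distributional assumptions; per-edge correlation degrades as 1/√k for
heavily co-regulated partners, so recovery tolerances widen with edge
multiplicity as well as 1/√n. Genes regulated by both miRNAs and TFs follow
the miRNA-target rule (the planted feature), documented precedence.

**Cascade depth** is the longest-path position of a node's strongly connected
component in the condensation DAG — not BFS distance from root regulators.
BFS depth is not monotone along the directed-reachability order in dense
networks (a "downstream" node can sit nearer a root), which makes a
depth-planted gradient's direction seed-dependent; condensation longest-path
depth is strictly monotone along ordered pairs by construction, so the
planted direction is deterministic. Gradient shifts are applied after the
copula transform and clipped to valid ranges (≥0; ≤1 for divergence) with a
logged count.

Alignments are i.i.d. per-site substitutions (driven by the planted
per-miRNA rate when generating a full bundle) with occasional insertion and
deletion gap columns. Expression profiles are standard-normal for TFs; a
gene's profile is the signed sum of its regulators' profiles plus noise, so
per-edge correlation signs carry the edge sign except where discordant
co-regulators dilute an edge. Pathway generation flags each signed TF-miRNA
pair as "common" with sign-dependent probability derived from
`common_pathway_base` and `pathway_or`, gives flagged pairs one shared
pathway, and adds `memberships_per_node` random memberships as annotation
noise — accidental co-memberships from that noise dilute the measured OR
toward 1, which is why OR-recovery checks scale the pathway count with the
pair count.

Every generator draws from its own seed-derived stream; the same
configuration yields byte-identical emitted files.

### What the generator does not emulate

Real curated networks have correlated ascertainment (well-studied TFs have
more recorded links), literature-biased signs, non-i.i.d. substitution
processes, and tissue-structured expression covariance. Passing
parameter-recovery tests shows the pipeline measures what was planted at
these sample sizes — not that the biological effect sizes in any real
network equal the planted ones.

## Problem sizes and numerical choices

Module tests run on reduced compositions (tens of nodes); parameter-recovery
checks use 20 seeded replicates at n ≈ 350–450 rated pairs per stratum for
correlations and ≈ 2000 pairs per arm for the odds ratio — sizes at which the
pre-registered tolerance bands ([0.4, 0.75] for planted ρ = 0.6; [1.5, 2.7]
for planted OR = 2.0; 3σ over replicate means for cascade directions) hold
with margin under the 1/√n and 1/√k arguments above. Exact-test enumeration
oracles cover every 2×2 table with N ≤ 40 and every untied rank-sum instance
with n ≤ 12. The divergence-estimator check pools 5 seeds × 1000 intervals
× 80 sites and applies a 3-standard-error band at the pooled site count.

The pipeline (`run_full_analysis`) is a pure function of (inputs, seed);
summary JSONs are byte-identical across reruns. Degenerate inputs —
empty strata, all-tied groups, zero-margin tables, unrated nodes — return
flagged results or logged drops rather than raising mid-pipeline; hard
validation failures (malformed files, class conflicts) abort with the failing
stage named.

## Known limitations

* Per-edge observations pseudo-replicate hub regulators in all pair-level
  statistics (shared with the analysis tradition this package follows).
* The `pair` vs `pair_pathway` counting ambiguity is surfaced, not resolved.
* Divergence uses the interval exactly as given; no flanking precursor
  sequence, no liftover, no dS or dN/dS.
* Mutually reachable regulator pairs carry no cascade information here;
  analyses of cyclic cores need a different estimand.
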