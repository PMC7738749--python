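# Methods

## Scoring model

The benchmark treats orthogroup inference as a clustering problem over a
fixed gene universe and evaluates it at the level of unordered gene pairs.
For each reference orthogroup (RefOG) $r$ with member set $M_r$,
$n_r = |M_r| \ge 2$:

* $TP_r$ = within-RefOG pairs co-assigned to one predicted orthogroup;
* $FN_r = \binom{n_r}{2} - TP_r$ (conservation holds by construction);
* $FP_r$ = co-predicted pairs with exactly one endpoint in $M_r$.

All three are divided by $n_r - 1$ before summation. The rationale is that
one misplaced gene breaks exactly $n_r - 1$ within-RefOG pairs, so after
this normalization a single-gene error costs one unit for every RefOG
size; dividing by the pair count $\binom{n_r}{2}$ instead would make large
RefOGs almost free to damage, and using raw counts would let the largest
RefOGs dominate. Precision, recall and F-score are computed from the
summed normalized counts, not averaged per RefOG.

**FP attribution.** A co-predicted pair spanning two different RefOGs $r$
and $s$ is counted as one FP in $r$'s tally *and* one in $s$'s: the
per-RefOG normalization requires every FP pair to be owned by the RefOG(s)
it damages, and a symmetric double attribution is the only choice that
treats both sides alike. A co-predicted pair between a RefOG member and a
gene in no RefOG is one FP for that RefOG; pairs touching no RefOG are
ignored. The brute-force oracle implements the same rule, so the choice is
pinned by tests at both routes.

**Restrictions.** Before any counting, both collections are restricted to
the benchmark gene universe (predicted genes of foreign species — e.g.
outgroup proteomes supplied to one method variant — are dropped with a
logged count) and purged of the low-certainty exclusion list. Scoring with
an exclusion list is exactly equivalent to physically deleting those genes
from every input (tested). RefOGs reduced below two members cannot form
pairs; they are excluded from the sums and reported as unscoreable, since
the $(n-1)$ normalization is undefined at $n = 1$.

**Degenerate aggregates.** If no predicted pair touches any RefOG,
precision is undefined; it is reported as a null sentinel and the F-score
as 0, so empty predictions are never rewarded. Recall is always defined
(every scoreable RefOG contributes at least one reference pair).

**Numerical policy.** Normalized counts are exact `fractions.Fraction`
values and aggregation sums them in sorted-RefOG-label order. This makes
reports byte-stable, results independent of input order, and tercile-wise
subtotals recompose the global P/R/F bit for bit. Floats appear only at
the reporting boundary (shortest round-trip repr in JSON, fixed decimals
in TSV).

**Exactness and diagnostics.** A RefOG is predicted exactly when some
predicted group, after universe restriction and exclusions, equals its
member set. Diagnostics per RefOG: *fragments* (distinct predicted groups
holding ≥ 1 member), *missing* (members assigned nowhere) and *extra*
(non-members sharing the plurality fragment, ties broken by lexicographic
group label). These separate the "oversplitting" failure mode from
individual missing genes.

**Adjusted Rand index.** Both collections are completed over the gene
universe by making unassigned genes singletons, then the standard
chance-corrected pair-counting form is evaluated:
$ARI = (\sum_{ij}\binom{n_{ij}}{2} - E)/(\tfrac12[\sum_i\binom{a_i}{2} +
\sum_j\binom{b_j}{2}] - E)$ with
$E = \sum_i\binom{a_i}{2}\sum_j\binom{b_j}{2}/\binom{n}{2}$. The
implementation is in-package (exact integer arithmetic until the final
division); scikit-learn's `adjusted_rand_score` serves only as an
independent cross-check in the tests. The universe completion matters:
with many background singletons on both sides, agreement on "not grouped"
counts toward the index, which is the intended reading of whole-proteome
partition agreement.

**Overlapping predictions.** Every benchmarked inference method emits
disjoint orthogroups, so overlap is treated as a parsing fault by default
(`strict` policy, error). A `first-wins` policy (lexicographically first
group label keeps the gene, warning logged) is available for deliberately
redundant inputs.

## Stratification

Each RefOG is profiled on four axes with these defaults:

| axis | measure | low | medium | high |
|------|---------|-----|--------|------|
| size | gene count $N$ | $N < 15$ | $15 \le N < 31$ | $N \ge 31$ |
| rate | mean pairwise identity $I$ (%) | $I > 73.8$ | $62.4 < I \le 73.8$ | $I \le 62.4$ |
| quality | norMD score $Q$ | $Q < 0.88$ | $0.88 \le Q \le 1.15$ | $Q > 1.15$ |
| domains | conserved-domain count $D$ | $D \le 1$ | $2 \le D \le 3$ | $D > 3$ |

The fixed cutoffs are the realized terciles of the 70-RefOG benchmark and
are the default; a data-driven scheme ranks the profiled values into
thirds of as-equal-as-possible size, never splitting tied values across a
boundary (ties are absorbed into the lower tercile, so discrete axes may
deviate from a perfect third). On the rate axis the label tracks the
*rate*, so high identity means a low rate. The published low-domain class
is $D = 1$; this implementation labels $D \le 1$ low so that a RefOG with
no conserved domain at all still receives a label.

**Mean pairwise identity** (the "FamID" rate proxy): per sequence pair,
identical residue columns divided by columns where at least one of the two
has a residue; columns gapped in both are ignored. This denominator makes
the measure invariant to all-gap columns and is the conventional reading
of percent identity on an MSA; the exact formula of the originally cited
score is defined in prior literature, so this choice is documented rather
than assumed identical.

**Conserved domains**: domain calls are first filtered to per-domain
independent e-value ≤ 1e-3 (configurable; the source analyses do not print
their threshold), then a family counts as family-specific conserved when
present in ≥ 75% of the RefOG's genes — presence/absence per gene, so
multiple instances of a family in one gene count once for prevalence. The
mean-domain-count measure, by contrast, counts instances.

**norMD is consumed, not computed.** Alignment quality scores come from a
two-column TSV produced by the external NORMD tool; reimplementing that
scoring function is out of scope for this package.

Per-tercile scores re-run the same aggregation on each tercile's subset of
pair counts; because sums are exact rationals, the three terciles of any
axis recompose the global scores exactly (tested bit-for-bit).

## Curation computations

**Gathering threshold.** Hits from an hmmsearch of the RefOG's HMM against
the proteomes are ranked by ascending e-value (ties: descending bit score,
then lexicographic gene ID; a gene hit multiple times keeps its best row).
The worst e-value among the seed members implies a count $k$; the gathered
set is the first $\lfloor 3k \rfloor$ hits of the ranking. The cut is by
rank, not by e-value, so tied e-values straddling the cut are resolved
deterministically. Deliberate over-collection is the point: false family
members are best identified on gene-tree evidence, not e-values. With
multiplier 1 the function returns exactly the seed-implied prefix, a
useful identity for testing.

**Column trimming.** A column is removed iff its gap fraction *strictly*
exceeds the threshold (default 0.5, mirroring TrimAl `-gt 0.5` = "more
than 50% gaps"); a column at exactly the threshold is kept. Short
alignments are conventionally trimmed at 0.75 or left untrimmed — that
judgement is case-by-case and therefore a caller-supplied parameter, not
auto-detected. Trimming is idempotent. The median gap fraction of removed
columns is reported as a sanity statistic.

**Longest-isoform reduction.** One record per gene locus — the longest
protein — with equal-length ties broken by the lexicographically smallest
record ID and output sorted by locus key. The locus is extracted from the
record ID by a user-supplied regex or callable, because isoform naming
conventions differ per source database.

## Synthetic fixtures

The generator emulates the benchmark's *shape*: by default 70 disjoint
RefOGs with sizes drawn from 5–60, spread round-robin (with a seeded
random starting species) over 12 species, plus 200 background genes in no
RefOG. Perturbations inject the observed failure modes — splits, merges,
dropped genes, background contaminants — in a fixed order (split → drop →
contaminate, merges last; merge + split of one RefOG is rejected as
ill-defined). Every output is a pure function of its arguments including
the seed (single `random.Random` stream, fixed draw order).

What the fixtures do **not** emulate: real sequence evolution (no gene
trees, duplications, indels or compositional bias — MSA fixtures are a
mutated ancestor at a controlled per-site substitution rate), real Pfam
architectures (domain tables are planted at chosen prevalences), or real
norMD behaviour (quality scores are uniform draws). Passing tests
therefore demonstrate the correctness of the *scoring machinery* on known
error structure, not the accuracy of any inference method on real
proteomes.

`oracle_score` re-derives every score by literal enumeration of all
$\binom{N}{2}$ gene pairs, sharing no code with the scoring module, and is
guarded to 2,000 genes. The equivalence campaign (200 randomized scenarios
mixing all perturbation modes, exclusions included) asserts exact equality
of every raw count, every normalized count, and the aggregates. At the
full default scale (70 RefOGs of size 5–60 plus background, ≈ 2,300–2,500
genes) the oracle guard is deliberately exceeded; identity-chain checks at
that scale therefore compare against the closed-form perfect scores
instead.

## Problem sizes used in the automated checks

The oracle-equivalence campaign uses 200 scenarios of 3–10 RefOGs (sizes
2–8) over 3–8 species with 5–20 background genes — small enough for exact
all-pairs enumeration while covering every perturbation mode and random
exclusions. The acceptance script scores one full-scale scenario (70
RefOGs, 12 species, ~2,400 genes), verifies oracle agreement on 50
randomized scenarios, and evaluates the one-missing-gene law for every
RefOG size from 2 to 50.

## Known limitations

* The FP double-attribution for cross-RefOG pairs and the
  all-genes-as-singletons universe completion for the ARI are documented
  design choices; alternative conventions (single attribution, ARI over
  assigned genes only) would yield slightly different absolute numbers.
* The package scores orthogroups only; it does not perform ortholog-pair
  benchmarking, hierarchical orthogroup reconciliation, or significance
  testing between methods.
* norMD, MSA inference, tree inference and HMM/BLAST searches are external:
  the package consumes their outputs in standard formats but never runs
  them.
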