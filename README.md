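# ogbench

Pair-based benchmarking of orthogroup inference methods against
expert-curated reference orthogroups.

Orthogroups — the complete sets of genes descended from a single ancestral
gene in the last common ancestor of a set of species — are the foundation
of comparative genomics, and several widely used tools (OrthoFinder,
OrthoMCL, SonicParanoid, Hieranoid, OMA, ...) infer them automatically from
proteomes. `ogbench` is for method developers and evaluators who need to
score such predictions against a curated gold standard of reference
orthogroups (RefOGs) and to understand *where* a method fails: oversplit
families, merged families, missing genes, or contamination.

## The scoring model

For each RefOG with member set $M$, $|M| = n$, every unordered gene pair is
classified against the predicted orthogroups:

* **TP** — both genes of a within-RefOG pair are co-assigned to one
  predicted orthogroup;
* **FN** — a within-RefOG pair not recovered, so $TP + FN = \binom{n}{2}$
  always;
* **FP** — a co-predicted pair $\{g, x\}$ with $g \in M$, $x \notin M$; if
  $x$ belongs to another RefOG the pair is also an FP there (each side's
  view of the same error).

Raw counts are normalized by $n - 1$: a single gene missing from a RefOG
breaks exactly $n - 1$ pairs, so this normalization makes one misplaced
gene cost one unit regardless of RefOG size (pair-count normalization
$\binom{n}{2}$ would bias toward small RefOGs; no normalization toward
large ones). The normalized counts are summed over RefOGs and

$$P = \frac{\sum TP_r/(n_r-1)}{\sum (TP_r + FP_r)/(n_r-1)}, \qquad
  R = \frac{\sum TP_r/(n_r-1)}{\sum (TP_r + FN_r)/(n_r-1)}, \qquad
  F = \frac{2PR}{P+R}.$$

Genes flagged as low-certainty RefOG members are discounted from all pair
counts. Sums are carried as exact rationals, so reports are byte-stable and
stratified subtotals recompose the global scores exactly.

On top of this the package computes: the number of RefOGs predicted
**exactly** (no missing or extra genes, after restriction to the benchmark
gene universe), per-RefOG fragmentation diagnostics (fragments / missing /
extra genes), the **adjusted Rand index** between the two partitions of the
gene universe, and **stratified** P/R/F across four technical-challenge
axes — RefOG size, evolutionary rate (mean pairwise sequence identity),
alignment quality (precomputed norMD scores), and conserved-domain
complexity (Pfam families present in ≥ 75% of a RefOG's genes) — each cut
into low/medium/high terciles.

It also implements the reproducible curation computations: selecting an
HMM gathering e-value threshold so the candidate set is 3× the
seed-implied hit count, trimming alignment columns with more than 50% (or
75%) gaps, and reducing proteomes to the longest isoform per gene locus.

## Worked example

Everything is testable offline: the built-in generator emits a complete
synthetic scenario (per-species proteome FASTAs, reference and perturbed
predicted orthogroups, expected scores from a brute-force all-pairs
oracle):

```bash
ogbench make-fixtures --out demo --n-refogs 8 --species 4 --background 20 --seed 5
ogbench score --refogs demo/refogs.txt --predictions demo/predictions.txt \
              --universe demo/proteomes --ari --out demo/report.json
# WARNING ogbench: precision 100.0%  recall 98.9%  F-score 99.4%  exact 6/8
```

The generated predictions drop one gene from two of the eight RefOGs.
`demo/report.json` then contains:

```
precision 1.0   recall 0.98883   f_score 0.99438   exact_count 6   ari 0.99327
```

and for the first damaged RefOG (44 genes):

```
n 44   tp_raw 903   fp_raw 0   fn_raw 43   tp_norm 21.0   fn_norm 1.0
fragments 1   missing 1   extra 0   exact false
```

which shows the normalization at work: losing one gene of 44 breaks 43 of
the 946 within-RefOG pairs, i.e. exactly **1.0** normalized unit, while
the 43 remaining co-members contribute $903/43 = 21 = n/2 - 1/2$ normalized
TPs. Real predictions are scored the same way; `--dialect
orthofinder-tsv` and `--dialect orthomcl` read the native output formats
of those tools, and `--exclusions` supplies the low-certainty gene list.

Other verbs: `ogbench stratify` (per-tercile scores), `ogbench gather`
(gathering thresholds from hmmsearch tblout), `ogbench trim` (gap-column
trimming), `ogbench reduce-isoforms` (longest transcript variant per
locus).

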