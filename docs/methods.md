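# Methods

## The assay model

The package models NlaIII/MmeI tag-profiling ("DGE") libraries. NlaIII cuts
at CATG; MmeI cuts 17 bp downstream, so every transcript is represented by a
21-nt signature — CATG plus 17 nt — taken, because the protocol retains the
bead-bound 3' fragment, from the **3'-most CATG site** of the sense strand
that has a full 17-nt overhang. Reads are 35 bp: the 21-nt tag followed by
3' adaptor sequence. Genes whose transcripts contain no such site are
invisible to the assay.

Two deliberately different tag views coexist:

* the **simulator** emits only the canonical (3'-most sense) tag per
  transcript, because that is what the chemistry produces;
* the **virtual library** indexes *every* CATG+17 occurrence on *both*
  strands of every transcript, because a mapper must resolve whatever tags
  arrive, including antisense transcription and internal sites.

## Tag cleaning and mapping

Cleaning trims each read at the first exact occurrence of the 3' adaptor
(truncating to 21 nt when the adaptor is absent, e.g. corrupted by a
sequencing error) and keeps the result iff it is exactly 21 nt, starts with
CATG and contains no N. Each rejection class (empty tag, N, bad length,
missing CATG prefix) is counted. There is no quality-score filtering beyond
the N rule.

Mapping is tiered: exact key lookup first; only if that fails, the union of
hits over all 63 Hamming-distance-1 neighbors. Tiering prevents a sequencing
error in another gene's tag from overriding an exact hit. At the accepted
tier: one hit gene → unambiguous; several → ambiguous (mapped, excluded from
gene counts); none → unknown. The partition identity
`unambiguous + ambiguous + unknown = clean_total` is asserted at run time.

Gene expression counts use **sense-strand unambiguous tags only**; purely
antisense tags are tallied separately and feed the strand report
(genes detected sense / antisense / both, and their ratio). A tag hitting
both strands of one gene is still unambiguous and counts as sense.
Coordinates are 0-based transcript positions; genomic positions are out of
scope. TPM is `count / clean_total × 1e6` where `clean_total` is the
library's clean-tag count.

"Expressed collectively" is the union of genes with ≥ 1 sense unambiguous
tag over the three libraries; "expressed in all" is the intersection.

## The exact count test

For counts `x, y` in libraries of sizes `N1, N2`, the conditional
distribution of `y` given `x` is

    p(y|x) = (N2/N1)^y (x+y)! / (x! y! (1 + N2/N1)^(x+y+1)),

algebraically a negative binomial NB(x+1, N1/(N1+N2)); tails are computed
through `scipy.stats.nbinom` (log-space internally), so counts of order 1e4
pose no overflow problem. Two-sidedness doubles the smaller tail, capped
at 1. Because the conditional construction is not orientation-symmetric, the
implementation always conditions on the smaller count (tie broken toward the
smaller library), which makes `p(x, y, N1, N2) = p(y, x, N2, N1)` hold
exactly. P-values that underflow double precision are clamped to the
smallest positive normal float rather than reported as 0. The test suite
checks the implementation against an independent direct log-gamma summation
of both tails over the full grid 0 ≤ x, y ≤ 50.

Multiple testing uses Benjamini–Hochberg step-up (via statsmodels) per
contrast. The default significance rule is FDR ≤ 0.001 **and**
|log2 ratio| ≥ 1; an FDR of 0.05 is an equally supported configuration (both
appear in practice for this protocol family). Log2 ratios add a pseudocount
of 0.5 tags — converted to TPM in the corresponding library — only to sides
that are exactly zero; genes with zero counts in both libraries of a
contrast are not tested.

## Gene action

The differential universe is the set of genes significant in at least one
pairwise contrast (F1 vs P, F1 vs M, P vs M). For each universe gene the
midparent contrast builds a pseudo-library
`N_MP = round((N_P + N_M)/2)` with count
`round((x_P/N_P + x_M/N_M)/2 × N_MP)` and applies the same exact test
against the F1 count, BH-corrected across the universe.

Decision order: (1) F1-vs-midparent not significant → additivity;
(2) F1 significantly above both parents → ODO; (3) below both → UDO;
(4) significant versus exactly one parent → HPD if the matched (non-different)
parent is the higher-expressed by TPM, LPD if the lower (a parental TPM tie
with one significant contrast → other); (5) everything else → other.
The taxonomy is rank-based, so swapping parent labels leaves categories
unchanged.

**Midparent fold-change threshold.** The pairwise rule's |log2 ratio| ≥ 1 is
*not* applied to the midparent contrast by default (its threshold is exposed
as `midparent_lfc_threshold`, default 0). This is forced by arithmetic: a
perfectly dominant gene has F1/MPV = 2f/(f+1) < 2 for any parental fold f,
so any fold cut-off ≥ 1 on this contrast would classify every dominant gene
as additive. Additivity is therefore a statistical statement (the F1 is not
significantly different from the midparent), which also matches published
gene-action tables in which dominance is the largest class.

## Presence/absence and PAV

"Present" means ≥ `presence_min_count` (default 1) sense unambiguous tags —
the assay has no stated detection floor, so one unambiguous tag counts.
The three presence booleans give eight classes; the summary table crosses
hybrid presence with {present only in P, present only in M, absent in both
parents}, with column percentages of that universe and the hybrid
present:absent ratio per parent-specific column. Genes absent everywhere are
excluded from the summary universe. Raising the threshold is monotone: it
can only remove "present" flags.

A PAV (presence/absence variation) gene list — genes present in one parental
genome only — is an input TSV (`gene_id`, `present_in_genome` ∈ {P, M}).
The cross-reference reports, per PAV gene: detection by tags, the presence
class, the F1 expression relation to the parents, the single-parent-plus-
hybrid complementation flag, and the gene-action category when available.
Cases such as "absent in both parents yet expressed in the hybrid" are
reported without interpretation.

## Enrichment

Hypergeometric upper tail P(X ≥ k) for k query hits among K annotated genes
in a universe of N, query size n; terms with no query gene are omitted.
Annotations are flat two-column maps; no ontology-graph propagation. Both BH
FDR values and Storey q-values are always computed; the significance column
follows the per-analysis convention (BH for GO-style analyses, q-values for
pathway-style analyses). π0 uses the fixed-λ plug-in
`min(1, #{p > λ} / (m(1−λ)))` with λ = 0.5 (configurable); when no p-value
exceeds λ the estimate is undefined and falls back to π0 = 1 with a warning,
making q-values equal BH values. The union of the two F1-parent DE sets is
enriched alongside each set separately, since merged pathway universes are a
common but underspecified convention.

## Synthetic data

The generator's defaults emulate the study design the package targets:
three libraries of 4.2 million 35-bp reads; transcripts 300–3000 nt at GC
0.45; a configurable fraction of CATG-free (undetectable) genes; a per-base
substitution error rate of 1%; 5% of reads drawn from the antisense strand
(per read, not per gene — enough to exercise strand accounting); and a
gene-action mode mixture of 9% additive, 23% HPD, 30% LPD, 13% ODO, 23% UDO,
2% other, matching the published proportions among differential genes in a
maize ear trio. True expression levels are drawn log-uniformly from a TPM
range (default 20–2000), with "different" levels separated by `fold_effect`
(default 4; ≥ 2 guarantees |log2 ratio| ≥ 1). Every stochastic operation
takes an explicit seed; outputs are byte-identical for a fixed seed.

Construction notes:

* CATG-free genes are built by rejection-with-repair: a remaining CATG
  occurrence has one base mutated until none remain (pure rejection has
  acceptance probability ~e^(-L/256) and is hopeless at L = 3000).
* Mode relations (e.g. additive F1 = (P+M)/2, ODO F1 = f·max(P, M)) hold
  *exactly* in the truth table. Because every relation is homogeneous of
  degree 1 in a gene's (P, M, F1) trio, genotype columns are normalized to
  1e6 by per-gene trio multipliers (Sinkhorn-style preconditioning plus a
  least-norm correction), which preserves the relations. For mixtures
  containing hybrid-only genes (absent in both parents, expressed in F1) an
  exactly balanced F1 column is structurally impossible — the hybrid column
  necessarily carries extra mass — so the correction is damped to keep all
  multipliers positive and the F1 sum comes as close as that allows. Library
  sampling renormalizes, so this does not affect statistical behavior.
* Reads are sampled multinomially at the given depth over detectable genes
  with positive TPM. Antisense draws use the gene's antisense-strand
  canonical tag; a gene whose reverse complement has no CATG site with a
  17-nt overhang falls back to its sense tag so depth stays exact.
* Reads are emitted in a minimal FASTQ dialect (constant quality "I");
  plain one-read-per-line text is also accepted downstream.

What the simulator does **not** emulate: 3' coverage bias, PCR duplication
structure, variable quality scores, alternative splicing or overlapping gene
models, allele-specific expression, and organellar contamination. Passing
tests on synthetic data therefore demonstrate the correctness of the
algorithms and the statistical calibration of the tests, not robustness to
every artifact of real libraries.

## Problem sizes used in tests and the acceptance script

Read-level end-to-end runs use 60–500 genes at 1e4–1e6 reads per library;
count-level experiments (gene-action recovery, null control) use 2000 genes
at the full 4.2e6-tag depth over 3 (recovery) or 20 (null) seeded
replicates, sizes at which the stochastic acceptance margins (≥ 90%/≥ 95%
recovery, FDP ≤ 0.10) are comfortably stable. The mapping oracle check uses
10,000 library keys × 10,000 query tags against a blockwise all-pairs
Hamming computation.

## Known limitations

* No replicate-aware dispersion modeling: the design pools biological
  replicates into one library per genotype, and the exact test models only
  sampling (shot) noise. Biological variance between replicate pools is
  attributed to expression difference.
* The 1-mismatch neighbor lookup assumes a fixed 21-nt tag; indels are not
  modeled (consistent with the tag chemistry).
* Enrichment treats annotations as flat sets; GO ancestor propagation would
  change K and k.
* The midparent pseudo-library rounds counts; at very shallow depth the
  rounding can dominate the contrast.
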