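# dgetag

Digital gene expression (DGE) tag-profiling analysis for inbred-parent/F1
hybrid trios, built around the NlaIII/MmeI "CATG+17" tag chemistry: each mRNA
contributes a 21-nt tag (the CATG site closest to its 3' end plus the 17
following bases), sequenced as 35-bp reads, and transcript abundance is the
tag count. The package takes three raw tag libraries — two inbred parents P
(B73-like) and M (Mo17-like) and their F1 hybrid — and produces per-gene
differential-expression calls, modes of gene action (the heterosis taxonomy),
presence/absence expression patterns, and term-enrichment statistics. A
seeded synthetic-data generator with full ground truth makes the entire
pipeline testable without any sequencing data.

Intended users: plant/crop transcriptomics groups analyzing heterosis with
tag-based DGE protocols, and anyone needing a tested reference implementation
of the classical two-library exact count test and the gene-action taxonomy.

## The statistics at the core

**Exact count test.** For a gene with `x` tags in a library of `N1` clean tags
and `y` tags in a library of `N2`, significance is judged with the classical
conditional test for digital expression profiles:

    p(y | x) = (N2/N1)^y · (x+y)! / ( x! · y! · (1 + N2/N1)^(x+y+1) )

which is exactly a negative binomial NB(x+1, N1/(N1+N2)) in `y`. The
two-sided p-value doubles the smaller conditional tail (capped at 1); the
test conditions on the smaller count so that it is symmetric in its two
libraries. P-values are corrected per contrast with Benjamini–Hochberg, and
a gene is called differentially expressed when **FDR ≤ 0.001 and
|log2 ratio| ≥ 1** (both configurable). Expression is reported in TPM
(tags per million clean tags): `tpm = count / clean_total × 1e6`.

**Gene action.** Every gene differential in at least one pairwise contrast is
classified from three contrasts — F1 vs P, F1 vs M, and F1 vs the midparent
value MPV = (P+M)/2, realized as a pseudo-library of size
`round((N_P+N_M)/2)` — into:

| category | rule |
|---|---|
| additivity | F1 vs MPV not significant |
| ODO (over-dominance) | F1 significantly above both parents |
| UDO (under-dominance) | F1 significantly below both parents |
| HPD (high-parent dominance) | F1 ≈ higher parent, ≠ lower parent |
| LPD (low-parent dominance) | F1 ≈ lower parent, ≠ higher parent |
| other | anything else (e.g. strictly intermediate) |

**Enrichment.** Gene sets are tested against flat annotation maps with the
hypergeometric upper tail P(X ≥ k); results carry both BH FDR values and
Storey q-values (fixed-λ plug-in estimate of π0).

## Worked example

Simulate a 500-gene trio at one million tags per library and run the whole
pipeline (a YAML config with the same block works via
`dgetag run-all --config cfg.yaml --outdir out`):

```python
from dgetag import PipelineConfig, run_pipeline

cfg = PipelineConfig(simulation={"n_genes": 500, "depth": 1_000_000}, seed=11)
res = run_pipeline(cfg, "out")
print(res["gene_action_summary"])
```

prints (among the stage logs):

```
{'total': 499, 'additivity': 51, 'non_additivity': 448,
 'HPD': 120, 'LPD': 130, 'ODO': 55, 'UDO': 133, 'other': 10,
 'pct_additivity': 10.2, 'pct_non_additivity': 89.8, 'pct_HPD': 24.0,
 'pct_LPD': 26.1, 'pct_ODO': 11.0, 'pct_UDO': 26.7, 'pct_other': 2.0}
```

499 of the 500 simulated genes were differential somewhere in the trio, and
the recovered category mix tracks the generator's default mode mixture
(9% additive, 23% HPD, 30% LPD, 13% ODO, 23% UDO, 2% other — at this depth a
handful of genes land in a neighboring category). `out/` also contains the
expression table, per-contrast DE tables, presence/absence summaries and the
run log; the first gene-action rows look like

```
gene_id  category  pattern
GENE001  HPD       B73 < Mo17 ≈ F1
GENE002  UDO       F1 < B73 ≈ Mo17
```

where the pattern string orders the three genotypes by expression with `≈`
marking a non-significant contrast.

CLI verbs for individual stages: `simulate`, `clean`, `buildlib`, `map`,
`de`, `gene-action`, `presence`, `enrich`, `run-all`.

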