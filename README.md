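# chromstate

Chromatin-state segmentation and broad-H3K4me3 analysis for CUT&RUN +
RNA-seq count data, built around the two-cell-type design used to profile
early porcine development (fetal fibroblast vs. trophectoderm cell lines).

Starting from binned read counts for H3K4me3, H3K27ac, H3K27me3 and BRG1
(with an IgG control), the package:

1. **normalizes** tracks by spike-in scale factors `C / spike-in reads`;
2. **binarizes** pooled counts with a Poisson tail rule — bin `b` is called
   for a mark iff `P(X >= count_b) <= p` with
   `X ~ Poisson(max(global mean, scaled control))`;
3. **segments** the genome with a multivariate Bernoulli-emission hidden
   Markov model (`P(obs | state k) = prod_m E[k,m]^x (1-E[k,m])^(1-x)`),
   learned by Baum-Welch EM over per-chromosome sequences and decoded by
   posterior argmax into K = 10 chromatin states;
4. **labels and annotates** states (TSS Active / Flanking / Bivalent,
   enhancer, repressed, quiescent) from emissions and TSS fold enrichment,
   and assigns genomic feature categories (promoter bands, exon, intron,
   downstream, distal intergenic) to intervals;
5. **detects broad TSS domains** — maximal TSS-state runs spanning >= 4 kb,
   the class associated with cell-identity genes;
6. **ranks cell-type-specific genes** by a leave-category-out Welch
   t-statistic on TMM-normalized log2(CPM+1), flagging the top decile;
7. **tests overrepresentation** of gene sets with the one-sided Fisher
   exact test and Benjamini-Hochberg FDR, and provides the 2^-ddCt qPCR
   utility.

A first-class synthetic-data module generates a complete miniature study —
genome, gene models, ground-truth state paths with planted broad and
cell-type-specific genes, Poisson mark counts, spike-ins, negative-binomial
expression — so every stage runs and is testable without any downloads.

## Worked example

Run the full pipeline on the default synthetic study (2 chromosomes x 2 Mb,
400 genes, 2 cell types):

```bash
chromstate run-all --seed 1 --out runs/demo
# ... stage logs on stderr ...
# run complete: runs/demo
```

or from Python:

```python
import chromstate as cs
cs.run({"seed": 1}, "runs/demo")
```

`runs/demo/` then contains the learned model (`model.tsv`), per-cell-type
state segmentations (`segments_*.bed`, names like `1_TSS_Active`), state
labels and enrichment tables, TSS-region tables with `is_broad` flags,
specificity rankings, enrichment results and an overlap report. For seed 1
the overlap report reads:

```
cell_type	broad_and_specific	broad_total	pct_broad_specific	k4me3_sites	k4me3_overlapping_k27ac
PFF-like	8	13	61.53846153846154	386	380
PTr2-like	7	13	53.84615384615385	387	380
```

meaning 13 genes carry broad (>= 4 kb) TSS-state domains per cell type, 7-8
of which are also in that cell type's top-decile specific genes (54-62%),
and nearly all H3K4me3 call runs overlap an H3K27ac run — the signature of
active promoters. The enrichment table ranks the planted
`developmental_process` term first:

```
term	k	K	n	N	p	q
developmental_process	13	20	13	400	8.76e-20	2.72e-18
```

i.e. all 13 broad-domain genes fall in the planted 20-gene developmental
term out of a 400-gene universe.

Stages can also be run standalone on each other's outputs — see
`chromstate --help` and the subcommands `simulate`, `normalize`,
`binarize`, `learn`, `decode`, `label`, `annotate`, `tss-regions`,
`specificity`, `enrich`, `ddct`.

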