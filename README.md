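# dualqtl

Bulk-segregant (X-QTL) mapping of *trans*-acting loci that affect the mRNA
production and the protein abundance of the same gene, measured
simultaneously in single live yeast cells with a dual fluorescent reporter
(mCherry ∝ mRNA production, GFP ∝ protein abundance).

In an X-QTL experiment, millions of recombinant haploid segregants from a
BY×RM cross are sorted by FACS: the ~3% of cells with the highest and the
lowest fluorescence in a channel form two pools, which are sequenced in
bulk. A locus that affects the sorted trait shows an allele-frequency
difference between the pools,

    ΔAF = AF_high(BY) − AF_low(BY),

where positive ΔAF means the BY (reference) allele increases expression.
Statistical support comes from a binned hidden-frequency model: within each
pool the unobserved allele frequency follows a Markov chain along the genome
(recombination fraction r = min(0.5, d/(2,200 bp/cM · 100)) over a gap of
d bp; transition mean p + r(1−2p), variance r(1−r)/N for effective pool
size N = 1,000) with binomial read-count emissions per 100-bp bin. The
per-bin LOD contrasts unconstrained pool frequencies against equality at
that bin, computed as a Savage–Dickey ratio of the two posterior frequency
distributions — so evidence aggregates across linked bins, which is what
makes 13× coverage sufficient. Peaks above LOD 3 get 2-LOD support
intervals, are merged across replicates within 75 kb, and pass at a
stringent LOD ≥ 4.5 calibrated by a replicate-null FDR,
FDR(thr) = (N_nullQTL/N_null) / (N_signalQTL/N_signal). Finally, each
gene's mRNA-QTLs and protein-QTLs are paired by confidence-interval overlap
and every locus is classified as **concordant** (same ΔAF sign in both
channels), **discordant** (opposite signs), **mRNA-specific** or
**protein-specific** — the signature of buffering and post-transcriptional
regulation.

The package ships a synthetic-cross simulator (meiosis at 2,200 bp/cM,
correlated single-cell reporter phenotypes with planted QTLs of all four
classes, cell-size-coupled fluorescence, 3% tail sorting of gated cells,
Poisson-13× pooled sequencing), so every stage of the pipeline is testable
against ground truth without any download. Intended users are statistical
geneticists working with pooled-sequencing designs and anyone who wants a
transparent, tested reference implementation of the sort-and-sequence
mapping stack.

## Worked example

Simulate one gene with all four planted QTL classes, map both channels,
and classify:

```python
from dualqtl.pipeline import (classify_study, map_gene_channel,
                              simulate_study, summarize_classes)

study = simulate_study(seed=1)          # 4 planted loci, 50,000 segregants
maps = {ch: map_gene_channel(study.pools[ch]) for ch in ("mRNA", "protein")}
loci = classify_study(maps["mRNA"], maps["protein"], gene=study.gene)
print(loci[["chrom", "pos_mrna", "pos_protein", "lod_mrna", "lod_protein",
            "delta_af_mrna", "delta_af_protein", "qtl_class"]].round(3))
```

prints

```
 chrom  pos_mrna  pos_protein  lod_mrna  lod_protein  delta_af_mrna  delta_af_protein        qtl_class
  chrI  250450.5     260450.5    18.094       24.687          0.288             0.354       concordant
 chrII       NaN     248450.5       NaN       26.501          0.022             0.353 protein_specific
chrIII  246450.5          NaN    28.447          NaN          0.395             0.005    mrna_specific
 chrIV  216450.5     256450.5    27.935       13.325          0.366            -0.239       discordant
```

Each row is one locus. The generator planted one QTL per class at position
250,500 of its chromosome; all four are recovered within ~35 kb with their
planted class. The concordant locus raises both reporters for the BY allele
(ΔAF +0.29 / +0.35); the protein-specific locus moves GFP (+0.35) but
leaves mCherry at noise level (+0.02, extracted from the mRNA tracks at the
protein peak without any significance requirement); the buffered
mRNA-specific locus is the mirror image; and the discordant locus pushes
mRNA up (+0.37) while the net protein effect is negative (−0.24).
`summarize_classes(loci)` reports the class counts (1/1/1/1) and the
direction-agreement statistic (3/4 same sign, exact binomial p = 0.625).

The same pipeline is available from the shell: `dualqtl simulate`,
`dualqtl map`, `dualqtl classify`, `dualqtl fdr` (see `--help`; all
thresholds and windows are flags with the defaults above).

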