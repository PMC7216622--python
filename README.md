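# icgec

Epigenetic conservation scoring of genes and histone marks between two
cell types.

When a stem cell differentiates, some genes keep their chromatin state
while others remodel it. `icgec` quantifies this per gene and per histone
mark from multi-mark ChIP-seq peak data: given the peak files of two cell
types, it assigns every gene a **gene score** and every mark a **mark
score** in [−1, 1], where values near +1 mean a fully conserved
epigenetic context and values near 0 (or below) mean the context has
substantially changed. It is aimed at comparative epigenomics analyses of
paired conditions — stem vs. derived cell types, matched tissues,
perturbation vs. control — built on processed peak calls such as the
Roadmap Epigenomics BroadPeak releases.

## The method

For each condition, a genes × marks *epigenetic circumstance matrix*
`G2M` is built: the level of mark *m* on gene *g* is the weighted peak sum

```
level(g, m) = Σ_p (L_p · S_p) / L_g
```

over all peaks *p* of mark *m* intersecting the gene's region (by default
2 kb upstream of the TSS through the TTS), where `S_p` is the peak's
signalValue, `L_p` the peak–region overlap length and `L_g` the region
length. After aligning the two matrices on shared genes and marks,
dropping genes with zero signal in at least half the marks, a log2(x+1)
transform, and per-mark / per-gene z-scaling, the core algorithm iterates:

1. **Gene contexts** `G2G^C`: weighted Pearson correlations (wPCC)
   between every pair of gene rows, weighted by the current mark weights
   `w_m`, clipped below at 0.
2. **Inner loop over genes**: each gene's score is the wPCC between its
   two context rows under the current gene weights `w_g`; the clipped
   scores become the next `w_g`, iterated to a fixed point.
3. **Mark contexts** `M2M^C` from the gene-scaled matrices, weighted by
   the converged `w_g`.
4. **Inner loop over marks**, symmetric to step 2.
5. Repeat 1–4 until both weight vectors stabilize.

Genes and marks whose contexts are conserved earn large weights and
dominate the comparison; the converged raw correlations are reported as
the gene and mark scores (unclipped, so mildly negative scores are
possible and meaningful). Setting all mark weights equal and skipping
step 4 recovers the simpler iterative co-expression comparison (ICC).

Downstream utilities classify genes into epigenetically dynamic/conserved
quartiles (EDG/ECG), test their overlap with differentially expressed
gene sets by size-preserving permutation, call
differentiation-direction-specific and -ubiquitous genes (DDSG/DDUG) via
Shannon entropy over per-direction scores, and compare per-mark
cross-condition dynamics between gene groups.

## Worked example

Score a simulated pair of 200 genes × 8 marks in which 20% of genes carry
a planted epigenetic perturbation:

```python
import icgec
from icgec import synthetic

m1, m2, truth = synthetic.generate_paired_matrices(
    n_genes=200, n_marks=8, frac_dynamic=0.2, seed=7)
pair = icgec.normalize_pair(m1, m2)
result = icgec.run_icgec(pair)

print("converged:", result.converged, "after", result.n_outer, "outer iterations")
print("mean gene score:", round(result.gene_scores.mean(), 3))
print(result.gene_scores.nsmallest(5).round(3).to_string())

edg, ecg = icgec.classify_edg_ecg(result.gene_scores)
dyn = set(truth.dynamic_genes)
print(f"EDG: {len(edg)} genes, {sum(g in dyn for g in edg)} of the "
      f"{len(dyn)} planted dynamic genes")
```

prints

```
converged: True after 3 outer iterations
mean gene score: 0.936
g0140   -0.249
g0147    0.259
g0196    0.341
g0126    0.396
g0086    0.491
EDG: 50 genes, 39 of the 40 planted dynamic genes
```

The mean score near 1 reflects that most genes are conserved between the
two simulated conditions; the five lowest-scoring genes are all planted
dynamic genes, and the bottom-quartile EDG class recovers 39 of the 40
perturbed genes.

The same pipeline runs from files via the `icgec` command:

```
icgec simulate --mode toy-genome --seed 1 --out toy/
icgec build-matrix --genes toy/genes.bed --genes-format bed \
    --mark mark0=toy/c1_mark0.broadPeak --mark mark1=toy/c1_mark1.broadPeak \
    --mark mark2=toy/c1_mark2.broadPeak --mark mark3=toy/c1_mark3.broadPeak \
    --out c1.tsv
# ... same for condition 2 ...
icgec normalize --m1 c1.tsv --m2 c2.tsv --out-prefix pair
icgec run --pair-prefix pair --out scores.tsv
```

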