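# coexmod

Weighted gene co-expression network analysis (WGCNA-style) for staged bulk
RNA-seq designs, built for the kind of question asked in developmental
transcriptomics: *which co-expression module, and which hub gene inside it,
tracks a maturation process across ordered sample groups?* The motivating
setting is a fetal skin time course (7 gestational stages × 3 replicates of
FPKM-normalized expression) in which the module peaking at the late,
mature-follicle stages is selected and screened for hub genes.

## The method

Starting from a genes × samples matrix X (FPKM, log2(x+1)-transformed by
default):

1. **Network.** Pearson correlation r_ij between all gene pairs; soft
   threshold to an adjacency a_ij = |r_ij|^β (unsigned, default) or
   ((1+r_ij)/2)^β (signed). β is chosen as the smallest power whose
   scale-free topology fit R² (regression of log₁₀ frequency on
   log₁₀ connectivity over 10 equal-width bins, negative slope) exceeds
   0.8, with a flagged plateau fallback when no power qualifies.
   Connectivity is k_i = Σ_{j≠i} a_ij.
2. **Topological overlap.** TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)
   with ℓ_ij = Σ_u a_iu a_uj, computed blockwise.
3. **Modules.** Average-linkage (UPGMA) clustering of 1 − TOM; a static or
   dynamic-hybrid tree cut with a minimum module size of 50; module
   eigengenes (ME) as the sign-oriented first principal component of each
   module's standardized expression; iterative merging of modules whose
   eigengenes correlate above 0.85; size-ranked color names (turquoise,
   blue, brown, …; unassigned genes are grey).
4. **Target module and hubs.** The target module maximizes the mean ME over
   a designated sample set (e.g. the last two stages). Per gene,
   kME = cor(gene, ME) with a two-sided Student-t p-value
   (t = r·√(n−2)/√(1−r²)); hubs are module genes with k ≥ k_min **and**
   kME ≥ kme_min (defaults 900 and 0.9; a `--k-quantile` alternative exists
   for data on other scales).
5. **Enrichment and nomination.** One-sided hypergeometric tests of the hub
   set against user-supplied GMT gene sets, Benjamini–Hochberg adjusted
   within namespace (BP/CC/MF/pathway); the final nominee(s) are the genes
   present in *all* selected GO terms and in ≥ `pathway_min` selected
   pathways.
6. **Concordance.** `spearman_concordance` scores two expression series by
   Spearman's |Rs| with the usual qualitative bands (>0.8 extremely strong,
   >0.6 strong, >0.4 medium, >0.2 weak).

A synthetic-data generator (`coexmod.synthetic`) plants all of this
structure — module profiles over stages, per-gene membership r_g via the
mixture gene = r_g·profile + √(1−r_g²)·noise, a late-peaking target module,
background genes, and annotation terms with a known unique multi-term
nominee — so the whole pipeline is testable against ground truth.

## Worked example

Simulate the default planted design (7 stages × 3 replicates, five 200-gene
modules with kME ∈ [0.6, 0.95], 500 background genes) and run everything:

```sh
coexmod simulate --out demo/fx --seed 7
coexmod --verbose run-all \
  --expression demo/fx/expression.tsv --sample-sheet demo/fx/samples.tsv \
  --out demo/out --k-min 0 \
  --gmt demo/fx/modules.gmt:BP --gmt demo/fx/go_terms.gmt:BP \
  --gmt demo/fx/pathways.gmt:pathway \
  --select-go GO_TARGET0 --select-go GO_TARGET1 --select-go GO_TARGET2 \
  --select-pathway PATHWAY0 --select-pathway PATHWAY1 --select-pathway PATHWAY2
```

which logs:

```
INFO coexmod: read: genes=1500, samples=21
INFO coexmod: filter: kept=1500, dropped=0
INFO coexmod: log_transform: base=2, pseudocount=1
INFO coexmod: pick_power: power=8, plateau_fallback=True
INFO coexmod: network: power=8, type=unsigned, genes=1500
INFO coexmod: cut_tree: modules=5, unassigned=497
INFO coexmod: merge_modules: modules=5, sizes={'turquoise': 207, 'blue': 202, 'brown': 200, 'yellow': 199, 'green': 195}
INFO coexmod: target_module: module=turquoise, n_target_samples=6
INFO coexmod: hub_screen: module=turquoise, k_threshold=0.0, kme_threshold=0.9, k_only=166, kme_only=0, both=41
INFO coexmod: enrichment: terms=11, significant=7
INFO coexmod: intersection: final_genes=['M0_G0189']
```

Reading the log: no power reached scale-free R² > 0.8 on this planted
(deliberately non-scale-free) network, so the flagged plateau power 8 was
used; the five planted modules were recovered at close to their true sizes
with the 500 background genes left unassigned; the late-peaking module
(turquoise, 207 genes, 193 of them from the planted target module) won the
eigengene ranking over the 115/135-day samples; 41 of its genes passed
kME ≥ 0.9; and the one gene planted into all three GO terms and all three
pathways (`M0_G0189`) came out as the unique intersection nominee. All
tables land in `demo/out/` as TSV with a `manifest.json` of SHA-256
checksums; a rerun with the same seed is byte-identical.

The same stages are available as library calls (`correlation_matrix`,
`soft_adjacency`, `tom_similarity`, `cut_tree`, `merge_close_modules`,
`select_target_module`, `kme_with_p`, `screen_hubs`, `hypergeom_enrich`,
`intersect_terms`) and as the subcommands `network`, `modules`, `hubs`,
`enrich`.

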