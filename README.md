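# phycorg

Comparative analysis of brown-algal (Phaeophyceae) organellar genomes:
mitogenomes and plastomes of *Sargassum* and its relatives in Fucales,
Ectocarpales and Laminariales.

Organellar genomes of congeneric brown algae are small, gene-dense and
nearly collinear, so the informative signal sits in fine-grained
statistics rather than in gross structure: codon-usage bias, predicted
C→U RNA-editing sites, the repeat census, single-nucleotide sites that
diagnose a subgenus, section or species from one sequence, and per-gene
Ka/Ks. `phycorg` implements that analysis stack as a library plus a thin
CLI, together with a truth-known synthetic-genome generator so every
detector can be validated end to end without downloading data.

## What it computes

- **Architecture** — gene inventories by class (PCG/tRNA/rRNA/ORF/tmRNA),
  coding fraction, pairwise gene overlaps and intergenic-spacer totals on
  circular coordinates; gene order anchored at any gene; Venn-style gene
  content comparison across orders.
- **Codon usage** — relative synonymous codon usage
  RSCU(c) = observed(c) / (family total / family size); positional GC
  (GC1, GC2, GC3, GC12); Wright's effective number of codons
  Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ with
  F̂ = (nΣp̂² − 1)/(n − 1) per synonymous family; the mutation-only
  expectation Nc = 2 + GC3 + 29/(GC3² + (1 − GC3)²); the neutrality
  regression of GC12 on GC3; PR2 coordinates G3/(G3+C3) vs A3/(A3+T3);
  and ΔRSCU optimal codons from the top/bottom ENC deciles
  (optimal: RSCU > 1 in the high-expression pool and ΔRSCU ≥ 0.08).
- **RNA editing** — homology-guided prediction of C→U sites: a genomic C
  is called edited when the C→T change converts the encoded amino acid
  into the one conserved in ≥ threshold of an aligned homolog panel
  (default 0.8) while the unedited amino acid falls below it; sites are
  classified into hydropathy categories (unchanged hydrophilic /
  hydrophobic, became hydrophilic / hydrophobic) from a pinned
  transition-type table with a Kyte–Doolittle fallback.
- **Repeats** — perfect microsatellites (1–6 bp units, MISA-style
  thresholds 10/6/5/5/5/5), tandem repeats (deterministic, exact
  detection of maximal intervals with k-spaced match fraction ≥ 0.8,
  span ≥ 14 bp, periods ≤ 200), and maximal exact dispersed repeat pairs
  ≥ 30 bp in forward, reverse, complement and palindromic orientation.
  Circular molecules are scanned on the doubled sequence.
- **Diagnostic SNPs** — codon-aware ortholog alignment, SNP calling with
  synonymous/non-synonymous classification against the panel-majority
  codon, and diagnostic-site identification: an allele fixed within a
  group and absent outside it, at subgenus, section or species rank.
- **Ka/Ks** — the Li–Wu–Luo degeneracy-class counting method (LWL) and a
  modified form (MLWL) that weights two-fold sites by the observed
  transition/transversion ratio and reassigns the transversion-degenerate
  Arg first positions and Ile third positions; Kimura two-parameter
  correction per class; pathway averaging for multi-hit codons.
- **Phylogenetic summaries** — shared-gene supermatrices, p-distances,
  neighbor-joining trees (Newick), and average-linkage clustering of
  RSCU vectors.
- **Synthetic data** — `phycorg.simulate` generates circular annotated
  genomes with a Fucales-style layout (35 PCGs, 25 tRNAs, 3 rRNAs,
  2 ORFs, 188 bp of planned overlap, 1,597 bp of spacer), configurable
  codon bias, and planted repeats, editable codons, clade-diagnostic
  SNPs and divergence with a chosen dN/dS — each with an exact truth
  record.

## Worked example

```python
from phycorg.simulate import SimConfig, generate_genome, plant_edit_panel
from phycorg.genome import extract_cds
from phycorg.architecture import summarize_genome
from phycorg.codon import count_codons
from phycorg.editing import predict_edits, summarize_edits

genome, truth = generate_genome(SimConfig(seed=1, planted_edits=80))
cds = extract_cds(genome)

s = summarize_genome(genome)
print(genome.length, s.spacer_total, s.overlap_total)

table = count_codons(cds)
print(table.total, round(table.rscu()["TTA"], 2), table.rscu()["ATG"])

panels = plant_edit_panel(cds, truth, seed=5)
sites = [x for c in cds for x in predict_edits(c, panels[c.gene], 0.8)]
es = summarize_edits(sites, genome.length)
print(es.total, round(es.density_percent, 2))
```

prints

```
34729 1597 188
8745 2.61 1.0
80 0.23
```

— a 34,729-bp circular mitogenome whose intergenic spacers total
1,597 bp and whose gene overlaps total 188 bp; 8,745 sense codons with
the planted preference for UUA (RSCU 2.61) and the unbiased AUG
(RSCU exactly 1); and all 80 planted C→U editing sites recovered, an
editing density of 0.23% of the genome.

The same stages run from the shell:

```sh
phycorg simulate --seed 1 --edits 80 -o out/
phycorg summarize out/synthetic-mt.gb -o out/
phycorg codon out/synthetic-mt.gb -o out/
phycorg repeats out/synthetic-mt.gb -o out/
```

Multi-genome stages (`snps`, `kaks`, `tree`, `all`) take several GenBank
files and a `--reference` where relevant; every stage writes TSV reports
and a JSON manifest into the output directory.

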