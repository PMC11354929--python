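# Methods

This note documents the models, conventions and numerical choices behind
`phycorg`, and what the synthetic-data validation does and does not show.

## Genome model and coordinates

Coordinates are 1-based inclusive (the GenBank convention). A feature on
a circular molecule may cross the origin; internally it is normalized to
an ordered interval list (`join(900..1000,1..50)` → `[(900,1000),(1,50)]`)
kept in biological order, so feature length, CDS extraction and span
arithmetic are rotation-invariant. Strand `-` means the coding sequence
is the reverse complement of the interval (the organellar "light chain").
Ambiguity codes are legal in sequences but are excluded from GC content
(numerator and denominator) and any codon containing one is dropped from
codon statistics with a logged warning. The translation table defaults
to 1 (the standard code, which brown-algal organellar PCGs use) and is
configurable per feature.

Architecture bookkeeping: the union of all feature spans plus the
intergenic-spacer total tiles the genome exactly. Overlaps are counted
once per unordered pair of distinct named genes; the protein-coding
fraction uses the union of PCG spans so overlapping genes are not double
counted; annotated intron features count toward gene spans (they are not
spacer) but not toward coding coverage.

## Codon-usage suite

*RSCU* is observed count over the uniform-use expectation within each
synonymous family; families never observed are reported missing rather
than zero, so downstream clustering can skip them pairwise. Single-codon
families (Met, Trp) have RSCU exactly 1 whenever observed.

*ENC* follows Wright: per-family homozygosity F̂ = (nΣp̂² − 1)/(n − 1)
for families with n ≥ 2 observations and F̂ > 0; class means over family
sizes 2/3/4/6; Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, clamped to
[20, 61]. A missing class mean (most often the lone 3-fold Ile class) is
imputed from the mean of the available 2- and 4-fold class means,
Wright's own rule; if neither is available ENC is undefined and the gene
is excluded from expression pools. Genes under 30 codons are flagged as
short but not excluded.

*Optimal codons*: genes are ranked by ENC; the top and bottom deciles
(⌈0.10·N⌉ genes, ENC ties broken by gene name for determinism) form the
expression pools. The lowest-ENC decile is taken as the high-expression
pool — strongest bias read as highest expression, the standard assumption
behind the ΔRSCU method — with a flag to invert. A codon is optimal when
its RSCU in the high-expression pool exceeds 1 and
ΔRSCU = RSCU_high − RSCU_low ≥ 0.08. The RSCU > 1 condition is applied to
the high-expression pool.

The neutrality fit is ordinary least squares of GC12 on GC3 (scipy); the
slope is read as the mutation-pressure share of codon-usage variation.
PR2 coordinates are G3/(G3+C3) and A3/(A3+T3) over third-position base
counts with stop codons excluded; a zero denominator yields an undefined
coordinate rather than an error.

## C→U editing prediction

The predictor is homology-guided: only non-synonymous C→T candidates are
scorable, because a synonymous edit leaves the protein unchanged and is
invisible to homologs; edits that would create a stop are not proposed.
A site is predicted when the edited amino acid matches at least a support
threshold of the panel at the aligned column while the unedited amino
acid stays below it. The threshold defaults to 0.8 (must exceed 0.5 so
the two conditions cannot both hold); raising it can only remove
predictions, which is tested as a monotonicity property. Panel columns
gapped in ≥ 50% of members are skipped; when the usable column count does
not equal the query length the translation is globally aligned to the
column-majority consensus, and an identity floor (default 0.5) guards
against mis-orthology.

Classification into hydropathy categories uses a pinned lookup of
(reference → edited) amino-acid pairs reproducing the published
organellar edit-type blocks — including R→W kept with the hydrophobic
"unchanged" block although arginine is conventionally hydrophilic — so
published summary percentages are reproducible; pairs outside the lookup
fall back to the sign of the Kyte–Doolittle index and are flagged
`extrapolated`. Summaries report percentages over the actual site count.

## Repeat detectors

*SSRs*: maximal perfect runs of primitive 1–6 bp motifs with per-unit
copy thresholds {1:10, 2:6, 3:5, 4:5, 5:5, 6:5} (MISA defaults; the unit
thresholds are configurable). The motif is reported in first-occurrence
phase, and a run strictly contained in a longer run of the same unit
length (a phase-shifted reading of the same repeat) is suppressed.

*Tandem repeats* are found by a deterministic, exact rule rather than a
probabilistic alignment: for period k, an interval qualifies when its
k-spaced match fraction is ≥ the match probability (default 0.80), both
boundary comparisons match, and its span is ≥ max(14, 2k) bp; maximal
qualifying intervals are reported, with intervals contained in a kept
call at a divisor period dropped and a phase-consensus agreement fraction
reported per call. The 14-bp minimum span corresponds to the smallest
tandem repeats reported in brown-algal plastomes. Indels are not
rescued — an insertion interrupts a repeat — so counts from gapped
finders are reproduction attempts, not guarantees; the `indel_prob`
parameter is accepted for interface compatibility only. The detector is
O(n·max_period) via prefix sums and is verified against an O(n²)
direct enumeration.

*Dispersed repeats*: all maximal exact pairs ≥ 30 bp in four
orientations (forward, reverse, complement, palindromic = reverse
complement), found by seed-and-extend on 30-mers against the transformed
sequence; self-pairings and zero-gap forward duplicates (which belong to
the tandem detector) are excluded. Circular molecules are scanned on the
doubled sequence with coordinates reduced mod L, so origin-spanning
repeats are found once.

## Diagnostic SNPs

Ortholog alignment is codon-aware: equal-length congeneric CDS align
positionally; unequal lengths align at the protein level against the
longest sequence and thread nucleotides back, so gaps come in multiples
of three. Columns containing any gap are excluded from SNP calling
(indels are not SNPs); a multi-allelic column is one SNP site. The
synonymous/non-synonymous effect substitutes each allele into the
panel-majority codon at the column (ties broken toward the
alphabetically first codon, deterministic).

A site is diagnostic for group G at a rank iff all members of G share one
allele (monomorphism inside G) and that allele is absent outside G — the
only predicate under which one sequence identifies the group. Singleton
groups are allowed (species-level identification).

## Ka/Ks

Both variants classify every codon position into fold classes by how
many of the three alternative bases preserve the amino acid (0-fold,
2-fold, 4-fold; the 3-fold Ile positions join the 2-fold class by
convention), average site counts over the two sequences, split observed
differences into per-class transition (P) and transversion (Q)
proportions — multi-difference codons averaged over substitution
pathways that avoid stop intermediates — and apply the Kimura
two-parameter correction per class
(A = ½ln 1/(1−2P−Q) − ¼ln 1/(1−2Q), B = ½ln 1/(1−2Q)).

LWL combines them with the equal-rate weights:
Ks = (L₂A₂ + L₄K₄)/(L₂/3 + L₄) and Ka = (L₂B₂ + L₀K₀)/(2L₂/3 + L₀).

MLWL replaces the 1/3 weight of two-fold sites with R/(R+1), R being the
observed transition/transversion ratio, and treats the sites whose
degeneracy runs through transversions separately instead of forcing them
into the transition-degenerate mould: Arg first positions (CGA/CGG/
AGA/AGG; one synonymous transversion; site weight 1/(2R+2), half the
transversion distance synonymous), the ATA third position (both
transversions synonymous, weight 1/(R+1)), and ATT/ATC third positions
(transition plus one transversion synonymous, weight (2R+1)/(2R+2)).
When no transversion (or no transition) is observed the weights go to
their limits; when neither is observed the sequences are identical and
the weights are moot. These equations are pinned in the implementation
as the package's reading of the modified method's published principles.
Saturation (a non-positive logarithm argument) flags the pair rather
than dropping it; Ks = 0 yields a missing ratio rather than infinity.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions of a Fucales
mitogenome: 35 PCGs + 25 tRNAs + 3 rRNAs + 2 ORFs (65 genes), 26,340 nt
of protein-coding sequence (8,780 codons including starts and stops),
twelve planned gene overlaps totalling 188 bp, 1,597 bp of intergenic
spacer, background GC 0.365, five light-chain PCGs, and a
trnS–trnD–trnA–rps10 block in the gene order. Codon bias favours
A/U-ending codons 4:1 with an extra boost for UUA and GUU (the strongly
preferred Leu/Val codons), and each gene draws a bias-strength exponent
from [0.4, 1.6] so ENC varies across genes and expression pools are
non-trivial. Everything is a deterministic function of the seed.

Planted features carry exact truth: repeats are wrapped in mismatching
guard bases so each is maximal at exactly its recorded span; editable
codons are substituted at recorded codon positions and the homolog panel
encodes the edited amino acid at those columns; clade panels plant
single-base substitutions at chosen degeneracy classes (four-fold third
positions for synonymous changes, amino-acid-changing positions
otherwise, one per codon, plus-strand genes only) so effect and
diagnostic status are exact by construction.

Divergence with a planted dN/dS is generated in the degeneracy-class
currency the estimators measure: the substitution budget is split so the
non-synonymous/synonymous event-rate ratio equals ω with respect to the
ancestor's LWL site counts (S = L₂/3 + L₄, N = L₀ + 2L₂/3), and each
event is drawn uniformly from single-base changes whose bookkeeping is
unambiguous on both sides (truly synonymous at four-fold sites or as
two-fold transitions; truly non-synonymous, non-stop, at zero-fold sites
or as two-fold transversions), at most one hit per codon. This makes
"recovering ω" a well-posed consistency check of the counting machinery.

What passing these tests does **not** show about real data: real
organellar sequences have compositional heterogeneity along genes,
overlapping reading frames, indels, genuine multiple hits and
transition/transversion bias that the generator idealizes away; tandem
and dispersed repeat counts from heuristic gapped tools will differ from
the exact detectors here; and homolog panels built from real alignments
carry correlated (phylogenetic) noise, not the independent per-column
noise the panel generator uses.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic data:
a full-size 34.7-kb mitogenome for architecture/codon/editing checks, a
14-genome clade panel (197 planted sites, 89 non-synonymous) for SNP
checks, detector-vs-oracle equivalence on 100 seeded sequences of
200–600 bp per detector, and dN/dS recovery from 30 pooled replicates of
500 codons at 120 substitutions each per ratio. RSCU family sums are
checked to 1e-9, ENC against an independent re-implementation to 1e-9,
qualifying-fraction comparisons in the tandem detector use a 1e-9 slack
on the cumulative score, and ENC/RSCU never include stop codons or
ambiguous codons. Deterministic tie-breaks: ENC pool ties by gene name;
majority codons by alphabetical order; NJ input taxa sorted.

## Known limitations

- The ortholog aligner is reference-anchored at the protein level; for
  distant homologs with complex indel structure a dedicated MSA tool is
  the right choice, and the 50% identity floor will refuse clearly
  non-orthologous input rather than align it badly.
- Bayesian tree inference is deliberately out of scope; the NJ and
  RSCU-cluster trees are sanity summaries, not posterior estimates.
- The tandem detector's exactness is a design choice; it will undercount
  degenerate (indel-containing) tandem arrays relative to gapped finders.
- MLWL's transition/transversion weighting uses the realized substitution
  ratio, which confounds mutation with selection at extreme ω; estimates
  at ω ≫ 1 are noticeably noisier than at ω ≤ 1.
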