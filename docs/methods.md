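# Methods

This note documents the models and procedures behind `nbs-profiler`, the
defaults they use, and what the synthetic-data validation does and does not
demonstrate.

## Identification and classification

Candidate NBS genes are assumed to come from two permissive upstream
searches (profile-HMM and protein homology, both at E ≤ 1.0; these searches
are outside the package boundary and their cutoff is kept in `Thresholds`
as provenance metadata only). `merge_candidates` takes the case-sensitive
union, and `verify_nbs` retains genes with at least one NBS (NB-ARC) domain
call at **E ≤ 10⁻⁴** in the domain-annotation table. Candidates absent from
the table are treated as lacking the domain and dropped with a warning.

Architecture classification follows a fixed evidence precedence
**RPW8 > TIR > CC**. A coiled-coil counts as present only at predictor
score ≥ **0.5**, because CC domains are unreliably detected by profile
search. The nine subclasses are the full/partial domain combinations
(CNL, CN, NL, N on the CC side; TNL, TN, NL, N on the TIR side; RNL).
The bare `NL`/`N` architectures carry no N-terminal evidence, so their
group membership is decided by the terminal residue of the kinase-2 motif:
tryptophan (W) is the non-TNL signature, aspartate (D) the TNL signature.
When no kinase-2 hit is available the gene defaults to the CNL group and
is flagged low-confidence. An RPW8 call without LRR is still labelled RNL
(logged); in practice RNLs carry the complete RPW8–NBS–LRR architecture.

## Motif scanning and order analysis

MEME-style de-novo discovery is replaced by scanning a curated,
configurable library of the eight canonical NBS motifs, expressed as
position-specific residue classes (widths 9–12, within the conventional
6–50 aa range). Scoring is +1 per position whose residue falls in the
class; the hit threshold is **80% of the width** (stored per motif in the
YAML so it can be tuned). Overlapping candidate windows are resolved
highest-score-first with leftmost tie-breaking, which makes output
deterministic. This is a deliberate design choice: the downstream analyses
— motif order and the kinase-2 terminal residue — depend only on motif
locations, not on rediscovering position weight matrices, and a library
scan removes an external binary. The library consensus strings are seeded
from the canonical NBS motif literature but are not a reconstruction of
any particular study's PSSMs.

Order verdicts partition genes with ≥ 2 distinct motifs:

- **conserved** — distinct motif names forming a subsequence of the
  canonical order (P-loop, RNBS-A, kinase-2, RNBS-B, RNBS-C, GLPL, RNBS-D,
  MHDL);
- **flanked_repeat** — an intact contiguous core in canonical order with
  every outside occurrence repeating a motif already in the core;
- **core_change** — anything else (the core order itself deviates).

Genes with fewer than two distinct motifs are *insufficient*.

## Cluster calling

"Gene cluster" is operationalised as transitive gap-chaining: per
chromosome, position-sorted genes join the current locus when the gap
between a gene's start and the locus's rightmost end so far is at most the
window (**250 kb** default; gaps are floored at 0 for overlapping genes).
Because the running end is the locus maximum, the partition equals the
connected components of the graph joining every gene pair whose pairwise
gap is within the window — the test suite asserts this equivalence against
a union-find oracle on 1,000 random instances, and monotonicity in the
window size. Loci with ≥ 2 members are clusters; locus ids follow natural
chromosome order. Genes on unassembled contigs (`chromosome ==
"unplaced"`) are split off before calling and reported separately.

## Gene structure and comparative statistics

Exon counts and genomic lengths come straight from the GFF3 gene models
(genes without exon features are treated as single-exon, with a warning
path). Correlations are Pearson product-moment with the two-sided t-test
(df = n−2); the cross-species correlation relates genome size (Mb) to
total NBS-gene count over the packaged 13-species census (missing RNL
entries count as 0). Whether the original census used Pearson or Spearman
is not documented; Pearson is assumed, consistent with a bivariate
correlation procedure. Subfamily contrasts use one-way ANOVA with Tukey
HSD (statsmodels) and a compact-letter display computed from maximal
cliques of the "not significantly different" graph at α = 0.05. Printing
conventions: r to 2 decimals, percentages to 1, means to 2.

## Ka/Ks estimation (NG86)

`kaks_ng86` implements Nei–Gojobori (1986) counting with Jukes–Cantor
correction:

- **Sites.** Per codon position, the synonymous fraction of the one-step
  nucleotide changes, computed over changes that do not create a stop
  codon; N = 3·codons − S, so N + S is conserved exactly.
- **Differences.** For each differing codon pair, all minimal substitution
  pathways are weighted equally; pathways through stop codons are excluded
  (if every pathway is blocked, all are used). Site and difference counts
  are averaged over the two sequences; gap/ambiguous codons are skipped
  pairwise.
- **Correction.** K = −(3/4)·ln(1 − (4/3)p) for both classes; p ≥ 3/4 is
  reported as saturated/undefined, as is ω when Ks = 0.

Per-codon site counts and per-pair difference counts are precomputed, so
the estimator is O(L) per pair. The test suite checks the counting against
an independently coded exhaustive pathway enumerator on *all* sense-codon
pairs and 1,000 random short alignments. Note that stop-codon conventions
differ between published NG86 implementations; the convention above
(stops disregarded in both site and pathway counting) is applied
consistently in the estimator, the oracle and the simulator.

Two estimator behaviours worth knowing:

- At ~7% nucleotide divergence the mean estimate of a planted ω = 0.3 over
  200 replicates of 1,000 codons is within ±0.02 of truth; the residual
  upward drift grows with divergence (multiple-hit correction error).
- The *mean of per-pair ratios* over short pairs (≈300 codons) is biased
  upward by roughly +0.03–0.05, a small-sample ratio (Jensen) effect.
  Calibration tests therefore use 1,000-codon pairs.

**Pair selection.** Analyzable pairs need ≥ 100 aligned aa and identity in
[0.40, 0.99]; both genes must be classified. The ceiling reproduces the
exclusion of near-identical conserved families (e.g. an RNL quartet) by a
lower divergence limit — within-genome homologs are paralogs, and this
window is the package's operationalisation of an "ortholog lower limit"
that the original analyses do not specify precisely. The subfamily
contrast reports group means of defined ω values and a Welch two-sample
test (the original test behind the CNL-vs-TNL contrast is unspecified;
Welch is the robust default).

## Duplication typing

A simplified, self-contained re-implementation of MCScanX-style rules over
a per-chromosome gene-rank map (ranks count *all* annotated genes, not
just NBS genes):

1. **wgd_segmental** — membership in a collinear block: chains of homolog
   anchors, grouped by chromosome pair, consistent in rank order on both
   segments (one fixed direction per chain), rank gaps ≤ 25, and ≥ 5
   anchors per block. Same-chromosome anchors within the proximal bound
   are local duplicates, not collinearity evidence, and are skipped —
   otherwise a tandem array would chain into a spurious "block".
2. **tandem** — homolog on the same chromosome within rank distance ≤ 2
   (at most one intervening gene).
3. **proximal** — same chromosome, rank distance ≤ 10.
4. **dispersed** — any remaining homolog.
5. **singleton** — no homolog above thresholds.

The priority order (wgd > tandem > proximal > dispersed) is the only
mechanism deciding genes with multiple evidence types, and a targeted test
fixture asserts this. The chaining is greedy rather than MCScanX's scored
dynamic programming; on desk-scale planted blocks the two agree, but the
simplification is not expected to be bit-compatible with MCScanX on dense
real genomes.

## Expression

FPKM[g,s] = 10⁹·C[g,s]/(N[s]·L[g]) with L the *exonic* (summed-exon)
length — whether the original pipeline used exonic or full gene length is
not stated; exonic is the standard choice. N[s] should be the true
per-sample mapped-fragment totals; the within-matrix column sums are only
a fallback when the matrix covers the whole transcriptome. Expression
categories come from the per-gene **maximum** FPKM across samples
(0 not detected; < 3 very low; 3–30 low; > 30 intermediate/high): the
maximum, rather than the mean, is used because one strongly expressed
sample is what marks a gene as intermediate/high. Tissue assignment is the
argmax of per-tissue mean FPKM, ties resolved rind > flesh > seed and
flagged. Heatmap export is log₂(FPKM+1), genes ordered by group then id.

## Synthetic data

The generator plants every structure the pipeline measures, with defaults
mirroring a small perennial-plant NBS family of 73 genes in a 16-chromosome
genome:

- **Composition** — subclass counts 31 CNL / 13 CN / 4 NL / 2 N (CNL
  group), 5 TNL / 1 TN / 10 NL / 3 N (TNL group), 4 RNL; largest-remainder
  apportionment for non-default sizes. Noise-free domain calls match each
  subclass exactly.
- **Geometry** — 12 cluster loci of sizes 7/6/4/4/4/3/3/2/2/2/2/2
  (41 genes), internal gaps below the 250-kb window, all other loci
  separated by more than the window; 9 genes on unplaced contigs.
- **Duplication families** — 33 tandem (rank-adjacent), 9 proximal (4
  background genes between members, hence rank distance 5, but spaced
  beyond the cluster window), 29 dispersed (partners on different
  chromosomes; unplaced genes pair with placed partners), 2 WGD genes
  embedded in mirrored runs of 6 background anchor pairs. Tandem families
  that do not fit the cluster spec are placed rank-adjacent but widely
  spaced.
- **Sequences** — per family, a 300-codon protein layout carrying the
  motif-library consensus in canonical order (14 genes get a leading
  duplicate P-loop → flanked_repeat; 2 genes get kinase-2/RNBS-B swapped →
  core_change; 7 and 5 conserved genes lose P-loop and GLPL respectively,
  matching motif-presence counts of 66/68 in a 73-gene family), reverse
  translated and evolved from a common ancestor.
- **Codon evolution** — a simple Markov scheme: uniform proposals over
  (codon, position, base), stop codons rejected, nonsynonymous:synonymous
  acceptance ratio ω:1, substitutions split binomially between the two
  branches. Only the rate ratio is controlled; there is no
  transition/transversion or codon-usage structure. Family ω defaults:
  CNL 0.31, TNL 0.42; RNL families evolve ~2 substitutions so their pairs
  exceed the 0.99 identity ceiling and drop out of Ka/Ks, as the
  conserved helper class does. Motif codons are *frozen* (synonymous
  change only), modelling the strong purifying constraint on functional
  motifs; as a result genome-wide NG86 means sit below the per-family
  input ω (≈0.26 vs 0.31 and ≈0.33 vs 0.42 at the defaults) while the
  CNL < TNL contrast is preserved. The unconstrained calibration
  simulations recover ω without this attenuation.
- **Kinase-2 residues** — planted per gene: W in 48 of 54 non-TNL genes, D
  in 13 of 19 TNLs (the NL/N subclasses are forced to their
  group-consistent residue so classification remains exact).
- **Exon structure** — planted per-group multisets totalling 249 exons
  (means 3.24 / 3.63 / 4.50 for CNL/TNL/RNL; 36 of 50 CNL-group genes
  with < 3 exons), exonic length fixed at 900 bp (the CDS length), introns
  drawn 200–4,000 bp. Exon-count/length correlation in generated genomes
  is therefore strongly positive — higher than real annotations, where
  exon sizes vary.
- **Counts** — negative binomial (shape 5, i.e. variance μ + μ²/5) with
  log-normal library-size factors around 2×10⁷ fragments; base FPKM 1.4
  (seed), 1.5 (flesh) and a rising rind profile 1.2→3.0; 7 silent genes;
  each expressed gene prefers one tissue (rind 46/66, seed 16/66, flesh
  4/66, boost ×2.5) and one planted gene has true rind FPKM 50 in the
  three late stages. The tissue boosts make absolute grand means higher
  than the base profile; the generator controls ordering and preferences,
  not absolute tissue means.

Everything is driven by one seed; a fixed seed gives byte-identical GFF3,
FASTA, TSV and JSON outputs (asserted by test).

**What passing on synthetic data shows — and what it does not.** Recovery
of planted structure validates the decision rules and their
implementations under the stated statistical model. It does not establish
performance on real annotations, where domain calls are noisy, cluster
geometry is not separated by clean margins, homology is continuous rather
than family-structured, and substitution processes have rate
heterogeneity. The domain-annotation table is deliberately noise-free in
the default configuration because subclass recovery is specified as exact
under noise-free evidence.

## Problem sizes used in the validation suite

Acceptance-style checks run at: all 61×61 sense-codon pairs plus 1,000
random ≤3-codon alignments for the NG86 oracle; 200 replicates of
1,000-codon pairs at 200 substitutions for ω recovery; 1,000 random
instances for the cluster oracle; 100 simulated genomes for duplication
recovery (≥ 95% required); 10 genomes for exact subclass recovery; 1,000
null data sets (3 groups × 20) for ANOVA type-I calibration. These sizes
give Monte-Carlo standard errors comfortably below the tolerances being
checked.

## Known limitations

- The motif library is a stand-in with fixed consensus classes, not
  empirically fitted PSSMs; recall on strongly diverged real NBS domains
  will be below the synthetic 100%.
- Collinearity detection is greedy chaining, not scored DP; no E-value
  model, no inversion-splitting beyond one direction per chain.  On
  sparse rank maps (few genes per chromosome, as in the scaled-down
  simulations) the rank-gap bound is permissive, so a dispersed homolog
  pair that happens to fall on a collinear block's chromosome pair with
  consistent ordering can occasionally be absorbed into the block and
  typed as WGD; this is the dominant residual error mode in the
  duplication-recovery simulation.
- NG86 only; no maximum-likelihood or γ-rate Ka/Ks models, no dating.
- Codon evolution has no indels; Ka/Ks inputs are pre-aligned codon
  pairs.  A protein-guided global codon aligner (`align_codons`, BLOSUM62)
  is provided as a convenience utility but is not a curated
  multiple-alignment workflow.
- FPKM only; no TPM or model-based normalisation, no differential
  expression testing.
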