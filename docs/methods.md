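# Methods

## Problem and model

`linspec` implements the comparative-genomics procedure for identifying
lineage-specific (orphan) genes in a focal plant species and characterizing
them. A focal proteome is partitioned by a staged homology filter:

1. **Stage 1 — outside-clade filter.** Every protein is searched against
   outside-clade genomic sequences and transcript assemblies
   (TBLASTN-style: the protein against all six translation frames of the
   nucleotide subjects). A gene with at least one hit at E < 1e-5 (strict
   inequality) in *any* outside-clade database is **evolutionarily
   conserved (EC)**.
2. **Stage 2 — within-clade filter.** The remainder is searched against
   transcript assemblies from clade relatives. A hit makes the gene
   **clade-specific**; no hit anywhere makes it **species-specific**.
3. **Stage 3 — knowledgebase rescreen.** Both lineage-specific sets are
   searched (BLASTP-style) against a protein knowledgebase whose records
   carry clade-membership taxonomy. A hit to a non-clade record promotes
   the gene to EC; a species-specific gene whose only support is a clade
   record moves to clade-specific. Transfers only ever move outward,
   toward broader conservation. Curated review is modelled as an explicit
   list of `ReassignmentDecision` records (auto-accepted by default), so
   the bookkeeping is reproducible and auditable; re-applying an applied
   decision list is a no-op.

The three labels partition the input at every stage; this invariant is
asserted at run time.

### Search statistics

The built-in desk-scale search backend computes optimal Smith–Waterman
local alignments with affine gaps (BLOSUM62, gap open 11, extend 1; a
length-k gap costs 11 + k) via Biopython's `PairwiseAligner`, and converts
raw scores S to expectations with the Karlin–Altschul formula
E = K·m·n·e^(−λS) using the published gapped defaults K = 0.041,
λ = 0.267 nats per score unit (m = query length, n = database length;
translated length n/3 for nucleotide databases). Alignments in translated
frames never cross a stop codon: frames are split at `*` and segments
scored independently, mimicking HSP behaviour. Per (query, subject, frame)
only the best alignment is kept — classification needs the existence of a
significant hit, not HSP sets. Segments too short to reach the score a
cutoff demands (bounded by the matrix's largest diagonal entry times the
segment length) are skipped; this is exact, not heuristic. A tabular
12-column (outfmt-6-like) reader lets genome-scale external search output
drive the classifier in place of the built-in backend.

## Characterization analyses

* **Genic features.** Exon counts; exon/intron/gene/CDS/protein lengths;
  GC of gene, exons, introns, CDS and the three codon positions. N bases
  are excluded from both numerator and denominator of GC; GC over zero
  informative bases is missing, never 0. Summaries report mean, sample SD
  (n−1) and median; exon/intron lengths are pooled over all features in a
  set by default (a per-gene-mean mode exists). Sets are compared with
  Welch's unequal-variance t-test (Welch–Satterthwaite df, two-sided) or
  a 2×2 chi-square without continuity correction.
* **Paralogous families.** Peptide regions ≥ 75 aa not covered by curated
  domain annotations are clustered into "novel domains" by single-linkage
  over pairwise alignments (> 45% identity over ≥ 75 aligned columns,
  E < 1e-3, all-vs-all). Families are connected components of the graph
  linking proteins that share any domain id; an identical-composition
  grouping mode is available but linkage is the default, since strict
  composition grouping would separate multi-domain relatives.
* **Segmental duplication.** Similar pairs (all-vs-all, E < 1e-10, at most
  5 subjects per query, deduplicated unordered) are chained on the genomic
  dot-plot by dynamic programming: unit score per pair, coordinates
  strictly increasing on both axes, chains broken when either-axis gap
  exceeds 100 kb, chains under 4 pairs discarded, the trivial
  self-diagonal excluded. Chains are extracted greedily best-first without
  pair reuse, and blocks are bounded by their first/last member genes.
  Unit scoring keeps the brute-force chain-enumeration oracle exact.
* **Co-expression and GO.** The co-expression threshold r\* is the 99th
  percentile of Pearson correlations over randomly sampled gene pairs
  (signed r, not |r|; sampled rather than all ~n² pairs, default 10⁶,
  seeded). Neighbours of a focal gene are all genes with r > r\* (strict).
  GO annotations with evidence codes IEP, IEA or RCA are removed before
  enrichment. Per-term enrichment is a one-sided Fisher exact test with
  Storey q-values: π₀ from the λ-grid 0.05…0.95 (step 0.05) with a cubic
  smoother extrapolated to λ→1, clipped to (0, 1]; Benjamini–Hochberg
  (π₀ = 1) is used for lists under 100 p-values, where the smoother is
  unstable. Five manually curated functional groups can be tested for
  over-representation among lineage genes versus background at FDR 1%.
* **Methylation density.** Methylcytosines per 100 bp in three
  gene-relative regions: 500 bp upstream, the coding region, and 500 bp
  downstream. "Coding region" is the genomic span from first to last CDS
  base of the representative model (introns in the denominator), because
  methylation calls are genomic; a spliced mode is available and flagged.
  Flanks are transcriptional (strand-aware) and truncated at chromosome
  ends with densities over the truncated length; calls on both strands are
  pooled, with CG/CHG/CHH context carried through.
* **SNP consequences.** Sites are reduced to biallelic ones (distinct
  non-N bases across reference + accessions equal to exactly two;
  monomorphic sites counted separately). Coding SNPs are assigned codon
  coordinates after splicing (splice first, then index codons; trailing
  partial codons skipped with a warning); minus-strand alternates are
  complemented. Synonymous means the mutated codon encodes the same amino
  acid (stop→stop included). Densities are per 100 bp of spliced CDS. The
  set-level non-synonymous:synonymous ratio defaults to the ratio of mean
  per-gene densities on unrounded means, with a total-count mode also
  reported; a SNP whose stated reference base conflicts with the genome
  FASTA is rejected.
* **Localization.** Per-isoform predictions (compartment + Reliability
  Class, 1 = best) collapse to gene level: lowest RC among
  Chloroplast/Mitochondrion/Secretory predictions wins; distinct
  compartments tied at that lowest RC give Uncertain (two isoforms
  agreeing on the same compartment at equal RC are not a tie); no
  targeting prediction at all gives Other. Per-compartment enrichment is a
  2×2 chi-square of each set against its complement.

Printed percentages everywhere use round-half-up to one decimal.

## Representative models and coordinates

Coordinates are GFF3 1-based inclusive throughout; strand-aware
"upstream" is transcriptional. One isoform per gene drives every per-gene
statistic: the annotation's representative flag if present, else the
longest-CDS isoform, ties broken by lexicographically smallest isoform id
(annotation releases rarely document their rule; this one is deterministic
and close to common practice). A CDS whose length is not divisible by 3 is
kept, flagged, and translated over its longest in-frame prefix — silently
dropping such genes would skew set counts.

## Synthetic data: what it emulates, and what it does not

The generator plants known ground truth for every analysis:

* **Genomes.** 70 EC / 20 clade-specific / 10 species-specific genes by
  default, on one chromosome, with 1–4 exons, 60–200 bp introns,
  600–1000 bp intergenic spacers (room for 500 bp flanks), proteins of
  80–200 aa built from random codons (ATG start, single terminal stop).
  EC genes get homologs in 3 outgroup databases (45% divergence) and 3
  clade databases (20%); clade genes only in clade databases; species
  genes nowhere. Divergence is the per-residue **amino-acid** substitution
  probability: homologs are mutated at protein level and back-translated
  with random codons. This pins down the protein identity that the
  translated searches see, so the two tiers create a clean detectability
  gap (outgroup homologs at ~55% identity remain detectable for a
  ~150 aa protein, while chance similarity between unrelated proteins
  stays far above E = 1e-5). A nucleotide-level substitution model would
  couple the tiers to codon structure and put the outgroup tier at the
  detection margin.
* **Expression.** 500 genes (the focal genes plus unannotated background)
  × 50 experiments; 5 planted modules of 10 genes loading 0.9 on a shared
  latent factor with unit total variance; GO terms coherent within modules
  plus background annotations, ~20% of which carry excluded evidence
  codes so the filter is exercised. The compendium is deliberately much
  larger than the module content so the resampled null percentile is not
  contaminated by planted signal — matching a genome-wide compendium in
  miniature.
* **Methylome.** Bernoulli calls at every cytosine (either strand) of each
  gene's three regions, at per-bp rates of 0.005/0.01/0.005
  (upstream/coding/downstream) for EC genes and twice that for both
  lineage-specific sets; context read from the local sequence.
* **SNPs.** 20 accessions; sites placed in spliced CDS with a target
  non-synonymous:synonymous ratio (default 1.0) achieved by drawing the
  desired class first and rejection-sampling sites against the codon
  table — the class is held fixed across site retries, since redrawing it
  on failure would bias toward the easier non-synonymous class. 5%
  multi-allelic sites and 10% N calls are injected to exercise the
  filters.
* **Localization.** Per-isoform compartment draws with label-dependent
  probabilities (secretory 0.45 for clade-specific vs 0.20 for EC,
  mirroring the kind of enrichment the analysis is meant to detect); RC
  drawn from a decreasing distribution; optional forced equal-RC ties for
  the Uncertain rule.

All draws come from `numpy.random.default_rng(seed)`; outputs are
byte-identical per seed. What the generator does **not** emulate: indels
and rearrangements, phylogenetically correlated divergence, linkage
disequilibrium among SNPs, array-normalization artifacts, and hierarchical
GO term structure. Passing tests therefore demonstrate the correctness of
the pipeline's logic and statistics under its stated model, not
performance on real annotations, where gene-structure errors and
assembly incompleteness dominate false classification.

## Numerical choices and problem sizes

* E-value thresholds compare strictly (<); the score bound used to skip
  hopeless segments is exact under the scoring matrix.
* Welch's test returns p = 1 when both sides are constant and equal;
  chi-square errors on a zero row/column.
* The null-threshold estimator requires ≥ 1000 sampled pairs and ≥ 10
  genes with ≥ 3 observations; correlations are pairwise-complete and
  undefined (missing) under zero variance, never 0.
* Analyses in the test-suite and acceptance script run at desk scale —
  100-gene genomes, 5 classification seeds, 10 000 planted SNPs, 200 000
  sampled null pairs, 10 000 null t-tests — sizes chosen so each
  Monte-Carlo check has comfortable margins around its tolerance.
* Chain extraction is O(n²) dynamic programming per chromosome pair,
  adequate for the pair counts the 5-subjects-per-query rule produces.

## Known limitations

* The built-in search backend is exhaustive Smith–Waterman without
  heuristic seeding, composition-based statistics or sum statistics over
  multiple HSPs; at genome scale one substitutes real BLAST tabular
  output through the provided reader.
* The published gapped Karlin–Altschul constants are used for all scoring
  configurations; changing the matrix or gap penalties without updating
  K and λ shifts the absolute E-value scale (the classifier's behaviour
  depends only on the cutoff, which is configurable).
* Whether the historical analyses computed exon statistics pooled or
  per-gene, included introns in "coding region" denominators, or used
  count vs density-mean SNP ratios is not documented; each choice here is
  a documented default with the alternative available as a mode.
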