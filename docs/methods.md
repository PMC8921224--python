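# Methods

This note documents the models, parameter choices and numerical behaviour
of the package, including what the synthetic-data generator does and does
not emulate.

## Coordinates and containers

All coordinates in the data model are 1-based inclusive, matching GFF3 and
methratio conventions; BED/bedGraph writers convert to 0-based half-open
at the boundary. Methylomes are pandas DataFrames sorted by
(chromosome, position, strand) with at most one record per cytosine
position and strand; CG sites are kept per strand (no symmetric-site
merging), since the upstream extraction operates per cytosine. Gene exons
are the union over transcripts (overlapping exon intervals are coalesced),
which also defines the union-exon length used for FPKM.

## Methylome model

A cytosine's context is derived from the reference: CG if the next base
(5′→3′ on the cytosine's strand) is G; CHG if the next base is H (A/C/T)
and the second base is G; CHH if both are H. Positions whose context is
undeterminable (N neighbour, chromosome end) are excluded, and records
whose stated context disagrees with the genome are dropped with a logged
count.

* **Coverage filter**: ≥ 4 effective (bisulfite-informative C+T) calls per
  position, applied uniformly before all downstream computation —
  including the level comparisons — since the source procedure does not
  state a narrower scope. "Coverage" is the effective C+T column, not raw
  depth, because that is what methratio-style output provides.
* **Weighted level**: pooled counts Σ C / Σ (C+T) over a region and
  context ("C" pools all three contexts). Regions without informative
  calls are *undefined* and propagate as missing, never as 0, to avoid
  deflating sparse windows. Track output rounds to 4 decimals.
* **Non-conversion**: the all-context weighted level of the
  organelle-flagged chromosomes. The methylation-free comparison tests
  |level(nuclear) − level(organelle)| against 3 combined binomial SEs.

## Methylation-category classifier

Backgrounds p_bg are pooled per region class (body, promoter, downstream)
and context across all expressed genes, clamped into [1e-6, 1−1e-6] so a
degenerate all-zero background remains testable. Each gene contributes:
per-context body, exon-only and intron-only counts, and per 500-bp
promoter/downstream bin pooled-context counts; the bin with the maximum
pooled level is the tested unit (n = 0 bins rank lowest; ties go to the
gene-proximal bin; max-bin selection carries no extra multiplicity
correction beyond the gene-level BH, matching the described procedure).
Untestable regions (n = 0) get p = q = 1 — absence of coverage reads as
absence of methylation evidence.

The one-tailed binomial p is P(X ≥ k) with X ~ Bin(n, p_bg); BH families
are one per (region class, context) across the expressed-gene set. The
decision order is teM → gbM → pM → dM → UM; teM precedence over gbM is
forced by gbM's requirement of non-significant CHG/CHH, and pM precedence
over dM by dM's requirement of a non-significant promoter. The
Intron-teM/Other-teM split uses intronic CHG/CHH significance alone
(default); the stricter intron-and-not-exon reading is available as
`intron_rule="intron_not_exon"`. Promoters overlapping a neighbouring gene
are not trimmed.

## Differential expression engine

The engine is a deliberate stand-in for DESeq2 (which covers the same
ground), accepted on calibration properties rather than bit-equivalence;
the test suite cross-checks log2 fold changes and significance calls
against pydeseq2 on a small panel.

* **Normalisation**: median-of-ratios size factors over the contrasted
  samples (library-size fallback for degenerate matrices).
* **Dispersion**: per-feature pooled within-group method-of-moments
  estimates, moderated by a trend α(μ) = a0 + a1/μ fitted with a Huber
  M-estimator (plain OLS is wrecked by the heavy right skew and leverage
  of 4-d.o.f. moment estimates). The per-feature dispersion is clipped
  into [0.9, 2.0] × trend: the lower bound guards against variance
  underestimates; the upper bound discards overshoots that would
  needlessly deflate power. Null simulations (2,000 features, n = 3 vs 3,
  dispersion 0.1) give type-I error 0.04–0.06 at nominal 0.05 across
  seeds.
* **Wald test**: group means fitted as (Σ counts + 0.5)/Σ size factors
  (the 0.5 pseudocount keeps zero groups finite without moving
  well-covered estimates); the SE comes from the NB Fisher information
  with weights μ/(1 + αμ). All-zero features are excluded from testing
  and from the BH family.
* **DE thresholds**: FC > 2 (genes, TEs, non-annotated), FC > 4
  (antisense), padj < 0.01, applied to the Wald log2FC estimate.

## Regulation patterns

Features with full DE status in *mddcc* are classified by their behaviour
in the single mutants. A single-mutant response counts as *mild* when the
unadjusted Wald p < 0.01 with a change in the same direction and no
fold-change floor: a "mildly increased" gene is precisely one whose shift
need not reach the DEG threshold, and the call is per feature within the
mddcc-DE subset rather than a genome-wide screen, so the raw p-value is
the appropriate scale. δ = 1 log2 unit (configurable) separates "further
increased" (Dosage) from "comparable" (mCG / non-mCG); comparability is
checked before the dosage gaps when both could apply. Down-regulated
features are classified on mirrored fold changes. Features fitting no rule
are Unclassified.

## Intron-teM 3′ screen

The split intron is the intron with the maximum pooled non-CG weighted
level. Counts are summed over replicates; genes with WT 5′ < 10 are
excluded. The statistic log2[(3′/5′ mutant)/(3′/5′ WT)] is computed from
exact integer cross-products, making it exactly invariant to scaling both
parts of one genotype. A mutant 5′ (or WT 3′) of zero leaves the gene
unflagged with an explicit reason; mutant 3′ = 0 flags at −∞. The screen
reports both the mddcc-only and the any-mutant flag tallies, which answer
different questions about where 3′ transcripts are lost.

## TE insertion caller

The alignment backend is exact substring search with a uniqueness check,
adequate for the kilobase-scale synthetic genomes the package ships; real
data enters as SAM produced by an external aligner. "Uniquely maps" means
exactly one exact-match location over both strands; multi-mapping
segments are discarded. Extremities are 300 bp (truncated non-overlapping
halves for shorter TEs), strand-normalised; clip matches must be
end-anchored (the TE terminus is the extremity terminus) and ≥ 20 nt, and
an equally long match to a second TE is flagged ambiguous and excluded
from calling. Recursive clipping trims the genomic remainder 1 nt at a
time from the junction side down to 20 nt.

Clusters group same-(chromosome, TE, extremity) breakpoints within 100 bp
(configurable; the source procedure does not state a window). A cluster's
interval is the min–max span of its members' genomic alignments; an
insertion is called when two ≥ 4-read clusters from opposite extremities
overlap by 4–19 bp, the overlap being the TSD. With clean junction reads
the left-flank footprints end at the last duplicated base and the
right-flank footprints start at the first, so the overlap equals the TSD
exactly; junction-adjacent mismatches shorten the recovered footprint and
can shrink the reported TSD. Filters: within 3 kb of a centromere span or
chromosome end, within 500 bp of an N-run (runs of ≥ 4 N), or TSD
intersecting the donor TE's own span.

## Synthetic-data generator

The generator is the package's acceptance harness; it emulates the
*statistical structure* of the study inputs, not sequence realism.

* **Genome**: random nucleotides; gene slots of two 400-bp exons and one
  400-bp intron, pitched so no gene's 2-kb flank overlaps a neighbour's
  (planted promoter/downstream signals stay attributable to one gene); a
  TE zone of distinct random TEs with intact extremities; a 2-kb N block
  as centromere analog; an insertion target zone; a 20-kb organelle
  control chromosome.
* **Methylomes**: WT levels are painted per planted category — gbM body
  CG 0.3; teM body CHG/CHH (and CG) 0.3, placed in introns for Intron-teM
  and in exons for Other-teM so the two planted classes are identifiable
  under the intron-significance rule; pM/dM one random 500-bp bin at 0.4;
  background CG 0.05, CHG/CHH 0.02. Genotypes erase contexts (ddcc:
  non-CG ×0; met1: CG ×0 and non-CG ×0.7, mirroring the mild non-CG
  reduction seen when CG maintenance is lost — toggleable; mddcc: all ×0).
  Observed rates are nonconversion + (1 − nonconversion) × level with
  nonconversion 0.004; coverage is 1 + Poisson(mean − 1), mean 20, so the
  ≥ 4 filter has bite. Methylation is binomially sampled per site —
  read-level bisulfite errors, mapping bias and duplicate structure are
  not modelled, so passing tests demonstrate the *decision logic*, not
  robustness to alignment artifacts.
* **Counts**: gamma-Poisson NB with Var = μ + αμ², α = 0.05, n = 3
  replicates per genotype; planted patterns use log2 effects
  (ddcc, met1, mddcc): Redundancy (0,0,3), DosageI (0,1.5,3),
  DosageII (1.5,0,3), DosageIII (1.2,1.2,3), mCG (0,3,3),
  non-mCG (3,0,3) at mean 500 over a null background at mean 200. Planted
  features are kept a minority of each panel (≈ 12%) because
  one-directional shifts in a large fraction of features bias
  median-of-ratios normalisation. Intron-teM genes emit separate 5′/3′
  part counts with a 5-fold planted 3′ depletion in selected genotypes,
  plus genes planted below the WT 5′ ≥ 10 filter.
* **Reads**: junction-spanning reads (10 per side by default, 100 nt,
  genomic portion 25–75 nt) are emitted as unmapped-with-sequence records
  paired with a properly mapped genomic mate; background proper pairs
  cover the reference. Boundary negatives (TSD 3 or 20 bp, 3 supporting
  reads) and filter decoys (2.5 kb from the chromosome end, inside the
  donor span) are planted on request and marked in the truth file.
* Every generator is a pure function of (config, seed); identical seeds
  reproduce identical bytes.

## Problem sizes

The test and acceptance runs use: a 2,004-gene genome (~11 Mb) for
classifier recovery and a 2,000-gene all-background genome for the
false-positive control; 2,000 features for DE null calibration; a
1,200-gene panel with 150 planted patterns for pattern recovery; a
~200-kb genome with 5 recoverable planted insertions plus 3 boundary
negatives and 2 filter decoys for the caller. These sizes give the
recovery and calibration statistics comfortable margins (e.g. the
pattern-recovery estimate has SE ≈ 2 points at 150 planted features)
while the whole acceptance run stays around a minute.

## Known limitations

* The classifier assumes promoter/downstream regions derive from the gene
  span (TSS = strand-aware span start); transcript-level TSS variation is
  not modelled.
* The DE engine's dispersion moderation is tuned for few-replicate
  designs; with many replicates the trend floor is unnecessarily
  conservative.
* The insertion caller's exact-match backend does not tolerate
  sequencing errors inside the matched segments (only junction-adjacent
  mismatches, via recursive clipping); real-data use should feed it
  aligner-produced SAM.
* Antisense and non-annotated features are consumed as externally
  produced count tables; their discovery (stranded counting, transcript
  assembly) is upstream of this package.
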