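# Methods

`estpoly` detects polymorphisms between two diploid DNA sources from an
EST (expressed-sequence-tag) assembly, classifies a related tetraploid's
allele origins, and scores coding divergence. This note describes the
models and procedures, the parameters that matter, what the synthetic
data emulates, and the numerical choices made where the design was
genuinely open.

## The discriminating-SNP rule

The substrate is a *sourced pileup*: per contig position, base counts
split by the DNA source of each read (the two subspecies accessions).
A position is called as a source-discriminating SNP iff

1. total called-base depth ≥ `min_total_depth` (default 8);
2. each source contributes ≥ `min_source_depth` reads (default 2);
3. within each source, the modal base accounts for ≥ `homogeneity`
   of that source's reads (default 0.90; 0.99 for stringency
   re-analysis), with no modal tie;
4. the two modal bases differ;
5. the rarer of the two modal alleles, counted over all reads, reaches
   `min_minor_fraction` of total depth (default 0.20).

Homogeneity is applied **per source** — at a 100× position with 80
source-A reads and 20 source-B reads, a G↔A call requires ≥ 72 A-reads
carrying G and ≥ 18 B-reads carrying A. An alternative reading (per
allele) exists, but the per-source form is the one consistent with the
worked 72/80–18/20 arithmetic and with the idea of a marker that is
"nearly homogeneous within a single DNA source"; it is what the
implementation and its tests pin down. `min_source_depth = 2` is this
package's own guard: a single read cannot evidence within-source
homogeneity. Modal ties never call (deterministic; no arbitrary
tie-break). A third base among the non-modal reads does not veto a call
but is recorded in diagnostics. N bases never count toward depth.

Within-source variants (intra-accession heterogeneity) use the same
depth threshold with the second-most-common base at ≥
`min_minor_fraction` of that source's reads.

Summaries tabulate SNPs per contig (contigs with > 13 SNPs are flagged
as likely assembly chimeras), density as total assembled bp per SNP,
minor-allele-fraction bins ([20–30), [30–40), [40–50]%, left-closed),
and the six unordered mutation classes (C/T, A/G transitions; A/T, C/G,
A/C, G/T transversions).

## SSR scanning and inter-source repeat polymorphism

The scanner reports maximal perfect tandem repeats of primitive 2–10 bp
motifs. Unit thresholds default to 7 for dinucleotides, 5 for tri-
through octanucleotides and 4 for nona-/decanucleotides; homopolymers
are suppressed by default (enable `report_homopolymers` to scan
mononucleotide runs at ≥ 10 units). Runs are found per motif length k
as maximal stretches where each base equals the base k positions
earlier; complete units are counted from the left anchor. A run whose
motif is a power of a shorter motif is reported only at the shorter
period. Two repeats separated by ≤ `max_interruption` bp (default 100)
are additionally recorded as one compound SSR; component repeats keep
their individual records so frequency matrices can exclude or include
compound formation.

Motifs are canonicalised to the lexicographically smallest cyclic
rotation of the motif or its reverse complement, rendered `X/revcomp(X)`
(GT → AC/GT, GGT → ACC/GGT), partitioning each motif space into
strand- and phase-free classes.

Polymorphic SSRs between the sources are found on the two per-source
consensus sequences. A repeat found in either consensus is anchored in
the other by its left flank — 20 bp of exact sequence immediately 5' of
the repeat, required to occur exactly once — and the unit count of the
same motif at the anchored position is compared. Differing counts give
a unit-count polymorphism; equal counts with a displaced right flank
give an internal indel. Exact-match flanks are conservative: a flank
broken by a nearby substitution leaves the locus *unresolved*, never
polymorphic, so the polymorphic count is if anything an underestimate.
The per-source consensus takes each source's modal base per position,
IUPAC ambiguity codes on ties, N where uncovered.

## Tetraploid allele-origin classification

Short reads of the tetraploid sample are placed on the reference
contigs ungapped with at most one substitution, both strands searched;
a read whose best placement is tied across distinct loci is discarded
(deterministic and conservative; the behaviour of multi-mapping reads
in stringent short-read aligners is otherwise tool-specific). At each
discriminating SNP with ≥ `min_depth` (default 20) overlapping reads,
an allele is present when ≥ `min_variant_fraction` (default 10%) of
*all* overlapping reads carry it. Both parental alleles present →
`both`; exactly one → `A_only`/`B_only`; neither, or a non-parental
base above the fraction → `other`; below depth → `insufficient_depth`,
excluded from denominators. The `both` fraction over evaluable SNPs is
the summary evidence for mixed (allopolyploid-like) ancestry.

A consequence of ungapped ≤ 1-mismatch placement worth knowing: a read
from the non-reference source that spans **two** discriminating SNPs
carries two mismatches and is dropped, depleting the non-reference
allele at tightly clustered SNPs. At the realistic inter-source density
of ~1 SNP/kb only SNPs with a neighbour within ~9 bp are pushed below
the 10% fraction (≈ 1–2% of SNPs), so a true 1:1 allotetraploid scores
a both-fraction of ~0.95–1.0 rather than exactly 1. This is a property
of the mapping stringency, not of the classifier.

## Ka/Ks with the +1 pseudocount

Per contig the two source consensuses share coordinates, so the codon
alignment is read directly through the ORF annotation; codons
containing N or a stop in either source are dropped, as are contigs
whose consensus lengths differ (length-changing repeat polymorphisms
break shared coordinates). Counting is Nei–Gojobori style: each codon
position contributes the fraction of its three single-base changes that
are synonymous to S and the remainder (including changes to stops) to
N, so S + N equals the aligned length; site counts of the two sequences
are averaged. Multi-hit codon pairs are averaged with equal weight over
all minimal mutational pathways, excluding pathways through stop codons
(if every pathway passes a stop, all are counted, translations of stops
compared as a 21st state).

One unit is added to both substitution classes before forming the
proportions, pS = (Sd+1)/S and pN = (Nd+1)/N, each then Jukes–Cantor
corrected, d = −(3/4)·ln(1 − 4p/3). The pseudocount keeps the ratio
finite and positive when either class has no observed changes — without
it, genes with Nd = 0 would be pinned at 0 and genes with Sd = 0
undefined. The cost is bias at low divergence: with only a handful of
observed changes, the +1 pulls ratios toward (Nd+1)S/((Sd+1)N), so
ratios from short or conserved alignments should be read as shrunk
toward ~S/N-weighted unity. The estimator converges to the unmodified
one as counts grow (a property the tests check).

Ratios > 2.5 are discarded as probable alignment artifacts; the rest
classify as stabilizing (< 0.15), intermediate ([0.15, 0.50)) or
diversifying ([0.50, 2.50]). The interval estimate of the ratio
distribution is a pooled-resample percentile bootstrap: `n_draws`
(default 146,744) resamples with replacement are pooled and the α and
1−α quantiles of the pool (α = 0.025) are the endpoints. Whether such
an interval should describe the distribution's quantiles or a CI of a
location statistic is a genuine design fork; the quantile reading is
the default here because the estimand is "the distribution", and at
large `n_draws` the endpoints converge to the empirical 2.5%/97.5%
quantiles (tests assert agreement of ECDF levels to ±0.5%).

## The synthetic-data generator

The generator emulates the study design downstream stages expect: two
diploid sources, each as two haplotypes; fixed inter-source differences
planted homozygously (both haplotypes of source B); heterozygous sites
on one haplotype of one source; one ORF per contig; optionally one SSR
per contig near the 3' end whose unit counts may differ between
sources; EST-like labelled reads with recorded true placements; and
unlabelled 80 bp tetraploid reads drawn from the four haplotypes at a
configurable source-A proportion.

Defaults reflect the study conditions: ~1 kb contigs, fixed divergence
1×10⁻³ per bp (~1 SNP/1.1 kb between sources), heterozygosity 4×10⁻³
per bp (~1 variant/250 bp within a source), 20× EST depth per source,
400 ± 60 bp EST reads, 80 bp tetraploid reads at 40×, substitution
error 10⁻³, ORF covering 60% of the contig. Reads may run off contig
ends and are truncated, keeping realised depth uniform along the
contig. ORF differences are planted codon-aware: for each difference
landing in the ORF, the synonymous/non-synonymous category is drawn so
the expected count ratio matches `ka_ks_target` given that codon's
available changes (stop-creating changes excluded), and realised
category counts are recorded as truth.

Planted SSRs sit inside a 30 bp untouched guard zone (no substitutions
planted within 25 bp of the repeat) so flank anchoring is exercised,
not sabotaged; the guard flanks are repaired once on the shared
ancestral sequence so both sources keep identical anchors and the run
cannot extend into a flank. When the two sources' repeat lengths
differ, coordinates downstream of the repeat shift between sources;
the generator therefore plants nothing downstream of an SSR, and the
pipeline calls SNPs only on contigs whose two consensuses have equal
length. What the generator does **not** model: 454 homopolymer indel
errors, expression-level variation between genes (depth is one
configurable distribution), splice forms, or assembly chimerism — so
passing recovery tests demonstrate correctness of the rules, not
robustness to those artefacts.

All randomness flows through `numpy` generators seeded from the
configuration; a fixed config reproduces byte-identical FASTA/TSV
outputs. The pipeline derives per-stage seeds from one global seed by
fixed offsets so stages re-run in isolation reproduce.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run at desk scale, chosen to
make the statistical checks stable: 10⁴ random pileup columns for exact
oracle agreement; 50 error-free 1 kb contigs at 20×/source for SNP
recovery (~47 planted SNPs; sensitivity ≥ 0.99 with zero false calls);
200 random 1 kb sequences for SSR scanner/oracle agreement; 100 contigs
with 50 unit-count-differing and 50 equal-unit planted SSRs; 40 contigs
at 50× tetraploid depth for the mixture checks; 500 pairs of 300 codons
at a planted rate ratio of 0.3 for Ka/Ks median recovery (±0.1); 10⁶
pooled draws for bootstrap convergence.

## Known limitations

- The SNP rule is count-based; no base qualities or genotype
  likelihoods (the source data had none to offer per-read).
- Gapped alignment, indel calling and imperfect (approximate) SSRs are
  out of scope; repeat polymorphism detection relies on consensus
  comparison, not read-level indel evidence.
- The Ka/Ks counter is the unweighted Nei–Gojobori scheme; no
  transition/transversion weighting, no among-site rate variation, and
  no outgroup polarisation — selection classes are descriptive labels
  on a pairwise ratio, not formal tests.
- Ratios from the +1 pseudocount are biased toward unity at low
  divergence (see above); comparisons are meaningful within a dataset
  at similar divergence, less so across divergence scales.
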