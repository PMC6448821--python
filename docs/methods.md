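# Methods

## Problem setting

A yeast strain evolves the ability to grow on maltotriose during a
serial-passage experiment. Crossing the evolved clone back to its parent
and dissecting tetrads shows the trait behaves as a dominant allele at a
single locus; bulk-segregant sequencing maps it; inspection of the mapped
transporter gene reveals a chimeric allele created by ectopic gene
conversion between two paralogous MALT transporter genes. maltpipe
implements each analytical step of that chain and a simulator that
generates matched inputs with ground truth.

## Sequence primitives

**Global alignment.** Needleman–Wunsch with match +1, mismatch −1, linear
gap −2 (Biopython's `PairwiseAligner` in global mode; the first alignment
in its canonical enumeration is taken, so output is deterministic). Scores
are verified in the test suite against an independent plain-Python
dynamic-programming oracle.

**Percent identity.** Matches over comparable columns × 100, where columns
with a gap in either row are *excluded* from the denominator (the common
p-identity convention; the underlying study does not state one). `N` never
counts as a match. Amino-acid-level identity translates the ungapped rows,
realigns the proteins and scores that alignment.

**Sliding identity tracks.** Default 10-bp windows, step 1. Inside a
window, gap columns count as *mismatches*, so indel-rich windows score low
rather than silently vanish — the opposite convention from whole-alignment
identity, chosen so the track stays defined everywhere. Windows more than
50% `N` are masked. Window centers are reported 1-based.

**Codon work.** Translation uses the standard genetic code; codons with
`N` give `X`; a terminal stop is stripped and flagged, internal stops
warn and are flagged rather than dropped. Back-translation of a protein
alignment expands each residue to its source codon and each gap to `---`,
after verifying the protein row equals the CDS translation. Codon-pair
classification compares translated residues for single-position changes;
pairs differing at ≥ 2 positions are `multi_hit`, and stop-involving pairs
are a separate flagged class.

## Chimera detection

The candidate is put in register with each panel paralog. Equal-length
sequences (the simulator's families, and conversion between same-length
paralogs generally) are taken as already positionally comparable; unequal
lengths are registered by global alignment and projected onto candidate
coordinates, with positions gapped in either projection skipped and
counted. This matters: at ~20% divergence an optimal aligner occasionally
buys a spurious compensating indel pair with lucky downstream matches,
which would corrupt per-position SNP counts on sequences that are in fact
collinear.

At every position where the two parents differ (informative site) the
candidate's base votes `matches_A` / `matches_B` / `matches_neither`.
Tract inference is run-based parsimony, not an HMM: a maximal run of at
least `min_run = 3` consecutive donor-matching sites becomes a tract;
shorter runs are reported separately as isolated sites (point conversion
or homoplasy). The evidence for a conversion tract in this setting is a
single clean cluster of dozens of donor-matching SNPs, for which the
simplest segmentation suffices; `min_run = 3` guards against recurrent
point mutation mimicking conversion.

Because clustered-SNP evidence cannot localize an exchange breakpoint
between informative sites, every tract carries two intervals: the
*minimal span* (first to last donor-matching site) and the *maximal span*
(from just after the previous recipient-matching site to just before the
next one, clamped to the gene ends when unflanked). The true tract always
contains the minimal span and is contained by the maximal span.

`scan_gene_family` scores every ordered (recipient, donor) pair and keeps
the one minimizing sites assigned to neither parent, breaking ties by
fewer tracts (which orients recipient vs donor: the wrong orientation
explains the flanks as two donor runs), then lexicographically; ties are
flagged in the report. SNPs inside the maximal span are counted per
nucleotide against the recipient; codon effects are tallied per codon,
with multi-hit codons counted once by their net amino-acid effect — this
keeps nucleotide-level and codon-level tallies independent, matching how
such results are conventionally reported (N SNPs, of which M
nonsynonymous).

## Bulk-segregant scan

Input is per-site allele counts for the two pools (TSV or a minimal VCF
with per-sample `AD`); read alignment and variant calling are out of
scope, counts being the sufficient statistic for the scan. A site is a
*fixed difference* when the alt frequency is ≥ `fix_hi` = 0.95 in one pool
and ≤ `fix_lo` = 0.05 in the other with both depths ≥ `min_depth` = 10.
Near-fixation rather than strict 1/0 tolerates sequencing error and one
mis-phenotyped segregant in pools of 30 (1/30 ≈ 0.033 < 0.05). All three
thresholds are exposed on the CLI. Raising `fix_hi` or lowering `fix_lo`
can only shrink the fixed-site set (monotonicity, property-tested).

Windows are non-overlapping 1-kb tiles, 1-based inclusive in reports and
0-based half-open in BED output; adjacent candidate tiles are merged into
regions in a companion report so a locus straddling a tile boundary is one
finding. Windows whose mean total depth exceeds 1.8× the genome median
are flagged as likely collapsed-paralog artifacts (the depth signature of
reads from several loci piling onto one); flagging annotates, never
filters. Sites with more than two alleles are collapsed to ref vs the
highest-depth alt and flagged multiallelic.

## Tetrad analysis and division budget

Patterns are tallied over fully viable tetrads only (dead-spore tetrads
are reported but excluded). `consistent_single_locus` is true when at most
10% (configurable) of fully viable tetrads deviate from 2:2 — rare
gene-conversion 3:1 tetrads should not overturn a single-locus call. The
spore-count test is the exact two-sided binomial at p = ½ using the
minimum-likelihood two-sided definition (sum of probabilities of all
outcomes no more likely than observed); conventions differ between
packages, so the choice is stated and enforced against a full-enumeration
oracle in the tests.

The division budget is `n_passages × mean(days_per_passage) ×
divisions_per_day × n_lineages`, with the passage interval taken at the
midpoint of the stated range (3.5 days for a 3–4-day regime). Both the
exact product and the value rounded to the nearest 10 (the convention for
quoting such totals) are returned.

## Simulator

**Gene families.** Each family member descends from one random in-frame
ancestor CDS (ATG start, sense codons) by codon-aware point mutation:
proposed substitutions favour transitions 2:1 over each transversion and
are rejected if they create a stop, so members stay clean CDS and protein
identity tracks nucleotide identity, as in real transporter paralogs. An
initial per-gene mutation load is computed from the target pairwise
identity, then a correction loop mutates the most-similar pair until all
pairs fall within ±2 percentage points of the target; defaults are four
genes of 1848 bp (~616 aa, typical for a Major Facilitator Superfamily
sugar porter) at 80% nucleotide identity. The start codon is never
mutated.

**Conversion.** `apply_gene_conversion` copies the donor over a 1-based
inclusive tract of the recipient (default length 230 bp, position uniform)
and leaves the donor untouched; it is idempotent and its diffs are
confined to the tract (exhaustively property-tested).

**Tetrads and pools.** Each of the markers (every 500 bp on a 100-kb
genome by default) is heterozygous in the F1 and segregates exactly 2:2
within each tetrad; markers assort independently (free recombination — no
linkage map, deliberately). Phenotype is dominant presence of the derived
allele at the causal marker with penetrance 1; the null scenario instead
assigns phenotypes by a genotype-independent 2:2 split per tetrad. Pool
depths are Poisson(coverage); alt reads are Binomial(depth, f(1−ε) +
(1−f)ε) with f the pool's true allele frequency and ε = 0.005 the
per-read error rate. Default pools are the 30 + 30 spores of 15 tetrads
at 100× coverage.

**What the simulator does not emulate:** read-level artifacts (mapping
bias, indel error), linkage between markers, spore death, incomplete
penetrance, more than one causal locus, and post-conversion mutation
(so simulated chimeras carry no homoplasy). Passing recovery tests
therefore demonstrates correctness of the inference logic under the
stated model, not robustness to every property of real pooled sequencing
data.

## Validation at study conditions

`maltpipe.validation` (used by the test suite and
`scripts/acceptance.py`) measures: recovery of the true (recipient,
donor) pair with the maximal span bracketing the true tract over 200
seeded family-plus-tract scenarios; exact agreement of reported SNP
counts with a brute-force per-position diff; detection of the causal 1-kb
window in 100 causal scenarios and the mean number of candidate windows
in 100 null scenarios; and byte-identity of repeated CLI runs at a fixed
seed. Problem sizes (200/100/100 replicates, 100-kb genome, 200 markers)
keep the full validation around a minute on one CPU while leaving
binomial noise on a 95% recovery criterion near ±3 percentage points.

## Known limitations

- Recipient/donor orientation relies on the tract being shorter than its
  flanks; a conversion replacing most of a gene would be reported with
  the roles swapped.
- The run-based segmenter does not model overlapping or nested tracts,
  nor conversion between non-homologous sequences.
- Window-level BSA reporting does not refine the causal interval below
  the tile size; with markers every 500 bp a causal window contains one
  or two markers.
- The minimal VCF reader handles only `CHROM/POS/REF/ALT` + per-sample
  `AD`, by design.
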