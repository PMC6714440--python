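# Methods

`raptorsig` re-implements, as a tested desk-scale pipeline, the bespoke
comparative-genomics computations used to characterize predatory and
nocturnal adaptation in raptor genomes: a conserved-region window scan,
olfactory-receptor (OR) repertoire classification and entropy diversity,
counting-method dN/dS with gene-set acceleration tests, GC3 composition
profiling, and variant-based genome metrics (heterozygosity rate, depth-based
gene filtering). Every stage is exercised end-to-end on synthetic data with
planted, machine-readable ground truth.

## Highly conserved region (HCR) scan

Differences between same-order genomes (an upstream mapping/variant-calling
product; here an input, or simulated) are tiled into fixed windows of
`window_size` = 100,000 bp, counted per window, and each window is tested for
**depletion** of variation against the rest of the genome with Fisher's exact
test on the 2x2 table

```
[ window_diffs        window_len - window_diffs  ]
[ genome_diffs        genome_len - genome_diffs  ]
```

where the genome row **excludes the focal window**, keeping the two rows
independent (pooling the focal window into the genome row would make the
margins dependent and slightly anticonservative). The default alternative is
one-sided depletion, since the scan targets *reduced* variation; a two-sided
test is available by flag. P-values are adjusted with the Benjamini-Hochberg
step-up procedure (default); a Storey-style variant (single-lambda pi0
estimate at lambda = 0.5, applied as a multiplier on the BH values) is
exposed as `fdr_method="storey"`. Windows with q < 1e-4 are significant, and
only the **middle 10 kb core** of each significant window is reported as an
HCR, because scaffold ends in draft assemblies are enriched for mis-assembly
and gaps.

Choices the scan definition leaves open, fixed here:

- windows are tiled from coordinate 0 of each scaffold, non-overlapping;
- testing pools windows genome-wide rather than per scaffold;
- gap/N regions supplied as a BED subtract from a window's *effective
  length* before testing;
- the terminal short window of a scaffold is tested but never yields a core
  if it is shorter than the core size;
- BH ties are processed in stable (p, scaffold, start) order (q-values are
  unaffected by tie order; the ordering only stabilizes output).

## OR repertoire classification and diversity

Candidate OR coding sequences (found upstream by homology; clade labels are
inputs) are processed as:

1. **Extension** — a candidate lacking a start (stop) codon is scanned
   in-frame up to 90 bp upstream (downstream) on the coding strand and
   extended to the nearest ATG (TAA/TAG/TGA); scans truncate at scaffold
   boundaries and set a missing-end flag on failure.
2. **Deduplication** at 100% identity (byte-identical CDS collapse to the
   first occurrence; stable, idempotent).
3. **Classification**: *pseudogene* on frameshift evidence (CDS length not a
   multiple of 3, or an annotated indel lesion) or a premature stop in the
   frame anchored at the start; else *partial* if the start and/or stop is
   missing after extension; else *intact* if the protein exceeds 215
   residues (long enough for seven transmembrane domains). A complete ORF of
   <= 215 residues is labeled *partial*, because intactness is defined
   conjunctively (start AND stop AND length); it carries no lesion, so
   pseudogene would be wrong, and it is not a complete receptor.

Repertoire diversity of a clade's intact genes is the mean **Shannon entropy
in nats** (natural log) of alignment columns, computed over non-gap residues;
columns with a gap fraction *strictly above* 20% are excluded (a column at
exactly 20% is retained). Both `-` and `.` count as gaps; `X` counts as a
21st residue class and flags the result (`has_nonstandard_residues`), since
the entropy bound is then ln 21 rather than ln 20. Diversity is undefined
for fewer than two sequences or zero surviving columns (an error, never a
silent 0).

## Counting-method dN/dS

The maximum-likelihood codon models used in the original selection scans are
out of scope; the pipeline uses the Nei-Gojobori (1986) counting method as
the desk-scale estimator, with the standard nuclear genetic code:

- **Sites**: at each codon position, the synonymous fraction is the number of
  the 3 possible single-nucleotide changes that preserve the amino acid,
  divided by the number that do not create a stop codon; s + n = 3 exactly
  per codon (the stop-excluding normalization).
- **Differences**: for codons differing at k positions, synonymous and
  nonsynonymous step counts are averaged over all k! mutational pathways;
  pathways passing through a stop codon are discarded. If every pathway is
  stop-blocked, all pathways are used with a warning — in the standard code
  this cannot happen for sense-codon pairs (verified exhaustively in the
  tests), so the fallback exists only for robustness.
- Codons containing gaps, ambiguity codes, or stops in either sequence are
  skipped pairwise; site counts are averaged between the two sequences, so
  the estimate is symmetric.
- pN and pS are corrected for multiple hits with the Jukes-Cantor formula
  d = -(3/4) ln(1 - 4p/3), the standard companion to NG86 counting. p >= 3/4
  raises a saturation error. omega = dN/dS is reported as undefined (`None`)
  when dS = 0, never as a silent infinity.

**Gene-set acceleration** between species groups is a two-sided Mann-Whitney
U test on per-gene omega values: exact enumeration over all group-A index
assignments when both groups have <= 8 members (two-sided p defined as
P(|U - n_a n_b/2| >= |U_obs - n_a n_b/2|), ties counted half in U), and the
tie-corrected normal approximation otherwise. All values tied across both
groups yields p = 1 with a degeneracy warning.

## GC3 profiling

GC3 of a coding sequence is the fraction of third codon positions that are G
or C, over codons whose third position is an unambiguous base (an incomplete
terminal codon is trimmed with a warning). The comparative "normalized GC3"
profile is defined here as a two-step standardization, chosen to reproduce
heatmap-style comparative semantics:

1. within each species, z-score each gene's GC3 across that species' genes
   (removes species-level base-composition offsets);
2. average the normalized values per gene set per species;
3. z-score each gene set's averages across species, so each output row has
   mean 0 and SD 1 (sample SD, ddof = 1).

Zero-variance rows are defined as 0. Both intermediate tables (per-gene
normalized values and per-set means) are emitted so alternative
normalizations can be audited. Sets with fewer than two genes are excluded
with a warning.

## Group-specific residues

A column of a protein alignment is target-specific when (a) every target row
carries the same non-gap residue, (b) no outgroup row carries that residue,
and (c) no target row is gapped; strict mode additionally rejects columns
with outgroup gaps. The original workflow's manual alignment inspection is
replaced by these explicit, reportable gap rules.

## Heterozygosity rate and depth filter

- **Callable length** is the number of bases with depth strictly greater
  than 5 ("> 5" is strict: a depth-5 base contributes nothing). Tracks may
  be bedgraph-style intervals or per-base arrays; both give identical
  results.
- **Heterozygosity rate** = biallelic heterozygous SNVs (genotype with two
  distinct alleles) on callable bases, divided by callable length. Whether
  variants are intersected with callable regions before counting is
  toggleable (`intersect=`, default on, chosen for internal consistency:
  numerator and denominator then refer to the same bases).
- **Depth filter**: an autosomal gene is removed iff its mean depth is
  strictly below 0.5x or strictly above 2x the genome-wide mean; a
  sex-linked gene iff strictly below 0.25x or strictly above 2x (sex
  chromosomes sit near half depth in the heterogametic sex). Boundary depths
  are kept. Gene mean depth is taken over the gene's exonic span, since the
  filter guards gene-family size calls.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their seed (byte-identical reruns) over
uppercase ACGT; ambiguity codes are never emitted. Planted truths are
returned in machine-readable form sufficient to score every downstream stage.

- **Differences** are simulated directly as a per-bp Bernoulli process
  (background 5e-3 per bp; planted conserved windows at a multiplier of the
  background), not by aligning simulated genomes — the scan statistic
  consumes only per-window counts. Default scan conditions: 20 Mb (200
  windows of 100 kb), five planted windows at 5% of background, seed-driven.
- **OR-like genes** are complete ORFs of 310 codons embedded in scaffolds
  between frame-safe flanks (sense, non-ATG codons, so no spurious in-frame
  starts or stops); partial genes lack the start and/or stop within the
  annotated span, alternately recoverable within the 90-bp flank (truth
  labels reflect the post-extension status); pseudogenes carry a 1-bp
  deletion, 2-bp insertion, or internal stop.
- **Codon pairs** evolve by uniform single-nucleotide proposals filtered by
  selection: stop-creating proposals are rejected, nonsynonymous changes are
  accepted with probability min(1, omega), synonymous with
  min(1, 1/max(omega, 1)); the process stops at a fixed accepted-substitution
  count (0.3 per codon by default, a moderate interspecific divergence), so
  divergence is held constant across seeds. **Each codon receives at most
  one substitution**: pathway averaging in the counting estimator can assign
  fractional nonsynonymous differences to a codon hit twice by synonymous
  events, so unrestricted multi-hits would make even a strictly purifying
  (omega = 0) simulation yield spurious nonsynonymous differences; the
  single-hit restriction makes the planted truth exact at every omega while
  leaving the neutral calibration unchanged.
- **Protein alignments** plant target-specific columns; all other columns
  share a consensus with noise constructed so the specificity rule is never
  satisfied (noise either breaks target unanimity or leaves the target
  residue present in an outgroup row; occasional outgroup gaps are planted).
- **Depth/heterozygosity**: a 100-bp-binned Poisson(~30x) track with 10%
  low-coverage (uncallable) bins; heterozygous SNVs placed only on callable
  bases at 1e-3 per bp; per-gene mean depths near the genome mean (clipped
  to [0.6x, 1.8x] so non-anomalous genes never sit on a filter boundary)
  with 15% of genes planted below 0.25x, in (0.25x, 0.5x), or above 2x.

What the generators do **not** emulate — and therefore what passing tests do
not establish about real data: alignment and assembly error, annotation
mistakes, transition/transversion and codon-usage bias (the substitution
process is uniform, which is exactly the regime where NG86 counting is
unbiased; on real data with ts/tv bias it is known to misestimate), rate
variation among sites or genes, linkage between variants, read-level noise
(depth is simulated at the summary level; no FASTQ), and multiallelic or
indel variation in the heterozygosity input.

## Problem sizes and numerical choices

Default problem sizes: 200 windows x 100 kb for the scan; 300 OR genes of
310 codons; 5,000-codon alignments for calibration (three seeds per omega);
1.2-Mb depth tracks (>= 1e6 callable bp) with 100 genes; 20 random
alignments for the specific-site round trip. These sizes keep every stage's
sampling error far smaller than the effects being detected (e.g. a planted
window's expected count is 25 against a background of 500, > 40 interquartile
distances under the null).

- Fisher's exact test, BH adjustment, and the Mann-Whitney normal
  approximation are delegated to scipy; the exact small-sample Mann-Whitney
  path and all counting machinery are implemented here.
- Entropy of a single-symbol column returns exactly 0.0 (not -0.0).
- The exact Mann-Whitney enumeration compares |U - center| with a 1e-12
  guard for float half-tie arithmetic; U values are multiples of 0.5, so the
  guard never changes a discrete decision.
- Cross-species and per-species z-scores use sample SD (ddof = 1); a
  zero-variance vector z-scores to all zeros rather than NaN.
- Degenerate inputs raise typed errors (`UndefinedStatisticError`,
  `SaturationError`, `InvalidSequenceError`, `DataIntegrityError`) rather
  than returning sentinel values.
- All writers are atomic (temp file + rename): a failed run leaves no
  partial outputs. Intervals are 0-based half-open everywhere in memory and
  in TSV/BED outputs; VCF I/O converts at the boundary.

## Known limitations

- The counting estimator stands in for ML branch and branch-site models; it
  supports the comparison machinery (acceleration tests) but does not
  reproduce published per-branch omega values.
- OR clade assignment, homology search, and domain detection are inputs, not
  computations; the pipeline starts from candidate sequences.
- The Storey FDR option uses a single-lambda pi0 estimate, not the full
  smoother.
- `extend_orf` extends to the *nearest* in-frame codon; it does not evaluate
  alternative more distant starts.
- The heterozygosity module assumes a single-sample VCF; only the first
  sample's genotype is inspected.
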