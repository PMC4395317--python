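# Methods

## The problem

Whole-genome amplification of a single cell fails regionally: within an
affected segment only one haplotype is amplified, so every heterozygous
site in the segment appears homozygous. For tumor single-cell data this
turns real mutations into silent false negatives. The toolkit's central
device is *linkage*: a germline SNP heterozygous in the individual and
within one read length of a target site almost always lies in the same
amplification segment, so its observed zygosity in a cell reports whether
the region kept both haplotypes. Both alleles visible at the anchor ⇒ no
dropout ⇒ a mutant-free target is a confirmed wild-type (−1). One allele
⇒ dropout ⇒ the target stays undefined (0).

## Genotype model

At one site in one sample the data D are the pileup bases b with Phred
qualities Q, e = 10^(−Q/10). For a diploid genotype G = {A₁,A₂}:

- p(b|A) = 1 − e if b = A, else e·w_b/(1 − w_A), where w_G = w_C = gc/2,
  w_A = w_T = (1−gc)/2. The error mass e is split over the three wrong
  bases proportionally to their genomic abundance; at gc = 0.5 this is
  the uniform e/3 model, and at GC/AT = 2/3 the misread probability into
  a G or C base is (2/7)·e (weight 2 out of 2+2+3). The four values sum
  to one for any allele.
- p(b|G) = ½p(b|A₁) + ½p(b|A₂): a read samples one chromosome uniformly.
- p(D|G) = ∏ p(b|G); posterior p(G|D) ∝ p(G)·p(D|G), normalised over the
  ten genotypes (the evidence cancels).
- Prior p(G): Hardy–Weinberg products of the composition weights, w²
  for homozygotes and 2ww′ for heterozygotes. This is the only
  GC-dependent, normalised, reference-free construction available to us;
  it is a design choice, kept replaceable (any mapping Genotype→prob can
  be passed to the posterior).

Calling rule: the argmax genotype is reported only when (a) the site has
strictly more than `min_depth` (default 5) qualified reads and (b) its
posterior is at least `ratio_threshold` (default 1000×) the sum of the
other nine. Otherwise the call is UNCERTAIN, which downstream code treats
as "no information" — never as wild-type. Both gates are strict readings
of "more than 5" / "a thousand times higher"; `min_depth` is exposed for
analysts who prefer ≥ semantics. Ties at the argmax (possible only in
degenerate inputs) are UNCERTAIN, consistent with the dominance rule. A
dominance ratio with numerically zero tail mass is +∞ and the call
succeeds.

Numerics: likelihoods accumulate in log space with max-subtraction
normalisation (a 20-read pileup at e = 10⁻⁴ underflows naive products);
observations are grouped by error probability so each column costs a
4×10 table contraction. Log-space and direct-product evaluation agree to
10⁻⁹ on small pileups (tested), and posteriors normalise to 1 within
10⁻¹².

## Anchoring and its self-validation

`find_linked_pairs` joins targets to anchors on the same chromosome at
distance 1 ≤ d < `read_length` (default 90 bp, strict, configurable).
Anchor evidence is genotype-level: the anchor's call in the same cell is
NO_DROPOUT (het), DROPOUT (hom) or UNINFORMATIVE (uncertain). A target
coded −1 requires a hom-ref call plus at least one NO_DROPOUT anchor; a
DROPOUT verdict from a second anchor does not veto, since a dropout
boundary can fall between anchors and positive evidence of both
haplotypes suffices.

The strategy validates itself on pairs of germline SNPs heterozygous in
both bulks and < 90 bp apart: whenever one member is called het in a cell
(both haplotypes demonstrably present), the other must not be hom. Each
(cell, pair) is counted in both orientations — either member may play the
witness — which makes the denominator convention explicit in the output.
Zero informative cases yield NA, never 0.

## Mutation pipeline

Record filters are strict inequalities on QUAL (>20), FS (<40), QD
(>1.5), GQ (>20) and depth (>5 cell, >20 bulk), failing on the first
violated criterion with a machine-readable reason; a missing annotation
fails its criterion. Site logic: het in ≥ k cells (k = 3 by default; an
exact binomial tail computation `min_support_cells(n, fp, α)` is provided
for analysts who prefer a calibrated k), hom-ref in a normal bulk with
> 20 reads, present in the tumor bulk, outside known-SNP exclusion sets
(site lists or regions, plus a population table with MAF > 0.01 strict),
outside amplified-region blacklists, and inside target regions ± 90 bp
flanks when targets are supplied. A missing normal bulk is a hard error:
a germline het SNP whose normal-sample coverage is shallow can lose an
allele to dropout there, be typed hom-ref, and then surface as a fake
somatic mutation in every cell showing the second allele. The pipeline
therefore *excludes* sites whose normal genotype is not established at
depth rather than calling them.

## FNR estimation and summaries

Over SNPs het in both bulks, a cell's false-negative rate is the fraction
of its evaluable sites (call present, depth > 5) not recovered as het.
Per-cell averaging ("typical cell") and pooled averaging ("typical
observation") answer different questions and both are reported
(`average_fnr`, `pooled_fnr`); cells with no evaluable site are NA and
excluded from the average. Summary ratios are reported as
numerator/denominator plus a percentage rounded at display precision
(integers by default, one decimal for densities and FNRs).

## Clonal-consistency scan

From the ternary matrix, for every unordered site pair {a, b} (orientation
fixed by matrix column order) the scan enumerates all cell triples
(x, y, z) coded (1,−1), (−1,1) and (1,1) respectively. Because −1 entries
are anchor-certified, loss of heterozygosity cannot forge the pattern;
surviving cases point at cell fusion or recurrent mutation. All witness
triples are listed (then grouped per site pair in the report); site pairs
within one read length on a chromosome are flagged as possible
shared-amplicon artifacts but not suppressed. The implementation is
checked against an exhaustive independent enumeration on both the
packaged matrix and random matrices.

## Simulator

`simulate_truth` + `simulate_reads` generate: germline het SNPs (density
default 0.4%, a configurable fraction placed as < 90 bp pairs; alleles
assigned to one of two phased haplotypes at random), somatic mutations on
a complete binary lineage tree with cells at the leaves, optional cell
fusion (a fused lineage carries the union of two nodes' mutation sets;
`n_fusion_cells` cells are sampled from it), and **regional** dropout:
each (cell, segment) independently loses one haplotype with probability
`ado_rate`. Reads are Poisson-depth pileups drawing a surviving haplotype
uniformly, with base errors at probability e and misread identities drawn
by the same GC weights as the inference model; bulks are dropout-free,
the normal bulk is wild-type at somatic sites and the tumor bulk
heterozygous there, and chosen sites can be forced to shallow normal
coverage to reproduce the miscall scenario.

Parameter defaults are the study conditions: gc = 0.41, ado_rate = 0.2
inside the reported 7–44% platform range, read_length = 90 bp,
segment_length = 100 kb (the scale of MDA amplicons — dropout is regional
precisely because amplification fails in long segments), Phred 30 errors.
Somatic targets get their anchor placed inside the same segment by
construction; this embodies the linked-amplification assumption and is
the regime in which confirmed wild-types are provably safe. Shrinking
`segment_length` toward the read length breaks that assumption and is the
knob for studying the method's failure mode (anchors straddling segment
boundaries), which real data cannot isolate.

What the simulator does *not* model: read-level artifacts (chimeras,
alignment error, strand bias), copy-number variation and loss of
heterozygosity, cell-to-cell depth variability beyond Poisson, partial or
allele-biased amplification within a segment, and doublet contamination.
Passing tests therefore demonstrate the method's logic and calibration
under its own assumptions, not robustness to every real-data pathology.

## Experiment scales

The seeded benchmark experiments use sizes that make Monte-Carlo noise
small relative to the effects measured: dropout-rate recovery uses 3
cells × 10,000 het loci (dropout is segment-correlated, so the standard
error is computed on cells × segments, 300 effective trials); anchored
confirmation pools ≥ 100 confirmed wild-types across 5 seeds against an
expected error count of zero; clonal detection uses 20 pure-clonal and 20
fusion runs at 16 cells, 8 mutations, depth 40 and ado 0.1 (low end of
the platform range, chosen so that the x/y/z witness cells all have a
high chance of successful confirmation in any single run).

## Known limitations

- Anchoring reach is bounded by SNP density (~0.4% of exonic sites), so
  only a small fraction of targets can ever be confirmed; the toolkit
  reports 0 (undefined), not −1, everywhere else.
- The prior construction stands in for an unpublished table; posterior
  calls at depth > 20 are insensitive to it, but shallow-depth behaviour
  near the gate depends mildly on the prior.
- The VCF reader covers the SNV subset with QUAL/FS/QD/GQ/DP/GT only;
  multi-allelic records and indels are counted and skipped, never
  genotyped.
- The pipeline consumes already-called records; upstream alignment and
  recalibration quality is out of its control.
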