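# Methods

## Overview

`rsnpscan` implements an integrative annotation chain for GWAS variants in
non-coding DNA: assemble disease SNP sets (leads plus linkage-disequilibrium
proxies), score each SNP against a library of transcription-factor position
weight matrices (PWMs) for allele-dependent binding, call regulatory SNPs
(rSNPs) with a per-motif calibrated p-value, map rSNPs to target genes
through a catalogue of regulatory elements (REMs), split the genes into
protein-coding and non-coding, corroborate the coding genes by disease-set
over-representation, and corroborate the non-coding genes by
guilt-by-association: their top co-expressed protein-coding partners are
pooled and tested for the same disease terms.

All external resources the chain would normally consume (GWAS catalogue,
LD server output, JASPAR motifs, EpiRegio REMs, GTEx expression, DisGeNET)
are emulated by a synthetic-data generator with planted ground truth, so
every stage is testable end to end without downloads.

## The differential binding statistic

For a SNP at position $v$ and a PWM of length $m$ with base-2 log-odds
$L[i,b]$ against the background, every window of length $m$ covering $v$ is
scored on both strands (the reverse strand scores the window against the
reverse-complemented matrix). The binding score of an allele $a$ is

$$S(a) = \max_{\text{offset},\,\text{strand}} \sum_i L[i, x_i(a)]$$

with $x(a)$ the local sequence carrying allele $a$. The differential
binding score is $D = S(\text{ref}) - S(\text{alt})$ — the log-odds ratio
of the two binding affinities, in bits. $D > 0$ means the variant weakens
the best binding site; $D < 0$ means it creates or strengthens one.

Ties between equally scoring windows resolve to the smaller offset, then
to the forward strand, so scans are deterministic.

### Per-allele binding p-value

The exact distribution of the window score for an i.i.d. background
sequence is computed once per motif by dynamic-programming convolution
over positions, with scores discretized to a 0.01-bit lattice (the
discretization error is orders of magnitude below any decision
threshold). The binding p-value of an allele is the tail
$P(S \ge s)$ under that distribution. A SNP×motif pair is only considered
further if at least one allele has binding $p \le 0.5$ — the either-allele
form keeps both binding-loss and binding-gain events detectable.

### Differential binding p-value

Under a panel of null SNPs, $D$ is approximately symmetric around zero
and heavy-tailed; we model it as zero-centred Laplace with a per-motif
scale $b$, estimated by its maximum-likelihood estimator
$b = \operatorname{mean}|D|$ over all scoreable panel SNPs (zeros
included). The differential-binding p-value is the two-sided tail

$$p_\text{diff} = \exp(-|D|/b).$$

A motif with fewer than 100 scoreable panel SNPs (configurable), or with
$b = 0$ (e.g. a uniform matrix), is flagged uncalibrated and excluded
from scanning. A SNP is an rSNP if at least one pair passes both the
binding filter and $p_\text{diff} \le 10^{-3}$.

The two-sided form was chosen because both loss and gain of binding are
biologically actionable; this is a package-level decision, as is the
Laplace family itself — a one-parameter scale family is the natural
two-sided model for a difference of maxima of log-odds sums, and its
adequacy is a measurable property (see calibration below), not an
assumption.

## Motif handling

TRANSFAC-format count matrices (JASPAR's bulk-export format; the raw
JASPAR 4-line dialect is accepted via a flag) are converted to
frequencies with a pseudocount of 0.25 per cell under a uniform
background (both overridable), then to base-2 log-odds. Flanking
positions with Shannon entropy above 1.9 bits (of a 2-bit maximum) are
trimmed before calibration and scanning; interior positions are never
removed, and a fully uninformative motif is dropped with a warning.
Trimming is idempotent and the kept flanks always satisfy the threshold.

## Thresholds

| parameter | default | role |
|---|---|---|
| gwas_alpha | 1e-5 | lead significance, strict `<` |
| r2_min | 0.75 | proxy LD filter, inclusive |
| window | 500,000 bp | proxy distance to lead, inclusive |
| entropy_trim | 1.9 bits | flank trimming |
| pseudocount | 0.25 | PFM → PWM |
| p_bind_max | 0.5 | per-allele binding filter (either allele) |
| p_diff_max | 0.001 | rSNP call |
| k_coexpr | 10 | partners per non-coding gene |
| fdr | 0.05 | enrichment significance (BH) |
| min_query | 30 | smallest query set tested |
| n_null_scale | 200,000 | null-panel cap for scale estimation |
| seed | 123 | default RNG seed |

The package runs its own studies at desk scale: the default synthetic
scenario uses a 100 kb genome, 8 motifs, 2,000 null SNPs for scale
estimation, 400 GWAS-null SNPs, 24 planted sites, 312 genes and 200
expression samples. These sizes keep a full study plus calibration in the
order of a minute on one core while leaving every statistical property
measurable; `n_null_scale` accepts the full-scale value when a larger
panel is supplied.

## Enrichment

One-sided (over-representation) Fisher exact tests: the p-value is the
upper hypergeometric tail, computed by `scipy.stats.hypergeom`; the odds
ratio uses a 0.5 continuity correction only when a cell of the 2×2 table
is zero. Benjamini–Hochberg step-up q-values (via `statsmodels`) control
the FDR across terms; significance is `fdr <= 0.05`. Queries with fewer
than 30 genes inside the universe are not tested — they return an
explicit skipped marker, since at that size the test is underpowered.
The default universe is the full gene annotation; DisGeNET-style
catalogues state no universe, so this is a package decision and is
configurable.

## Co-expression guilt-by-association

Spearman rank correlation (Pearson on average ranks; paired missing
values dropped; zero-variance vectors excluded with a logged count)
between each candidate non-coding gene and every protein-coding gene
across samples. Partners are ranked by signed rho descending — "most
highly correlated" — with lexicographic tie-breaks for determinism, and
the top 10 kept. The union of partners over a disease's non-coding genes
feeds the enrichment stage. ncRNA–ncRNA pairs and self-correlation are
excluded; a non-coding gene absent from the matrix yields a skipped
marker rather than an error.

## The synthetic-data generator

The generator is first-class, tested code. It emulates, at desk scale:

- **Genome**: i.i.d. bases at a configurable GC content (default 0.41,
  human-like), on one synthetic chromosome.
- **Motifs**: random PWMs built from one deep "anchor" column
  (near-deterministic base, count depth 10,000) plus core columns whose
  log-odds spreads are stratified across an exponential-variance
  spectrum, flanked by near-uniform columns for the trimmer to remove.
  The exponential-variance mixture is the regime in which differences of
  binding scores follow a Laplace law — i.e. the generator produces
  motifs for which the scorer's null family is adequate, as it is for
  curated TF motif libraries. Candidate draws are screened internally
  (consensus information content within 15–23 bits; an intrinsic
  disruption cost of ≥ 11 bits on both strands, so the disrupted site
  cannot rescue itself through a shifted or reverse-complement
  alignment; a null simulation on a separate background genome
  confirming Laplace scale, KS distance and tail mass near nominal).
  Screening is deterministic in the seed and bounded; it is part of the
  motif model, not a per-run fit.
- **Planted sites**: each motif's consensus is written at deterministic,
  well-separated positions; a position is probed along a fixed grid
  until the planted site, disrupted at its maximum-information column,
  loses at least 10.5 bits — recovery of planted variants is therefore a
  property of the construction, not of luck with the background draw.
- **SNPs**: one disruptive SNP per planted site (ref = consensus base at
  the maximum-information column, alt = the column's log-odds minimizer,
  reported in genome orientation) plus uniformly placed null SNPs.
  Null SNPs avoid planted-site intervals: a variant inside a planted
  binding site would not be null, and correct ground-truth labels are
  what downstream calibration checks rest on.
- **GWAS tables**: disruptive SNPs and 80% of a separate null set are
  genome-wide-significant leads (p drawn log-uniformly below 1e-5); the
  rest fall between 1e-5 and 1e-2 to exercise the significance filter.
  Proxies are placed around random leads with r² in [0.5, 1] and
  distances up to ±600 kb so both LD filters have work to do.
- **REMs**: every planted site is covered by one REM linked to its
  target gene with random padding; decoy REMs avoid all SNP positions.
- **Expression**: one latent factor per co-expression module; the
  non-coding gene and its 10 partner coding genes load on the factor
  with additive Gaussian noise (default sd 0.1 at loading 1); all other
  genes are independent noise; a global shift keeps the matrix
  nonnegative (rank correlations are unaffected).
- **Disease catalogue**: one target term containing all planted partner
  genes plus 5% background, and one control term sampled purely at
  background rate.

Identical scenarios produce byte-identical output files; every artifact
is written in the external format the consuming module reads (FASTA,
TRANSFAC, TSV/CSV), so fixtures double as format tests.

### What passing tests do and do not show

The generator's genome has no repeat structure, no GC heterogeneity and
no linkage disequilibrium beyond the fabricated proxy table; its motifs
are screened for compatibility with the scorer's Laplace null, whereas a
real motif library contains members for which the approximation is
poorer; its expression model has a single factor per module and no
tissue covariance. Green tests therefore demonstrate the correctness of
the machinery and the calibration of the statistics *under the stated
model*, not the biological error rates to expect on real human data.

## Numerical choices

- Coordinates: 1-based SNP positions in all input tables (VCF
  convention), 0-based half-open intervals internally and for REMs (BED
  convention); conversion happens at read time.
- Window-score discretization: 0.01 bits.
- Zero frequencies with pseudocount 0: a −100-bit sentinel replaces
  −∞ so window sums stay finite.
- Ties: window ties to smaller offset then '+' strand; partner-rank ties
  lexicographic by gene id; duplicate association rows keep minimum p;
  duplicate proxies keep maximum r².
- Multi-allelic variant rows expand to one biallelic record per alt;
  indels are skipped with a warning; a ref allele contradicting the
  genome is skipped with a warning.
- Scale estimation floor: 100 scoreable null SNPs per motif.

## Known limitations

- The Laplace null is an approximation; its measured adequacy on the
  default scenario (per-motif KS ≲ 0.05 at n = 2,000) does not transfer
  automatically to arbitrary motif libraries.
- The extreme tail of the null is slightly heavy: across generator
  seeds, the emitted null-pair count at the 10⁻³ cutoff runs about
  1.2–1.6× its nominal expectation. The excess events are SNPs that
  destroy or create a motif's anchor column in a window with favourable
  context — genuine binding-change events under the scoring model that
  the synthetic ground truth nevertheless labels null. The same
  behaviour is expected (and unmeasurable) with real motif libraries,
  where dbSNP "null" panels also contain true binding-altering variants.
- LD is consumed, never computed: the package cannot assess proxy
  completeness.
- The enrichment universe matters and real catalogues do not state one;
  results should be read relative to the configured universe.
- Guilt-by-association transfers annotation, not mechanism; co-expressed
  partners of a non-coding gene are hypotheses, not targets.
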