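# Methods

This note documents the models, algorithms and parameter choices behind
`corebind`, what the synthetic data emulate, and the limits of what
passing tests demonstrate.

## Coordinates and interval semantics

All internal coordinates are 0-based half-open.  BED is passed through
unchanged; GFF3 (1-based closed) is converted on read and back on write.
Overlap requires at least one shared base pair, so abutting intervals are
distinct — the convention of standard interval tools.  The binding-event
location of an interval is the single base ⌊(start+end)/2⌋ (floor for
even lengths, a convention the data do not constrain).  Within a
transcript, overlapping exons are merged before introns are derived as
inter-exon gaps; introns are deduplicated across transcripts.

## Core reconciliation

Datasets carry a technique label and an FDR tier (percent).  An interval
from any dataset at `high_tier` (default 1) is emitted iff it overlaps an
interval at ≤ `low_tier` (default 25) from a dataset of a *different*
technique; two datasets of the same technique never confirm each other.
The emitted geometry is the stringent interval's own span — not the
intersection or union with its confirmer — because the stringent call is
the better-localized one; overlapping emissions are then merged and their
support lists concatenated.  Requiring stringent evidence in one
technique and at least permissive evidence in the other trades recall for
the removal of technique-specific artefacts: with the default synthetic
tier sensitivities (0.7 stringent, 0.95 permissive per technique) the
expected site-level recall is
2·(0.7·0.95) − 0.7² ≈ 0.84, and the measured values (~0.83–0.86 across
seeds, precision ≥ 0.99) match.

## Gene assignment and binding features

Assignment uses the full interval: all genes overlapping ≥ 1 bp are hits;
otherwise the closest gene within `max_range` (default 10 000 bp) of
either interval edge is the hit, measured edge-to-edge; equidistant genes
are all assigned (no arbitrary winner).  An interval abutting a gene is a
"nearest" hit at distance 0.

Location classification uses the centre point only.  A centre inside a
gene span is genic; genic centres inside the merged exons of a containing
gene are exonic, otherwise intronic.  When several genes contain the
centre, a gene whose exons contain it wins, ties broken by smallest gene
id.  TSS distances are signed, positive downstream of the TSS in the
gene's reading direction (`strand_aware`); `literal_start` mode instead
uses the raw difference to the annotated gene start, reproducing the
simpler convention of taking the start coordinate as the TSS
approximation regardless of strand.  Equidistant TSSs break ties on gene
id.  The bound/unbound intron comparison calls an intron bound on ≥ 1 bp
overlap with a core interval and uses a two-sided Wilcoxon rank-sum test:
exact enumeration of all C(n+m, n) group assignments when both samples
have ≤ 8 observations (ties handled through average ranks; the two-sided
p doubles the smaller tail, capped at 1), tie-corrected normal
approximation with continuity correction otherwise.

## Invariant-set normalization

Two-colour quantities are M = log₂(sample/reference) and A = mean log₂
intensity; dye-swapped arrays are sign-flipped first (an involution).
The normalization is built for the regime where the majority of genes
genuinely change, which breaks global centring: the median gene is a
changed gene, so median-centring biases the unchanged class by roughly
the typical shift.

Selection of the invariant anchor set reconstructs per-array channel
intensities ch₁ = A + M/2, ch₂ = A − M/2 and ranks *both channels
jointly* in their pooled distribution.  A gene is a candidate when, on
every array, the fraction of the pooled distribution lying between its
two channel values is below `rank_diff_threshold` (default 0.05) and its
current |M| is below `max_abs_m` (default 0.5).  Two deliberate choices:

- Pooled ranking, not within-channel ranking.  Ranking each channel
  separately makes the rank difference of a *truly unchanged* gene grow
  with the fraction of genes that changed (the bulk shift displaces the
  whole rank scale); against the pooled distribution the rank separation
  is proportional to the gene's own |M| and independent of what the rest
  of the genome does.
- The absolute |M| cap.  Rank separation carries almost no information
  in the sparse tails of the intensity distribution, where even a
  strongly changed gene has few neighbours between its channel values;
  without the cap, extreme-intensity changed genes contaminate the
  anchor set (~13% contamination in the default simulation; 0 with it).

Selection iterates: after each pass the per-array M is re-centred by a
lowess trend (span 0.4) fitted on the current candidates, and selection
repeats until the set changes by < 1% or 10 iterations.  The iteration
matters because the first pass truncates symmetrically around zero
rather than around the (unknown) dye-bias curve, biasing the implied
curve toward zero; re-centring makes the truncation symmetric around the
current estimate, so the residual bias contracts geometrically.  The
final normalization fits one lowess of the *original* oriented M on A
over the converged anchor set and subtracts it from all genes, then
removes the anchor genes' median.  Because the converged selection is
symmetric around the true bias curve, this final fit is unbiased even
though the anchor set is a truncated sample.

Anchor-set recall is intentionally modest: a truly unchanged gene must
pass the rank window on *every* array, and with replicate noise
σ ≈ 0.3 against a window of ~0.28 in M units the per-array pass rate is
~0.65, so the intersection over four arrays retains on the order of a
fifth to a third of the unchanged genes.  That is sufficient (hundreds
to thousands of anchors) and harmless — what matters for the fitted
curve is that the anchor set is uncontaminated and symmetrically
selected, not that it is complete.

Differential expression is a per-gene two-sided one-sample t-test of the
oriented, normalized M against 0 (df = n−1), an ordinary rather than
moderated statistic: it is exactly testable, and with four replicates at
the effect sizes of interest the thresholds, not variance moderation,
determine the calls.  Genes with < 3 non-missing replicates are
"untested"; zero-variance genes get p = 1 when aveM = 0 and p = 0 (with
a warning) otherwise.  Call tiers: strict |aveM| ≥ 1 and p < 0.01;
moderate |aveM| ≥ 0.5 and p < 0.05.

A column-wise quantile normalizer (per-rank means, ties receiving the
mean of their tied-rank targets, NaN-aware through quantile
interpolation) is provided as a shared utility for sample/control
channel preprocessing.

## Targets and enrichment

Direct targets are the intersection of the bound gene set with the
up/down DE calls at a chosen tier; direction and supporting interval ids
are carried.  Term enrichment is the exact hypergeometric upper tail
P(X ≥ k) with Holm–Bonferroni correction applied per enrichment run.
The gene-length correction replaces the hypergeometric null with an
empirical one: R (default 10 000) query-sized gene sets drawn without
replacement with per-gene probability proportional to gene length
(Gumbel top-k sampling, which realizes exactly this distribution), and
p = (1 + #{k\* ≥ k})/(R + 1).  Rationale: under uniform binding, longer
genes accumulate more intervals, so a binding-derived query is
length-biased; resampling with the same bias cancels it, and the
empirical p converges to the hypergeometric p as the length spread
vanishes.  Orthologue mapping expands many-to-many tables to all
partners and reports the overlap count with a comparison set.

## Co-occurrence testing

The observed statistic S is the number of first-set intervals overlapped
by ≥ 1 second-set interval.  The null re-places every second-set
interval uniformly at random on its original chromosome, preserving its
length; p = (1 + #{S\* ≥ S})/(n_samples + 1), one-sided for enrichment.
Chromosome and length preservation keep the marginal interval
composition fixed; the null does not model mappability, GC or
inter-interval spacing.  Each unordered TF pair is tested once with
labels in lexicographic order (the second resampled), after union-merging
multiple datasets per TF; descriptive counts and percents are reported
for both directions from the observed data, and Benjamini–Hochberg
adjusts across pairs.  The add-one estimator is never below
1/(n_samples+1); with a discrete count statistic and ties counted
conservatively (≥), it is slightly superuniform under the null, by about
the expected tie mass E[P(S\* = S)] ≈ (2πλ)^(−1/2) for an overlap count
with mean λ.  The default synthetic TF-pair size (2500 intervals per set
on a 4 × 5 Mb genome, λ ≈ 300) keeps this discreteness artifact an order
of magnitude below the resolution of the calibration checks; it is also
the realistic scale for embryonic TF binding datasets (thousands of
intervals).

## Motif scanning

PWM counts are smoothed with ε = 0.25 per cell: p(b, i) =
(count + ε)/(total + 4ε).  The background is a first-order Markov chain
fitted from the scanned sequences themselves (add-1 smoothing on
transitions; initial probabilities from overall base frequencies; a base
never observed as a predecessor gets a uniform row).  The weight of a
word w is log₂ P_pwm(w) − log₂[π(w₁)·∏P(wᵢ|wᵢ₋₁)], using π at the word's
first base rather than the chain's stationary distribution (simpler and
directly testable).  Log base 2 and the retrieval threshold (default 4)
are parameters, since scanning tools differ in both.  Both strands are
scanned; a reverse-strand hit is the forward score of the window's
reverse complement, reported at the forward offset.  Non-ACGT bases
invalidate any window containing them.  By Gibbs' inequality the
expected weight of background-generated words is ≤ 0.

## Synthetic data

The generator is the package's study design; one top-level seed fans out
to per-stage child seeds (`numpy` SeedSequence spawn keys) so stages are
independently regenerable and the full run is deterministic.

- **Genome/annotation**: 4 chromosomes × 5 Mb, 2000 non-overlapping
  genes of 1–10 exons; intron lengths from a log-normal mixture
  (natural-log μ 4.8/8.5, σ 1.0/0.7, 80/20 short/long — medians ~120 bp
  and ~5 kb, echoing the strongly bimodal intron-length landscape of
  compact insect genomes); exon lengths log-normal (~300 bp); uniform
  random sequence.
- **Binding evidence**: 500 true sites (25% within ±500 bp of a gene
  start, the rest uniform), lengths U(200, 800).  Per technique a site
  is detected at the permissive tier with probability 0.95 and, nested,
  at the stringent tier with probability 0.7, its span jittered ±50 bp;
  50 (stringent) / 500 (permissive, nested) uniform false positives per
  technique.  This reproduces the qualitative structure of tiered peak
  calls: stringent = high precision/moderate recall, permissive = the
  reverse, artefacts independent between techniques.
- **Expression**: 35% invariant genes (M = 0), the rest at ±2 with 90%
  down; per-array smooth intensity-dependent dye-bias curves (amplitude
  ≤ 0.3), noise σ = 0.3, four arrays of which two dye-swapped.  The
  65%-changed, down-dominated regime is exactly the one that defeats
  global centring.
- **TF pair**: fraction ρ (default 0.5) of the second set copied from
  the first with ±100 bp jitter, remainder uniform.
- **Sequences**: 1000 × 500 bp uniform background; a word sampled from
  the PWM planted at a recorded offset in 80% of sequences.  The default
  synthetic PWM (8 bp, consensus CAACAATG, 300:1 counts) is deliberately
  high-information so a sampled word almost surely clears weight 4,
  keeping planted signal separable from background matches.

What the synthetic data do *not* emulate: probe-level tiling-array
signal, chromatin context and mappability, HOT regions, correlated
false positives between techniques, heterogeneous effect sizes in
expression, and motif instances at realistic information content.
Passing recovery tests therefore demonstrates correctness of the
algorithms under their stated assumptions, not performance on real
embryo data.

## Numerical and engineering choices

Overlap queries use per-chromosome sorted starts with running-maximum
ends (binary search, no tree dependency).  Lowess curves are evaluated
at new points by linear interpolation with flat extrapolation.  All
randomness flows through explicitly seeded `numpy` Generators; pipeline
outputs are plain text with fixed float formatting, and identical
config+seed reproduce a run directory byte for byte.  Problem sizes in
the test-suite simulations (e.g. 10 000 genes × 4 arrays for the
normalization recovery check; 200 seeded pairs × 200 resamples for
co-occurrence calibration; 200 random instances for each brute-force
oracle comparison) were chosen so the whole suite completes in well
under a minute per module while keeping Monte-Carlo error far from the
asserted margins.

## Known limitations

- The co-occurrence null ignores spacing structure and genome
  accessibility; against clustered real peaks it is anti-conservative.
- The invariant-set method needs the unchanged class to be a coherent
  minority near M = 0 (up to a smooth intensity bias smaller than the
  typical true change); if *every* gene changed, no internal anchor
  exists.
- Enrichment treats terms independently (no ontology DAG propagation).
- The GFF reader handles gene/mRNA/exon features with ID/Parent
  attributes only; identifier namespaces are matched exactly.
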