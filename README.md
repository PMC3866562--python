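# corebind

Integrative analysis of transcription-factor binding and expression data
for regulatory genomics.  The package addresses a recurring problem in TF
studies: genome-wide binding maps from any single technique (DamID,
ChIP-chip) carry technique-specific artefacts, mutant expression profiles
in which *most* genes change defeat standard normalization, and "bound"
alone is a weak predictor of regulation.  `corebind` implements the full
chain from raw interval sets and two-colour array measurements to a
high-confidence direct-target gene list, with every stage testable on
seeded synthetic data carrying planted ground truth.

## What it computes

**Core binding intervals.** Given interval sets labelled with technique
(`damid`/`chip`) and FDR tier (e.g. 1% stringent, 25% permissive), an
interval called at the stringent tier enters the core set iff it overlaps
(≥ 1 bp) a call at or below the permissive tier from a *different*
technique; confirmed stringent spans are emitted and overlapping
emissions merged, with full provenance.

**Gene assignment.** Every gene overlapping an interval is a hit; an
interval overlapping no gene is assigned its closest gene within 10 kb of
either edge (edge-to-edge distance, equidistant ties all kept).

**Binding features.** Each interval is represented by its centre,
⌊(start+end)/2⌋, and classified exonic/intronic/intergenic; signed
distances to the nearest TSS are profiled (±500 bp window); bound vs
unbound intron lengths are compared with a Wilcoxon rank-sum test (exact
enumeration for small samples, tie-corrected normal approximation
otherwise); overlap with enhancer catalogues is counted per category.

**Invariant-set expression normalization.** For the regime where the
majority of genes genuinely change, per-array channel intensities
ch₁ = A + M/2, ch₂ = A − M/2 are ranked against their pooled
distribution; genes whose two channel values occupy nearly the same
pooled quantile on every array (and whose |M| stays under an absolute
cap) form the invariant anchor set, refined iteratively with lowess
re-centring.  A lowess curve of M on A fitted over the anchor genes only
is subtracted from all genes.  Differential expression is a per-gene
one-sample t-test of the oriented, normalized M against 0, with calls at
|aveM| ≥ 1 and p < 0.01 (strict) or |aveM| ≥ 0.5 and p < 0.05
(moderate).  Dye-swap replicates are sign-flipped before analysis.

**Direct targets.** Target genes = bound genes ∩ DE-called genes, with
direction and supporting intervals carried along.

**Co-occurrence.** For two TF interval sets, the statistic is the number
of first-set intervals overlapped by the second; the null re-places each
second-set interval uniformly on its own chromosome, preserving length,
and p = (1 + #{S\* ≥ S})/(n<sub>samples</sub> + 1).  The pairwise driver
union-merges each TF's datasets, tests every unordered pair once, and
adjusts with Benjamini–Hochberg.

**Motif scanning.** Words are scored as the log₂ likelihood ratio of a
pseudocount-smoothed PWM against a first-order Markov background fitted
from the scanned sequences; matches with weight ≥ 4 are retrieved on both
strands.

**Enrichment.** Upper-tail hypergeometric term tests with Holm–Bonferroni
correction, or a gene-length-corrected empirical null (query-sized gene
sets resampled without replacement with probability ∝ gene length),
cancelling the bias of long genes accumulating more binding intervals.

## Worked example

Run the whole synthetic study end to end (a 20 Mb genome, 2000 genes,
500 planted binding sites, two techniques × two tiers, four arrays with
two dye swaps and 65% of genes changed):

```
corebind run --seed 1 --out run1
```

The run log reports, stage by stage:

```
core: 418 reconciled intervals
assignment: 419 hits, 362 bound genes
features: 79.2% genic, 68.0% of genic intronic; 84/418 within 500 bp of a TSS
expression: 256 invariant genes; DE at strict tier: 126 up, 1170 down
targets: 239 bound-and-DE genes
cooccur: pvalue=0.00497512 over 200 resamples
motif: 870/1000 sequences with a match (fraction 0.8700)
metrics: target precision 0.992, recall 0.865
```

Reading it: of the planted binding evidence, 418 intervals survive
cross-technique reconciliation; most sit in genes and predominantly in
introns; 1296 genes pass the strict DE thresholds after invariant
normalization (down-regulation dominating by design); intersecting bound
with DE yields 239 direct-target genes, recovering the planted
bound-and-changed set with precision 0.992 and recall 0.865.  The planted
half-shared TF pair is called co-occurring at the resampling floor
(p = 1/201), and 87% of sequences carry a motif match (80% planted plus
background matches).  Identical seed and config reproduce the run
directory byte for byte.

Each stage is equally usable on real files (BED, GFF3, FASTA, TSV) via
the `corebind` subcommands `core`, `assign`, `features`, `normde`,
`targets`, `enrich`, `cooccur` and `scan`, or from Python through
`corebind.*` — see `docs/methods.md` for the model details and parameter
meanings.

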