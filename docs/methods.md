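# Methods

This note documents the models behind `cenfiber`'s generators and analyses,
the defaults and why they were chosen, and what the synthetic data does and
does not emulate.

## Synthetic genome and chromatin

A toy genome is a set of equal-length chromosomes (default 8 × 40 kb for
study-scale runs) with methylatable sites drawn independently per base with
probability `at_fraction` (default **0.6**). Strand handling is collapsed:
the methyltransferase acts on adenines of either strand, so the methylatable
set corresponds to the A/T positions of a real genome, and budding-yeast
genomes are roughly 60% AT. Coordinates are 0-based half-open (BED
conventions) throughout.

Each centromere is a `CentromereModel`: an annotated interval whose CDE
lengths default to (8, 165, 25) bp — CDEI and CDEIII are short
protein-binding boxes, CDEII the AT-rich element carrying the centromeric
nucleosome (165 bp in *K. marxianus*, ~half in *S. cerevisiae*) — plus a
protected-region architecture: one centered block of `protected_width` bp
(single-nucleosome model) or two blocks separated by an accessible linker
(double-nucleosome model). Protected blocks may extend up to one nucleosome
length past the annotated centromere, since a wrapped nucleosome can protect
flanking DNA.

Bulk chromatin tiles each chromosome with 147-bp protected intervals
separated by integer linkers ~N(20, 10) truncated at 0; within one
nucleosome length of a centromere the tiling is replaced by the centromeric
block(s). Two phasing modes exist for fiber simulation:

* `bulk_phasing="genome"` (default): all fibers share the genome-wide
  layout. This keeps a single ground truth against which footprint recovery
  can be checked exhaustively.
* `bulk_phasing="fiber"`: each fiber re-draws its bulk nucleosome phase
  (centromeric blocks stay fixed). This emulates the fact that each sequenced
  molecule comes from a different cell, where only strongly positioned
  features line up across molecules. It is the mode under which the averaged
  cross-centromere density profile shows the in-vivo behaviour — a peak at
  the centromere center — because genome-phased bulk nucleosomes would
  otherwise produce flank positions as dense as the centromere.

## Fiber methylation model

Fibers get uniform random starts over concatenated chromosome coordinates
and normal lengths (mean 15 kb, sd 3 kb, clipped to ≥1 kb and the chromosome
end), matching long-read lengths >10 kb. Every methylatable site is
methylated independently: probability **0.8** in accessible DNA (efficient
but incomplete labeling) and **0.02** inside protected intervals (incomplete
protection plus miscalls). The background rate matters: it is the reason the
study filters footprints >400 bp (incomplete methylation can merge a real
footprint with flanking DNA), and the generator deliberately produces such
artifacts. Neither rate is measured for Hia5 in these strains; the defaults
are round values in the regime the method requires (strong accessible/
protected contrast, non-zero background), and the analyses are
sensitivity-tested against them (the footprint caller's monotonicity test
varies the protected rate from 0 to 0.3).

Not emulated: sequencing error, base quality, polymerase kinetics, diploid
genomes, replication intermediates, strand-resolved methylation. Passing
tests therefore show the statistics recover a known architecture from
realistic per-site noise — not that any upstream base caller is accurate.

## Footprint calling

The caller is a run-length rule over each fiber's methylatable sites in site
order (genomic gaps between sites carry no information — a 165-bp AT-rich
element simply contains more sites):

1. every run of ≥ `split_run` (default **2**) consecutive methylated sites
   is a hard boundary;
2. segments between boundaries are trimmed to their outermost unmethylated
   sites;
3. a segment is emitted if it has ≥ `min_sites` (**5**) unmethylated sites
   and spans ≥ `min_len` (**80**) bp.

Tolerating isolated methylated sites is the load-bearing choice. At a 2%
background rate, a 227-bp protected block (~136 sites at `at_fraction` 0.6)
contains at least one methylated site on ~93% of fibers; a caller that split
on every methylated site would shatter most centromeric footprints and could
not recover the true width as a median. Adjacent methylated *pairs* inside
protected DNA are rare (~5% per block), while accessible linkers at an 80%
per-site rate contain a pair almost surely, so the ≥2-run boundary preserves
true edges with ~1-2 bp bias. `split_run=1` recovers the strict splitting
rule for users who want it. No further gap-bridging is performed.

Spans are classified by `nucleosomal_range` (80, 200): below is
subnucleosomal, inside nucleosomal, above oversize. Oversize footprints are
retained — the 227-bp centromeric footprint *is* oversize relative to a
canonical 147-bp nucleosome — and the >400 bp exclusion is applied only in
the centromeric size extraction, where the study applies it. Footprints
truncated by fiber ends are flagged boundary-censored but kept (a flag
excludes them if desired).

## Occupancy statistics

Windows are centromere center (floor of the interval midpoint) ±1000 bp.
Nucleosome density at a base is the number of nucleosome-class (nucleosomal
+ oversize) footprints overlapping it divided by the number of fibers
overlapping it; bases with zero fiber coverage are undefined (NaN), not
zero, and are excluded from the cross-centromere unweighted average.
Subnucleosomal footprints are excluded from the numerator. Overlap semantics
everywhere are half-open intersection of length ≥1 bp. Per-fiber footprint
disjointness guarantees density ∈ [0, 1], and duplicating every fiber leaves
the profile unchanged.

The species comparison uses the classic pooled-variance unpaired two-tailed
*t*-test (Welch available behind a flag); identical zero-variance samples
report t = 0, p = 1 by convention. Medians and quartiles are reported
alongside, since the size distributions are the scientifically meaningful
summary.

### Single- vs double-nucleosome call

A fiber must span the whole centromere to be informative. It is called
**single** when exactly one footprint covers ≥90% of the centromere;
**double** when ≥2 nucleosome-class footprints overlap the centromere with
≥2 methylated sites in the gap between them (methylated linker DNA);
otherwise **ambiguous**. The count of methylated sites strictly inside the
centromere is reported per fiber but does not cap the single call by
default: at the default background rate a 227-bp protected region carries
~2.7 internal methylations on average, so a cap of 1 would misclassify ~75%
of genuinely single-nucleosome fibers as ambiguous; an optional
`max_internal_methylations` restores a strict cap.

## Rupture-force survival analysis

Force is the survival axis: the load ramps linearly (0.25 pN/s), so force is
time up to scale. Escapes are right-censored at their recorded force — the
attachment demonstrably survived to that force. The generator draws rupture
forces from a Gaussian mixture truncated at 0 (component resampling), flags
a Bernoulli `censor_fraction` of events as escapes, and records each escape
at a uniform fraction of its latent rupture force (censoring precedes
rupture). A helper shifts all component means by a constant so the mixture
median hits a target exactly, letting tests parameterize generators by the
reported medians while keeping the mixture shape.

The Kaplan-Meier estimator processes distinct rupture forces in order;
censored events tied with a rupture force remain in the risk set at that
force. The running product is computed in exact rational arithmetic
(`fractions.Fraction`), so with no censoring the estimator reduces to the
empirical survival function bit-for-bit. Greenwood's formula supplies the
variance and the 95% band uses the log(−log) transform (a common default;
the band construction is otherwise unspecified). The survival median is the
smallest breakpoint with S ≤ 0.5 (the R `survival`/lifelines convention),
and is signaled as undefined when the curve never reaches 0.5.

The log-rank test sums observed minus hypergeometric-expected rupture counts
with the standard variance over distinct rupture forces; χ² with 1 df,
two-sided. Escapes are included as censored observations by default
(`include_escapes=False` drops them), and a group with zero ruptures
triggers a warning rather than an error. Type-I error calibration is
regression-tested: over 1,000 null pairs (n = 50 per arm, 10% censoring) the
rejection rate at α = 0.05 must sit within 3 binomial standard deviations
of 0.05.

Bimodality is assessed by fitting 1- and 2-component Gaussian mixtures
(EM, 5 starts, fixed seed) to rupture forces only (censored forces carry no
modal information) and comparing BIC; "bimodal" requires the 2-component
fit to win by ≥6 BIC units, the usual strong-evidence convention, with a
unimodal fallback on non-convergence. Requires n ≥ 20.

## Distance geometry

Distance samples are log-normal, parameterized by their true median (the
log-normal median is exp(μ), so μ = ln median) with log-scale sd 0.3 for
inter-kinetochore distances and 0.15 for doublet lengths — spreads chosen to
resemble the reported interquartile ranges. All values are nanometers
internally; the CSV reader converts μm inputs. The consistency report gives
two readings of "doublets fit the inter-kinetochore distribution": the
fraction of doublet lengths inside [min, max] of the inter-kinetochore
sample, and the fraction within ±`tol` (default 100 nm) of its median, plus
shared-bin (50 nm) histograms for an overlay. Both fractions are invariant
under common rescaling, and the tolerance-based fraction is monotone in
`tol`. Whether a tomographic end-to-end length and a fluorescence
center-to-center distance are strictly commensurable is a biological caveat
the statistics cannot resolve.

## Pipeline, formats, reproducibility

The pipeline driver chains simulate → call → occupancy → rupture → geometry
from a YAML config, writes every intermediate as plain text (fiber table
TSV, BED6, BED6+2 footprints, bedGraph densities, CSV events/distances,
TSV reports), and records a manifest with parameter echo and SHA-256
digests. Every generator takes one integer seed and derives all sub-draws
from a single stream; whole-pipeline digests are a pure function of
(config, seed). An adapter converts MM/ML-tagged aligned long reads
(SAM/BAM, m6A calls with likelihood ≥128/255) into fiber records for
real-data entry.

## Problem sizes

Study-scale checks use 8 centromeres × 40-kb chromosomes with 1,000 fibers
(~47× coverage, ~370 filtered centromeric footprints per run, batched to
≥1,000 for the species *t*-test), 200-800 fibers for architecture calls,
n = 200 rupture events per condition, and 1,000 simulated pairs for log-rank
calibration. These sizes put Monte-Carlo error well inside each check's
tolerance (e.g. the KM median's sampling sd at n = 200 is ~0.3 pN against a
±0.5 pN recovery criterion) while keeping any single run in seconds.

## Known limitations

* The footprint caller is a deterministic run-length rule, not a
  probabilistic segmentation; it inherits a ~1-bp conservative boundary bias
  (edges at outermost unmethylated sites), which cancels in species
  comparisons but is present in absolute sizes.
* Single/double discrimination degrades as the linker shortens below the
  inter-site spacing; the default parameterization (30-bp linker) is
  comfortably detectable.
* The BIC bimodality call depends on mixture separation relative to
  component sd; weakly separated mixtures (Δ/σ ≲ 2.5) at n ≈ 200 are often
  preferred unimodal. This conservatism is intentional (margin 6).
* The log-rank χ² approximation is asymptotic; for very small groups the
  exact permutation distribution is not implemented.
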