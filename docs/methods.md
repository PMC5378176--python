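# Methods

## Coordinate conventions and interval algebra

All coordinates are 0-based half-open (BED convention); 1-based inputs must
be converted at the boundary. The *center* of an interval is
`floor((start + end) / 2)` and is the reference point of every
site-centered analysis; no summit information is used. Two intervals
overlap iff they share ≥ `min_overlap` bp on the same chromosome (default
1 bp), so adjacent half-open intervals never overlap. Strand is ignored for
overlap and used only in motif scanning. Peak "strength" is the BED score
column, treated as an opaque ordinal quantity; nothing downstream assumes a
particular strength metric (fold enrichment, −log p, read count, ...).
Overlap queries run on an interval tree; tests check exact agreement with
an all-pairs brute force.

## Peak partitioning and classification

Partitioning removes, per strain, peaks overlapping the Prdm9-KO set
(`removed`), then pools peaks overlapping the other strain's remainder
(`common`, matched by any-overlap, not 1:1), leaving `specific`. The three
parts exactly reconstitute the input per strain.

Classification consumes *binary* overlap evidence against called DMC1 and
H3K4me3 peak sets. H3K4me3 status is `strain_specific` when an H3K4me3
peak of the focal strain overlaps the PRDM9 peak and no H3K4me3 peak of
the other strain does; `shared` when both strains' marks overlap; `none`
otherwise. The six-cell decision table is

|           | strain-specific K4 | shared K4 | no K4 |
|-----------|--------------------|-----------|-------|
| DMC1 +    | 1a                 | 1b        | 1c    |
| DMC1 −    | 1d                 | 2A        | 2B    |

Subclass 1c (DMC1-positive, mark-free) is retained as a label because the
grid logically contains it, even though it is rare in practice. Peaks
common to both strains are classified with a shared-vs-absent H3K4me3 call
only, since a strain-specific call is impossible there. Design choice:
real analyses may call "enrichment" from signal rather than binary peak
overlap; thresholds for such calls are not part of this package's surface,
and binary overlap with called peaks is used throughout.

Strength bins are equal-count quantile bins (sizes differ by ≤ 1), ordered
by increasing score, with ties broken by coordinate; the per-bin overlap
fraction against a second set yields the Spo11-dependence profile.

The class-distribution test is a one-sample Pearson goodness-of-fit of one
genotype's (class 1, 2A, 2B) counts against the other genotype's
proportions: `E_i = N_obs · ref_i / N_ref`, χ² = Σ (O_i − E_i)²/E_i, df = 2.
This form — not the 2×3 contingency test, which gives ≈ 244.9 on the same
counts — reproduces the published statistics (272.26 and 431.24) exactly
from their printed count triples; the contingency variant remains available
behind `method="contingency"`.

## GC* estimation

Polarization applies strict parsimony to (domesticus, castaneus, outgroup)
base triples: if the focal bases disagree and the outgroup matches one of
them, a single substitution is assigned to the other branch with the
outgroup base as ancestral. Sites where all three agree contribute to the
ancestral weak/strong opportunity tallies of both lineages (as do call
sites); sites where the outgroup matches neither focal base, or with any N,
are discarded entirely. Back-mutations and outgroup-branch changes are
assumed absent, matching the generator's single-event branches so recovery
is exact in expectation.

Counts aggregate in 10-bp bins of the offset d = pos − center over all
centers, d ∈ [−extent, extent) with extent 2 kb by default (bin width from
the figure convention; extent chosen to cover the visible flanks). A
position inside two centers' windows is counted once per center; the
generator's minimum site separation (4.5 kb default) makes this rare.

The estimator is opportunity-normalized: r_WS = n_WS/N_W, r_SW = n_SW/N_S,
GC\* = r_WS/(r_WS + r_SW), undefined (NaN, never 0) when no informative
event falls in a bin. The raw count ratio n_WS/(n_WS + n_SW) is confounded
by base composition and is available only as a `raw_ratio` sensitivity
variant. W→W and S→S substitutions never enter the estimator. A
delta-method standard error from the two binomial counts accompanies every
bin. An `exclude_cpg` flag (off by default) drops calls whose ancestral
base forms a CpG with an adjacent tabulated position, since CpG
hypermutability can mimic S→W flux.

Smoothing uses a cubic smoothing spline with the penalty chosen by
generalized cross-validation (`lam=0` interpolates); its residual sum of
squares is bounded by the constant-mean fit. The lineage contrast is a
Welch two-sample t-test on per-bin GC\* values whose bin midpoint lies
within ±500 bp of the center (per-bin, not per-peak, testing; "Student"
equal-variance form available via `equal_var=True`). Degenerate
zero-variance inputs with equal means return t = 0, p = 1. The expected
elevation is reported for both lineages at every site set; the matching
allele/lineage pairing (Dom2→domesticus, Cst→castaneus) is never
hard-coded into the estimate.

## Motif scanning

PWMs are position-probability matrices regularized with pseudocount 0.01
per cell (columns renormalized), scored as log₂ odds against background
base frequencies (uniform by default). The default hit threshold is 80% of
the maximal attainable score; windows containing N are skipped without
error. Reverse-strand scoring uses the complemented, position-reversed
matrix and reports hits at forward coordinates. Positional densities
histogram hit *start* offsets (a deliberate convention — it shifts
densities by up to the motif width relative to midpoint assignment) in
[−extent, extent] and sum them in 50-bp windows advanced 1 bp, giving
2·extent − w + 2 windows. Hits are counted per position, not once per
peak; the per-peak notion is served separately by
`motif_containing_count`. The randomized control redraws each peak's start
uniformly on its own chromosome, preserving chromosome and length only
(GC-matched shuffling was considered and not implemented; at the uniform-
background scale of the generator it would be indistinguishable).

## Coverage metaplots

Tracks are per-bp counts with an explicit library size; replicate pooling
sums counts and library sizes before normalization. Profiles are computed
at 1-bp resolution in RPKM (count · 10⁹ / library size for a 1-bp window)
and combined with the matched input by subtraction or by a ratio
stabilized with a pseudovalue defaulting to the input's genome-wide mean
RPKM; the mode is a required argument, never a silent default, because
both conventions are in common use. Sites whose window exceeds chromosome
bounds are skipped with a warning. The intergenic-only filter (zero
overlap with gene annotations) precedes H3K36me3 metaplots to exclude
transcription-coupled signal; it is idempotent. Peak-strength/mark
correlations quantify the mark over the peak interval itself by default
(the window used for this in published analyses is not standardized) and
report Pearson and Spearman together.

## Density statistics

Window-count correlations pool all chromosomes' non-overlapping windows
into one genome-wide vector (per-chromosome averaging was the alternative;
pooling is the simpler defensible choice), including trailing partial
windows; a site belongs to the window containing its center. Pearson is
the headline coefficient with Spearman reported alongside, and results are
descriptive — no significance is attached, as window counts are spatially
autocorrelated. Feature-overlap percentages use exclusive context labels
with precedence promoter > genic > intergenic (rows sum to 100); CpG
overlap is reported independently.

## Synthetic data generator

The generator plants truth-labelled sites for two strains on an i.i.d.
random genome and derives every peak set from them, so that each
downstream stage has an exact expected answer:

* class 1 sites carry the strain's allele motif (consensus planted at the
  center), a DMC1 peak and strain-specific H3K4me3 (plus H3K36me3 in B6);
* class 2A sites sit in planted promoters with H3K4me3 in both strains,
  no DMC1, and a CpG island with probability 0.85;
* class 2B sites carry no marks; a CTCF motif is planted in 60% (B6) /
  11% (RJ2) of them, the published fractions;
* the Prdm9-KO set contains only nonspecific background peaks, which also
  contaminate both strains' sets and the Spo11-KO set;
* the Spo11-KO PRDM9 set contains the class 1 and 2B sites but no class
  2A sites (class 2A binding is DSB-dependent).

Key defaults, chosen once as desk-scale study conditions: 7-Mb
three-chromosome genome, background GC 0.42 (mouse-like), 50/20/30 class
1/2A/2B sites per strain, peak widths ~N(300, 60²) bp truncated at 120
(hotspot scale), log-normal strengths with class-ordered means
(1 > 2A > 2B), minimum center separation 4.5 kb so GC* windows rarely
overlap. Coverage is Poisson with background rate 0.05/bp and a Gaussian
enrichment kernel (20× at the apex, sd = width/4); the input track is pure
background and library sizes are realized totals.

Divergence is simulated per branch as at most one event per site:
weak→strong with probability u_WS (default 0.01), strong→weak with u_SW
(0.01), u_WS multiplied by m = 3 within ±300 bp of class 1 centers on the
lineage carrying the matching allele, giving planted
GC\* = m·u_WS/(m·u_WS + u_SW) = 0.75 at hotspot centers and 0.50
elsewhere. W→W/S→S events and outgroup-branch changes are off by default
and exist only to test estimator invariances. Everything is deterministic
under the configured seed, with independent RNG streams per stage;
regenerated outputs are byte-identical.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level noise and mappability, realistic
base composition (isochores, CpG islands as compositional features),
overlapping or clustered peaks, indels and alignment error in the
three-species table, CpG hypermutability, back-mutations, and polymorphism
segregating within lineages. Planted-truth recovery demonstrates
correctness of the bookkeeping and estimators, not robustness to these
real-data complications.

## Problem sizes and numerical choices

The acceptance checks run at desk scale, chosen as the package's own test
conditions: GC\* recovery uses 2000 class 1 sites on a 24-Mb genome with
±2-kb profiles (center-bin estimate compared at 3 delta-method SEs);
lineage-test calibration uses 200 replicates of 150 sites each with ±600-bp
profiles; the interval oracle uses 10⁴ intervals per set; the motif
enumeration oracle uses an 8-wide PWM (4⁸ enumerated w-mers) at a 50%
threshold so the exact hit probability is large enough to test sharply.
Genome-scale published counts (peak totals per strain, the 0.71
class-1/class-2B window correlation, CpG-overlap percentages on real
annotations) require the original raw data and whole-genome alignments and
are not recomputable here; the two chi-square statistics are recomputed
exactly from their printed count triples.

Floating-point policy: GC\* bins with no informative events are NaN and
excluded from splines and tests rather than imputed; BED scores round-trip
exactly via shortest-repr formatting; chi-square expected counts are never
rounded. Ties in strength binning break by coordinate so binning is a
deterministic total order.

## Known limitations

* Classification is binary-overlap-based; a signal-level enrichment caller
  would be needed to reproduce borderline class assignments on real data.
* The polarization model ignores outgroup-branch changes; enabling
  `outgroup_rate` in the generator quantifies the resulting site loss but
  no correction is applied.
* `positional_hit_density` supports step = 1 only.
* The pipeline runner orchestrates synthetic end-to-end runs; file-based
  inputs are supported stage-by-stage through the CLI subcommands rather
  than through `run`.
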