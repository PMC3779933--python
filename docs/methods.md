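# Methods

This note documents the models and algorithms implemented in `fosmidscreen`,
the defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Synthetic data

**Taxon sequence models.** Each taxon is an order-3 Markov chain over
{A,C,G,T}: 256 length-3 contexts, each with a 4-vector of next-base weights.
Random models draw each context row from a symmetric Dirichlet
(concentration 1.0 by default; 0.5 for "strongly distinct" taxa — lower
concentration pushes rows toward the simplex corners and makes 4-mer usage
more idiosyncratic).  An order-3 chain is the minimal model that gives taxa
genuinely different tetranucleotide distributions, which is exactly the
structure compositional binning assumes; it deliberately omits everything
else real genomes have (genes, GC skew along the replichore, repeats, mobile
elements).  Default genome length is 500 kb per taxon — a desk-scale stand-in
for multi-Mb genomes that still dwarfs a single 36–48 kb insert.

**Libraries.** Clones draw a taxon from the configured mixture, then a
uniformly placed insert with length uniform in [36,000, 48,000] bp (the
size-selection window of fosmid cloning).  A Poisson(`active_gene_rate`)
number of gene-planting events per clone (capped at 3) inserts enzyme
families — either one random mapped family or, when a linkage group is
configured for the taxon, a whole co-occurring family set — and the clone's
true activity profile is the union of the substrates those families map to.
The default rate of 0.05 planted genes/clone is a demonstration setting
chosen to yield enough confirmed clones (a few dozen per 1,520) to bin; the
validation experiments that emulate a production screen use 0.003,
matching the ~0.26% positive rates such campaigns report.

**Plate signal model.** Pooled-well readings are additive:
`value = background + host_background + Σ active-clone contributions +
N(0, σ_bg)`, clipped at 0, drawn independently per timepoint (24 h, 5 d).
No published signal magnitudes exist for these assays, so the defaults are
round numbers in arbitrary plate-reader units: background 5, σ_bg 1, active
contribution N(10, 1) — a strong (10σ) single-clone signal.  Nonzero
`host_background` models endogenous activity of a wild-type expression host
(amylase, phosphatase); 0 models the multi-knockout host.  Solid-media
phosphatase and protease assays are visual and modelled as binary readings
(modality `visual`); noise on visual scoring is not modelled.  The generator
performs no read-level simulation: the pipeline consumes assembled clone
sequences, as the post-assembly stage of the real workflow does.

**Annotations.** Per-ORF family tables emulate HMM-search output.  True
planted families are reported with probability 1 − `fn_rate`, e-values
log-uniform in [1e-30, 1e-2]; spurious records are added per clone as
Binomial(⌊insert/1.2 kb⌋, `fp_rate`) draws with e-values log-uniform in
[1e-3, 1], so the conventional 0.1 cut-off is exercised from both sides.

## Hit calling

Per (plate, substrate, timepoint), the threshold is mean + `sd_multiplier` ×
SD over **all** wells of the plate, negative controls included (the rule's
plain reading), with strict inequality and `sd_multiplier = 2`.  The SD is
the population flavour (divide by *n*): the plate's wells are the entire
population under test, not a sample; a switch (`population_sd=False`)
selects the n−1 flavour.  A well is positive if it passes at **any**
timepoint (`combine_timepoints="any"`); "all" and single-timepoint rules are
available.  Positive calls within 10% of the threshold are flagged
near-threshold; when a re-screen reading set is supplied, such calls must
reproduce to stay confirmed — mirroring the borderline activities real
screens fail to reproduce.  Confirmation is restricted to the substrates the
clone's pooled well was detected on: the expansion exists to confirm a
detected activity, and the restriction keeps pooled-phase and
individual-phase false positives from compounding.  Under pure Gaussian
noise the rule fires on ≈2% of wells per timepoint — an irreducible cost of
a fixed 2σ cut.

## TNF/ESOM binning

**Features.** Sequences shorter than 2 kb are excluded; the rest are cut
into non-overlapping 2 kb fragments, trailing remainders dropped.  Each
fragment's 256 overlapping 4-mer counts are accumulated on both strands
(insert orientation in a fosmid is arbitrary; switchable), windows
containing N skipped, and normalised to relative frequencies in fixed
lexicographic column order (AAAA…TTTT).  Features are z-scored per column
(population SD; constant columns map to 0) before training; `"none"` is one
switch away.

**Map.** The emergent SOM has ≥ ⌈5.5 × n_fragments⌉ neurons with
column/row ratio ≈ 1.6, toroidal topology (standard for emergent maps;
avoids border artifacts).  The codebook is initialised from a seeded uniform
distribution over each feature's data range.  Online training visits samples
in a seeded random order each epoch; the best-matching unit (BMU, minimal
Euclidean distance, ties to the lowest row-major index) and all neurons
within the current radius are pulled toward the sample with Gaussian weight
exp(−d²/2(r/2)²) times the learning rate.  Radius decays linearly 24 → 1 and
learning rate 0.5 → 0.05 over 20 epochs.  The codebook is float32 for
throughput; training is deterministic for a fixed seed.

**Bins.** The U-matrix assigns each neuron the mean codebook distance to its
8 toroidal neighbours; genome bins appear as connected low-height regions.
Automated extraction replaces visual map inspection deterministically:
neurons at or below the 60th U-percentile seed bins as toroidal 8-connected
components; seed components that remain connected when the threshold is
relaxed to the 85th percentile are merged (components separated only by
shallow intra-genome ridges belong together — the relaxed threshold plays
the role of the inspector's judgement of which valleys are one basin);
merged components smaller than 5 neurons become label 0 (boundary).  The
85th-percentile merge level is the midpoint of the range that proved stable
in development: much lower leaves single genomes split across map patches,
much higher (≥95) fuses distinct taxa.  `merge_q=None` disables merging; a
k-medoids alternative on the codebook and manual neuron-label tables are
also supported, and the U-matrix is always exportable for inspection.

**Assignment.** Each clone goes to the bin holding the plurality of its
fragments' BMU labels ("majority" read as plurality, since fragments may
span more than two bins), ignoring label-0 fragments unless a clone has
nothing else; ties go to the bin with the smaller mean fragment-to-codebook
distance and are flagged.

## Concordance

Annotations are filtered at e-value ≤ 0.1 with the lowest-e-value record
kept per ORF (per ORF, not per clone — one clone legitimately keeps several
families across ORFs).  Families map to substrates through an editable
two-column table shipped as package data; the default relation covers the
GH families named for these assays (GH1/GH3 β-glucosidases, GH9 cellulases,
GH10 xylanases, GH13/15/31/97 starch hydrolases, GH2/20/84/109
hexosaminidases, phosphatase and peptidase domains) and deliberately maps
carbohydrate-binding modules to nothing.  Unmapped families are logged, not
errors.  The four-state clone × substrate classification and its summaries
(confirmed-given-predicted proportion, undefined — not 0 — when nothing was
predicted; fully-concordant flag) are pure functions of the two profiles.

## Pipeline

One YAML config with a mandatory top-level seed drives a run; stage seeds
are derived from it, so a run is a pure function of the config.  Every
stage writes delimited-text artifacts plus a SHA-256 manifest; identical
config and seed give byte-identical bundles.  The design-arithmetic audit
recomputes plate/day/campaign throughput from the pooling parameters rather
than trusting configured totals.

## Validation experiment sizes

The seeded experiments in `fosmidscreen.validation` use: 50 pure-noise
96-well plates (4,800 wells) for the false-positive rate; 50 pooled assay
plates (76,000 clones, ~0.3% planted actives at a 6σ effect, one substrate)
for end-to-end sensitivity; and 5 taxa × 30 clones (~3,100 fragments,
~17,000 neurons) and 2 taxa × 30 clones for binning recovery, scored as
clone-level adjusted Rand index against the generating taxa.  These sizes
keep a full validation run within a few minutes on one CPU while leaving
hundreds of planted events behind each rate estimate.

## Limitations

- The signal model is additive Gaussian with no growth kinetics, plate
  gradients, evaporation edge effects or inter-plate drift; passing the
  sensitivity/specificity suites shows the logic is correct under the
  stated noise model, not that real plates behave this way.
- Synthetic genomes are compositionally homogeneous, so binning recovery
  here is an upper bound: real genomes carry horizontally transferred
  regions and local composition shifts that blur TNF signatures.
- The family → substrate relation is a curated best effort and is data, not
  code; predictions are only as good as that table.
- Visual (solid-media) assays are noise-free binary in simulation.
- No coverage- or marker-gene-based binning, no reference-database
  comparison, and no interactive map viewer (static exports only).
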