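# Methods

## The recording model

A plate image is a binary 8×12 grid, one bit per well of a 96-well
plate. The biological channel is modelled in three layers:

**Latent excision fraction.** Each well holds a population of recorder
cells; the fraction `f_w` of recording plasmids whose LoxP-flanked
segment was excised summarises that population's light exposure. We
model `f_w ~ Beta(9, 1)` for lit wells (mean 0.9) and `Beta(1, 9)` for
dark wells (mean 0.1). The Beta family is a deliberate modelling
choice: the real channel only guarantees that the two states' ratio
distributions are separable, and Beta gives bounded, skewed fractions
with tunable overlap. Degenerate point masses (`f_on=1, f_off=0`)
give the noiseless channel used for identity checks.

**Read depth.** Per-well read counts are negative binomial with mean
`depth_mean` (default 500) and size/dispersion 5, reflecting the strong
per-well amplification variability of barcoded amplicon pools; `inf`
selects Poisson and `None` a fixed depth. The defaults are package
choices — the study's real depth distribution lives only in its
deposited sequencing data, which this package does not require.

**Read structure.** Each read is a structured amplicon:

```
i7(8) | pad(20) | well-code(10) | [spacer(12), red only] |
left(20) | LoxP(34) | intervening(40) | LoxP(34) | right(20) | i5(8)
```

Excision removes `intervening + LoxP`, leaving exactly one LoxP site
(Cre acting on direct repeats). The red-light recording construct
carries the extra spacer barcode, which is how the two color channels
are separated in a co-culture. LoxP is the canonical 34-bp site; pad,
flanks, spacer and intervening sequences are fixed arbitrary constants
chosen to be mutually Hamming-distant (verified by tests) — the real
plasmid sequences are not public in printed form, and nothing downstream
depends on their identity, only on their distinctness. Substitution
errors are i.i.d. per base (default 0.1%); qualities are constant Q30
placeholders, and quality-aware decoding is out of scope. Single-end
full-template reads are the default; a paired-end mode (R1 = 5' barcode
end, R2 = reverse-complemented 3' locus end) is provided.

Pooling concatenates and shuffles read sets; dilution is Bernoulli
thinning at rate 1/factor; random access resamples index-matched reads
with replacement to `amplification×` their count and carries over other
reads at `off_target_rate`.

What the simulator does **not** emulate: PCR chimeras, index hopping,
context-dependent error spectra, indels, or recorder growth dynamics.
Passing tests therefore demonstrate the pipeline's correctness under a
clean, separable channel — not its accuracy on any particular real
sequencing run.

## Readout

Demultiplexing requires both i7 and i5 to match one index entry within
`max_mismatch` (default 1); distance ties are discarded rather than
broken, since a silently misassigned read corrupts a pixel of the wrong
image. Well-codes are matched the same way. Because reads are
positionally rigid amplicons, excised/intact classification uses a
fixed-offset 16-mer window directly after the first LoxP site (budget 2
mismatches): the window reads as the intervening region in intact
molecules and as the right flank in excised ones; both-or-neither is
AMBIGUOUS and excluded from ratios.

The per-well statistic is the bounded fraction
`r = n_excised / (n_excised + n_intact)` rather than the raw
excised:intact quotient — monotone-equivalent for any thresholding rule
but defined at zero intact counts and confined to [0, 1]. Wells with no
informative reads are MISSING (NaN), never 0: at 1000× dilution most of
the plate is MISSING and conflating that with "confidently dark" would
hide the failure mode.

## Deconvolution pipeline

`deconvolute` composes four stages on one channel's 96 ratios:

1. **LOF curation.** Local Outlier Factor is computed from first
   principles on the 1-D values (k-nearest neighbours, k-distance,
   reachability distance, local reachability density, LOF = mean
   neighbour-LRD over own LRD). Duplicate-saturated neighbourhoods get
   infinite LRD; the conventions inf/inf = 1 and finite/inf = 0 keep
   scores defined, which matters because noiseless plates consist
   entirely of duplicated 0/1 values. Neighbourhood sizes default to 20
   (blue) and 10 (red). A well is an outlier when its score exceeds
   both an absolute cutoff (default 2.5 — finite uniform backgrounds
   legitimately reach LOF ≈ 2 at their edges in 1-D, while detached
   points score far higher) and the strict (1 − contamination) score
   quantile (contamination default 0.05), which caps the damage any
   curation step can do at ~5% of wells and leaves all-tied score
   vectors untouched. Outliers are reassigned to the nearest inlier
   value (ties to the lower value); the operation is idempotent.

2. **Clustering.** Four methods share one interface:
   - *k-means* is solved exactly by dynamic programming over contiguous
     partitions of the sorted values (optimal in 1-D, deterministic —
     randomized restarts can only approximate this);
   - *GMM* is a univariate EM with deterministic initialisation from
     the exact k-means partition, tolerance 1e-6 on the log-likelihood,
     at most 500 iterations and a variance floor of 1e-6; the
     log-likelihood trace is recorded and is non-decreasing;
   - *DBSCAN* and *OPTICS* come from scikit-learn (eps defaults 0.2,
     min_samples 5, OPTICS ξ = 0.05); their noise points are attached
     to the cluster of the nearest clustered value, and an all-noise
     result falls back to a single cluster.
   Requested k is clamped to the number of distinct values inside the
   pipeline (a noiseless plate has only the values {0, 1}).

3. **Full ON/OFF assessment.** With cluster means sorted ascending, the
   plate is ALL_ON when even the lowest mean exceeds the cutoff and
   ALL_OFF when even the highest falls below it (cutoff default 0.5 on
   the bounded fraction; `calibrate_cutoff` instead takes the midpoint
   between the grand means of lowest and highest clusters across a
   collection of fitted plates).

4. **Cluster grouping.** Mixed blue plates map the lowest-mean cluster
   to OFF and all others to ON; red plates map the two lowest-mean
   clusters to OFF (the red construct's raw ratios run higher overall),
   or just the lowest when only two clusters exist. MISSING wells are
   excluded from stages 1–3 and called 0 at output ("no reads, no
   evidence of exposure"), with a logged warning; plate-level
   ALL_ON/ALL_OFF calls cover every well including MISSING ones.

`oracle_threshold` is the benchmarking counterpart: an exhaustive scan
of all midpoints between adjacent sorted ratios (ties resolved to the
lowest threshold) given foreknowledge of the truth. Both it and the
unsupervised pipeline achieve exactly 1.0 on the noiseless channel.

### Choosing k on synthetic data

The synthetic channel produces cleanly bimodal ratio plates, so the
matched clustering setting is two components/clusters, and the
examples, acceptance checks and CLI smoke configurations use
`gmm, k=2`. Three-component models remain in the menu and as the
library default because real plates show substructure (e.g. partially
excised populations) that a third component absorbs — but on bimodal
data a 3-component fit splits whichever mode is broader, and the blue
grouping rule then miscalls the upper OFF sub-cluster as ON
(`examples/clustering_workflow.py` shows this: gmm(3) drops to 0.5
where every 2-cluster method scores 1.0). This is a property of the
rank-based grouping rule, faithfully implemented, not of the mixture
fit itself.

## Barcodes

Well-codes default to length 10 with pairwise Hamming distance ≥ 3,
generated by greedy closure over a seeded random candidate stream; with
`d_min ≥ 2k+1`, any k-substitution corruption decodes uniquely
(verified exhaustively for small codes). The shipped 24-entry index
table pairs eight i7 and eight i5 placeholder 8-mers combinatorially —
stand-ins for commercial index kits.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use: 15 patterns × 7 method
settings for the noiseless identity; 10 seeds × 2 plates × 7 settings
for full ON/OFF; 20 seeds at depth 500 for noisy recovery and the
dilution curve (factors 1/10/100/1000); a five-image pool at 10,000
reads per well thinned 1000× for random access (thinning per plate
before pooling — distributionally identical to diluting the pool — to
keep the peak read count small); and 100 seeded EM fits for mixture
recovery. These sizes give stable statistics while keeping a full run
in minutes on one core. Every random draw flows from an explicit seed;
the CLI derives per-stage seeds from a master seed by stable CRC32
hashing of stage names, so any stage reruns identically in isolation.

## Known limitations

- Decoding assumes the fixed amplicon layout; indels or truncated reads
  are counted as unassignable rather than rescued by alignment.
- Patterns with four or fewer lit (or dark) wells on an otherwise
  uniform noiseless plate can lose that minority to outlier curation:
  a duplicate group smaller than the contamination allowance is
  indistinguishable from a low-density artefact by LOF. Real noisy
  ratios do not tie exactly, so the quantile guard rarely binds there.
- The red-channel grouping rule is rank-based and assumes its stated
  cluster layout; it is applied verbatim, not re-derived.
- Reported accuracies quantify recovery under the synthetic channel
  only; re-analysis of real deposited reads is a documented optional
  workflow, not part of the test suite.
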