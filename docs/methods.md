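# Methods

This note documents the models and procedures implemented in
`valleycall`, the parameters that matter, what the synthetic-data
generators do and do not emulate, and the numerical and design choices
made where the design was genuinely open.

## 1. Enhancer calling from histone-mark peaks

Active enhancers are flanked by H3K27ac-marked nucleosomes with a
nucleosome-depleted, factor-bound core, and lie outside
H3K27me3-repressed chromatin. The caller operationalises this as:

1. **Merge** — H3K27ac peaks that overlap or are book-ended are merged
   (`merge_touching_peaks`); the result is sorted and strictly
   separated.
2. **Valleys** — every *adjacent* same-chromosome peak pair with
   inter-peak gap `0 < g ≤ max_inner_gap` (default 3000 bp) yields a
   candidate valley, the interval between the two peaks. A peak may be
   the right flank of one valley and the left flank of the next.
   Restricting to adjacent pairs avoids nested and overlapping valleys;
   non-adjacent "bimodal" pairs would always contain a third peak in
   between, which contradicts the valley picture.
3. **Repressive exclusion** — a candidate is dropped iff its valley
   shares ≥ 1 bp with an H3K27me3 peak of the same condition.
   Book-ended repressive peaks do not disqualify. This is the strict
   reading of "devoid of" repressive marks, chosen for determinism; a
   coverage-ratio variant could be layered on top but is not needed for
   peak-call inputs.
4. **Annotation** — each valley is assigned to the gene minimising
   |TSS − valley midpoint| (signed distance, negative = TSS left of the
   midpoint; ties break to the smaller TSS coordinate, then
   lexicographic gene id, so outputs are deterministic). The midpoint
   anchor is configurable to nearest-edge. Genomic context uses the
   valley midpoint with precedence promoter > exonic > intronic >
   intergenic; the promoter window is strand-oriented
   [TSS − 2000, TSS + 500) by default — "close to a promoter" has no
   universal definition, so both bounds are parameters.

**Reported region.** The enhancer reported is the inter-peak valley,
not the peak-to-peak span: the regulatory core sits between the
flanking acetylated nucleosomes. `PutativeEnhancer.span` exposes the
full span for consumers that prefer it.

**Condition comparison.** Valleys from two conditions are linked when
their gap is ≤ 0 (overlap or book-ended). Because one valley can touch
two in the other condition, the link graph is collapsed into connected
components; each mixed component counts once as a "common" element, so
`unique + (members projected into components) = total` holds exactly on
both sides.

## 2. Signal profiles and clustering

`extract_matrix` computes, for each length-1 stranded anchor, the exact
length-weighted mean coverage in `bin_size` bins across ±`window`
(prefix-integral arithmetic, not sampling). Uncovered bases count as
zero; anchors within `window` of a chromosome start are zero-padded and
flagged. Minus-strand rows are reversed so bins are in anchor
orientation. Defaults: ±5000 bp windows with 50 bp bins (200 bins) for
motif-centred heatmaps; ±2000 bp for TSS profiles.

The metaprofile is the column mean. At active TSSs it exhibits the
peak-dip-peak shape (acetylation on both flanking nucleosome arrays, a
dip at the nucleosome-depleted start site); `has_peak_dip_peak` tests
exactly that — a central local minimum strictly below maxima located
off-centre on both sides.

Clustering is scikit-learn k-means with k-means++ initialisation, 10
restarts, 300 max iterations, tolerance 1e-6, fixed `random_state` —
bit-reproducible given the seed. k defaults to 5 (the number of
H3K27ac-positioning classes typically distinguished around a bound
motif: acetylation left, right, both sides, centred, weak). Rows are
not normalised before clustering by default (absolute signal carries
information); per-row max-normalisation is a flag. Heatmap row order is
cluster id, then row sum descending.

## 3. Motif analysis

A `PWM` stores a count matrix (width × ACGT), pseudocount (default 1.0)
and background (default uniform); column probabilities are
`(counts + pc·bg) / (total + pc)` and scores are log2 odds in bits.

**Exact thresholds.** The score threshold for a target p-value is the
smallest *attained* score `s` with `P(score of a background word ≥ s) ≤ p`,
computed by dynamic programming over the distribution of the
integer-rescaled score (lattice of 1e-3 bits). The DP is exact on the
lattice; scanning scores windows on the same lattice, so threshold
comparisons never depend on float rounding. Widths above 25 are refused
(lattice width grows linearly, but 4^w enumeration-equivalence and
memory both degrade; a sampling mode would be the right tool there).

**Scanning** reports every position × strand at or above threshold;
the minus strand is scored with the reverse-complemented matrix at the
same forward coordinates; windows containing N are skipped.

**Enrichment statistic.** Per sequence,
`log( mean over windows/strands of 2^score )` — the log average
likelihood ratio, a raw-score statistic in the Clover tradition — and
the set statistic is its mean over sequences. The null shuffles each
sequence independently per replicate (mononucleotide by default,
preserving composition; a dinucleotide mode via Eulerian-walk shuffling
is available) and `p = (1 + #{null ≥ obs}) / (1 + N)`, never exactly 0.
Differential enrichment between sets A and B uses
`stat(A) − stat(B)` with a pooled re-splitting null (the permutation
test appropriate for "is this motif hotter in A than B"), and
Bonferroni-style e-values `p × n_motifs`, flagged at e ≤ 0.05.

**AP1 fixture.** The shipped AP1 (Jun:Fos) matrix is a *synthetic*
consensus-built TGA(C/G)TCA count matrix for tests and demonstrations,
not a published matrix; the central C/G column is slightly asymmetric
(9:7) so the matrix has a unique maximum-score word whose exceedance
probability (6.1e-5) sits below the default 1e-4 scan p-value. Real
analyses should load JASPAR matrices (`read_jaspar`).

## 4. Conservation

An alignment-free scan in the phylogenetic-footprinting tradition:
300 bp windows slide along the reference (step 50 bp); a non-reference
species supports a window iff at least `min_shared` of the window's
distinct 8-mers co-occur inside a single 300 bp window of that species,
on either strand. Requiring co-occurrence within one species window is
what makes the statistic length-independent and true to the idea of a
conserved *cluster* of short motifs; because the words are a bag, motif
rearrangement and relocation within the element do not affect the call.
Windows supported by ≥ `min_species` (default 7 of 9, the reference
counting as one) are merged into blocks.

`min_shared` defaults to 20. Calibration: a random 300 bp window pair
shares ≈ 2.6 distinct 8-mers by chance, but support takes the *best*
window of the other species, and residual homology at deep divergence
raises the per-species noise floor to ≈ 10–16 shared words; deeply
conserved elements of 60–80 bp contribute ≈ 35–70. Twenty separates
the two regimes by a wide margin in both directions; it is exposed as a
parameter and is the main free knob of this component.

N-containing 8-mers are ignored. Monotonicity holds by construction:
lowering `min_species` or `min_shared` never removes reported bases.

## 5. Expression response and direct-target logic

Counts (probes × samples, with probe classes endogenous / positive /
negative / housekeeping) are normalised in three independently
toggleable steps following the vendor's public scheme: (1) per-sample
positive-control scale factor = mean of per-sample positive geometric
means over the sample's own; (2) content factor computed likewise from
housekeeping probes; (3) background = per-sample mean + 2 sd of
negative probes, subtracted and floored at 1.

Per contrast, fold change is the linear ratio of group means and the
p-value a two-sided unpaired pooled-variance t-test on log2 counts.
The pooled test (rather than Welch) is deliberate: at n = 3 per group
the Welch degrees-of-freedom estimate is markedly conservative (null
rejection ≈ 0.035 at α = 0.05 in simulation), while the pooled test is
calibrated (≈ 0.050) and the equal-n design makes the two statistics
identical anyway. Calls: up iff FC ≥ up-threshold and p ≤ α; down iff
FC ≤ down-threshold and p ≤ α (thresholds inclusive). Two named preset
threshold pairs are shipped — `figure` (1.5 / 0.25, the default) and
`methods` (1.25 / 0.75) — because both appear in this assay's
literature; recovery benchmarking uses `methods`, since a planted
4-fold repression sits exactly on the `figure` down-threshold and would
be called at chance.

Direct-target logic: a probe called in the same direction in both the
plain contrast (FGF vs control) and the translation-blocked contrast
(FGF+cycloheximide vs cycloheximide-vehicle) is `direct_up`/`direct_down`;
called in the plain contrast only, `indirect_*`; probes called only
under cycloheximide are reported separately and left unclassified. The
cycloheximide baseline is the CHX-vehicle condition (configurable to
untreated).

`enhancer_expression_test` asks whether enhancer-associated transcripts
are expressed higher than the rest: one-sided Mann–Whitney
(with-enhancer > without), normal approximation with tie correction,
exact enumeration for groups under 3 (falling back to the asymptotic
form when ties make the exact distribution undefined); fully tied data
return p = 0.5.

## 6. Synthetic data and what passing tests mean

The generators produce every input the pipeline consumes, with recorded
truth, deterministically per seed:

- **Genome/genes** — i.i.d. bases at 42% GC (vertebrate-like), 1 gene
  per 25 kb with 2–4 exons and random strand.
- **Enhancers** — per condition 40 valleys by default, 20% shared
  between conditions; valley 200–2500 bp between 500–1500 bp flanks,
  placed so that nearest-TSS assignment recovers the designated target
  gene; peak records get Gaussian edge jitter (sd 30 bp, truncated so a
  flank never invades more than 25% of its valley). Decoy bimodal pairs
  whose valley carries H3K27me3 are planted to exercise the repressive
  filter; H3K27me3 domains cover repressed-gene loci in the treated
  condition. Placement keeps same-condition structures more than the
  3 kb pairing distance apart, so edge jitter is the only noise source
  for the caller.
- **Coverage** — 25 bp bins, Poisson noise around plateaus (flanks 20,
  valley 2, background 1) and a peak-dip-peak TSS profile (bumps of 15
  at ±100–600 bp, dip of 2 at the TSS). Coverage realism is secondary:
  peak calling is out of scope, the tracks exist for profile/heatmap
  code.
- **Motifs** — the fixture's maximum-score word written into 60% of
  treated-condition-unique valleys at random offset/strand.
- **Orthologs** — one reference locus; 8 other species as i.i.d.
  substituted copies at 45% divergence (deep, so background windows
  fall below the shared-word floor), with 80 bp conserved elements
  re-copied at 1% substitution into 7 of the 8 at random positions
  (exercising position independence).
- **Counts** — negative binomial, dispersion 0.1 for biological probes
  and 0.01 for spike-ins (spike-ins carry technical noise only),
  baselines log-uniform 500–5000 (well above background, as probes are
  designed to be), |log2FC| = 2 planted into 10 probes per responsive
  class, lane and content effects log-normal (sd 0.15) for
  normalisation to remove.

What passing tests do **not** show about real data: no spurious or
missing peaks (only edge jitter), no copy-number or mappability
artefacts, no correlated replicate structure, mononucleotide sequence
composition only, and star-topology orthologs without a phylogeny.
Recovery rates on this generator are therefore upper bounds for field
performance.

A note on the classification benchmark: at the generator's stated
noise (dispersion 0.1, n = 3, |log2FC| = 2) the per-contrast detection
power of the calibrated t-test is ≈ 0.96, and a direct call requires
two contrasts to fire — so mean accuracy on planted responsive probes
is ≈ 0.90, a power ceiling of the design rather than an implementation
artefact; the acceptance suite measures and reports it as such.

## 7. Orchestration

`run_all` executes simulate → call → compare → profiles → motifs →
conservation → response in dependency order, writes every artefact plus
a markdown report into the run directory, and records a `MANIFEST` of
SHA-256 hashes stamped with the seed and a config hash (the output
directory itself is excluded from run identity). Any stage failure
aborts with the stage name. Reruns with the same config and seed are
bit-identical; all randomness flows from the single config seed.

Default problem sizes for the bundled simulation runs (1 Mb genome, 40
enhancers per condition, 2.5 kb ortholog loci, 200-probe count tables)
were chosen so a full run and the entire test suite execute comfortably
on a laptop while keeping every statistical check adequately powered.

## 8. Known limitations

- The enhancer caller consumes peak calls; it cannot rescue peaks the
  upstream caller missed, and "bimodal" pairs separated by a third
  (possibly spurious) peak are not considered.
- The exact-threshold DP quantises scores to 1e-3 bits; thresholds are
  exact on that lattice, within `width × 5e-4` bits of the continuous
  value.
- Conservation support is a bag-of-words count; it cannot distinguish a
  genuinely conserved element from coincidental k-mer clustering in
  repetitive or low-complexity sequence (no repeat masking).
- The re-splitting differential-motif null assumes exchangeable
  sequence sets; strong length or composition imbalance between sets
  weakens that assumption (lengths are preserved per sequence, so only
  set-level imbalance matters).
- NanoString normalisation follows the vendor's public scheme; other
  schemes (e.g. RUV-style factor removal) are out of scope.
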