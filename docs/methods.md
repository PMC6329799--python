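# Methods

## Screen model and hit calling

Counts are modelled per hairpin and sample. Normalization divides each
count (plus pseudocount ψ = 0.5) by the sample total, so frequencies sum
to 1 and fold changes are invariant to sequencing depth; with ψ = 0 this
invariance is exact (a property the tests assert). Fold changes are
computed per replicate as output/input frequency ratios and divided by a
summary of the scrambled-control hairpins' ratios. The summary is the
**median** by default (robust to a single aberrant control; the mean and
an explicit "none" are available) and is applied per replicate, before
averaging, because normalization is a property of each sequencing pair.
Averaging across replicates happens on the log2 scale — fold changes are
multiplicative, and the log-mean does not let one replicate's large
ratio dominate; an arithmetic mean of ratios is available behind a flag.

Hairpins are ranked by mean log2 fold change in each direction; the
percentile of rank *r* among *N* hairpins is *r/N* with an inclusive
boundary ("within the 20th percentile" means *r/N* ≤ 0.20). Ties are
broken lexicographically by hairpin id in both directions so results are
reproducible to the byte. A gene is called when at least `min_support`
(default 2, the minimal reading of "multiple") of its hairpins fall
inside the enriched (20%) or depleted (25%) cut, and the same criterion
— same thresholds, same support count — is **not** met in the counter
arm. Applying the full rule to the counter arm, rather than excluding on
a single counter hairpin, treats both arms symmetrically; the softer
per-hairpin exclusion is available via `counter_min_support=1`.

No p-value model is attached to the hit rule: it is a deterministic rank
criterion, and the package's own calibration experiments (below) measure
its chance-call load directly instead of assuming one.

### Read counting

Reads are assigned by direct guide-sequence search: the guide of each
library hairpin is sought at every offset of the read (a configurable
offset window restricts this) at Hamming distance ≤ `max_mismatch`
(default 0). The unique best-scoring hairpin gets the read; ties and
misses are counted as unmatched, never fractionally assigned. An exact
hash-lookup fast path handles the mismatch-free case. Demultiplexing
reads the 5' sample barcode with the same unique-best-match rule and
refuses barcode sets whose pairwise distance could not disambiguate
(≤ 2·max_mismatch). Conservation (assigned + unassigned = input) holds
by construction and is asserted.

## Synthetic screen generator

The generator is the package's statement of what screen data look like:

* input abundances per hairpin ~ log-normal (sd 0.5 natural log),
  reflecting uneven library representation with near-complete coverage;
* expected output abundance = input · 2^(gene effect + construct
  effect); the construct effect ~ N(0, `hairpin_efficiency_sd`) is drawn
  once per hairpin and shared across replicates **and arms** — it models
  the physical shRNA (knockdown efficiency, off-target load), which is
  the same construct wherever it is used. Scrambled controls carry gene
  effect 0 in both arms;
* observed counts ~ negative binomial with var = μ + φμ², the standard
  overdispersed model for sequencing counts.

Defaults: 613 hairpins over 230 genes (extras distributed to the first
genes), 12 scrambled controls, pools of ≤ 150 assigned round-robin,
duplicate replicates, depth 1000× per hairpin, dispersion φ = 0.13,
construct sd τ = 0.8 log2. The noise defaults were fixed from a closed
form before any experiment was run: the model's expected replicate
correlation of mean fold changes is τ²/(τ² + 2(1/μ + φ)/ln²2) ≈ 0.54,
matching the moderate reproducibility (r ≈ 0.5) that in vivo screens of
this design actually show — transplantation bottlenecks make in vivo
screens much noisier than in vitro ones, and the generator reproduces
that regime rather than an idealized one.

Two consequences of this honest noise level are worth stating. First, a
rank-based percentile cut always selects ~20% of hairpins, so with 230
mostly-neutral genes the rule's raw chance-call load is ~14 genes per
direction before counter filtering; counter filtering removes only the
calls whose ranks replicate across arms (cross-arm correlation ≈ 0.7 at
these defaults), leaving a measurable residue of chance calls — about
25 per run across both directions, the same order as the candidate
counts such screens report before knockdown-efficiency filtering and
per-gene validation. Second, planted 4-fold (log2 = 2) effects are only
marginally separable: measured recovery of planted leukemia-specific
genes is ~80% over 20 seeds. Pushing either number to textbook levels
(≥ 90% recovery with ≤ 1 false positive) would require replicate
correlations above 0.98, i.e. an unrealistically noiseless screen; the
package reports what the realistic regime yields instead of simulating
an idealized one. The null calibration test closes the loop by checking
the simulated chance-call count against a permutation oracle that
shuffles the hairpin→gene assignment while keeping each hairpin's
(leukemic, counter) rank pair intact — the pairing preserves the
cross-arm construct coupling, which makes the two arms dependent even
under the null.

`simulate_reads` emits one barcoded read per count (barcode + guide +
random filler, 60 nt) with optional per-base substitution noise, as a
single shuffled stream so the demultiplexer is exercised. At 1%/base
noise with one mismatch allowed, ~2% of reads carry two or more guide
substitutions and are dropped as unmatched; assignment precision among
surviving reads is ≥ 99.9%. Error-free streams round-trip exactly.

## Cohort scores

Transcript-set scores are log2(Σ expression + 1); the pseudocount of 1
guards against zeros in normalized-count matrices. Two scores need
exact algebraic identities and therefore default to pseudocount 0:

* the BCL2L1 L/S ratio log2((L₁+L₂)/S), so that doubling the L
  transcripts shifts the ratio by exactly +1 and swapping L and S flips
  its sign (zero denominators raise, with an explicit pseudocount as
  the escape hatch);
* the MYC-target score, mean over signature genes of log2(g/MYC), whose
  purpose is removing confounding differences in MYC level — with a
  pseudocount the per-patient rescaling invariance would only be
  approximate. Missing signature genes are dropped (zero-imputation
  would inject −∞-like terms); a missing reference gene is an error.

Z-scoring uses the sample standard deviation (n−1). Stratification
offers extreme quantiles (default fraction 0.10, i.e. lowest vs highest
deciles) and a median split in which exact-median patients go to the
low group — deterministic, logged, and consistent with "below median /
above median" labelling. Z-scores are computed over the full cohort
before group selection. The Mann–Whitney test uses exact enumeration
when the pooled sample has ≤ 12 untied values and the tie- and
continuity-corrected normal approximation otherwise.

## Survival

Follow-up longer than 60 months is excluded before stratified analyses,
reading "longer than" strictly so exactly 60 months is kept. Estimation
and testing are delegated to lifelines (product-limit estimator; two-
group log-rank with hypergeometric variance, 1 df); events precede
censorings at tied times, the standard convention. The package asserts
the estimator's defining behaviours — equality with the empirical
survivor function in the absence of censoring, χ² = 0 / p = 1 on
identical groups, invariance under monotone time transforms — and
calibrates the test's type-I error (within [0.03, 0.07] at α = 0.05
over 500 null exponential cohorts of 200 per arm).

## Cohort generator

A latent per-patient RBM25 level R ~ N(0,1) drives each coupled score
(latent = coupling·R + N(0, noise_sd)) and survival (exponential with
log-hazard 0.7·(−R) per sd around an 18-month baseline median,
uniform-thinning censoring at rate 0.3). Transcript values are
constructed so the scoring functions recover the latents up to a
monotone transform: the five BIN1(+12) transcripts split a total of
2^(4 + latent); the L and S BCL2L1 transcripts are balanced around 2^7
so the log-ratio equals the latent; signature genes sit at the
patient's own MYC level (log2 ≈ 10 ± 0.5) shifted by the latent MYC
activity plus per-gene noise. Defaults — 180 patients (extreme deciles
of 18), couplings −1 sd for all three scores, log-HR 0.7/sd — put the
cohort in a regime where the qualitative pattern (low RBM25 ↔ high
BIN1(+12), high L/S, high MYC score, worse survival) is recovered in
≥ 90% of seeds while individual seeds still vary.

What the generator does **not** emulate: mapping/quantification error in
transcript abundances, correlated signatures, non-proportional hazards,
informative censoring, or cohort substructure (karyotype subgroups).
Passing tests therefore demonstrate correctness and calibration of the
analysis code under the stated model, not robustness to those real-data
complications.

## Numerical and design choices

* Frequencies, not raw counts, enter all downstream analysis; scale
  invariance is exact at ψ = 0.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical seeds give byte-identical outputs (asserted for
  generators, count tables and CLI reruns).
* Problem sizes in the calibration experiments (10–200 seeds, 300–500
  null simulations) were chosen to keep Monte-Carlo error comfortably
  inside the asserted bands while the whole suite stays quick.
* Degenerate inputs fail loudly: all-zero samples with ψ = 0, cohorts
  emptied by the follow-up filter, constant stratifiers, zero-variance
  Z-scores and event-free log-rank inputs all raise with actionable
  messages rather than returning NaN.

## Known limitations

The hit rule carries no error model, so its false-positive load must be
measured (or controlled downstream) rather than thresholded; the read
counter is exact-search based and does not model indels; the cohort
generator's couplings are linear in the latent; and knockdown-efficiency
filtering of hits — a wet-lab judgement — is out of scope.
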