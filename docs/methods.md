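# Methods

This note documents the models implemented in `mosaicburden`, the defaults
and why they were chosen, the construction of the synthetic benchmark data,
and the numerical decisions that affect results. Nothing here reports an
empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. UMI consensus error correction

Reads carrying the same unique molecular identifier (UMI) and mapped start
derive from one source molecule, so a base call supported by the family
consensus cannot be produced by a single sequencing error. Grouping is
greedy and directional: within a (chrom, start) bucket, UMIs are processed
in descending read count (ties lexicographic) and each joins the first
accepted family whose seed UMI is within `max_umi_edit_distance` (default 1,
Hamming). Greedy directional merging is linear-time and deterministic; full
clique clustering buys little at panel-scale UMI diversity.

Consensus is count-based: families below `min_family_size` (default 3) are
dropped; at each offset the modal base is emitted iff its fraction is at
least `min_agreement` (default 0.75, required > 0.5 so the modal base is
unique whenever it passes); ties and sub-threshold offsets are masked and
counted per site (`n_masked`), never added to depth. Quality scores are
deliberately not consulted: the count rule already achieves the target
error suppression (measured post-consensus discordance is far below e/5 at
e = 0.01, family size 5 — the acceptance suite recomputes this), and a
quality-weighted rule would add a tunable without a calibration target.
These thresholds are standard single-strand consensus practice and are
exposed as configuration.

## 2. Background error model and low-VAF callers

For one sample's consensus pileup, candidate sites (top-alternate fraction
above `mask_alt_fraction`, default 0.005) are excluded and the remaining
sites give

* e — pooled non-reference fraction (floored at 1e-6, capped below 0.5);
* ρ — method-of-moments intraclass correlation from the per-site
  top-alternate fractions: Var(f) = e(1−e)[ρ + (1−ρ)·E(1/N)], clamped to
  [0, 1).

Two callers test the top alternate base at each site with depth ≥
`min_depth` (default 500 consensus families, roughly a quarter of the
2000-fold design target, so sites thinned by masking are still testable):

* binomial: p = P(X ≥ n_alt), X ~ Binomial(N, e);
* beta-binomial: the same upper tail with a Beta(eσ, (1−e)σ) mixing
  distribution, σ = (1−ρ)/ρ. For ρ < 1e-8 the beta parameters exceed the
  numerically stable range and the distribution is indistinguishable from
  binomial, so the binomial tail is used directly; the two agree to 1e-10
  at ρ = 0 by construction.

Only the top alternate base is tested (one mosaic event per site; other
bases remain visible in the pileup). Emission requires p ≤ α (default 1e-6
per caller — at 2000× this passes ~30 alternate reads against e = 0.001,
i.e. VAF ≈ 1.5%, matching the classification window below). Candidates are
integrated across callers: `intersection` (default — error-robust),
`union`, or `at_least_k`. Classification uses the open mosaic window:
somatic iff 0.015 < VAF < 0.35; VAF ≥ 0.35 is germline-like; VAF ≤ 0.015 is
filtered. Both endpoints are strict inequalities. Region annotation
resolves overlaps with precedence exonic > UTR > intronic > intergenic; a
contig absent from the gene model degrades to intergenic with a warning
rather than failing.

Indels, strand-bias and population-frequency filters are out of scope; the
caller surface accepts any pileup with A/C/G/T counts, so such filters can
be applied upstream.

## 3. Negative-binomial burden GLM

Per-sample somatic counts are modelled as NB2 with log link:
log μ = Xβ, Var(y) = μ + μ²/θ. The design contains an intercept, treatment
coding of disease group with control as reference, sex, age, origin
(treatment-coded against the most frequent level, alphabetic tie-break, for
determinism), and log total coverage. Coverage enters as a covariate, not
an exposure offset: variant yield saturates at consensus depth, so a unit
elasticity assumption would be wrong.

Fitting alternates (i) IRLS for β at fixed θ with working weights
w = μ/(1 + μ/θ) and step-halving, and (ii) a bounded update of θ on
log-θ ∈ [log 1e-3, log 1e6], until the relative log-likelihood change is
below 1e-8 or 100 iterations. θ is initialized by the method of moments
after a Poisson warm start. Two dispersion modes exist:

* `dispersion="ml"` — plain profile ML. Each half-step maximizes the same
  joint likelihood, so the log-likelihood path is monotonically
  non-decreasing (property-tested), and with θ pinned at 1e6 the fit
  coincides with a Poisson GLM to 1e-6.
* `dispersion="adjusted"` (default) — the θ-step maximizes the Cox–Reid
  adjusted profile likelihood, ll − ½ log det(XᵀWX), the REML analogue for
  GLMs. Plain ML underestimates dispersion when p parameters are estimated
  from n ≈ 15–30 samples, which makes Wald tests anti-conservative; with
  the adjustment, simulation at n = 30, θ = 10 gives null type-I ≈ 0.05
  and 95% CI coverage ≈ 94% (recomputed by the acceptance suite).

Wald inference uses cov(β) = (XᵀWX)⁻¹ at the converged fit and references
the statistics against Student's t with n − p degrees of freedom — a
small-sample correction that converges to the normal reference. Equi- or
under-dispersed counts pin θ at the 1e6 bound (an effectively Poisson fit,
flagged by θ, not an error). Rank-deficient designs raise an error naming
the collinear columns; `BurdenGLM.from_dataframe(..., drop_collinear=True)`
instead drops offending covariate columns (never intercept or group) with a
warning, which the pipeline uses because small simulated cohorts can
produce coincidentally collinear dummies.

The summary t-test is Welch's by default (the pooled-variance variant is a
flag); group means and sample SDs are reported alongside. Multiple testing
uses Benjamini–Hochberg throughout (via `statsmodels.multipletests`;
brute-force step-up is the test oracle). Per-gene ratios use a pseudo-count
of 0.5 in numerator and denominator to stay defined for genes with zero
counts, and reuse the NB GLM per gene for p-values.

## 4. Cell-type-resolved calling

This is a re-specification, not a port, of cell-type-stratified callers for
single-cell RNA data: every threshold is explicit configuration. Per-cell
base counts are aggregated exactly by annotated cell type (unannotated
barcodes are an error listing offenders; zero rows are retained so all
types appear at every site). At a site, a cell type is testable with ≥
`min_cells` (5) covered cells and ≥ `min_depth` (20) aggregated reads; its
alternate count is tested against a beta-binomial (ρ = 0.01) whose rate is
the pooled alternate fraction of all *other* cell types (floored at 1e-4).
A site is somatic iff ≥1 type passes after BH across types at α = 0.01, at
most `max_host_types` (2) types pass, and the pooled non-host alternate
fraction is below 0.05 (germline screen); an alternate fraction ≥ 0.2 in ≥
3 covered types short-circuits to `germline_like`. RNA-specific artifacts
(editing, splice-adjacent errors) are handled only through these screens —
a site blacklist is a hook, not implemented.

Per-cell burden counts carried somatic variants by ≥ 1 alternate read —
exactly testable against planted truth under sparse coverage, unlike
genotype likelihoods. Cell-type comparison fits one NB GLM of per-cell
counts on cell type (treatment coding) with log per-cell covered-site
count as an exposure offset, then Wald-tests all pairwise coefficient
differences with BH across contrasts — so contrasts compare variants per
covered site. The offset form was chosen on identifiability grounds:
coverage differs far more between cell types than within them, so a freely
estimated coverage coefficient is nearly collinear with the type effects
and inflates contrast variance (measurably destabilizing the pairwise
tests in simulation); a per-type cell count is *exactly* collinear and is
rejected with an explanatory error. The free-coefficient form remains
available as `size_adjustment="covariate"`. Types with < 10 cells are
excluded with a warning. Cluster summaries (mean/median burden, condition
composition) take cluster labels as given — no de-novo clustering.

## 5. Signatures and gene sets

SNVs are mapped to the 96 pyrimidine-centred trinucleotide channels
(substitution-major COSMIC ordering); purine-reference events are
reverse-complemented, a 2-to-1 surjection from the 192 stranded contexts
verified exhaustively in the tests. Contig-edge SNVs are skipped and
counted. Refitting is non-negative least squares onto a catalog whose rows
sum to 1 — deterministic, scale-invariant in fractions, exact on mixtures
inside the non-negative span. NNLS was chosen over likelihood-based
refitting to keep the decomposition closed-form and reproducible; it is a
substitution for whatever refitting tool a given study may use, and the
catalog is always an input: a reader for COSMIC-layout TSVs is provided,
and the bundled `synthetic_catalog()` is a Dirichlet-drawn stand-in (its
first label "SBS26" merely gives pipelines a named mismatch-repair-style
signature to track; it is not COSMIC data). Condition comparisons refit the
observed spectrum per condition and attach 95% bootstrap CIs over SNVs
(seeded; < 50 SNVs flags low confidence).

Gene-set burden uses a weighted permutation null: n_snv genes are redrawn
with probability proportional to a per-gene weight (default covered panel
length — longer targets accrue more SNVs by chance), n_perm times;
p = (1 + #{null ≥ observed})/(n_perm + 1), BH across sets. The pseudo-count
keeps p strictly positive; because the statistic is discrete the p-values
are conservative (super-uniform) rather than exactly uniform under the
null, and the property tests check exactly that (one-sided KS in the
anti-conservative direction plus a direct bound at α = 0.05).

## 6. Synthetic data: what it emulates, and what it does not

The generators define the package's study conditions; all are pure
functions of their seed (a global seed fans out to stage/sample child seeds
by stable hashing, so stages reproduce independently of execution order).

**Panel** — one random contig carrying the requested genes (default the
seven panel genes with the strongest sporadic-disease enrichment: VAPB,
MAPT, FUS, NEFH, CCNF, NEK1, TBK1), each 5'UTR + 3 exons/2 introns + 3'UTR
with a 150 bp targeted flank and untargeted intergenic gaps (~16.5 kb
targeted for 7 genes).

**Bulk cohort** — group sizes default to 9 sALS / 4 fALS / 6 controls with
mean somatic variant counts 80 / 40 / 40 per sample: a two-fold sporadic
excess, at per-sample magnitudes comparable to deep-panel mosaic studies.
Somatic true VAFs are log-uniform on (0.015, 0.35) — reproducing the
low-AF-heavy spectrum of bulk mosaicism without asserting any particular
empirical law — germline variants sit near 0.5/1.0, and site depth is
Poisson around the sample's coverage (lognormal jitter around 2000×).
Observed alternate counts at a planted site are multinomial with success
probability vaf(1−e) + (1−vaf)e/3. Read-level simulation (UMI-tagged,
per-base error, Poisson family sizes) exists for the consensus module;
pileup-level simulation is used at cohort scale for runtime.

**Single-cell cohort** — ten annotated cortical cell types, 100 cells per
type with excitatory neurons boosted 1.5× (the most abundant type in
cortical censuses) and labelled cluster 5; per-cell, per-site coverage is
zero-inflated (Bernoulli coverage × shifted Poisson depth), denser for
neurons, emulating expression sparsity. Clonal variants are heterozygous in
a carrier fraction (default 0.25) of their host type's cells; the default
clonal census plants variants in five cell types with a 3× excitatory
excess (36 vs 12), giving per-cell burdens of order 0.5–2 detected variants
over 400 simulated sites — the regime in which cell-type contrasts are
meaningfully powered, mirroring the many-variants-per-cell scale of
transcriptome-wide single-cell somatic calling scaled to panel size.

**Not emulated:** quality-score ladders, indel errors, PCR chimeras,
doublets, strand artifacts, RNA editing, mapping error, population
structure in germline variants, and between-sample batch effects. Passing
benchmarks therefore demonstrate correctness and calibration of the
statistics under the stated generative model — error suppression,
type-I/power, CI coverage, end-to-end recovery — not robustness to every
artifact of real libraries. Real-data entry points (VCF/BED/FASTA/TSV
readers, COSMIC catalog reader, GMT gene sets) accept standard formats so
the same code runs on real pileups.

## 7. Problem sizes in tests and acceptance

The shipped benchmarks use: 1e5 null sites (calibration), 1000 replicate
sites (power), 1500 molecules × ~100 bp (UMI), 300 + 1000 GLM replicates at
n = 30 (coverage/type-I), 100 cohort replicates at 9 vs 6 samples over a
two-gene panel (end-to-end detection), 10–15 single-cell replicates at
~1050 cells × 400 sites, and a two-gene demo pipeline for determinism.
These sizes give Monte-Carlo error comfortably below the decision margins
they support while keeping the full suite around a minute of compute.

## 8. Known limitations

* The binomial caller ignores site-to-site error heterogeneity; with a
  global e it is anti-conservative at genuinely noisy sites. The
  beta-binomial caller and the intersection rule are the mitigation.
* The beta-binomial ρ is a single global parameter; per-site error
  profiles (e.g. context-specific) are not modelled.
* Wald-t inference is approximate; likelihood-ratio or resampling tests
  would be preferable at very small n or very low counts.
* The single-cell caller assumes independent errors across cells and no
  ambient contamination; its germline screen is a heuristic, not a
  genotype model.
* NNLS refitting inherits the identifiability limits of the supplied
  catalog: strongly collinear signatures trade off weight.
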