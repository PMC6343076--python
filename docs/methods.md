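# Methods

This note documents the models, conventions and parameter choices behind
each stage of the package, what the synthetic-data generator does and does
not emulate, and the known limitations.

## 1. The activity model

A community holds taxa `t = 1..n` with relative cell abundances `p_t`
(Σp=1), 16S copy numbers `c_t` (integer, default 1), and per-cell activity
factors `a_t > 0` — the number of 16S rRNA transcripts per gene copy, the
latent quantity of interest. The two amplicon pools sample taxa
multinomially with weights

- rDNA: `p_t · c_t` (gene copies),
- rRNA: `p_t · c_t · a_t` (transcripts),

each normalized to 1. Consequently the per-taxon ratio of rRNA to rDNA pool
fractions equals `a_t / K` with the single community constant
`K = Σ p c a / Σ p c`. The rRNA/rDNA ratio estimator recovers activity only
up to `K`: ratios are comparable *within* a sample and across taxa, and a
ratio of 1 means "as active as the community's abundance-weighted mean",
not any absolute transcription rate. All estimator tests compare against
`a_t / K`, not `a_t`.

## 2. Synthetic communities

`SimScenario` fixes one experiment; every random stream derives from
`(seed, stream-name[, sample, pool])` via `numpy.random.SeedSequence`, so
outputs are bit-reproducible and per-sample streams are independent.

**Abundances and activities.** `p_t ∝ LogNormal(0, abundance_sigma)`,
default σ=1.5 — a realistic species-abundance distribution in which a
150-taxon community spans roughly four orders of magnitude of abundance.
`a_t ~ LogNormal(0, activity_sigma)`, default σ=1.0, drawn independently of
`p_t` under the `independent` model. Under `kill_the_winner` the sorted
activities are assigned in inverse order of abundance rank, then jittered
multiplicatively (σ = 0.2·activity_sigma), encoding the hypothesis that
fast growers are preferentially lysed/grazed and therefore rare; realized
Spearman(p, a) is typically ≤ −0.95.

**Reference sequences and tree.** A random bifurcating topology is built by
iteratively joining random pairs; branch lengths are exponential, rescaled
so the mean pairwise patristic distance equals `mean_divergence`
(default 0.05 substitutions/site). The root sequence evolves down each
branch with Poisson(branch length × sequence length) point substitutions at
uniformly chosen sites (with replacement), each replacing the base with a
uniformly chosen different base — the Jukes–Cantor jump process, so pairs
at path length `t` differ at a fraction ≈ ¾(1−e^(−4t/3)) of sites.
References are then forced at least `min_taxon_distance` (default 8) edits
apart by extra substitutions on too-close tips: the simulated taxa are
distinct populations, not strain microvariants, matching the separation the
skew denoiser assumes between true biological sequences. With the floor at
its default, a rare taxon can never be legitimately absorbed into an
abundant neighbor's error cloud at the depths the package targets
(absorption at d=8 would require a 2^17 ≈ 130,000-fold size skew). Setting
`min_taxon_distance=1` recovers the bare-distinctness behavior, and
`mean_divergence=0` raises, since duplicates are then forced.

**Reads.** Taxon of origin is multinomial over the pool weights; each read
copies its reference and substitutes each base independently with
probability `sub_error_rate` (default 1/20,000 — the middle of the
1/10,000–1/50,000 range reported for Taq polymerase), plus `rt_error_rate`
(default 1/15,000, the reverse-transcriptase scale) for rRNA reads only. A
substituted base always changes, so the realized mismatch fraction equals
the configured rate (no ¾ correction). Indels default to 0, keeping
edit-distance structure clean; qualities are a constant Phred 30 (the
expected-error filter only needs Σ10^(−Q/10), so a per-base quality model
adds nothing at this fidelity). Reads are single-end; headers carry the
true taxon after `;truth=`, read only by tests and truth-evaluation code.

**Not emulated:** chimeras, primer/adapter artifacts, paired-end structure,
instrument-specific quality profiles, strain microdiversity, compositional
coupling between samples. Passing tests therefore demonstrate estimator
correctness under the sampling-plus-substitution-noise model, not
robustness to every real-world artifact; chimera removal in particular is
delegated to an external blacklist hook.

## 3. Unit formation

**Filtering.** Reads shorter than 230 bases or with expected errors
Σ10^(−Qᵢ/10) > 1 are discarded (the standard expected-error criterion).

**Dereplication.** Exact full-length equality, pooled across all samples
and pools (one unit space per experiment, so rDNA and rRNA columns are
directly comparable); output ordered by decreasing size with lexicographic
tie-break, which makes downstream unit formation invariant to read order.

**OTUs.** Greedy centroid scan in that order: a unique joins the best
existing centroid at identity ≥ 0.97 (highest identity; ties to the
larger-founder, then earlier, centroid); otherwise it founds a centroid if
its pooled size ≥ 8, else it is excluded from centroid formation (it can
still be recruited during read mapping). Centroids are pairwise < 0.97 by
construction.

**ZOTUs.** Uniques below 8 pooled reads are removed, the rest scanned in
decreasing size; `u` merges into accepted centroid `c` when
`size(u)/size(c) ≤ β(d) = 2^-(αd+1)` with `d = edit distance ≥ 1` and
α = 2 (the published default of the skew-denoising family; exposed as a
parameter). Among qualifying centroids the smallest `d` wins (ties: larger
centroid, then earlier). β declines geometrically in `d`, so a sequence two
edits from a 1000-read centroid must have ≤ 31 reads to be explained as its
error cloud.

**Identity convention.** One definition is used everywhere (clustering,
read mapping, ZOTU→OTU mapping): take an optimal unit-cost edit alignment
of the two full sequences (edlib), drop terminal gap columns, and report
matches / remaining columns. End gaps are free for identity though not for
the alignment objective — for the equal-length, substitution-dominated
amplicons this pipeline targets the distinction is immaterial, and the
convention is symmetric (arguments are canonically ordered before aligning,
since different tie-breaks among equally optimal alignments could otherwise
give direction-dependent values). Threshold-based callers screen with an
edit-distance bound that provably cannot exclude a pair above the
threshold.

**Mapping.** Each filtered read goes to the best-identity representative
meeting the method's floor (0.97 for OTUs, 1.0 for ZOTUs; ties to the
larger, then earlier, unit). Assignment is memoized per distinct read
sequence. Unmapped reads are counted per (sample, pool) and reported, never
redistributed — on noisy data the ZOTU pipeline maps markedly fewer reads
than the OTU pipeline, and that diagnostic is part of the method
comparison.

**Contaminants.** A unit whose mean relative abundance across
negative-control columns exceeds 5% is removed from every column; a control
with zero mapped reads contributes 0 to the mean (the conservative reading
of "average over controls"). The boundary is strict (> 5%, not ≥). An
externally produced blacklist (e.g. reference-based chimera calls) can be
supplied alongside.

## 4. Paired profiles and summaries

Relative abundances are fractions of *mapped* reads per pool per sample —
mapped-read denominators keep rDNA and rRNA comparable between methods
whose mapping rates differ. Units absent from both pools of a sample are
omitted; the remainder are classed `shared` (both pools), `phantom` (rRNA
only; ratio undefined, excluded from ratio statistics and correlations but
counted separately), or `dna_only` (rDNA only; ratio 0 — dormant/dead
candidates). An optional pseudo-count mode (+k reads to both pools) gives
phantoms finite ratios for sensitivity analysis; default off. Ratio
distribution statistics are reported both including dna_only zeros and
restricted to shared units, since whether ratio-0 units count toward
"fraction below 1" is a reporting choice. Production is a unit's share of
the sample's rRNA pool; the cumulative curve accumulates production in
decreasing rDNA-abundance order (phantoms rank last), conserving mass to 1.
Abundance–production association uses Pearson correlation on log10
fractions over shared units (zeros are excluded by construction).

## 5. Diversity and structure

- **Shannon** in bits (log2), natural log by flag.
- **Faith's PD** is root-inclusive: the branch-length sum of the union of
  observed tips' paths to the root. The choice shifts all values by the
  root path and is stated here because toolkits differ.
- **Rarefaction**: exact without-replacement subsampling
  (multivariate hypergeometric) to a fixed depth, metric averaged over
  `n_reps` draws (default 10), seeded; columns below depth raise.
- **UniFrac**: unweighted = unique branch length over covered branch
  length (in [0,1]); weighted = Σ branch length × |flow difference| with
  flows the fraction of each sample's reads descending through the branch,
  non-normalized by default (normalized by flag). Cross-checked against
  scikit-bio's implementations in the tests.
- **Default tree**: 1 − cosine similarity of overlapping 6-mer count
  profiles, neighbor joining (scikit-bio), negative branch lengths clamped
  to 0, midpoint-rooted. This is deliberately lightweight scaffolding — a
  k-mer NJ tree is *not* a publication-quality phylogeny and any
  user-supplied newick overrides it; its topology recovery improves with
  sequence divergence, which the tests verify by Robinson–Foulds distance
  against the generator's true tree.
- **PCoA**: Gower-centered −D²/2, symmetric eigendecomposition; axis
  proportions are eigenvalues over the sum of *positive* eigenvalues;
  negative eigenvalues are reported, never corrected.
- **PERMANOVA**: Anderson's sums-of-squared-distances pseudo-F with free
  label permutations from a seeded generator;
  p = (1 + #{F* ≥ F}) / (1 + B), never exactly 0. Null calibration
  (rejection rate at α=0.05 within [0.02, 0.09] over 200 null datasets of
  12 samples at B=199) is asserted in the acceptance suite.
- Each (sample, pool) is treated as its own ordination point; summing
  pools before ordination is the documented alternative and is a one-line
  groupby for the caller.

## 6. Genome-side activity

Relative genome abundance is length-weighted mean contig coverage divided
by total metagenome reads, then normalized to sum to 1 across the sample's
genomes (default) so that the transcription/abundance ratio is
fraction-over-fraction like the amplicon side; the raw unnormalized value
is available by flag, and the ratio is invariant to rescaling coverages.
ORF TPM is `10⁶ · (count/kb) / Σ(count/kb)`; a genome's relative
transcription is its ORFs' TPM sum / 10⁶, so unbinned ORFs dilute all
genomes rather than being redistributed. Genomes with zero abundance but
positive transcription are flagged as the genome-side analog of phantoms
and excluded from ratio statistics.

**iRep.** Coverage windows (5 kb non-overlapping in the simulator; a
property of the input table otherwise) are filtered of zeros, sorted
ascending, assigned ranks on [0,1], trimmed 5% per end, and OLS-fit as
log2(coverage) vs rank; iRep = 2^(fitted span), with the fit R² as a
diagnostic and all-equal coverage returning exactly 1. No GC correction or
mapping-quality filtering is applied — the module consumes coverage tables,
not alignments. The estimator is slightly biased upward because sorting
turns symmetric coverage noise into span inflation; at the simulator's
noise level (window coverage averaged over ~670 read placements at 20×,
i.e. ~4% relative noise) the bias is under 0.03 at true values 1.2–2.0, and
the simulated-recovery tests assert estimates within [1.8, 2.2] at true
2.0. At materially lower coverage or smaller windows the bias grows and
iRep values should be read as upper bounds.

## 7. Problem sizes and numerical choices

Simulation-backed tests run at the package's reference conditions: 150-taxa
communities (σ_abundance 1.5, σ_activity 1.0), 10⁴–10⁵ reads per pool,
three samples for phantom accounting, 400 coverage windows at 20× for
replication, 200 null datasets × 199 permutations for PERMANOVA
calibration. Consistency checks distinguish systematic error from counting
noise: a taxon observed with `k` reads carries ~1/√k relative noise in its
ratio, so per-taxon tolerance bands apply to well-sampled taxa
(≥10⁴ reads per pool → <5%) while rarer taxa are held to the same bound
only on average. Mass-conservation identities (pool fractions, TPM,
production curves) are asserted to 10⁻⁹ relative or better; exact ties in
sorting and clustering are always broken deterministically (size, then
lexicographic or first-come order) so every pipeline output is a pure
function of the scenario seed.

## 8. Known limitations

- The rRNA/rDNA ratio identifies activity only up to the community
  constant `K`; cross-sample ratio comparisons assume `K` is comparable.
- 16S copy-number variation is a confounder the estimator cannot remove
  (`r_t` estimates `a_t` only when `c_t` is constant); the generator
  exposes it as an optional switch for sensitivity studies.
- The denoiser cannot distinguish a genuine biological variant inside a
  larger taxon's skew envelope from an error; with realistic strain
  structure (excluded here by the separation floor) exact recovery is not
  achievable in principle.
- The k-mer NJ default tree is adequate for rank-level PD/UniFrac contrasts
  on well-separated units, not for fine phylogenetic inference.
- PERMANOVA uses free permutations; no support for restricted/nested
  designs.
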