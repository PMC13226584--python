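# Methods

`kmerbeta` tests a simple but consequential claim: that beta-diversity
measured directly on k-mer content of raw reads — with no reference database,
no taxonomic classification — agrees with beta-diversity measured on the true
species composition, provided k is long enough and rare k-mers are filtered.
This note records the models, conventions and numerical choices behind the
implementation, and what the synthetic benchmark does and does not show.

## Dissimilarity measures

Two measures are implemented in two parallel forms each.

**Bray-Curtis (abundance-based).** For samples A, B with species counts
N_{A,i}, N_{B,i} and totals N_A*, N_B*:

    BC(A,B) = 1 - 2 * Σ_i min(N_{A,i}, N_{B,i}) / (N_A* + N_B*)

The k-mer form replaces species counts by occurrence counts N_A(w) of each
canonical k-mer w in the sample's reads. Counts are used **raw**: BC is
invariant to rescaling both samples jointly but not to per-sample
normalisation — normalising first would effectively turn the computation into
a Manhattan-type distance and change the measure. A `normalize` switch exists
on the profile-based function for sensitivity checks and defaults off.
Profiles may carry real-valued counts so that estimated abundances from
classifier reports (Bracken-style `new_est_reads`) drop in without special
casing; the formulas are count-agnostic.

**Jaccard distance (presence-based).** With supports S_X = {i : N_{X,i} > 0}:

    d_J(A,B) = 1 - |S_A ∩ S_B| / |S_A ∪ S_B|

The k-mer form uses the sets of distinct canonical k-mers. Presence is
evaluated **after** the rare-k-mer filter, since the filter is applied before
any distance computation.

## k-mer counting conventions

* **Canonical k-mers.** A k-mer is counted together with its reverse
  complement, keyed by the lexicographically smaller of the two. This makes
  spectra strand-independent (reads are sampled from both strands) and
  matches standard practice in k-mer counting tools. A `canonical=False`
  flag exists for sensitivity analyses.
* **Singleton exclusion.** k-mers occurring exactly once in a sample are
  removed per sample (`min_count=2` by default), after counting and before
  any pairwise statistic. Rationale: at a 1% per-base error rate most
  erroneous k-mers are unique, so this filter removes noise mass at small
  cost in signal. The filter is per sample, not global across the collection.
* **k ≤ 31.** k-mers are packed 2 bits/base into 64-bit integers; numeric
  order equals lexicographic order, which keeps spectrum files sorted and
  streaming-mergeable. Windows containing any non-ACGT character are skipped
  deterministically rather than randomized or erroring.
* Pairwise statistics reduce to five numbers per pair (Σmin, the two totals,
  |intersection|, |union|) computed exactly over the union of key sets; both
  metrics share one pass.

## Mantel test

The observed statistic is Pearson's r between the condensed upper triangles
(Spearman = Pearson on midranks). The null is built by jointly permuting
rows/columns of the first matrix; p = (hits + 1)/(n_permutations + 1), so 999
permutations floor at p = 0.001 and never report 0. Matrices are aligned by
sample label, never by row position.

Numerical shortcut: a joint row/column permutation preserves the multiset of
condensed entries, so (a) the mean and norm of the permuted vector are
permutation-invariant and are hoisted out of the loop, and (b) for Spearman
the matrix can be rank-transformed once up front instead of re-ranking every
permutation. Both identities are enforced in tests against a naive
re-ranking implementation and against the scikit-bio Mantel statistic.

Default alternative is two-sided; one-sided variants are available. The
residual summary reports mean and **population** variance (ddof=0) of
absolute residuals between condensed matrices; ddof is configurable since
the convention is not universal.

## Synthetic communities

The generator emulates a small multi-environment WGS study (the shape of a
body-site panel: 4 environments × 3 samples) with read-level ground truth:

| parameter | default | meaning |
|---|---|---|
| `pool_size` | 40 | species in the global pool (100 kb uniform-random genomes) |
| `species_per_environment` | 12 | support size per environment |
| `shared_fraction` | 0.25 | fraction of the support drawn from a common core |
| `abundance_sigma` | 1.0 | log-normal shape of relative abundances |
| `reads_per_sample` | 50 000 | single-end reads per sample |
| `read_length` | 150 bp | fixed |
| `substitution_rate` | 0.01 | per-base, uniform to a different base |
| `reads_per_sample_spread` | 1.0 | log-uniform depth heterogeneity factor |

Choices where the design was genuinely open:

* **Support structure.** The pool is shuffled once per seed; the first
  `round(shared_fraction × species_per_environment)` species form a core
  present in every environment and each environment adds a disjoint private
  block. `shared_fraction=0` therefore yields exactly disjoint supports
  (true inter-environment Jaccard = 1), a useful hard separation case. The
  defaults (12 species/environment, quarter-core) give partial overlap, the
  qualitative situation of real body sites, while fitting in a 40-species
  pool (core + 4 private blocks = 39 ≤ 40).
* **Abundance law.** Log-normal relative abundances — the standard
  heavy-tailed model for microbial communities — integerised by the largest
  remainder method so counts sum exactly to the sample depth
  (deterministic, conserves totals, ties to lower index).
* **Reads.** Single-end only: downstream k-mer counting treats mates as
  independent sequence bags, so pairing adds nothing here. Substitutions
  only (no indels): sufficient to stress k-mer divergence, since a single
  substitution already destroys k overlapping k-mers. Quality strings are
  constant 'I' and never consumed.
* **Seeding.** Every stage (genomes, supports, per-sample abundances, depth,
  per-sample reads) derives its generator from a SHA-256 hash of
  (master_seed, stage name, sample id). The full experiment is reproducible
  from one integer, and adding samples does not perturb existing ones.

**What the generator does not model:** real genomes (uniform random sequence
has no repeats, shared genes, or conserved regions, so inter-species k-mer
collisions are rarer than in nature — separation results here are easier
than on real data); paired-end structure and insert sizes; indels and
quality-dependent errors; read-length heterogeneity; host contamination;
within-species strain variation. Consequently a passing benchmark shows the
pipeline's *internal* consistency and the k-mer/taxonomy agreement under
idealized conditions, not classifier-grade performance on real metagenomes.

## Benchmark scales

The tests run the full study design (12 samples × 5×10⁴ × 150 bp reads,
k = 21) for three seeds, where reference-free Bray-Curtis reaches Mantel
Pearson ≈ 0.99 against ground truth with p at the 0.001 floor. Structural
checks (disjoint environments, noise monotonicity, depth-heterogeneity
effects on Jaccard) use smaller communities (10³–10⁴ reads, 20–50 kb
genomes), which keep the whole suite in minutes; the effects tested are
scale-free in the ranges used. Depth heterogeneity of 10× is treated as the
"strongly unequal library size" regime; there the seed-averaged Mantel
correlation of Jaccard with truth falls at or below Bray-Curtis's, the
expected behaviour of a presence-based measure whose unions grow with depth.

One benchmark artefact worth knowing: because every sample in an environment
shares that environment's species support (and at the default depth every
supported species receives reads), the truth Jaccard matrix takes exactly two
values — 0 within an environment and a constant between environments (6/7
with the default core/private split: 3 shared of a 21-species union). Its
condensed vector is therefore almost entirely ties, which caps the Spearman
correlation any k-mer matrix can reach against it at ≈ 0.668 even when the
k-mer matrix separates the environments perfectly; the low Spearman-Jaccard
numbers in the benchmark report reflect that ceiling, not a failure of the
reference-free measure. Real communities, with sample-level presence
variation, do not have this degeneracy.

## UPGMA dendrograms

Average linkage over the dissimilarity matrix, with cluster height equal to
half the merge distance and branch lengths as ultrametric height
differences. Tie-breaks are deterministic: among equally close pairs, the
one containing the lexicographically smallest member label wins (then the
smaller partner), and children are emitted smallest-label first, so the
newick string is a pure function of the matrix. On ultrametric inputs the
generating topology is recovered exactly; on real matrices the trees are
qualitative summaries only — no linkage method is canonical for this use.

## Degenerate inputs and errors

Empty read sets yield empty spectra (logged, not an error); a pair of empty
spectra makes any distance undefined and raises, naming the pair. Matrices
are validated as symmetric, hollow and in [0,1] to 1e-12 before condensing.
Correlations on zero-variance vectors raise rather than return NaN.
Mantel requires n ≥ 3 samples. Bracken reports are rejected unless
`new_est_reads == kraken_assigned_reads + added_reads` on every row.
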