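# Methods

## Data model and input conventions

A methylome is a table of merged-strand CpG sites with methylated and total
read counts; the level is always recomputed as `meth/total`. Internally all
coordinates are 0-based half-open (BED convention); `pos` is the forward-
strand C of the CpG dinucleotide. Bismark `.cov` input (1-based inclusive) is
shifted on read. Strand merging sums the forward record at `p` with the
reverse record at `p+1`; read counts are conserved exactly (integer
arithmetic). Coverage filtering keeps sites with **strictly more than**
`min_reads` reads (default 5) — the boundary value 5 is removed — and drops
everything not on a configurable chromosome whitelist (default chr1–22, X,
Y), which is how scaffold removal is implemented without naming an
assembly-specific scaffold list. Filtering is applied after strand merging so
that a CpG covered 3+3 across strands survives a 5-read cutoff; the order is
configurable. A CpG undetected in a sample is masked, never imputed; every
downstream mean and test uses only detected entries.

## Per-sample UMR calling

Levels per chromosome are segmented with a two-state Gaussian-emission HMM:
initial means (0.1, 0.8), initial variances 0.02, self-transition 0.99,
variance floor 1e-4. Parameters are refined by Baum–Welch EM (≤ 20
iterations, absolute log-likelihood tolerance 1e-4); after EM the low-mean
state is re-identified as Unmethylated if the means swapped. Viterbi runs of
the Unmethylated state become UMRs when they contain ≥ `min_cpg` (5) CpGs and
their mean level is ≤ `max_umr_level` (0.1); each UMR spans its first to last
member CpG (half-open end = last position + 1). A state with near-zero
posterior weight keeps its previous parameters during EM, which makes
homogeneous inputs (all-low or all-high) well behaved.

## Reference UMR consensus

Consensus is computed base-wise, not by interval voting: per-base support is
the fraction of normal samples whose UMRs cover the base, maximal runs with
support ≥ `min_support` (0.8) are trimmed to their first/last contained CpG
and kept at ≥ `min_cpg` CpGs. Base-wise consensus is order-independent and
makes the reported support interpretable; the reported value is the fraction
of samples whose UMR union covers the entire emitted interval. Raising
`min_support` can only shrink refUMRs (anti-monotonicity), which the tests
assert.

## Three-state differential HMM

For refUMR CpGs, Δ = mean tumor level − mean normal level (detected samples
only; a CpG seen in just one cohort is masked). Estimation is deterministic,
with no EM by default:

* **Provisional partition.** Hyper if Δ ≥ +0.2, Hypo if Δ ≤ −0.2, else
  NoDiff (`delta_threshold` configurable).
* **Emissions.** Gaussian per state with the class sample mean/variance
  (variance floor 1e-4). An empty class falls back to declared means
  (+0.3, −0.3, 0) with the overall Δ variance; if a degenerate partition
  violates the ordering μ_Hyper > μ_NoDiff > μ_Hypo, the offending mean is
  restored to its fallback.
* **Transitions.** Counted over adjacent CpG pairs *within* the same refUMR
  (never across region boundaries), +1 pseudocount, row-normalized.
* **Decoding.** Per region, Viterbi in log space; the initial distribution is
  a point mass on the provisional class of the region-mean Δ. Exact
  log-probability ties break toward NoDiff, then Hyper, making decoding fully
  deterministic. Path-level (Viterbi) assignment was chosen over posterior
  marginals because the classification step needs coherent borders, not
  per-CpG confidences. Baum–Welch refinement of the estimates exists behind
  `em_iters` but is off by default: the deterministic estimators are
  reproducible and order-independent.

The decoder is verified against exhaustive enumeration of all 3^n paths on
random parameterizations, and the forward–backward routine (used by the UMR
caller's EM) against brute-force likelihood summation.

## Statistical testing

Per CpG, a two-tailed Welch t-test across samples (pooled-variance variant by
flag); undefined when either cohort has < 2 detected values or both cohorts
are constant. BH adjustment is applied once over all refUMR CpGs
genome-wide (no per-region stratification), via the standard step-up
implementation, and checked against the definitional computation. The
statistical Hyper flag requires `q < 0.05` **and signed** Δ ≥ +0.2: a
negative difference cannot be hypermethylation, so the absolute-value reading
of the effect threshold is available only behind `use_absolute` for strict
replication. A CpG's final `is_hyper` is the OR of the HMM state and the
statistical flag.

## Classification and segmentation

Hyper CpGs merge into hypermethylated regions; by default only contiguous
hyper CpGs merge (`max_gap_cpgs = 0`, the most conservative reading;
bridging is configurable and can only increase the hyper proportion). The
proportion denominator is the refUMR's CpGs detected in both cohorts. Classes:
proportion ≥ 0.8 ⇒ fhUMR (the boundary value 0.8 is assigned to the closed
upper class to avoid an unclassified band); 0 < proportion < 0.8 with ≥ 5
hyper CpGs ⇒ phUMR ("≥ 5 CGs" is read as five *hyper* CpGs — the refUMR CpG
floor is already enforced at consensus time); otherwise none. No extra hyper-
CpG floor applies to fhUMRs. phUMRs are partitioned exactly: partial-Hyper =
the merged hyper-region intervals, flanking-UMR = maximal runs of the
remaining CpGs.

## Quantification, comparator and annotation

Region quantification takes cohort means over detected CpGs and reports the
signed difference; callers needing the magnitude take absolute values. The
CGI-mean comparator computes per-sample island means, Welch-tests cohorts,
BH-adjusts across islands and calls hypermethylation at `q < 0.05` and
|Δ| > 0.2. The "missed fraction" is the share of phUMRs whose whole-region
|Δ| stays below 0.2 while the hyper-region Δ clears it — the dilution effect
partial erosion causes. CGI context uses 2 kb shores and 2 kb shelves on
**both** flanks of merged islands (the flanking concept is symmetric even
where it is described downstream-only), with precedence CGI > shore > shelf >
open sea; a one-sided mode exists behind a flag. Genes map an interval into
[TSS − 2 kb, TES] strand-aware; hits are promoters when the interval touches
[TSS − 2 kb, TSS], else gene bodies, and multi-gene overlaps yield multiple
assignments. Conservation is the coverage-weighted mean over bases covered by
the track (bedGraph or plain-text fixedStep/variableStep wiggle).

## Synthetic methylomes

The generator plants `n_regions` CpG-dense low-methylation regions
(μ_UMR = 0.05) in a high-methylation background (μ_bg = 0.85, sparse
background CpGs between regions), assigns each region a class
(none/partial/full, default weights 0.2/0.4/0.4) and, for partials, erodes a
contiguous block from one end (20–60% of CpGs; internal blocks optional),
lifting eroded tumor means by `erosion_delta` (0.4). Observed data follow a
beta-binomial hierarchy: per sample and CpG, level ~ Beta(mκ, (1−m)κ) with
concentration κ = 50 (biological variation), reads ~ Binomial(depth, level)
with depth ~ max(1, Poisson(λ = 30)); the max-1 clamp stands in for exact
zero-truncation, which is immaterial at λ = 30. Defaults are the benchmark
conditions: 10 normal vs 10 tumor samples, 200 regions, 25–60 CpGs per
region — region sizes typical of promoter CpG islands and large enough that
the smallest planted partial erosion still contains ≥ 5 CpGs, the floor the
classification rule imposes.

What the generator does **not** emulate: genome sequence and CpG spacing
heterogeneity, copy-number and tumor-purity dilution, partially methylated
domains, correlated (smooth) biological noise along the genome, and
hemimethylation. Passing the benchmark therefore demonstrates correctness of
the inference machinery under the declared noise model, not performance on
real tumor methylomes.

## Scoring and reported quantities

Truth regions match predictions by maximal interval overlap; unmatched truth
counts as a miss. Border error is measured in CpG-index units between the
planted erosion boundary and the boundary of the predicted hyper region.
`scripts/acceptance.py` reports, per run: classification accuracy and the
fraction of borders within ±1 CpG on the default conditions (200 regions),
the missed fraction under the 0.2 benchmark, phUMR/fhUMR counts, a matched
no-erosion null run (fraction of p < 0.05, count of fhUMR calls — expected
~0.05 and 0), and the Viterbi-vs-enumeration agreement on 200 random
regions. The null run uses 60 regions, enough for several thousand CpG-level
tests while keeping the script fast.

## Known limitations

* The per-sample UMR caller is a generic two-state segmenter; it does not
  model CpG density or distance between sites, so very sparse regions can
  fragment.
* The HMM ignores inter-CpG distance; transitions are per-step, not
  per-base-pair.
* Only two-cohort designs are supported; hypomethylation is modeled as a
  state but not emitted as a product.
* Welch's t-test on [0,1] levels is approximate for small cohorts and
  extreme means; a beta-binomial test is out of scope.
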