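# Methods

## Scope and model

`xsig` implements a comparative-transcriptomics pipeline: tumor signatures
are derived from oncogene-driven animal models profiled by SAGE tag counts,
mapped into human gene identifiers, and used to classify individual human
cohort samples by gene-set enrichment. The statistical core — the
running-sum enrichment statistic with permutation nulls — is implemented
from scratch; everything around it (linear algebra, t distributions,
hierarchical linkage) uses numpy/scipy.

## Differential expression on SAGE counts

Tag counts are normalized per sample to TPM: `tpm = count / library_size ×
1e6`, so each sample column sums to exactly 1e6. A pseudocount of 1 TPM is
added to numerator and denominator of every ratio and log, which bounds
fold changes for genes absent in one condition (fold changes are reported
as magnitudes ≥ 1 with a separate direction flag).

Two test designs match the two study designs:

* **Unreplicated** (single tumor, ≥ 2 controls): per gene, the per-control
  log2 ratios `r_c = log2((tumor+1)/(control_c+1))` are tested against
  mean 0 with a two-sided one-sample t (df = n_controls − 1). This design
  treats the ratios as independent even though they share the single
  tumor's noise; under biological overdispersion it is therefore
  anti-conservative. That is a property of the design, not a bug: the
  package reproduces it faithfully, and the calibration guarantees below
  are stated for the replicated design.
* **Replicated** (≥ 2 per group): pooled-variance two-sided Student's t on
  `log2(TPM+1)`; a Welch option exists but is not the default. Identical
  groups give t = 0, p = 1 by convention.

Genes with zero variance receive a variance floor equal to the smallest
nonzero per-gene variance in the dataset (overridable), keeping perfectly
consistent ratios testable instead of silently dropping them.

Selection: a gene is deregulated iff fold change > 1.5 AND p < 0.05 AND
max(mean tumor TPM, mean control TPM) > 10. Selection is monotone in all
three thresholds. Three-model intersection enumerates all 7 Venn regions
exactly, per direction.

The bundled worked-example table of genes commonly deregulated in all
three models lists per-model fold-change magnitudes and p-values; one
listed fold change rounds below the 1.5 cutoff, so the reproducible
intersection criterion on that table is per-model significance (p < 0.05)
plus direction consistency, which yields exactly 21 common up-regulated
and 16 common down-regulated genes.

qPCR validation values use `log2 FC = −ΔΔCT = −[(CT_target −
CT_reference)_transgenic − (CT_target − CT_reference)_control]`.

## Identifier collapsing and homolog mapping

Many-to-one collapsing (transcripts → gene cluster; microarray probes →
gene cluster) takes the per-sample maximum expression value — the rule is
applied per value, not to row means, so it is well defined for cohort
data and idempotent. One-to-many homolog mapping keeps only the first
human cluster of each zebrafish cluster's ordered homolog list (the list
order is treated as authoritative input); outputs are deduplicated because
distinct zebrafish genes can share a first homolog, and unmapped inputs
are returned explicitly. The accounting identity
`|output| + |dropped| + |duplicate merges| = |input|` holds exactly.

## Enrichment statistic

For a ranked list of N genes with scores `s_i` (sorted non-increasing,
ties broken lexicographically by gene id for bit-reproducibility) and a
set with n_hits members in the list, the running sum increments by
`|s_i|^w / Σ_hits |s_j|^w` at hits and decrements by `1/(N − n_hits)` at
misses. The enrichment score ES is the running-sum value at its maximum
absolute deviation; when a positive peak and a negative trough tie in
magnitude (possible exactly, e.g. with rational miss steps), the earlier
position wins, decided with a 1e-12 tolerance so that summation order
cannot flip the sign. The running sum always ends at 0; ES ∈ [−1, 1]. The
leading edge is the hits at or before the extremum (at or after, for
negative ES). Weight w defaults to 1 (the established weighted form);
w = 0 gives the classic Kolmogorov–Smirnov form whose extreme placements
have analytic values ±1. If every hit has score exactly 0 at w > 0, hit
increments fall back to equal steps rather than 0/0.

Ranking metrics: two-class comparisons use the pooled two-sample t
statistic (signal-to-noise is available as an option); a singleton target
class uses `(x − mean_rest)/sd_rest`, the rest-only studentization, since
a two-sample t is undefined at n = 1. The rest class must have ≥ 3
samples. Pre-ranked mode scores genes by `−log10(p)` for up-regulated and
`+log10(p)` for down-regulated genes (p = 0 clamps to the smallest
positive float with a warning).

## Permutation nulls, NES, p, FDR

* **Phenotype permutation** relabels samples and recomputes the full
  ranking and ES per arrangement. When the number of distinct
  arrangements (C(n, k); n for a singleton class) is within the
  permutation budget, the null is enumerated exhaustively — then the
  observed arrangement is itself in the null and the empirical p is the
  plain count ratio (never 0). Sampled nulls use add-one smoothing,
  `p = (1 + #{|null same-sign| ≥ |ES|}) / (1 + #same-sign)`.
* **Gene-set permutation** scores random same-size sets on the fixed
  ranking (vectorized), the standard null for pre-ranked analysis and the
  recommended null for singleton phenotype classes (see below).

NES = ES / mean(|same-sign null ES|); null ES are normalized the same way.
FDR q for a positive NES is `[frac. pooled null NES ≥ NES] / [frac.
observed NES ≥ NES]` (mirrored for negative), clipped to [0, 1] and made
monotone by a running minimum processed from least to most extreme |NES|
within each sign — so a stronger enrichment never reports a larger q.
With a single scored set the ratio reduces to the pooled same-sign tail
fraction. Default 1000 permutations (tests and evaluation studies use
200, which bounds the p resolution at 1/201 and keeps runs fast).

## Per-sample cohort classification

Each cohort sample in turn is the singleton target class; the signature is
scored on the sample's ranking, and the sample is *correlated* with the
signature when q < 0.25 and NES > 0 (the positivity requirement means a
signature planted *down* in a sample can never flag it). Signatures whose
overlap with the cohort's gene universe is below `min_set_overlap`
(default 5) return an explicit no-result marker; such samples stay in all
denominators.

Null choice matters for singleton classes. The singleton-arrangement
(phenotype) null — which sample plays the singleton — is provided and
exhaustive for cohorts within the permutation budget, but in a cohort with
a genuinely correlated subgroup that null *contains the other correlated
samples*: every strongly enriched arrangement is a subgroup member, so a
member's rank within the null approaches its rank within the subgroup and
sensitivity is structurally capped no matter how clean the separation.
The gene-set permutation null scores random same-size sets on the sample's
own ranking, is unaffected by cohort structure, and is the established
recommendation for phenotype classes with very few samples; it is the
default used in the recovery studies. Both modes are one config field
apart.

Representation summaries report, per dataset and overall, the percentage
of samples correlated with each signature, with at least one, and with
each pair and the triple. The overall row is sample-weighted (total
flagged / total samples) by default; dataset-averaged is a flag. The
inclusion–exclusion sanity invariants (any ≥ each single; triple ≤ each
pair) are asserted before results are written.

Stage profiles run one stage-vs-rest enrichment per ordered stage label
(two-class ranking for stages with ≥ 2 samples, singleton rule otherwise).

## Pathway matrix and clustering

Per (pathway, condition): score = sign(NES) × min(−log10(q), cap), cap 4
(q = 0 is treated as 1e-4); q = 1 gives exactly 0; a pathway absent from a
condition's results is missing (NaN). The exclusion filter drops a pathway
when missing-or-zero cells exceed `max_missing` (default 5) — the two weak
states are counted as one clause, which is what makes the "more than five"
tally well defined. Retained values are never altered. Clustering is
agglomerative (scipy linkage; Euclidean + average linkage by default, the
defaults of the desktop tool traditionally used for such heatmaps), with
rows name-sorted first so equal-distance merges resolve deterministically;
missing cells enter distances as 0 (neutral). The merge tree exports to
Newick.

## Synthetic data

* **SAGE generator**: baseline gene abundances are log-normal (σ = 2)
  proportions shared by all models — a heavy-tailed library in which a few
  genes dominate, as in real SAGE. Planted genes multiply (up) or divide
  (down) the configured fold change (default 8) into tumor proportions
  before renormalization; counts are negative-binomial via gamma–Poisson
  with gene-level dispersion 0.2 by default. Planting is restricted to
  genes whose baseline TPM lies in [20, 1000]: signature genes are
  expressed (the selection criteria include a TPM floor, so sub-floor
  genes are unrecoverable by design) and not library-dominating (so the
  compositional renormalization perturbs unplanted genes only slightly).
  Library sizes are drawn uniformly from 10–23 million tags — the study
  scale; gamma–Poisson sampling cost is independent of depth, so realism
  is free. The three-model overlap is a controlled Venn design (common
  core default 21 up / 16 down). xmrk and Myc get a single tumor sample
  (unreplicated design), kras gets 3 tumors vs 3 controls.
* **Cohort generator**: per-gene baselines (log2 mean ~ U(6, 12), sd ~
  U(0.3, 0.8)), Gaussian noise of one gene-sd, and each sample joins each
  signature subgroup independently with probability 0.2 — memberships
  overlap, producing the co-correlation structure. Members add
  `effect_size × gene_sd` (default 3) to that signature's genes.

What the generators do *not* emulate: real gene identities and
co-expression, batch and platform effects, tag-mapping ambiguity, and
cohort-specific missingness. Passing recovery tests therefore shows the
pipeline's statistics are correct and well calibrated under the stated
noise model, not that real cohorts reach any particular representation
percentage.

## Evaluation studies (tests + acceptance script)

All studies are seeded and regenerate their inputs:

* common-gene table intersection → exactly 21 up / 16 down;
* running-sum ES vs brute-force enumeration over every subset of random
  universes (N = 5, 8, 12; weights 0 and 1) to 1e-10, plus analytic ±1
  extremes;
* null calibration: 6-vs-6 label-independent data, 20 random sets,
  200 permutations, 10 seeds — pooled nominal p super-uniform (one-sided
  KS at the 1% level plus the permutation grid step) and the fraction of
  sets at q < 0.25 below 0.25 + 3 Monte-Carlo SEs;
* cohort recovery: 100 samples, 1200 genes, three overlapping subgroups,
  effect 3 sd, 10 seeds — sensitivity and specificity ≥ 0.9 and
  representation percentages within 10 points of the planted truth;
* DE calibration and recovery: replicated-test type-I within binomial 99%
  bounds of 0.05 at default settings; planted 8-fold genes recovered with
  sensitivity ≥ 0.9 at defaults; null full-selection fraction ≤ 1% at low
  dispersion (0.01) — at the default dispersion of 0.2 the unreplicated
  design's ratio correlation inflates null selection (a documented
  property of that design, see above);
* pathway-filter boundary: weak in 6 of 30 → excluded, exactly 5 →
  retained, random patterns vs a counting oracle;
* ΔΔCT worked value +4 and sample-swap antisymmetry.

Problem sizes (300–2000 genes, 100-sample cohorts, 200 permutations, 10
seeds) were chosen so each study finishes in seconds while keeping
Monte-Carlo error well inside the asserted margins.

## Known limitations

* The unreplicated one-sample ratio test cannot separate the single
  tumor's biological noise from signal; its null selection rate grows with
  dispersion. Interpret unreplicated signatures as the original design
  intended: candidate lists, validated downstream.
* FDR q from permutation pooling is an estimator, not a guarantee; with
  very few scored sets its resolution is coarse.
* Homolog mapping trusts the first-entry order of the supplied table; no
  sequence-based inference is attempted.
* No multiple-testing correction is applied at the DE stage (matching the
  original procedure); the selection thresholds are the control.
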