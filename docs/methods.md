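# Methods

## The immigration ratio

Consider a completely mixed reactor with sludge retention time θ fed a
stream in which population *i* has relative abundance f_i. At steady state
a non-growing population with first-order decay rate b reaches a reactor
abundance of f_i · s with survival factor s = 1/(1 + bθ): washout and decay
can only dilute it. The ratio of mean digester to mean influent relative
abundance,

r_i = mean_digester_i / max(mean_influent_i, ε),

is therefore ≤ 1 for non-growing immigrants (up to compositional
renormalization) and ≫ 1 for populations sustained by in-situ growth. The
ratio is a proxy, not a net growth rate: it ignores flow variation, uses
relative (compositional) abundances, and inherits 16S copy-number and PCR
biases. Its power comes from the bimodality of its abundance-weighted
distribution — growing and immigrating populations separate into two modes
— and from the THP control: thermal-hydrolysis pre-treatment lyses feed
biomass, so THP reactors show only the growing mode.

Conventions and defaults:

- **Influent combination** — the primary-stream and surplus-stream means
  are averaged 50:50 (`mean_of_streams`), reflecting the typical organic
  mass ratio of the two feeds; a `pooled` mean over all influent samples is
  available because sample counts per stream are unbalanced in real
  surveys.
- **Pseudo-abundance ε** — half of one read at the rarefaction depth
  (5×10⁻⁵ at 10 000 reads). It gives digester-only OTUs large finite
  ratios (an OTU at 1% maps to r = 200) without letting sampling zeros
  produce infinities. Configurable.
- **Weights** — each OTU enters the ratio distribution with mass equal to
  its mean digester abundance in the analyzed group, so the histogram
  describes read mass, not OTU counts.
- **Thresholds** — growing above 10, non-growing at or below 1 (inclusive:
  a ratio of exactly 1 is consistent with pure pass-through). The band in
  between is reported as `intermediate` rather than forced into a class.
- **Scope** — ratios are computed per process group across plants by
  default; a per-plant mode is available (`plant=` argument).

## Split detection

The split of the weighted log10-ratio distribution is located by a
two-component Gaussian mixture fitted by EM with per-observation weights
(the OTU read-mass weights above). Standard mixture implementations do not
accept observation weights, so the 1-D EM is implemented in
`immigratio._mixture` (50 restarts from random weighted-quantile splits,
tolerance 1e-8 on the weighted log-likelihood, variance floor 1e-6). The
split is the point between the component means where the weighted
posteriors are equal, solved in closed form (quadratic) and cross-checked
in tests against a dense grid search.

The distribution is flagged **bimodal** only when all three hold:

1. component means separated by more than 2 pooled standard deviations
   (σ_pooled² = π₁σ₁² + π₂σ₂²);
2. each component carries ≥ 2% of the read mass — a component holding a
   fraction of a percent of the reads (e.g. residual immigrant DNA in a
   THP reactor) is not a mode of the distribution;
3. the fitted mixture density has two local maxima whose connecting valley
   drops below half the minor peak. This prominence condition rejects
   "shoulder" fits, where EM carves a narrow satellite component out of a
   unimodal distribution that can satisfy the first two rules.

When any condition fails the detector falls back to the fixed split
(default ratio 10) with a logged warning and reports the dominant mode's
location, so the THP control can still be checked for "a single mode above
10".

## Normalization and structure metrics

- **Rarefaction** draws without replacement (multivariate hypergeometric)
  to the target depth, so no OTU exceeds its observed count and column
  sums are exact. Samples short of the depth are dropped with a warning by
  default (the alternative raises). All draws come from one seeded
  generator in column order, so output is bit-identical per seed.
- **Abundance filter** (≥ 0.1% in at least one sample, inclusive) defines
  the reporting universe only; columns are not renormalized, so reported
  fractions remain fractions of total (domain) reads.
- **Domain-restricted runs** (e.g. archaea amplified with non-specific
  primers): by default the full table is rarefied, then restricted to the
  domain and re-fractioned (`domain_order="rarefy_first"`); restricting
  first and rarefying within the domain is available since survey write-ups
  rarely pin the order down.
- **Abundant core**: OTUs ranked by mean relative abundance over the scoped
  samples (all digester samples by default); the core size is the smallest
  k whose cumulative share of the summed means reaches the threshold
  (default 80%).
- **PCA** operates on Hellinger-transformed profiles (square roots of
  fractions) by default — the standard pre-treatment that makes Euclidean
  ordination behave sensibly on compositional data; `log1p_scaled` and
  `none` are provided because published figures often leave the transform
  unstated. Components are oriented deterministically (largest-magnitude
  loading positive).
- **Alpha diversity**: observed richness, Shannon (natural log), inverse
  Simpson, computed on even-depth counts (a warning is emitted otherwise).
- **Taxonomy**: 7-rank lineages are prefix-closed (a gap truncates all
  lower ranks); the placeholder-token list mapping to "unclassified" is
  explicit and configurable because classified-read fractions depend
  directly on it. Curation overrides (exact OTU rows beating lineage-prefix
  patterns) reset ranks below the overridden one so no stale labels
  survive. Rank aggregation falls back to OTU ids for unclassified OTUs,
  conserving column sums exactly.

## The synthetic generator

`SimConfig` defaults define the study conditions the tests and the
acceptance script run under:

| parameter | default | rationale |
|---|---|---|
| n_otus | 2000 | order of the filtered OTU universe in digester surveys |
| depth | 10 000 reads | standard even subsampling depth |
| samples | 80 digester per group, 60+60 influent | ~1/2-scale of a multi-year survey (up to ~280 digester and 121/137 influent samples per group) |
| lognormal_sigma | 2.0 | rank-abundance spread of influent communities spanning ~4 decades |
| stream_membership | 0.65 per stream | partial overlap between primary and surplus communities, ~12% of OTUs in neither |
| survival_range | (0.01, 0.67) | s = 1/(1+bθ) with decay b ∈ [0.05, 2] d⁻¹ and SRT θ ∈ [10, 55] d |
| thp_survival | 1e-3 | lysed feed biomass; a trace of persistent DNA |
| grower_fraction | 0.15 | ~300 growing populations, matching the scale of the abundant core |
| grower_sigma, enrichment_range | 0.5, (50, 200) | growers emulate the abundant core, whose spread is far narrower than the full influent rank-abundance curve |
| dirichlet_concentration | 500 | moderate sample-to-sample variability (communities stable over time, rare OTUs highly dispersed) |

Construction: each stream draws log-normal abundances over its OTU subset.
Digester mass per OTU = feed fraction (50:50 stream mean) × survival for
stream members, plus feed-independent grower mass for a grower subset
chosen preferentially from OTUs absent (then rarest) in the streams. The
grower block is scaled so total unnormalized mass is exactly 1; this makes
a pure immigrant's analytic expected ratio equal its survival s *exactly*
(rather than s divided by a dataset-dependent normalizer), which the tests
exploit. Growers absent from both streams have infinite analytic ratio,
recorded as +inf and compared through the ε-regularized variant. Reads are
Dirichlet-multinomial per sample; all randomness flows from `seed`.

What the generator does **not** emulate: temporal dynamics and reactor
upsets, per-plant community differences within a process group (plants of a
group share a true composition and differ only through sampling noise),
copy-number and PCR/primer bias, chimeras, and OTU-clustering artifacts.
Passing recovery tests therefore shows that the statistic works when its
steady-state assumptions hold — not that those assumptions hold in any
particular reactor.

Recovery scoring: predicted `growing` is correct for true growers,
`non_growing` for true immigrants, and `intermediate` counts against the
true class; balanced accuracy is the mean of the two recalls. Classification
near the noise floor is intrinsically hard: an OTU at the 0.1% filter
boundary has few reads per sample, and with overdispersed counts its ratio
estimate spans a factor of a few — the residual misclassification sits
almost entirely in that stratum.

## Numerical choices and degenerate inputs

- Ties in abundance rankings (top taxa, core) break by label ascending, so
  orderings are total and reproducible.
- `detect_split` requires ≥ 10 positively weighted OTUs and ≥ 2 distinct
  ratios; all-zero weights, all-zero samples, transposed count tables and
  conflicting override rows are rejected with named entities rather than
  silently repaired.
- Float output is written at 6 significant digits; round trips preserve
  counts exactly and floats to that precision.
- Pipeline outputs are fully determined by the manifest (config + seed +
  version): re-running reproduces every table byte-identically.

## Problem sizes

The default test and acceptance runs use the full default generator
(2000 OTUs, 360 samples) for the end-to-end recovery checks — a few seconds
of compute — and small purpose-built tables (≤ 300 OTUs) for unit-level
oracle comparisons, including 10 000-replicate rarefaction draws checked
against the exact hypergeometric distribution.
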