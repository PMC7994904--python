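# Methods

## Screen model and analysis procedure

The pipeline targets pooled knockout screens with a GeCKO-style library
(six sgRNAs per gene plus non-targeting controls) sequenced at ≥500 reads
per guide, with one baseline collection (T0, two replicates) taken before
the culture is split into vehicle and drug arms, and three later
collections (T1–T3) under stepwise-escalating drug concentration.

Counts are depth-normalized to reads-per-10⁷ per sample; each positive
column of the normalized table sums to 10⁷ exactly (a conservation
property the tests assert), making normalization invariant to rescaling a
sample's raw depth. Guides whose baseline counts fall strictly below 50
reads — about 10% of the expected per-guide count at 500× coverage — are
flagged as noise and excluded identically from every downstream contrast.
With two T0 replicates the default statistic is their mean (minimum and
all-below modes are available); the threshold can alternatively be framed
as a fraction of the expected per-guide count. Because T0 precedes the
arm split, the mask is global rather than per-arm.

Fold-changes are per-guide pseudocounted log₂ ratios of drug over
same-timepoint vehicle. Gene summaries use the arithmetic mean of guide
log fold-changes (`mean_mode="mean_of_logs"`). The alternative reading —
the log₂ ratio of mean normalized abundances — is offered as
`mean_mode="log_of_means"`; the two differ in principle (Jensen) and the
mean-of-logs form is the default because it composes with the per-guide
sign-concordance count, which is defined on the same per-guide values.

Sign matching is strict: a log fold-change of exactly 0 matches neither
sign, and a gene whose mean is exactly 0 gets terrace rank 0 and is
excluded from candidate selection. Non-targeting control guides do not
form a real six-guide gene set (any large pseudo-gene passes a fixed k ≥ 4
gate trivially), so they are excluded from gene summaries by default and
available via `include_controls=True`.

DRACO keeps genes with concordance k ≥ 4 ("four of six", literal mode:
genes reduced below four usable guides by the noise filter can never
pass; a proportional mode requiring k/n ≥ 2/3 with n ≥ 3 is available)
and reports each survivor's max-|L_FC| guide at its signed value. Ties —
on |L_FC|, and everywhere else in the package — break lexicographically
on guide/gene id so every ordering is total and runs are reproducible.

Top-candidate selection for the terrace method filters to rank ≥ 4 and
orders by rank first, then mean L_FC; rank-then-mean was a genuinely open
choice (mean-only ordering within the rank-filtered pool gives the same
lists whenever ranks are saturated) and the rank-first form was chosen
because the terrace chart itself presents rank as the primary key. The
DRACO method orders by the selected guide's signed value alone. Both
restrict to the requested direction's sign (a "most dropped-out" list
never back-fills with enriched genes). Enrichment-side selection applies
the same k ≥ 4 rule symmetrically.

## Screen comparison

Top-list overlap reports the intersection count (symmetric) and the
fraction relative to the reference list. Panel alignment orders a fixed
gene panel by screen A's score (mean L_FC by default; the DRACO selected
value optionally) with a stable sort, and reports Pearson, Kendall tau-b
(ties are expected in discretized scores) and Spearman rho. The naive
O(n²) rank-correlation implementations live in the test suite as oracles,
not in the package.

## Combo-efficacy ranking

Viability is blank-subtracted absorbance relative to the vehicle mean;
signals below blank clamp to 0% viability and are flagged. The additive
gap is killing(combo) − killing(best single agent) in percentage points,
where "best" is the higher mean killing of the two singles. Levels: the
scheme fixes gap < 20 ⇒ levels 1–2, 20 ≤ gap < 30 ⇒ levels 3–4,
gap ≥ 30 ⇒ level 5; the internal sub-boundaries (level 2 from 10, level 4
from 25) are package choices and configurable — only the 20- and 30-point
boundaries are contractual. Negative gaps are reported as rescue
interactions at level 1. Significance is a two-tailed two-sample t-test
of combo vs best-single replicate killing; Welch's form is the default
(robust to unequal variances) with pooled-variance Student's available.
A combo is "effective" only when significant at α = 0.05 with a positive
gap; with fewer than two replicates in either group the level is still
computed but the effective flag is undefined rather than guessed.

## FASTQ spacer counting

Exact matching only: the 20-mer following the first occurrence of the
vector anchor (default `CACCG`, configurable; anchor-free substring scan
available) is looked up in the library's spacer index. Reads are
partitioned into matched / unmapped / anchor-missing so accounting always
conserves the total — the statistics double as library-quality metrics.
No mismatch tolerance, trimming, or demultiplexing is attempted.

## Synthetic screens

`SimConfig` defaults describe the study conditions the pipeline is tested
under: 2,000 genes × 6 guides + 100 controls, log-normal baseline
composition (σ = 0.8, a typical post-amplification library skew),
coverage 500 reads/guide, and negative-binomial counts with dispersion
α = 0.2 (var = μ + αμ², in the range reported for pooled-screen count
data; at the defaults the simulated T0 replicate Pearson correlation is
≈ 0.7, and the null per-guide log fold-change SD is ≈ 0.9). Guide
efficiency is a mixture: 20% inactive, the rest Beta(5, 2) (mean 0.71) —
the heterogeneity that motivates concordance filtering. Effects are
per-gene: a basal knockout fitness f_g (essential genes default −0.4 per
collection interval, acting in every arm) and a drug-interaction effect
d_g acting under pressure. Abundances evolve multiplicatively,
a(t+1) = a(t)·exp(e·(f_g + p(t)·d_g)), with the pressure schedule
(0.5, 1, 2) mirroring stepwise dose escalation; vehicle arms have p = 0.

The strong-effect default is |d_g| = 1.0: a fully efficient guide
accumulates ≈ 3.5 natural-log units (≈ 5 log₂) by T3 — the magnitude of
a clear terrace-plot dropout. Larger values were rejected because a
handful of enrichment genes would then take over a macroscopic fraction
of the drug arm's reads and shift every null guide's fold-change through
renormalization, which real screens of this design do not show. Labeled
gene classes: `strong_dropout` (≥4 efficient guides guaranteed),
`single_efficient_guide` (one guide at e = 1, five at e = 0 — the
false-positive mode for per-guide ranking), `strong_enrichment`,
`essential`, `null`; labels are assigned to randomly permuted genes so
label never correlates with gene id.

What the generator does *not* emulate: infection/MOI structure, PCR
amplification bias (overdispersion absorbs it only on average), guide
off-target effects, cell-cycle or density dependence, and genetic drift
between collections (arms differ only through fitness and sampling).
Consequently, passing recovery tests shows the ranking logic is correct
under the stated noise model, not that real screens at these depths have
these error rates.

Plate simulation inverts the viability computation: absorbance =
blank + signal·(1 − killing/100)·(1 + cv·ε) with multiplicative Gaussian
noise; at cv = 0 the round trip is exact, and at the default cv = 0.05
with four replicates the estimated killing is within ±3 points of truth
in ≥95% of runs (asserted by Monte-Carlo in the tests).

## Numerical and degenerate-input choices

- Pseudocount +1 on normalized values guarantees finite fold-changes at
  zero counts; N_d = N_c = 0 gives L_FC = 0 exactly.
- An all-zero sample column is an error (normalization undefined), never
  silently dropped.
- Guides present in the library but absent from a count file are
  zero-filled with a warning: dropout screens legitimately drive counts
  to zero, so absence is data, not corruption.
- Zero variance makes Pearson/Spearman/Kendall undefined; the package
  raises rather than returning NaN.
- The editing-efficiency diagnostic is the two-sample KS statistic
  between normalized abundances of essential-targeting guides and all
  others; it must grow from T0 to late timepoints when editing works.
- Problem sizes in tests and the acceptance script (2,000-gene screens,
  10⁵-draw Monte-Carlo oracles) were chosen as the smallest sizes at
  which the stochastic checks have stable margins.

## Known limitations

- No statistical model for hit calling (no p-values/FDR as in
  count-model frameworks like MAGeCK); terrace/DRACO are deterministic
  rankings, and the four-of-six gate is their only false-positive
  control. Under pure noise, six iid sign-symmetric fold-changes pass
  k ≥ 4 about 62% of the time — the gate thins single-guide artifacts
  (it rejects ~60% of them, and the per-gene mean rejects none) but is
  not a significance test, so ranked position, not gate passage, carries
  the evidence.
- Exact spacer matching undercounts reads with sequencing errors in the
  spacer; counts are relative, so ranking is unaffected unless error
  rates differ per guide.
- Efficacy levels 2 and 4 depend on configurable sub-boundaries; only
  level ≥ 3 and level 5 calls are comparable across configurations.
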