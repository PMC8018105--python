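# Methods

## Data model

A study is four aligned tables: a probe annotation (probe id, chromosome,
1-based position, CpG-island relation), a probes × samples beta matrix
(methylation fractions in [0, 1], missing allowed), optional methylated/
unmethylated channel intensities of the same shape, and a sample sheet
linking samples to patients, primary/relapse status, relapse index and
molecular subgroup. Substructure labels are normalized to six canonical
categories (ISLAND, N_SHORE, S_SHORE, N_SHELF, S_SHELF, UNDEFINED); the
synonym map accepts manifest dialects ("Island", "OpenSea", "N Shelve"),
and anything unrecognized becomes UNDEFINED with a logged count. Alignment
takes the probe intersection of annotation and matrix and the sample
intersection of matrix and sheet, preserving matrix order; it is
idempotent and refuses empty intersections. Raw scanner files are out of
scope — matrices arrive preprocessed, and no normalization (quantile,
functional, dye-bias) is applied here.

## Scales

Betas are the natural reporting scale (group means, substructure
summaries); testing happens on M = log2(β/(1−β)), which roughly
stabilizes variance across the methylation range. β is clipped to
[ε, 1−ε], ε = 10⁻³ by default, before the logit so M stays finite at the
boundaries; the inverse map is exact away from the clip. The two scales
are never mixed inside one statistic: a result is either a beta-scale
mean comparison or an M-scale test, and outputs say which.

## Paired differential methylation

Each patient contributes one pair. Two pairing policies exist because
real relapse cohorts have more relapses than primaries: `first_relapse`
(default) keeps the earliest relapse; `all_relapses_averaged` averages a
patient's relapse profiles into one pseudo-sample. Patients missing
either member are dropped with a count.

Per probe, the paired design reduces to a one-sample t on the M
differences. The sample variance is floored at 10⁻⁸ (M² units) so
constant probes give t = 0, p = 1 rather than an infinite statistic.
Probes with fewer than two complete pairs are flagged NaN and excluded
from adjustment. BH adjustment is the step-up procedure applied over the
finite p-values.

Empirical-Bayes moderation is opt-in. The model takes s²_g as scaled
chi-square around σ²_g with an inverse-chi-square prior (d₀, s₀²);
posterior variances interpolate probe and prior, and the moderated t has
df + d₀ degrees of freedom. (d₀, s₀²) come from moment matching on
log s²: the excess dispersion of log variances beyond the chi-square
expectation determines d₀ through an inverse-trigamma (Newton) solve.
When observed dispersion does not exceed the chi-square expectation, d₀
is infinite and s₀² falls back to the arithmetic mean of the variances —
unbiased, and exact when all variances coincide.

Scopes: the whole cohort and each subgroup separately. A subgroup with
fewer than two complete pairs yields an empty table plus a warning, not
an error, because n = 2 subgroups are a fact of life in these cohorts
(df = 1 runs fine; a single pair does not).

## Substructure status and fractions

For each non-open-sea stratum, the vectors of per-probe primary means and
relapse means are compared with a two-sided t over probes. The default
treats the two means of one probe as a matched pair (paired t over
probes); a Welch unpaired variant is exposed because the group-mean
comparison can defensibly be read either way, and the output labels the
mode. Strata with fewer than two usable probes are flagged without a
statistic.

The fraction analysis selects probes at raw p < α (α = 0.05). The
selection is a marginal screen — probes are not ranked against each other
— so the uncorrected p is the appropriate filter; an adjusted-p switch
exists. Selected probes are classified by strict sign of logFC: negative
= hypomethylated, positive = hypermethylated, exactly zero = neither
(excluded from denominators, preserving the identity hypo + hyper =
classified). Open-sea probes are dropped, matching the substructure
analysis; a flag can re-include them as a sixth category. Percentages are
reported per stratum for three panels (all changes, hypo, hyper), each
summing to 100.

## Copy number

Total intensity per cell is methylated + unmethylated. Per patient and
locus the log-ratio is log2((I_rel + c)/(I_prim + c)) with pseudocount
c = 1 intensity unit guarding zeros. Per-patient median-centering
(default on) removes array-wide scale differences; note it shifts every
locus of a patient by one constant, so when a large fraction of the
genome carries an event the affected-vs-unaffected contrast, not the raw
affected mean, is the centering-invariant quantity. The cohort view ranks
loci by cross-patient variance of the log-ratio (default; recurrent
change) or by maximum absolute value, breaks ties by genome position,
and renders the top k (default 1000) in genome order with patients
grouped by subgroup. No segmentation is performed — output is
locus-level.

## Morphology

Scores arrive as data (no image analysis): ordinal cell density (1–3),
necrosis and vessel proliferation (0–3), Ki67 percent (0–100). Groups are
summarized as mean ± SEM and compared with an unpaired two-sided t.
Pooled variance is the default because it is the variant that reproduces
published group comparisons from their printed summaries; Welch and a
Mann–Whitney alternative are available. `t_from_summary` rebuilds group
SDs as SEM·√n, so summary-level and raw-level tests agree to machine
precision on the same data. Ordinal scores are treated as interval data,
as is conventional in histology scoring.

## Synthetic cohorts

The generator emulates a paired five-subgroup cohort (default 11/2/23/7/2
patients, one primary + one relapse each, extensible to multiple
relapses). Defaults were chosen once to describe the emulated study:

- **Substructure composition** follows the reference 450K breakdown
  (31% islands, 13%/10% shores, 5.1%/4.6% shelves, 36% open sea).
  Chromosomes are 22 equal 100 Mb autosomes — sex chromosomes are
  excluded so copy-number tests are not sex-confounded.
- **Baseline betas** are a two-component Beta mixture: Beta(2, 18) (low,
  mode ≈ 0.06) and Beta(18, 2) (high). Island probes draw low with
  probability 0.8; all others high with probability 0.8. This reproduces
  the canonical bimodal marginal with islands mostly unmethylated.
- **Noise** sits on the M scale: a per-patient offset shared by the pair
  (SD 0.5) and per-sample residual noise (SD 0.3) — values that give
  realistic within-pair beta scatter of a few percent at mid-range.
- **Planted relapse effects** are specified on the beta scale, the scale
  on which substructure results are read: relapse β = invlogit2(M₀ +
  patient + noise) + δ, clipped to [0.001, 0.999]. Adding δ after the
  back-transform makes the expected relapse − primary beta difference
  equal δ exactly (away from the clip, which censors shifts for probes
  near the ceiling). Defaults plant +0.05 in islands for the three
  subgroups where island hypermethylation is expected and −0.03 in
  shelves for two of them.
- **Intensities** are lognormal with median 2000 fluorescence units and
  log-SD 0.1 per (probe, sample). Because draws are independent across
  samples, the relapse/primary log2-ratio SD is σ√2/ln 2 ≈ 0.2 — the
  scale observed for paired array total-intensity ratios, where probe
  affinity cancels. Copy-number events multiply relapse-sample totals
  inside a chromosome window for one subgroup; no events are planted by
  default, reflecting cohorts whose copy-number profiles stay stable at
  relapse. Methylated intensity is total·β, unmethylated total·(1−β).

The truth table records the per-probe beta shift and per-locus log2
intensity factor per subgroup. Identical config + seed reproduces every
matrix bit-for-bit.

What the generator does **not** model: Infinium I/II chemistry
differences, batch and scanner effects, cell-composition heterogeneity,
probe cross-reactivity, correlated neighboring probes, or shared probe
affinity across samples. Passing tests therefore demonstrate statistical
correctness of the pipeline under a clean generative model, not
robustness to array artifacts.

## Numerical choices and degenerate inputs

- Variance floor 10⁻⁸ (M²) in the paired t; ε = 10⁻³ beta clip.
- CNV pseudocount 1 intensity unit; loci with zero total everywhere are
  dropped with a count.
- Top-k ties break by (chromosome, position) with a stable sort, so
  selection is deterministic and invariant to patient order.
- Zero-variance equal-mean group comparisons return t = 0, p = 1;
  zero-variance distinct-mean summary tests report p = 0.
- BH leaves NaN p-values NaN and adjusts over the finite entries.
- All randomness flows from one integer seed; orchestrated runs derive
  stage seeds deterministically from it.

## Problem sizes

The shipped analyses and checks run at 20,000–22,000 probes and 45
patients — composition-faithful scale-downs of a full 485,577-probe
array study, sized so the entire suite and the acceptance script run in
well under a minute each while Monte-Carlo errors stay an order of
magnitude below the tolerances being asserted. The accounting checks
(partition totals, hypo/hyper decomposition) run at the full published
counts since they are O(n) bookkeeping.

## Known limitations

- The substructure t over probes ignores spatial correlation between
  neighboring probes; on real arrays its p-values are anti-conservative.
- Copy-number log-ratios are locus-level and unsegmented; single-locus
  calls on real data would need smoothing the package deliberately omits.
- The moderated-t path assumes exchangeable variances across probes;
  probe-type mixtures violate this mildly on real 450K data.
- Multiple relapses per patient are handled by selection or averaging,
  not by mixed models.
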