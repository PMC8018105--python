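# epirelapse

Toolkit for asking how a tumor's DNA methylome changes at relapse, when
each patient contributes a matched primary and recurrence profiled on a
450K-style methylation array. It was built around paired ependymoma
cohorts — five molecular subgroups of very unequal size (down to n = 2)
— but the machinery is generic to any paired tumor array study.

The package answers four questions, each in its own module:

1. **Which probes change?** (`diffmeth`) Betas are converted to M-values,
   `M = log2(β/(1−β))`, and each probe gets a paired two-sided t-test on
   the per-patient differences `d_i = M_relapse,i − M_primary,i`:
   `t = d̄ / (s_d/√n)`, df = n−1, with Benjamini–Hochberg control across
   probes. Optional empirical-Bayes moderation shrinks per-probe variances
   toward a common prior, `s̃² = (d₀s₀² + df·s²)/(d₀ + df)`, with (d₀, s₀²)
   estimated by moment matching on log variances.
2. **Where do changes sit?** (`substructure`) Probes are stratified by
   CpG-island relation — island, N/S shore (≤2 kb from an island), N/S
   shelf (the next 2 kb), open sea excluded — and the per-probe mean betas
   of the primary and relapse groups are compared within each stratum.
   Probes significant at raw p < 0.05 are split by the sign of their
   logFC into hypo- (logFC < 0) and hypermethylated (logFC > 0) sets and
   reported as per-stratum percentages.
3. **Does copy number move?** (`cnv`) The total fluorescence intensity
   (methylated + unmethylated channel) tracks local DNA copy number, so
   `log2((I_relapse + c)/(I_primary + c))` per locus and patient, median-
   centered per patient, is a copy-number log-ratio; a cohort heatmap
   shows the top-1000 most variable loci in genome order.
4. **Does morphology change?** (`morphology`) Ordinal histology scores
   and Ki67 percentages are compared between groups with an unpaired
   pooled-variance t, reconstructible from published mean ± SEM summaries
   alone.

A seeded generator (`synthetic`) draws whole paired cohorts with known
ground truth — bimodal beta baselines conditioned on substructure,
patient effects and residual noise on the M scale, planted beta-scale
relapse shifts per subgroup, and lognormal intensities with optional
chromosome-window copy-number events — so every statistical claim in the
test suite is checked against planted parameters.

## Worked example

```python
from epirelapse.report import RunConfig, run_all

report = run_all(RunConfig(simulate={"n_probes": 20_000}, seed=1,
                           out_dir="results_demo"))
cohort = next(d for d in report.dmp if d.scope == "cohort")
print(cohort.n_pairs, cohort.n_sig_raw, cohort.n_sig_adjusted)
```

prints `45 7995 7345`: 45 primary/relapse pairs were tested at 20,000
probes; 7,995 probes fall below raw p = 0.05 and 7,345 survive BH —
driven by the generator's default planted effects (+0.05 island beta
shift in three subgroups, −0.03 in shelves for two). The substructure
stage of the same run localizes them: in the cohort fraction table 98.0%
of hypermethylated significant probes are in CpG islands while shelves
carry 90.0% of the hypomethylated ones (see
`analysis/03_substructure_fractions.py`, which prints these tables).

The numbered scripts under `analysis/` walk the full study in order —
cohort simulation, paired differential methylation, substructure
status/fractions, copy number (a stable run and a planted-gain control),
and morphology from published summaries — writing small tables to
`results/` and large matrices to `scratch/`. For the morphology stage,
`t_from_summary(11.62, 2.83, 14, 26.05, 3.16, 25)` reproduces the
published Ki67 relapse-vs-primary p-value (0.0043 pooled) from group
summaries alone.

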