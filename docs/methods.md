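# Methods

## The screening model

The package treats a pan-cancer study as a set of independent tumor-type
cohorts, each carrying up to four omic layers over a shared sample
universe: gene expression and exon expression on the log2 scale for both
tumor and normal samples, and methylation beta values, miRNA expression
and survival endpoints for tumor samples only (the tumor-only layers
mirror how tumor atlases are organized). Every screen is a per-cohort
statistic followed by a cross-cohort summary; no statistic is ever pooled
across cohorts, so cohorts act as independent replications of each
hypothesis.

**Differential expression.** The contrast statistic is the signed fold
change `sign(Δ)·2^|Δ|` with `Δ` the difference of arithmetic means of the
already-log2 values (mean of log2, not log2 of mean — the inputs are
log-scale normalized values, and this reading is stated explicitly
because the formula is ambiguous when written inline). The magnitude is
therefore always ≥ 1 and the value is +1 when the means tie. Significance
uses the Welch unequal-variance t-test: tumor and normal arms differ
grossly in size and provenance, so the equal-variance assumption is not
defensible. A gene × cohort cell is called `up`/`down` only when
`|FC| ≥ 1.4` **and** `p ≤ 0.05`; this compound gate is also the display
rule of the summary table, so blank cells in the report never indicate
missing data. No multiple-testing correction is applied anywhere — the
screens are deliberately calibrated at the raw per-test level, matching
the thresholds the consensus counting assumes; a Benjamini–Hochberg
adjusted column can be added by the caller from the stored p-values.

**Exon usage.** The isoform-specific vs constitutive exon contrast uses
the same signed-FC encoding but a *paired* t-test, since both exons are
measured in the same samples. The survival stratifier is the per-sample
difference `log2(exon9) − log2(exon2)`. PSI is the plain binomial
proportion `inclusion/total`; the package computes it only on counts (the
synthetic generator's, or any table supplied by the caller) — external
splice-graph PSI values are accepted as a precomputed column, never
recomputed.

**Survival.** Stratifiers are dichotomized at the median with ties
assigned to the low group (a deterministic tie rule is required; when the
median ties with the maximum the split falls back to strict-less-than so
both groups stay non-empty). Mean-splitting is available behind a flag
because the source material describes both rules in different places;
median is the default as the Methods-section rule. The log-rank statistic
is the classic Mantel–Cox accumulation over distinct event times of
observed minus hypergeometric-expected events, `χ² = (ΣO−ΣE)²/ΣV`,
referred to the upper tail of χ²₁ with no continuity correction. It is
implemented in-package (and cross-checked against `lifelines` in the test
suite) because the favorable/unfavorable direction call needs the sign of
`ΣO − ΣE` in the high group, which library wrappers do not expose:
more-events-than-expected among high-stratifier samples ⇒ unfavorable.
Kaplan–Meier curves come from `lifelines`.

**Correlation consensus.** Pearson `r` with the two-sided p from
`t = r·√((n−2)/(1−r²))` on `n−2` df; pairs with missing values are
dropped and at least 3 complete pairs are required (no smaller floor is
defensible; the source states none). Correlations use tumor samples only,
since the coupled layers exist only on the tumor side. A cohort
"qualifies" for a (feature, target) pair when `|r| ≥ 0.3` and `p ≤ 0.05`;
the criterion printed as "−0.3 ≤ r ≥ 0.3" is read as `|r| ≥ 0.3`,
consistent with how the figure captions state it. "Always negative" means
≥ 1 qualifying negative cohort and 0 qualifying positive ones — neutral
cohorts (weak or non-significant) do not break the flag. Probe selection
for survival follow-up takes features with strictly more than
`min_neg_cohorts` negative cohorts, sorted by count then probe id.

**miRNA screens.** The mirDIP class tier is an ordinal
(low < medium < high < very high); candidate screens keep predicted
miRNAs at or above the configured tier whose correlation qualifies in at
least 5 cohorts (either sign, with the direction profile reported).
Exon-9 targeting uses StarMir site probabilities (`LogitProb ≥ 0.5` on
CDS-seed/seedless sites) and requires ≥ 1 qualifying cohort against the
exon's expression. Feedback detection is the largest interpretive choice
in the package: "satisfied in at least 5 tumors" is read as ≥ 5 cohorts
positive with the ligand **and** ≥ 5 cohorts negative with the predicted
receptor, counted separately, with the intersection of the two cohort
sets reported so the stricter same-cohort reading can be audited from the
output. The prediction gate applies to the receptor arm only (it is
evidence that the miRNA can bind the receptor transcript; no prediction
is needed for the miRNA to be induced by the ligand).

## The synthetic generator

The generator produces exactly the dependence structures the screens
test for, each behind one interpretable parameter:

| mechanism | model | default |
|---|---|---|
| expression | `N(baseline + Δ_c·1[tumor], σ)` per gene, log2 units | σ = 1; Δ from the study table in the full-study config |
| methylation | `beta = invlogit(a + b·expr + ε)`, `ε ~ N(0, σ_β)` | `b = −0.3`, `σ_β = 0.4` for coupled probes (population r ≈ −0.6 at σ = 1) |
| miRNA | `m = baseline + δ·ligand + ε` | δ = 0.5, noise 0.866 (r ≈ +0.5 with the ligand) |
| repression | target `expr −= γ·m` | γ = 0.577 (r ≈ −0.5 with the target) |
| exon | `K ~ Bin(T, π)`; exon9 `= log2(1+K) + offset`, exon2 `= log2(1+T)` | π = 0.95, T = 500, offset 0.7 |
| survival | exponential times, hazard `h₀·HR^1[expr > cohort median]`, censoring `U(0, follow-up)` | h₀ = 1/1500 d⁻¹, HR = 2, follow-up 3000 d |

Choices worth stating:

* Expression is simulated directly on the log2 scale with Gaussian
  residuals — the screens operate entirely on log2 values, so a count
  model would add machinery without changing any statistic under test.
* Beta values go through a logistic link and a clamp to [0, 1]: this
  respects the beta range while keeping a monotone coupling whose sign is
  the sign of the slope. The link is near-linear around beta 0.5, so the
  intercepts of coupled probes are chosen to center them there; strongly
  hyper-/hypomethylated probes sit in the flat tails and attenuate.
* The exon model makes PSI the binomial proportion by construction. The
  literal inclusion model alone forces the isoform-specific exon below
  the constitutive one (`E[log2(1+K)] ≤ log2(1+T)`), which cannot produce
  the positive relative abundances seen in real cohorts; the additive
  per-exon log2 coverage offset (default 0.7, i.e. net FC ≈ 1.5 at
  π = 0.95, the "moderate increase" regime; the strongest observed
  cohort corresponds to a net offset of 1.34, FC ≈ 2.53) represents
  exon-length/efficiency differences and leaves the PSI counts untouched.
* Censoring is independent uniform over the follow-up window — the
  simplest non-informative mechanism under which the log-rank test is
  valid.
* miRNAs exist only in the tumor arm, so any repressor with a nonzero
  mean would shift its target's tumor/normal fold change wholesale. The
  full-study config therefore centers repressor miRNAs near zero
  (log2-normalized units). One consequence is deliberate and real: a
  ligand-driven feedback miRNA transmits `−γ·δ·Δ_ligand` onto its
  receptor target, so in the full-study simulation the receptor fold
  changes drift from their planted values in cohorts where the ligand is
  strongly shifted, and receptor modulation counts differ from the
  planted table. That is the feedback motif acting, not a defect; tests
  that check fold-change recovery use configs without miRNA coupling.
* One seeded generator drives all sampling, in a fixed iteration order
  (cohorts → genes → miRNAs → probes → exon → survival), so identical
  configs serialize byte-identically.

What the generator does **not** emulate: per-layer missingness patterns,
batch effects, copy-number or mutation structure, count-level sequencing
noise, correlated probes within a region, or non-proportional hazards.
Passing tests therefore demonstrate that the screens recover the stated
effect structures at the stated sample sizes under clean noise — not
that they are robust to the artifacts of real atlas data.

## Numerical conventions and degenerate inputs

* `Δ = 0` returns FC = +1 (sign convention); `|FC| < 1` is rejected as
  invalid input to classification.
* Both arms constant and equal: t-test returns (0, 1); constant but
  unequal: degenerate-variance error.
* `|r| = 1` returns p = 0 (the limit of the t transform); zero variance
  raises rather than returning NaN.
* Median split needs ≥ 4 valid samples; an all-identical stratifier
  cannot be split. Log-rank with zero events is undefined and raises.
* Missing values are dropped pairwise (correlations, paired exon tests)
  or per arm (fold changes); TSVs use the literal `NA` token, and empty
  cells are accepted on read.
* Fixture survival entries carry only the gate bound `p ≤ 0.05` (the
  printed tables show chi-squares, not p-values); the distinction between
  "blank because gated" and "not applicable" is preserved on load.

## Problem sizes used in validation

The acceptance script and the stochastic test suites run at reduced but
statistically adequate sizes chosen as the package's own validation
budget: 50–100 replicates for fold-change recovery at n = 200/arm,
300–500 null cohorts of n = 100 for log-rank calibration, 4 000
feature-cohort pairs at n = 15 for the Pearson null rate, and 20–30
replicates for probe/feedback recovery (12 and 6 cohorts of n = 200,
with 20 null probes and 50 decoy miRNAs respectively). At these sizes
the planted effects are recovered essentially always and the null rates
sit within binomial bands around their nominal levels.

## Known limitations

* The log-rank direction call is the sign of `O − E`; with χ² near zero
  the direction is noise (the results carry `significant` so callers can
  ignore it).
* The consensus flags treat cohorts symmetrically; cohort sample sizes
  differ by two orders of magnitude in the full study, so "qualifies in
  k cohorts" weights a 47-sample cohort equally with a 1 099-sample one,
  as the original screening strategy does.
* PFI endpoints are simulated with the same machinery as OS (independent
  draws); no dependence between the two endpoints is modeled.
* `weakly upregulated` has no printed magnitude bound in the source
  material; the package implements only the single `|FC| ≥ 1.4` gate.
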