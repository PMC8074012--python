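# Methods

## Design and measurement model

The package analyses a factorial treatment × insult design measured by
microarrays in four groups — control (Ctrl), treatment alone (Mg), insult
alone (HI) and treatment followed by insult (MgHI) — through four contrasts:

* three **two-color** co-hybridization experiments, where each replicate
  array yields one normalized log2 test/reference ratio per probe:
  Mg vs. Ctrl at 1.5 h, 3 h, 6 h, 12 h and 24 h after injection; MgHI vs. HI
  and HI vs. Ctrl at 3 h and 12 h after the insult; three replicate arrays
  per contrast and timepoint;
* one **one-color** comparison of MgHI arrays against Ctrl arrays pooled
  from the treatment-only and insult-only experiments, on log2 intensities.

Inputs are assumed normalized (LOWESS within array for ratios, a common
one-color normalization across arrays); normalization internals are out of
scope. Each array is treated as one independent biological sample, which is
the unit on which the statistics actually operate (n = 3 per condition and
timepoint).

On the log2 scale the per-gene group means are Ctrl = b, Mg = b + m,
HI = b + h, MgHI = b + x, so the contrasts estimate m, x − h, h and x.

## Probe quality control

1. **Uniformity** — a probe is removed if any spot is flagged non-uniform.
2. **Detection (one-color only)** — a probe must show signal *strictly*
   above `detection_factor × background` (default 2) in at least
   `min_detected` (default 2) replicate arrays of every
   condition-by-timepoint group. Boundary equality fails; the rule is
   deliberately a literal reading and both constants are configurable.
   Two-color tables have no detection rule — the detection clause applies
   to one-color analyses only.
3. **Annotation** — only probes mapped to a validated gene symbol are kept;
   RIKEN-clone and control probes are excluded and counted.
4. **Multi-probe resolution** — per gene × contrast × timepoint the probe
   with the largest |mean log2 ratio| represents the gene (ties break to the
   lexicographically smallest probe id, for determinism). The choice is made
   per contrast and timepoint, not globally, because gene lists are
   extracted at each timepoint separately. When significant probes of one
   gene disagree in direction at one timepoint, the gene is flagged
   `splice_conflict` and enters both direction lists.

## Differential calls

Two-color ratios are tested with a classical one-sample t against 0
(df = n − 1, two-sided); one-color comparisons with a pooled-variance
two-sample t (Welch switchable). Degenerate inputs never crash a batch run:
a zero-variance vector gives p = 1 when its mean is 0 and p = 0 (flagged
`degenerate`) otherwise.

Benjamini–Hochberg step-up adjustment is applied across probes separately
within each contrast × timepoint family. A probe is **called** under the
default `union` rule when |FC| ≥ `fc_threshold` (default 2) **or**
BH-adjusted p ≤ `p_threshold` (default 0.05), with
FC = sign(m̄)·2^|m̄| (signed fold change; repressions negative). The
`union` default follows the study's and/or selection wording; because
FC-only selection is statistically permissive, `intersection` and `p_only`
variants are exposed. Whether the threshold applies to raw or adjusted p is
also configurable (`use_adjusted`, default adjusted).

Calls are merged over timepoints per contrast: a gene is a member of the
merged directional list if called at any timepoint, in every direction in
which it was called. Genes called in opposite directions at *different*
timepoints are flagged `biphasic`; both-direction calls at a *single*
timepoint come from splice conflicts. Amplitude summaries report median and
quartiles (linear interpolation — stated because quartile conventions
differ) of signed FC per direction plus a two-sided Mann–Whitney comparison
of |FC| between directions.

## Directional list algebra

All set operations act on (gene, direction) pairs; subtraction removes
matching pairs when the subtrahend is directional and whole genes when it
is direction-free (the L2 ∖ L3 step). With L1, L2, L3, L7 the merged lists
of the four contrasts:

* **A** = L1 (proper treatment effects); **A1** = same-direction overlap of
  L1 and L2.
* **B1 (de novo)** = (L5 ∪ L6 ∪ L7) − A1 − L11, where L5 = L2 ∖ L3 (gene
  level) and L6 = opposite-direction overlap of L1 and L2 reported with
  L2's direction.
* **B2 (reversed)** = (L8 ∪ L9) − A1, where L8 = opposite-direction overlap
  of L3 and L2 and L9 = L3 genes whose one-color comparison is
  *equivalent*. Reported directions are the treatment's modulation, i.e.
  opposite to the L3 direction.
* **B3 (amplified)** = L10 − A1; **C (insensitive)** = L11.

Two constructions were genuinely open and are resolved as follows:

* **Amplified vs. insensitive (L10/L11).** Both are same-direction overlaps
  of L3 and L7; the direct MgHI-vs-HI contrast (L2) is the only measurement
  that tests amplification, so L10 requires a same-sign L2 call and L11
  requires L2 silent (gene level). An opposite-sign L2 call routes the gene
  to the reversal list instead; the three cases partition the overlap.
* **Equivalence for L9.** Absence of significance alone is weak evidence of
  "no difference", so L9 requires, at every one-color timepoint, unadjusted
  p > 0.05 **and** |mean log2 difference| < log2(1.5). The band is
  configurable. Equivalence is evaluated on the gene's representative
  (largest-|FC|) probe, the probe most likely to show a difference — a
  conservative choice.
* **Disjointness of the B sub-lists.** The plain concatenation
  (L5 + L6 + L7) − A1 − L11 would leave every amplified gene in B1 as well
  (it reaches L7 but is excluded from L11 by the L2 criterion), and
  reversal genes can reach B1 through L6/L7 under noise. Since the final
  categories must partition the entries — a gene entry is de novo *or*
  reversed *or* amplified — B1 additionally subtracts L10 and the
  reversal-claimed entries (L8, L9). `assemble_B` asserts pairwise
  disjointness and fails hard on violation.

Per-entry classification precedence is therefore B1/B2/B3/C (disjoint),
then SHARED (A1), then MG_ONLY (A outside A1); UNAFFECTED covers universe
genes in no list. Provenance records every list an entry belongs to.

Reported tallies always satisfy
`distinct = induced + repressed − dual`, with the per-direction counts
inclusive of dual-direction (biphasic / splice-discordant) genes.
Percentages in reports are rounded half-up to one decimal.

## Enrichment, regulators, ontogeny

Over-representation uses the right-tailed hypergeometric tail
P(X ≥ k) (Fisher exact) and its EASE variant (tail at k − 1; k ≤ 1 gives
p = 1, so singleton overlaps are never significant and EASE ≥ Fisher
always). Fold enrichment is (k/n)/(K/N). Bonferroni and BH-FDR columns
adjust the EASE p-value over the collection, matching annotation-tool
convention. Two filter profiles are built in: keyword/GO (count ≥ 10 and
Bonferroni < 1e−4, or EASE < 1e−4 with FE > 2) and pathway (count ≥ 10,
Bonferroni < 0.05, FDR < 10%). The universe defaults to the genes surviving
QC (the detected background), standard over-representation practice;
queries are flattened to gene level because set membership is
direction-blind.

The regulator statistic is the unweighted sign-consistency activation
z-score over a user-supplied signed regulator→target network:
z = (n_c − n_i)/√(n_c + n_i), activated when z > 2, inhibited when z < −2
(strict inequalities; z = −2 exactly is undetermined). Commercial tools
weight literature edges proprietarily; only the published unweighted form
is claimed. Genes carrying both directions are ambiguous and excluded from
the consistency count; regulators with no overlapping target are omitted.

Ontogeny concordance labels an effect *anticipating* when its direction
matches the gene's spontaneous developmental trajectory (induced on an
increasing trajectory or repressed on a decreasing one) and *antagonistic*
otherwise; genes absent from the developmental table are skipped and
counted.

## Synthetic data

The generator emulates the full design at the normalized log2 scale. Each
gene receives a planted class fixing (m, h, x) up to a random sign s and
the effect size e (default 2 log2 units ≈ 4-fold, a strong but realistic
microarray effect):

| class | m | h | x | expected category |
|-------|---|---|---|-------------------|
| NULL | 0 | 0 | 0 | UNAFFECTED |
| MG_ONLY | s·e (all 5 timepoints) | 0 | 0 | MG_ONLY |
| BIPHASIC | +e then −e at successive timepoints | 0 | 0 | MG_ONLY (dual) |
| SPLICE_DISCORDANT | ±e on two probes at one timepoint | 0 | 0 | MG_ONLY (dual) |
| DE_NOVO | 0 | 0 | s·e | DE_NOVO (B1) |
| REVERSED | 0 | s·e | 0 | REVERSED (B2) |
| AMPLIFIED | 0 | s·e | 2s·e | AMPLIFIED (B3) |
| INSENSITIVE | 0 | s·e | s·e | INSENSITIVE (C) |
| HI_ONLY | 0 | s·e (first timepoint only) | = h | INSENSITIVE (C) |

HI_ONLY is listed separately from INSENSITIVE only by kinetics (a
single-timepoint insult effect untouched by the treatment); an insult
effect the treatment does not modify is by definition category C. Replicate
noise is i.i.d. normal(0, `noise_sd_log2`, default 0.25) per spot. Class
allocation is deterministic by largest-remainder quota (a multinomial
switch exists), so recovery tests are exact. One-color intensities are
2^(b + group effect + noise) with per-probe baselines b ~ U(10, 15) log2
units over a constant background of 16; the floor keeps a 4-fold repression
of the weakest gene safely above the 2× background detection threshold, so
detection loss is an injected artifact rather than a side effect of the
effect model. Default class mix: 55% null, 10% treatment-only, 8% de novo,
6% reversed, 6% insensitive, 5% amplified, 5% insult-only, 2.5% biphasic,
2.5% splice-discordant — regulated fractions of the order reported for
acute-injury brain transcriptomes.

Quality artifacts are injected explicitly and logged: each probe is flagged
non-uniform in one randomly chosen sample with probability
`frac_low_quality` (so the retained fraction after the uniformity filter is
1 − q up to binomial error), and each one-color spot is pushed to
≤ 2 × background with probability `frac_below_detection`.

What the generator does **not** model: dye bias, spatial array effects,
intensity-dependent variance, cross-hybridization, correlated noise between
probes of one gene, and pooling of animals within an array. Passing tests
therefore demonstrate the correctness of the statistics and of the set
algebra under the stated noise model, not robustness to array-level
artifacts beyond the injected ones.

## Numerical and reproducibility choices

* All randomness flows from one `numpy.random.Generator` seeded from the
  mandatory config seed; identical configs give byte-identical TSVs.
* BH adjustment is statsmodels' `fdr_bh`; t tests and the Mann–Whitney and
  hypergeometric computations are scipy's. The tests check these paths
  against independent closed-form and integer-enumeration oracles.
* Zero-variance conventions (above) are flagged rather than fatal.
* The run manifest echoes the configuration, SHA-256 checksums of all
  inputs, stage timings and list sizes.

## Calibration

`interarray.calibration.empirical_fdp` measures the realized
false-discovery proportion of the BH rule on generator output: 2,000 genes,
10% non-null at |log2FC| = 2, sd 0.25, n = 3, calls at BH-adjusted p ≤ 0.05,
averaged over 100 replicate studies (the problem size keeps the whole run
in seconds). Under independence the step-up procedure satisfies
E[FDP] = π₀·α = 0.045 here; the acceptance test verifies control at the
nominal 0.05 with a one-sided 3σ Monte-Carlo allowance for the
100-replicate estimate, and `scripts/acceptance.py` reports the raw mean.

## Known limitations

* With only three replicates the t test has df = 2 and fat tails; single
  outlier arrays strongly influence calls. No moderated/empirical-Bayes
  variance model is provided (out of scope).
* The FC-only arm of the `union` call rule has no error control; the
  `p_only` and `intersection` rules are the statistically safer options.
* The equivalence band for L9 is a pragmatic device, not a TOST-style
  equivalence test; its error rate is not controlled.
* Enrichment assumes genes are exchangeable within the universe; no
  gene-length or expression-level bias correction is attempted.
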