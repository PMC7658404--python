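# Methods

## Model and procedure

The package builds a qualitative classifier for a binary phenotype from
within-sample orderings of gene-pair expression values. For genes i, j and
group c ∈ {1, 2} (group 1 is the positive class), the ordering frequency

    p_ij(c) = P(E_i > E_j | c)

is estimated by the group-wise fraction of samples with E_i strictly
greater than E_j. A pair is phenotype-associated when the 2×2 table of
ordering counts differs between groups by a two-sided Fisher exact test
after Benjamini–Hochberg adjustment across all tested pairs. Retained
pairs are oriented so that FD = p(1) − p(2) > 0, i.e. the pattern
E_up > E_down is the one enriched in the positive class.

The signature is selected by a grid scan: FD cutoffs at every multiple of
0.01 between the smallest and largest candidate FD; per cutoff, the panel
of pairs at or above the cutoff is made gene-disjoint by a greedy sweep in
(FD desc, p asc, lexicographic) order, then the vote threshold k is chosen
by exhaustive search over 1..m to maximize F = 2·sens·spec/(sens+spec) on
the training labels. The best panel/k combination over all cutoffs is the
signature. Classification of a sample is then: count the pairs whose
positive ordering holds, call positive iff the count reaches k.

Assumptions worth stating: group labels are exchangeable within groups
(no covariate adjustment); expression values within one sample are
comparable (same unit before ranking — true of any single-platform
profile); ties E_i = E_j are rare (continuous data) and are resolved
against the tested pattern, deterministically.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| DE FDR | 0.01 | BH threshold gating genes into the pair space |
| pair FDR | 0.01 | BH threshold on Fisher tests across all pairs |
| FD grid spacing | 0.01 | cutoff resolution of the panel scan (dimensionless frequency difference) |
| pair space | `de_by_all` | pairs with ≥1 differential gene; `de_by_de` restricts to both-differential for tractability |
| removal stage | `per_panel` | redundancy removal inside each panel; `global` removes once before the scan |
| `log2` flag (DE test) | off | log2-transform before the t test for linear-scale intensities; never autodetected |

Tie-breaks are deterministic everywhere: equal F-scores prefer the larger
k (stricter rule) and the larger FD cutoff (smaller, higher-FD panel);
pair sorting is (FD desc, p asc, lexicographic). These choices make
training reproducible to the bit; a unique optimum is not guaranteed in
general, only a canonical one.

## The differential-expression stand-in

The DE gate uses Welch's t, or a moderated variant that shrinks per-gene
pooled variances toward their across-gene mean with a fixed prior weight
d0 = 4 (degrees of freedom increase by d0). This is a deliberate
simplification of full empirical-Bayes variance modeling: the gate only
restricts the pair space, and every downstream claim is validated by
planted-truth recovery rather than DE counts. The gate is the one stage
that is *not* invariant to per-sample monotone transforms — hence the
`log2` flag — and the invariance tests therefore fix the gene gate when
comparing screens across distortions.

## Synthetic cohorts

`generate_cohort` emulates a two-group expression study: per-gene baseline
means are Gaussian on a log-like scale (center 8, sd 1.0, resembling log2
microarray intensities), within-gene noise is Gaussian (sd 0.5), and each
planted pair shares a baseline. Per sample, a Bernoulli draw (π+ or π− by
group) picks the pair's intended winner, which gets a +δ offset (loser −δ,
δ = 2·noise_sd) before noise; in the rare samples where noise still
contradicts the draw, the two values are swapped. The draw is therefore
the exact ground truth, the planted ordering frequency is exactly binomial
in π, and the deterministic limits (π = 1 or 0) are exact.

Defaults are the reference study conditions used by the test suite and the
acceptance script: 2000 genes, 30 planted pairs, π+ = 0.95, π− = 0.05,
60+120 training and 40+80 held-out samples, 10 seeds. These sizes keep the
full 10-seed recovery loop comfortably within a desk-scale run while
leaving the pair screen genuinely large (~10^5 tested pairs per cohort).

What the generator emulates: group-dependent orderings, log-scale
baselines, probe replication with unbiased collapse, platform dropout,
monotone batch distortions, bimodal methylation betas with planted
hypermethylation. What it does not: correlated gene modules, mixed tumor
purity, array saturation, missing values, annotation errors, or label
noise. Passing tests therefore demonstrate correctness of the algorithms
under the stated statistical model, not robustness to every artifact of
real cohorts.

A consequence of the planting scheme worth knowing: a planted gene
oscillates ±δ around its baseline in a group-dependent way, so its
ordering against *any* background gene with a nearby baseline is also
genuinely phenotype-associated. The screen correctly reports such
incidental pairs; at high FD cutoffs they can outnumber the planted
pairings inside the chosen panel (the tie-break prefers the smallest
top-FD panel once F saturates at 1). Recovery claims are therefore stated
at the screen level (planted pairs retained) and at the performance level
(held-out sensitivity/specificity), not as identity of the final panel.

## Numerical choices

- Fisher p-values depend only on the two group-wise counts given the group
  sizes, so they are memoized over (a, b); the two-sided p is the
  hypergeometric mass of tables no more probable than the observed one.
- BH adjustment is the standard step-up, computed across the full set of
  tested hypotheses (all pairs, never only retained ones).
- AUC uses the midrank (tie = 1/2) convention — vote counts are small
  integers and ties are the norm — with a stratified bootstrap CI (2000
  resamples, fixed seed) since vote-count AUCs have no clean closed-form CI.
- Beta values use the standard +100-offset estimate M/(U+M+100), which is
  strictly below 1 for finite nonnegative intensities; synthetic
  intensities are back-solved from target betas via M = β(T+100), U = T−M
  with lognormal total intensity T, reproducing the targets exactly.
- The FD cutoff grid is anchored at multiples of the spacing rather than
  at the observed maximum, so cutoffs are comparable across cohorts.
- Degenerate inputs fail loudly: empty groups, missing genes, negative
  intensities and out-of-range probabilities raise; an empty site filter
  result warns instead (it is a legitimate outcome of disjoint manifests).

## Open design points, resolved

- Whether redundancy removal runs once globally or per FD panel is
  genuinely ambiguous in the method family; both are implemented
  (`removal_stage`), defaulting to per-panel, which keeps each scanned
  panel maximal and reproduces the scan narrative.
- The pair space is "at least one differential gene" by default (the
  literal reading), with the both-differential restriction as an option.
- The Fisher test is two-sided with post-hoc orientation by the sign of
  p(1) − p(2): both ordering patterns are covered without doubling the
  test count.
- The scale of loaded expression values is never guessed; REO statistics
  do not care, and the one scale-sensitive stage (the DE t test) takes an
  explicit flag.

## Known limitations

- The DE gate is a simplification (see above); cohort-level DE counts are
  not comparable to full empirical-Bayes pipelines.
- Training the vote rule and selecting the panel on the same cohort biases
  the training F-score upward; held-out evaluation is the honest number,
  and the acceptance script reports both.
- The hierarchical-clustering concordance check maps clusters to classes
  by majority of reference samples and declines to report (flags
  ambiguous) when a cluster has no or tied reference membership.
- With very small panels the vote count takes few distinct values, making
  ROC curves coarse and bootstrap CIs wide.
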