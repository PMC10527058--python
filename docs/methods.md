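# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic cohort does and does
not emulate, and the numerical edge cases.

## PSM scoring

Search-engine discriminant scores are modelled as a two-component Gaussian
mixture, f(x) = π·N(x; μ₁, σ₁²) + (1−π)·N(x; μ₀, σ₀²), with the first
component describing correct matches. The EM fit runs over all supplied
scores (targets and decoys together — decoy scores genuinely belong to the
incorrect component); initialisation takes μ₀, σ₀ from the decoy scores,
μ₁, σ₁ from the top decile of target scores, and π = 0.5. Iteration stops
when the log-likelihood changes by less than 1e-8 or after 500 iterations;
non-convergence is flagged on the result, not raised, because a mixture a
few iterations short of the optimum is still usable. Component standard
deviations are floored at 1e-3 to avoid collapse onto a single point, and
components are relabelled after fitting so that μ₁ > μ₀. The log-likelihood
trace is retained and asserted non-decreasing in the tests.

With unequal component variances the raw posterior
p(x) = π f₁ / (π f₁ + (1−π) f₀) is non-monotone: the wider component
dominates in one extreme tail, so an absurdly good score could receive a
*lower* posterior. The log-odds is quadratic in x; we hold the posterior
flat beyond the vertex of that quadratic (the monotone envelope), so a
better score never scores worse. This matters only in the far tails where
densities are tiny.

Decoy-based error control is deliberately independent of the mixture:
q-values use target-decoy competition, FDR(t) = r·D(t)/max(T(t), 1) with
r the decoy-to-target database ratio (default 1.0 for an equal-size
reversed database), monotonised by a running minimum from the weakest score
upward, tied scores sharing the q of the full tie block. The binned local
FDR uses equal-count score bins (default 20), the raw per-bin decoy/target
ratio, and count-weighted isotonic regression to enforce that the local
error rate cannot rise with score; values are clipped to [0, 1]. Summing
the local FDR over target PSMs approximates the expected number of false
targets, which the tests check against the global decoy count.

PSM acceptance applies the study's printed rules: posterior > 0.95
(`peptide_prob_min`), |mass error| ≤ 10 ppm (`max_mass_error_ppm`), decoys
removed. The mass-error wording in the source protocol is ambiguous
("exceeded 10 ppm" as a pass condition would accept *worse* matches); we
read it as a tolerance, the only physically sensible direction. Precomputed
posteriors in the input table take precedence over the mixture, supporting
engines that already report probabilities.

## Protein inference

Peptides are matched to proteins by exact substring search with isoleucine
and leucine collapsed (isobaric, indistinguishable by MS/MS). No in-silico
digest is performed: the pipeline consumes already-identified peptides, so
containment is the correct criterion. Peptides matching only decoy entries
are discarded; peptides matching nothing are reported as orphans rather
than failing the run.

Protein probability is the noisy-OR over distinct peptides,
P = 1 − ∏(1−pᵢ), using each peptide's best posterior in the sample. This is
the standard transparent combination rule; it assumes peptide-level errors
are independent, which overstates confidence for proteins whose peptides
share a spectrum neighbourhood, but at the 2-peptide / 0.95 double
threshold the practical effect is negligible.

Parsimony grouping applies, in order: (1) merge proteins with identical
accepted-peptide sets into one indistinguishable group; (2) remove proteins
whose peptide set is a strict subset of another's; (3) greedy minimal set
cover on the remainder, ties broken by (more uncovered peptides, more
distinct peptides, more total spectra, lexicographic accession) — a total
order, so results are independent of input ordering; (4) clusters are the
connected components of the protein–peptide sharing graph. Every peptide's
spectra are credited to the single group that covered it, keeping counts
integral and never double-counted; fractional splitting was rejected as
incompatible with a parsimony reading. Greedy set cover is the standard
heuristic for this NP-hard problem; on random instances of ≤ 10 proteins
the tests show it matches the exhaustive optimum in ≈ 99% of cases and by
construction never undershoots it.

Per-sample acceptance requires P ≥ 0.95 and ≥ 2 distinct peptides
(`protein_prob_min`, `min_peptides`).

## Quantification

Spectral counts are used raw by default (`normalization="none"`). The
analysis this package implements applies no between-sample normalisation,
and total-count scaling is actively harmful under one-sided regulation:
cancer samples carry extra spectra from cancer-only and up-regulated
proteins, so scaling to equal totals deflates every cancer count and
biases fold changes toward 1 (clearly visible on the synthetic cohort).
`total_count` scaling — each sample scaled to the grand-mean library
size — remains available for data with genuinely unequal acquisition depth.

The quality screen regresses log₁₀(SD + ε) on log₁₀(mean + ε) across
proteins (ε = 0.5 pseudocount; means/SDs over all 8 samples) and flags
|standardised residual| > 3 (`outlier_sd`). For Poisson-like counts SD ≈
√mean, so the regression is near-linear with slope ≈ ½ and a protein with
inflated technical variance stands far off the trend. A simpler mode
(`outlier_mode="global"`, |z| of log mean > 3) is provided because the
exact published rule is ambiguous; the regression form matches the
described log SD-vs-log mean diagnostic. With fewer than 10 proteins the
screen is skipped with a warning.

Fold changes use group means of normalised counts *without* pseudocount:
FC = m_cancer/m_control when m_control > 0; INFINITE when m_control = 0 <
m_cancer (the presence/absence signal, deliberately excluded from the
finite up-regulated tally); NaN-and-excluded when both are zero. The
up-regulation threshold defaults to 1.7 (the cut applied in the motivating
analysis; 1.5 appears elsewhere in that literature and is one config field
away).

The significance gate fits, per protein, log₁₀(count + ε) on an intercept,
a disease-status indicator (0 control / 1 cancer) and a subtype contrast
(0 control, −1 endometrioid, +1 serous), and reports the two-sided p of
the status coefficient (5 residual df on 8 samples). The factor coding is
our reconstruction — the source analysis names a two-way ANOVA without
stating its factors — and the contrast absorbs between-subtype variance so
the status test is not inflated by subtype heterogeneity. `welch_log`
(Welch's t on log counts) is the simpler alternative. Residual variance of
an exactly degenerate row (all counts equal) is floored at ε², yielding
p = 1 and a flag instead of a 0/0. The gate passes at p < 0.01
(`enrichment_alpha`).

## Partition, novelty, enrichment

A protein is "present" in an arm when accepted in at least
`presence_min_samples` samples of it (default 1 — the most faithful reading
of pooling per-arm identifications; set 2 for stringency). Rows sharing a
gene symbol are OR-combined before the calls, so the three Venn sets are
disjoint by construction and their sizes always sum to the number of
symbols present anywhere — the bookkeeping identity asserted on every run.
Within the cancer-only set, accession-level duplicates of one symbol are
collapsed to the accession with the most total spectra (ties:
lexicographic), with dropped accessions logged. Subtype attribution calls a
cancer-associated symbol `type1_only`/`type2_only` when present in exactly
one subtype's samples, else `both`. Novelty categorisation eliminates
sequentially — known in this cancer, then known in other cancers, then
merely having literature — leaving `novel_no_literature` as the residual;
precedence mirrors that elimination order.

Over-representation uses the exact one-sided hypergeometric tail
(scipy's survival function; verified against exact integer enumeration to
1e-12 for N ≤ 60) with Benjamini–Hochberg adjustment across terms. The
universe defaults to all symbols present in either arm; annotation
membership is intersected with the universe before counting. No external
annotation service is called — gene sets arrive as GMT files, keeping runs
offline and versionable.

## Cohort statistics

Group means and sample SDs (n−1), and a two-tailed two-sample t-test.
Welch's unequal-variance form with Welch–Satterthwaite df is the default:
on the published patient table it reproduces the printed p-values (0.188
for age, 0.041 for BMI) exactly, which the pooled Student form does not;
the pooled form is available by flag. The p-value is computed through the
regularised incomplete beta function I_{df/(df+t²)}(df/2, ½), checked in
the tests against numerical quadrature of the t density to 1e-9.

## Synthetic cohort

The generator emulates the 4-control vs 2+2-cancer design with planted
protein classes. Defaults: 30 common-equal, 20 common up-regulated at fold
3, 20 cancer-only, 15 control-only, 8 + 8 subtype-only proteins and 3
two-member paralog families (chosen once as a realistic small-study
proteome that exercises every code path; the paralog pairs share
max(1, ⌈0.05·n_pep⌉) peptides to engage the parsimony rules). Per-protein
abundance a ~ logNormal(0, 0.5); counts per (protein, sample) ~
Poisson(30·a·fold) with fold encoding the class, allocated multinomially
over the protein's 2 + Poisson(3) tryptic-like peptides (random sequences
ending in K/R, unique outside paralog families). Correct PSMs score
N(4, 1) with N(0, 3 ppm) mass error; incorrect PSMs are added at 0.15 per
correct PSM, alternating target/decoy (1:1), scoring N(0, 1) with
Uniform(−20, 20 ppm) error. The decoy database is the reversed targets.
Everything derives from one integer seed and regenerates byte-identically.

What it does **not** emulate: peptide detectability and length/charge
biases, intensity-dependent scoring, overdispersed biological replicates
(Poisson, not negative-binomial — two samples per subtype cannot identify a
dispersion parameter anyway), retention time, modifications, and shared
peptides beyond simple paralog pairs. Passing the planted-truth tests
therefore demonstrates the *logic* of the pipeline — error calibration,
inference, partitioning — under idealised counts, not performance on real
chromatographic data.

Problem sizes used throughout validation (≈ 29k PSMs per cohort, 200
proteins for the fold-change study, 200 random set-cover instances, n =
10,000 scores for the EM check) were chosen so each check has comfortable
statistical resolution while the whole suite runs in about a minute.

## Known limitations

* The noisy-OR protein probability and the two-Gaussian score model are
  transparent simplifications of the vendor tools they replace; scores with
  heavy-tailed nulls would need a different incorrect-component family.
* Presence/absence calls ignore abundance entirely; a protein just under
  the detection limit in controls appears "cancer-only". The
  `presence_min_samples` knob mitigates but cannot remove this.
* The two-factor gate assumes log counts are roughly homoscedastic across
  arms; with 8 samples, diagnostics are limited by design.
* Knowledge lists are consumed as given; curation quality bounds the
  meaning of "novel".
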