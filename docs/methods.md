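# Methods

This note documents the models, parameter choices and numerical decisions
behind `tadscreen`, and what the simulation-based tests do and do not
establish about real screen data.

## The screen model

A pooled growth-selection screen couples insert functionality to cell
growth. The simulator models clone abundance as exponential,
`a_i(t) = a_i(0) · exp(r_i · t)` over sampling days `t ∈ {0, 2, 4, 6, 8}`,
and sequencing as a multinomial draw of `depth` reads per
(time, replicate) sample from the abundance proportions. Defaults: three
replicates (random library) or six barcode replicates (design library),
depth 10⁴ reads per sample, uniform initial abundances (log-normal skew
optional), substitution-only sequencing errors at a configurable per-base
rate with constant Phred quality. These rates and depths are the package's
own choices of realistic study conditions; the depth is deliberately low
enough (~2 reads/member/sample at 5,000 members) that counting noise is a
real obstacle, as it is in practice.

Ground truth is planted by an explicit compositional rule: a peptide is
functional iff it contains ≥ 2 acidic residues (D/E), ≥ 1 aromatic residue
(F/W/Y) and 0 positively charged residues (K/R/H) — the acidic-activation-
domain signature. On uniform random 60-nt inserts this rule labels ~1.3%
of members functional, matching the ~1% functional rate the screen design
anticipates, without any tuning. Functional clones grow at
`g_functional = +0.05/day`, everything else (including stop-codon
controls) at `g_nonfunctional = −0.15/day`; the two-class rate structure
is the simplest one that produces the observable the analysis relies on —
a separable growth-estimate distribution with stop controls at the bottom.

What the simulator does **not** emulate: PCR amplification bias, chimeras,
indel sequencing errors in bulk data (indels are exercised through
constructed fixtures in read processing), realistic quality profiles, and
biological label noise (peptides near the functionality boundary). Passing
the recovery tests therefore shows the analysis chain is correct and
well-calibrated under its own model assumptions, not that those
assumptions exhaust real data.

## Read processing

The stage mirrors amplicon pipelines but implements only the contracts
that matter downstream:

- **Pair merging**: candidate overlaps from exact 15-mer seeds; the
  overlap is aligned (edlib prefix mode) and the merge is rejected if it
  needs more than 2 indels or does not reconstruct exactly 60 bases;
  disagreements resolve toward the higher-quality base.
- **Quality filter**: expected errors EE = Σ 10^(−Q/10) ≤ 1.
- **Demultiplexing**: prefix-anchored Levenshtein distance of each 8-nt
  barcode against the read start; assign the unique minimizer at distance
  ≤ 2, ties → unassigned.
- **Adaptor trimming**: 21-nt adaptors located anywhere with ≤ 2 edits
  (10% error rate); unlocatable adaptor drops the read.
- **Dereplication** at exact identity, discarding counts < 2, then
  **greedy clustering** by decreasing abundance (ties lexicographic):
  a sequence joins the first centroid with identity ≥ 0.90, else founds
  one. Mapping against designed references uses identity ≥ 0.80.

Identity is defined as matching columns over all columns of a global
end-to-end alignment (match +1, mismatch −1, gap −2, terminal gaps
penalized); the same definition serves clustering and mapping. Because
co-optimal alignments can differ in column counts, the test oracle
enumerates every optimal alignment and accepts any of their identities.

## Growth estimates and the stop-codon null

Counts are prefiltered (≥ 3 reads per sequence over all samples),
normalized per sample by total sum, and rescaled per replicate to the
day-0 value, imputing a single read where day 0 is zero but later samples
are not. Later-time zeros are kept as genuine dropout signal (y = 0).

Each sequence's pooled replicate points are fitted with a Huber
M-estimator (tuning constant 1.345, IRLS, MAD scale, ≤ 50 iterations,
convergence at |Δβ| < 1e−8) regressing (y − 1) on t with no intercept —
the intercept is pinned at 1 by the normalization. Fits are kept with
≥ 2 replicates, ≥ 10 raw reads, and convergence. Estimates are rounded to
two decimals (half away from zero) before thresholding; finer digits are
regression noise at these depths.

Inserts beginning with a stop codon encode truncated, necessarily
non-functional proteins and form the empirical null. Two threshold modes:
`design_max_stop` takes the maximum estimate of the designed stop
variants; `target_fpr` takes the smallest observed estimate whose stop
exceedance is ≤ the target. Classification is strictly greater-than, so a
stop variant that defines the threshold stays non-functional. Note that
with a few hundred stop controls the target-FPR threshold is a tail order
statistic: the held-out false-positive rate fluctuates with both the
calibration sample and the evaluation sample, so single-study FPR can
exceed the naive binomial band around the target even when the procedure
is calibrated on average. The seeded study in the test suite documents one
canonical draw.

## The feature catalog

Features follow encode → view → aggregate: an encoding (per-residue scale,
group membership, or regex pattern) maps the peptide to numbers, a view
selects subsequences (full sequence or sliding windows), and an aggregator
(count/sum/mean/max/presence) collapses them. The default catalog has
exactly 146 features in eight sets:

| set | n | content |
|---|---|---|
| aa_composition | 20 | residue frequencies, fixed IVLAFWYGSPKRHDETQNCM order |
| group_composition | 11 | aliphatic, aromatic, branching, charged, negative, phosphorylatable, polar, hydrophobic, positive, sulfur, tiny |
| minimotif | 108 | 18 group pairs × 3 gap bands × 2 aggregators |
| ninetad | 1 | any of four nine-residue TAD regexes |
| disorder | 1 | normalized mean disorder propensity |
| helicity | 2 | helix-propensity mean; hydrophobic moment |
| general | 2 | length; molecular weight |
| pi | 1 | isoelectric point |

Mini-motif pairs combine fine groups (negative DE, positive KRH, aromatic
FWY) and coarse groups (polar RKDEQNY; non-polar = its complement):
ordered fine×fine (9), unordered fine–coarse (6), unordered coarse pairs
including self (3). Gap bands are 0–2, 3–6 and 7–10 intervening residues;
counting scans overlapping start positions. This enumeration is the
package's own catalog design — the composition of the original 146 was
published only in supplementary material, so the catalog here reproduces
the stated structure (eight sets, 146 features, pairwise group motifs with
0–10 spacing) with a documented, reproducible enumeration.

Numerical choices: pI by bisection of the Henderson–Hasselbalch net-charge
curve with the EMBOSS pKa set (interval 1e−8; residual |charge| ≪ 1e−4);
disorder and helicity are normalized means of bundled propensity scales
(TOP-IDP-style and helix free energies) standing in for dedicated
disorder/helicity programs — they preserve rank structure, not the
original tools' absolute values; the hydrophobic moment uses the
Fauchère–Pliska scale at 100°/residue. The four nine-residue TAD regexes
are a synthetic reconstruction of the published motif variants (bulky
hydrophobic pair in a polar/acidic, K/R-poor nine-residue window); the
data file says so.

## Machine learning

Preprocessing — near-zero variance removal (95/5 frequency ratio),
correlation-cluster pruning (|r| ≥ 0.75; keep the member least correlated
to its cluster, always retaining the legacy TAD features: length, pI,
hydrophobicity, disorder, helicity, nine-residue motif), iterative QR
removal of exact linear combinations, centering/scaling — is fit on
training rows only, per cross-validation fold, and frozen for validation
rows. This is stricter than pruning once on the full dataset and is
audited by a test that perturbs validation rows and asserts unchanged
parameters.

Cross-validation: 5-fold × 10 repeats (50 splits), stratified by label —
at ~1–2% prevalence unstratified folds can lack positives entirely, which
would leave PR-AUC undefined; stratification is the package's choice. The
design library instead uses grouped 5-fold × 10 over the 13 TAD sets so
near-identical variants never span a split (13 groups → validation folds
of 3/3/3/2/2 groups). Training folds are subsampled to the minority class
(per library of origin for combined data); validation and test sets are
never subsampled.

Models: lasso and ridge logistic regressions over 50 evenly spaced λ on
[1e−5, 0.1] (linear spacing by default, log optional; sklearn's C maps as
1/(λ·n)), and gradient-boosted trees over the 32-point grid
(η ∈ {0.1, 0.3}, depth ∈ {2, 4}, subsample ∈ {0.5, 0.75},
rounds ∈ {30, 100}, min child weight ∈ {0.5, 1}, column fraction 0.8,
γ = 0). Selection uses the one-standard-error rule with complexity ordered
by penalty (larger first; L1 before L2) for penalized models and by
rounds, then depth, for boosted trees. The stacked model fits a logistic
meta-learner on the base models' out-of-fold probabilities over 50
bootstrap resamples (minority subsampling on the bootstrap-training side)
and averages the weights. PR-AUC uses the step-wise (achievable-precision)
estimator, not trapezoidal interpolation, which would be optimistic; the
baseline reported is the positive-class prevalence.

Importances are per-method percentages of the total |standardized
coefficient| (penalized; direction = sign) or gain (boosted; direction =
sign of the class-conditional mean difference, since trees carry none);
the stacked importance combines base importances by |stack weight|.

## Tolerance analytics

Per-TAD tolerance is functional/labeled variants; variants not detected in
the library ("missing") are excluded from numerator and denominator. The
pooled substitution matrix pools raw variants across TADs
(cell = functional fraction per wt→sub pair), leaves unobserved pairs
empty rather than zero, and orders rows/columns by the mean of observed
cells. Variant notation `<wt><pos><sub>` supports a configurable offset
for protein- vs domain-local coordinates.

## Problem sizes

The seeded simulation study uses 5,000 members, depth 10⁴, three
replicates, full λ and boosted grids and 50 CV splits (~1 minute on one
CPU); the depth sweep uses 200 members at 10³/10⁴/10⁵; unit tests use
libraries of 40–500 members. These sizes are chosen so the whole suite
runs in a few minutes while the study retains the imbalance and counting
noise that make the problem non-trivial.

## Known limitations

- Screen-derived labels are themselves thresholded estimates; the ML
  stage learns and is evaluated against them, so its measured PR-AUC
  reflects label noise as well as model quality.
- Disorder/helicity proxies are composition scales; peptides whose
  disorder depends on context (e.g. charge patterning) are out of their
  reach.
- The greedy clusterer assigns to the *first* acceptable centroid, not
  the best; at 60-nt scale with 90% identity this is inconsequential, but
  denser libraries could split clusters differently than a best-hit rule.
- The simulator's two-rate growth model has no per-clone rate variance;
  real screens show graded activity.
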