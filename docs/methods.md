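# Methods

This note records the models, conventions and numerical choices behind
`acidostab`, and what the synthetic benchmarks do and do not demonstrate.

## Sequences and alphabet

Sequences use the 20 standard one-letter codes plus a tolerated ambiguity
set {X, B, Z, U, J, O}.  Ambiguous residues count toward sequence length
but are excluded from every composition numerator, so compositions of
flagged records stay comparable with clean ones without discarding
records.  The strict FASTA policy rejects ambiguity codes outright; the
tolerant policy flags them.

Pairwise alignment is global Needleman–Wunsch via Biopython's
`PairwiseAligner` with BLOSUM62 and affine gaps (open 11, extend 1), the
default protein scoring of BLAST; U/J/O are mapped to X for scoring only.
Identity is reported over aligned (non-gap-pair) columns rather than over
the shorter sequence — the choice is configurable because conventions
differ.  When BLAST tabular files are ingested instead, the reported
percent-positives column (when present) is used as "similarity"; otherwise
internal alignment identity stands in, which is systematically lower than
percent-positives — results note which was used.

## Feature catalogue

889 entries in a fixed, documented order; 871 are computable from the bare
sequence and 18 (secondary structure, burial, disorder, surface
accessibility) must come from external predictors and are only ever read
from sidecar tables.  Conventions:

* `c_` features are absolute counts, `x_` features are normalised by chain
  length; dipeptide compositions divide by L−1 (a length-1 sequence has
  all dipeptide features 0).
* Category memberships: small {T, D}, tiny {G, A, S, P} and aromatic
  {F, H, Y, W} follow the published catalogue.  The catalogue names but
  does not list the remaining sets, so the package fixes them as module
  data (`tables.CATEGORY_SETS`): aliphatic {A, I, L, V}, hydrophobic
  {A, C, F, I, L, M, V, W}, polar {D, E, H, K, N, Q, R, S, T, Y},
  hydrogen-bond-capable side chains {D, E, H, K, N, Q, R, S, T, W, Y}.
* Net charge = count(K, R) − count(D, E); His is excluded, matching the
  common pH-7 convention.  Sulfur atoms = count(C) + count(M).
* pI comes from Biopython's Bjellqvist-pKa bisection; the instability
  index uses the DIWV dipeptide table (class "unstable" above 40); GRAVY
  is mean Kyte–Doolittle hydropathy; the aliphatic index is
  X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu) in mole percent.  These indices
  are computed on the ambiguity-free sequence.
* The mean-max-ASA feature averages a per-residue theoretical maximum
  solvent-accessible surface area table (Gly-X-Gly scale, bundled in
  `tables.MAX_ASA` and editable, since published value sets differ).
  The per-residue pI table used for the mean-residue-pI feature (`pI_avg`)
  is the standard free-amino-acid set.

## Ortholog pipeline

Stage order: RBH + filters → transmembrane removal → redundancy
clustering → length window.  Details:

* Best hit = smallest e-value, ties by higher percent identity, then
  lexically smallest subject id; both directions must agree and both
  e-values must be strictly below 1e-10.
* The length filter reads "difference of two sequences" as the absolute
  difference of raw lengths, strictly less than 5% of the shorter; the
  similarity filter is strictly greater than 30.
* Redundancy clustering emulates blastclust rather than invoking it (the
  program is unmaintained): single-linkage over all member sequences,
  linking at identity ≥ 0.25 with alignment coverage ≥ 0.5 of *both*
  sequences; one pair survives per connected cluster — the one with the
  smallest RBH e-value, ties by lexically smallest AP id (the retained
  representative is otherwise arbitrary and had to be fixed somehow).
* The length window keeps 50 < L < 600 strictly.

All stages are order-independent under these tie-breaks, and the pipeline
report records counts after each stage.

## Substitution matrix and bias tests

`counts[r][c]` is the number of aligned, non-gap, standard-residue columns
with AP residue `r` and NP residue `c`; cell (r, c) is the forward (NP→AP)
substitution c→r.  Gap and ambiguity columns are skipped.  The directional
ratio is `counts[r][c] / counts[c][r]`; the diagonal is reported as 1 by
convention and excluded from testing.  Display rounding is exact decimal
half-up at 2 places (binary-float rounding misclassifies exact midpoints
such as 217/200).

Significance uses the two-sided Fisher exact test.  The appropriate 2×2
conditioning is genuinely debatable, so four constructions are options,
with `occurrence` the default:

* `occurrence` — `[[n_fwd, N_r − n_fwd], [n_rev, N_c − n_rev]]`, where
  `N_k` is the total number of counted columns containing residue k in
  either role.  Asks whether c→r conversions are more frequent, relative
  to each residue's opportunity, than r→c conversions.
* `ap-occurrence` — margins restricted to AP-role occurrences.
* `global` — both counts against the total number of mismatch columns.
  With tens of thousands of mismatch columns this test is extremely
  conservative: on the bundled reference counts it calls nothing at
  p < 1e-10.
* `independence` — the classical per-cell enrichment test against the rest
  of the matrix (the only per-cell-asymmetric option; note its p-values
  are not symmetric between a cell and its mirror).

A cell with p < alpha (default 1e-10) is called favored in the direction
of its larger count; equal counts are never called.  On the bundled
reference counts the default construction yields 94 significant cells
(47 forward, 47 reverse), against 81 marked cells (43/38) in the published
rendering; the published markings are internally asymmetric for 7 residue
pairs, which no row/column-swap-invariant test can reproduce, and the
default construction agrees with 77 of the 81 marked cells.  Three of the
four discrepant cells sit within half an order of magnitude of the 1e-10
cutoff, consistent with the original margins being full-sequence residue
totals that cannot be reconstructed from the printed counts alone.

Composition comparison: for each residue, AP and NP means/SDs of `x_res`
across pairs, a two-sided unpaired t-test (Welch by default; Student's by
argument) and a two-sided paired t-test.  Degenerate paired differences
(zero variance) report p = 1 when all differences are zero, else p = 0,
and carry a flag.

## Scoring function

The relative difference is sign-symmetric and bounded:
`Δx = (x₁ − x₂)/(x₁ + x₂)`, defined as 0 when both values are 0; plain and
reference-normalised differences are selectable modes, and every reported
result names its mode.  The pair score is `S = Σ wᵢ Δxᵢ` over the ten
features x_K, x_small, x_T, x_tiny, x_aliphatic, x_aromatic, x_I, x_LQ,
x_Q, x_Y with weights in [−1, 1]; S > 0 predicts the first sequence is the
AP member, and a score of exactly 0 counts as incorrect (conservative tie
rule).

Hill-climb training: random initial weights in [−1, 1]; each step perturbs
one uniformly chosen weight by a uniform step in [−0.1, 0.1] (clamped) and
keeps the move only if the number of positively scored pairs strictly
increases.  The default budget is 100,000 iterations × 5 restarts (the
original protocol ran 10⁸ iterations; 10⁵ converges on data sets of a few
hundred pairs).  The returned weights average the restarts that attain the
best objective: because strict-increase acceptance creates flat plateaus,
a restart whose decisive weight starts far on the wrong side can stall,
and averaging a stalled restart into the consensus can flip the sign of a
weight that every converged restart agrees on.  When all restarts
converge — the typical case — this equals the plain average.

Evaluation: each oriented pair contributes one positive case and its
reversal one negative case, so by score antisymmetry TN = TP and FP = FN;
accuracy = (TP+TN)/(TP+TN+FP+FN).  The non-ortholog challenge scores every
(AP_i, NP_j) combination.  AUC uses the rank-sum formulation with ties
counted 0.5; ROC negatives are the reversed pairs.

## Random-Forest protocol

Classification is per sequence (AP vs NP), with scikit-learn forests
(default 5,000 trees; tests and the acceptance script use a few hundred,
which is ample for the synthetic checks).  Cross-validation folds are
assigned by ortholog pair, never splitting mates across train/test.  Gini
importances are averaged across folds and features ranked by the mean.
Feature selection uses a simple backward elimination — drop the
lowest-importance 20% per round, keep the subset with the best out-of-fold
AUC — which is *not* equivalent to varSelRF's algorithm.

## Synthetic generator

The NP sequence is drawn i.i.d. from a background composition (default:
the bundled NP composition means, normalised); the AP mate mutates each
site independently with probability `substitution_rate` (default 0.3,
≈70% pair identity, inside the real 30–90% identity band), drawing the
target from the background re-weighted by per-(from, to) bias multipliers.
Optional single-residue indels with geometric extension are applied after
substitutions and default off.  Defaults mirror the real study's scale:
393 pairs, lengths 51–599.

`study_bias_map()` scales the mutation flux *into* residues (T ×1.7,
A ×1.25, P ×1.2, Q ×0.45, N ×0.55, Y ×0.05, I ×0.6).  Per-direction
multipliers alone barely shift compositions because background flux
rebalances them; into-residue scaling reproduces AP−NP composition deltas
of the magnitude observed in real data (≈ +0.01 for Thr, ≈ −0.008 for
Tyr).  Under these conditions the shipped weights separate synthetic
ortholog pairs at high accuracy, which validates the scoring machinery —
not the biology: the generator has no rate heterogeneity, no domain or
family structure, no phylogeny, and a single shared background, so passing
synthetic benchmarks shows the statistics recover injected signal, not
that real proteomes behave like the simulator.

`generate_separable_deltas` plants a weight vector and draws delta rows
with a guaranteed positive margin along it (plus orthogonal noise, rows
rescaled into the unit box, which preserves separation); it exercises the
optimizer under known-answer conditions.  The hill-climb benchmark uses
margin 1.0: at smaller margins relative to the orthogonal noise the
strict-increase climber stalls in local optima well below perfect
accuracy, which is a property of the prescribed acceptance rule, not a
bug.

## Known limitations

* The 18 external predictor features are ingested, never computed; runs
  without sidecar files carry NaNs there, and the native 871-feature
  subset is the default modelling surface.
* BLAST, TMHMM and blastclust are not invoked; their outputs are inputs.
* The Fisher construction used by the original analysis is not uniquely
  recoverable from the published rendering (see above); all four
  implemented constructions are available and the default is the closest
  self-consistent one.
* Full-scale reproduction of the real 393-pair results requires the
  original proteomes and BLAST runs; the bundled artifacts cover the
  published count matrix, composition reference and weights.
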