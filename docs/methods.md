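# Methods

This note records the model, its assumptions, the defaults and the design
choices made where the design was genuinely open. It states nothing the
tests or `scripts/acceptance.py` do not themselves compute.

## Windows and alphabet

A candidate site is a cysteine; its context is the closed 1-based interval
`[site − ξ, site + ξ]` of the parent protein, giving a `(2ξ+1)`-mer with the
cysteine at the center. The default half-width is **ξ = 10** (21-mers), the
standard scale for thiol-modification context; ξ is a parameter everywhere
so the framework generalizes. Positions past a terminus hold the dummy
symbol `X`.

The alphabet is closed at 21 symbols: the native amino acids coded 1…20 in
alphabetical one-letter order, `X` = 21. Every non-native input character
(ambiguity codes B/Z/J, selenocysteine U, pyrrolysine O, `*`, gaps, digits)
is mapped to `X` during sanitization, with the replacement count logged.
Notably **U maps to X, not to C**: the center symbol of a window is strictly
the standard cysteine, and selenocysteine chemistry is out of scope.
Collapsing ambiguity codes loses a little information (B could be split
between D and N) but keeps the propensity matrix shape fixed.

## PSAAP features

For each class the occurrence frequency of residue code *i* at flank offset
*j* is

    p(i, j) = (count(i, j) + α) / (n + 21 α)

with pseudocount α (α = 0 means raw frequencies; columns then sum to 1
exactly). The propensity matrix contrasts the classes. Two functionals are
provided:

* **difference** (default): `Z = p⁺ − p⁻`. Bounded in [−1, 1], antisymmetric
  under class swap, identically zero when the classes share a composition,
  and its expectation at a planted enrichment *e* is exactly *e* — which is
  what the recovery tests exploit. Default α = 0.
* **log-odds**: `Z = ln(p⁺_α / p⁻_α)` with α > 0 required (default α = 1,
  add-one over the 21 symbols) so every ratio is finite. Offered because
  log-odds is the natural scale for a linear classifier; the difference form
  is the canonical one here because it needs no smoothing choice.

The `X` row participates in the matrix and in encoding: proximity to a
terminus is itself context, and the benchmark windows encode it via `X`
runs. Columns are ordered −ξ…−1, +1…+ξ; the serialization format pins this
order in its header.

A window's feature vector has Ω = 2ξ components, `Ψᵤ = Z(residue at
non-center position u, offset u)`; the constant center is omitted.

## Scorer and threshold

The canonical scorer is an **L2-regularized logistic model** on the 2ξ
propensity components. This keeps the "discriminative probabilistic model"
semantics of a conditional random field — it is the single-clique degenerate
case — while being fully specified, convex and deterministic. Defaults:
regularization strength λ = 1 (the sklearn `C` is 1/λ), convergence
tolerance 1e−8, max 1000 iterations, seed 42 (the fit itself is
deterministic given the data; the seed is recorded for provenance).

An alternative `chain_crf` scorer assigns each flank position a state from
{flank-of-positive, flank-of-negative} with tied per-position potentials and
scores a window by the posterior of the all-positive chain. With tied
potentials and only the two pure chains admissible, that posterior is
analytically a logistic response on the **summed** propensity — one weight
plus intercept — and it is implemented exactly as that collapse. It is an
interpretation (no published potentials or label scheme exists to match) and
is not the canonical scorer.

The decision threshold **δ** maximizes overall accuracy on the training
scores. Candidates are 0, 1 and the midpoints of adjacent distinct sorted
scores: predictions are constant on the intervals between distinct scores,
so this finite set contains an exact maximizer; a 10⁻³ grid scan can
therefore never beat it (property-tested). Ties among maximizers return the
smallest candidate, and a score exactly equal to δ is called **SNO** — both
are arbitrary closed choices, fixed and documented so results are
reproducible.

Threshold tuning happens **inside** each training set. Tuning δ once on the
full benchmark and reusing it across cross-validation folds would leak
held-out labels; that global variant is available as
`global_threshold=True` (CLI `--global-threshold`) for comparison
only.

## Metrics

Sn, Sp, Acc, MCC are computed in the per-class **miscount**
parameterization (`Sn = 1 − miss⁺/N⁺`, etc., with MCC written directly in
the miscounts) and cross-checked against the TP/FN/TN/FP parameterization;
the two are algebraically identical and `dual_check` asserts agreement to
1e−12. When a whole class is predicted one way an MCC denominator factor is
zero; the coefficient is then defined as **0**, matching its
"no better than random" reading (the all-positive predictor on balanced data
gives Sn = 1, Sp = 0, Acc = 0.5, MCC = 0). Computed MCC is clamped to
[−1, 1] to absorb last-ulp float overshoot at the exact limits. Text reports
print percentages to two decimals and MCC to four.

## Evaluation protocol

Cross-validation is **stratified** k-fold (default k = 10) repeated R times
(default R = 50), repeat *r* shuffling with derived seed `seed + r`.
Stratification is used because realistic benchmarks are mildly imbalanced
and it stabilizes per-fold class counts. Within every fold the entire
pipeline — frequency matrices, propensity matrix, scorer, δ — is refit on
the k−1 training folds only; the fold records expose the training class
counts so the no-leakage property is checkable. Per repeat, held-out
predictions are **pooled** across folds before computing metrics (pooled
MCC is always well defined; averaging per-fold metrics is available via
`pool_folds=False`); the aggregate is the mean over repeats, with the
population standard deviation as dispersion.

The **jackknife** (leave-one-out) refits the pipeline once per held-out
window and pools all held-out predictions; with the deterministic scorer it
yields a unique result for a fixed dataset, independent of any seed.

A protein is called **nitrosylated** iff at least one of its cysteines is
called SNO; cysteine-free proteins are valid inputs, reported
non-nitrosylated with a "no cysteine" flag. Query sequences shorter than 50
residues are flagged as likely fragments (warning, not error): flank
composition near artificial termini is unrepresentative.

## Synthetic data

The generator emulates the statistical structure the propensity matrix is
designed to detect, not any real SNO motif content.

* Negative windows draw each flank position i.i.d. from a background
  composition (uniform over the 20 natives by default; an approximate
  Swiss-Prot composition vector is included as an alternative).
* Positive windows use per-offset distributions shifted by planted
  enrichments `(offset, residue, e)`: mass *e* is moved onto the residue at
  that offset and the remainder rescaled, so the expected difference-form
  propensity at the planted cell is exactly *e*.
* Terminal truncation: with probability `terminal_pad_prob` (default 0.1) a
  uniformly drawn number of residues at one window end is overwritten with
  `X`, reproducing the X-runs real benchmarks acquire near termini.
* Default dimensions mirror the published benchmark scale: 731 positive and
  810 negative windows over 438 protein accessions, and 461 independent
  proteins for protein-level evaluation. Window provenance (accession, site)
  is nominal bookkeeping that satisfies the table invariants; it is not
  arithmetically consistent with the X-runs of truncated windows.

Two presets are fixed a priori. The **moderate** default motif — four
acid/base residues at ±1, ±2 with effect 0.15 and two weaker effects of 0.10
at ±5 — represents effect sizes typical of PTM motifs. The **strong** preset
(five offsets, effect 0.6 each) was sized by a binomial separation estimate
to give clearly separable classes (expected CV accuracy ≈ 0.96) and is used
where tests need near-perfect discrimination.

What passing synthetic tests shows: the pipeline recovers planted positional
compositional signal at the correct magnitude, discriminates when signal is
present, stays at chance when it is not, and is leak-free and deterministic.
What it does not show: performance on real SNO data, whose signal includes
residue correlations between positions, homology structure and
database-specific labeling biases that the i.i.d.-per-column generator
deliberately omits.

## Numerical and statistical choices

* Frequency columns at α = 0 sum to 1 within 1e−12 (asserted); counting is
  exact integer arithmetic before normalization.
* Planted-effect recovery is asserted within 3 binomial standard errors
  (±0.04 at n = 2000 per class for e = 0.5). The *null* agreement check
  compares all 21 × 20 per-cell frequency differences at once and therefore
  uses a multiplicity-corrected 4.5σ per-cell bound; a 3σ per-cell bound
  across 420 cells would be expected to fail by chance about once per draw.
* The label-shuffled null asserts the mean pooled MCC over 10 shuffles lies
  within ±0.15 of zero (per-shuffle MCC at n = 400 has standard error
  ≈ 0.05).
* Serialization (PSAAP TSV, model archive, CV report) renders floats with
  `repr`, i.e. shortest round-trip precision, so save→load is bitwise and
  determinism can be asserted as byte equality of archives.
* Problem sizes in the test suite and acceptance script (e.g. 200/class for
  end-to-end CV checks, 2000/class for recovery, 50 CV repeats at benchmark
  scale) were chosen as the smallest sizes at which the statistical bounds
  above are comfortably interpretable.

## Known limitations

* The difference functional treats all offsets independently; correlated
  positions (e.g. paired charged residues) are only captured through the
  linear combination the scorer learns.
* The chain-CRF variant is intentionally minimal (see above); a richer CRF
  with untied potentials would interpolate toward the logistic model and was
  not pursued.
* Benchmarks must be provided in the package's TSV schema; converting
  supplementary tables published as PDF into that schema is a one-time,
  out-of-band step.
* Negative labels in real benchmarks are "not yet observed modified", not
  verified negatives; the package treats labels as given.
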