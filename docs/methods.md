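# Methods

## The allocation model

`minimsim` simulates covariate-adaptive allocation by minimisation with a
random element.  The state of a trial is the marginal table
`n[f, c, a]` — the number of previously allocated patients with category `c`
of prognostic factor `f` in arm `a`.  An incoming patient with categories
`c(f)` gives each arm the marginal score `S(a) = Σ_f n[f, c(f), a]`, an
unweighted sum of raw counts (no factor weights, no range or variance
variants).  Allocation then branches on the minimum of `S`:

* minimum shared by `m ≥ 2` arms → draw uniformly among the `m` tied arms
  (classification *tie*; in the two-arm case this is indistinguishable from
  drawing among all arms, and among-tied is the standard convention, which we
  also apply for ≥ 3 arms);
* unique minimiser → assign it with probability `P` (*deterministic*),
  otherwise draw uniformly among the other `n_arms − 1` arms (*twist*).
  For ≥ 3 arms the probability `1 − P` is split evenly over all non-optimal
  arms regardless of their score ranking — the minimal assumption that keeps
  `P` exactly the probability of the optimal arm.

The patient being allocated never contributes to their own scores: the table
is updated only after the decision is classified.  A twist can never land on
an arm tied for the minimum, because the twist branch only fires when the
minimiser is unique.

`P` is restricted to `[0.5, 1.0]`, the range meaningful for this design:
`P = 1` is fully deterministic, and `P = 0.5` with two arms is simple
randomisation.

## Predictability and imbalance

*Predictability* is the fraction of allocations classified deterministic,
assuming an observer who knows the exact algorithm and every previous
patient's factors and assignment.  Ties and twists are unpredictable.  This
is deliberately not a guessing-strategy measure (e.g. "repeat the previous
allocation"); those estimate a different quantity.

*Imbalance* is evaluated once per completed trial, at final `N`:

* overall: `100 · max_{i,j} |n_i − n_j| / N` over arm totals;
* within-factor: `max_{c,i,j} |100·n[f,c,i]/n_i − 100·n[f,c,j]/n_j|`,
  i.e. percentage-point differences of category *proportions*.  Proportions
  (not raw counts) are the only reading under which a 5% threshold is
  comparable between arms of unequal size.  If an arm is still empty the
  statistic is reported as maximal (100) with a warning; this only arises
  for tiny `N`.

Both use max-pairwise comparisons for > 2 arms, the conservative extension
of the two-arm definition.  The cutoff is a step function of `N`:
40% (N ≤ 10), 20% (11–20), 10% (21–49), 5% (N ≥ 50).  Only
N ∈ {10, 20, 30, 40, ≥50} are tabulated in the source material; each gap
takes the next tabulated cutoff at its upper end, and 41–49 extends the
N = 40 value — a documented assumption.  A scenario's *imbalance verdict* is
true when at least 10% of its replicate trials (the `chance_threshold` of
`ImbalanceRule`) are flagged on either statistic.

## The Monte-Carlo engine

Defaults: 1,000 replicates per scenario cell and the P grid
{1.0, 0.9, 0.8, 0.7, 0.6, 0.5}.  Classification percentages are pooled over
all `N × replicates` allocations; imbalance probabilities are fractions of
replicates flagged.  A P-scan derives:

* `imbalance_onset_p`: the largest grid P whose verdict is true (`None` if
  balance holds everywhere);
* `recommended_p`: the smallest grid P whose verdict is false — the most
  randomness the design tolerates.  If the verdict is true at every grid
  value the scan sets `no_balanced_p` instead of recommending anything;
* `predictability_reduction_pct`: deterministic % at the top of the grid
  minus that at the recommended P.

**Seeding.** A master seed spawns one `SeedSequence` child pair per
replicate, keyed by the replicate index: one stream samples the cohort, the
other drives allocation.  Replicates are therefore order-independent, and a
P-scan reuses the identical cohorts and base uniforms at every P (common
random numbers), which sharpens reduction-in-predictability differences.
One uniform variate is consumed in the non-tie branch even at P = 1 to keep
the streams aligned across P.  In `scenario_grid` each row gets its own
child seed keyed by its position, so rows are independent and the grid is
byte-reproducible.

## The synthetic cohort generator

Patients are vectors of independent categorical draws with fixed prevalence
per factor — an idealised accrual with no time trends, no factor
correlations, no centre structure, no staggered entry and no dropout.
Passing tests therefore demonstrate properties of the allocation algorithm
under stationary accrual, not robustness to the messiness of real
recruitment.  "Unequal prevalence" presets are package conventions, since
the original scenarios never state the probabilities used: binary (0.7,
0.3), three-category (0.5, 0.3, 0.2), four-category (0.4, 0.3, 0.2, 0.1).
Configs always take explicit prevalence vectors, so users are never bound to
the presets.

## Verification strategy and problem sizes

* **Exhaustive oracle.**  For small designs, an independent dynamic program
  (`tests/dp_oracle.py`) enumerates every cohort and every random branch and
  propagates exact probabilities over table states.  Monte-Carlo per-step
  classification frequencies (10^5 replicates at N = 6, two arms, one or two
  binary factors) must fall inside exact binomial 99% intervals of the exact
  probabilities — a dual-route check of allocator and seeding together.
* **Steady-state cells.**  Tie/deterministic percentages are checked at
  N = 200 with 1,000 replicates against the published values within ±3
  percentage points.  The published in-text percentages do not always pin
  the N at which they were read; N = 200 sits comfortably in the "larger
  trial" regime and the percentages are flat in N there.
* **Worked example.**  The packaged 20-patient table is transcribed verbatim
  from its source and checksum-guarded.  Its column sums give marginal
  scores (18, 26) for the 21st patient; the source's text prints the group-B
  total as 27, but the summands it lists (8 + 9 + 2 + 7) and the table
  counts both give 26, so the package reports the arithmetic consequence of
  the published counts.  The allocation conclusion (group A, deterministic)
  is unaffected.
* **Properties.**  Hypothesis (derandomised) checks the classification
  partition, record/score consistency, absence of twists at P = 1, replay
  of the final table from the audit log, and the bound
  `|n_A − n_B| ≤ K` for one K-category factor at P = 1.

Numerical notes: prevalence vectors must sum to 1 within 1e-9; degenerate
(0/1) prevalences are accepted for testing point masses; scores and counts
are exact integers, so tie detection involves no floating-point tolerance.
The one-factor "predictability is nearly flat in P" behaviour holds for
P ∈ [0.7, 1.0] (differences < 2 points at N ≥ 200); at P = 0.5 the two-arm
scheme degenerates toward a coin flip and the deterministic share genuinely
drops by several points, so the flatness claim is tested on [0.7, 1.0].

## Known limitations

* No centre effects, stratification, blocking, urn or other biased-coin
  designs; no factor weighting.
* Imbalance is final-N only, not path-wise, so interim imbalance is not
  quantified.
* `recommended_p` is a grid quantity; it cannot resolve between grid points.
* Reference rows transcribe published summary values with tolerance
  annotations (±3 points for simulated percentages, exact for cutoffs); they
  are transcription, not simulation output.
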