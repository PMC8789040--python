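# Methods

## The selection model

A selection round is modelled as two sequential retention events applied
independently to every molecule.

**Step 1 (RNA capture on phage-displaying beads).** Each RNA species i is
retained with probability

    p1_i = c1 · θ_i + b1 · (1 − w)^n_washes ,

where c1 is the specific capture efficiency, b1 the per-molecule
nonspecific background, w the per-wash probability that a background-bound
molecule is lost, and θ_i the equilibrium occupancy of RNA i against the
displayed-protein mixture. The mixture is treated as a single effective
concentration C_P partitioned by protein abundances w_j, giving the
competitive single-site form

    θ_i = S_i / (1 + S_i),   S_i = C_P · Σ_j w_j / K_app(i, j).

For a single protein this reduces to the familiar C/(C + K_D). Washes act
only on the background term: specific complexes persist according to their
occupancy, a deliberate simplification that makes stringency monotone —
more washes or lower backgrounds can only improve a binder's enrichment
factor.

**Step 2 (complex pulldown via the docking sequence).** Symmetrically,
phage j is retained with probability c2 · θ_j + b2 · ρ · (1 − w)^n_washes,
where θ_j is its occupancy against the captured-RNA mixture at an effective
RNA concentration C_R, and ρ < 1 is the background reduction contributed by
the RNase H elution (which releases only genuinely hybridized complexes).

**Apparent affinity.** Phage display multivalency (≈10 protein copies per
virion) is modelled phenomenologically as K_app = K_D / copies^α (default
α = 1, copies = 10), and urea stringency as a multiplicative K_D penalty
(default 5). Both are acknowledged stand-ins for effects (avidity,
partial denaturation) that are not single-site phenomena; they are
monotone in the intended direction and keep the model analytically
checkable. Note that urea necessarily lowers a binder's occupancy too, so
stringency monotonicity is guaranteed only for the wash/background dials;
the urea dial trades background against signal exactly as in the
laboratory.

**Sampling.** Stochastic mode draws each species' survivors binomially,
reduces pools to the configured bottlenecks by multinomial sampling, and
amplifies with per-species lognormal bias (σ default 0.1) followed by
stochastic rounding. Expectation mode replaces every draw by its mean with
real-valued counts; the test suite verifies that expectation mode equals
the stochastic mean (100 seeds, 3-SE tolerance) and that a pure
binder/non-binder mixture reproduces the closed form
f′ = f·p_b / (f·p_b + (1 − f)·p_nb) to machine precision. An empty
post-selection pool is reported as a selection crash carrying the round
index, never as a silent zero.

**Reads.** Sequencing is simulated as a multinomial draw of templates by
abundance with independent per-base substitutions (default 10^−3; no
indels — the variable regions are short and flank-anchored), a prepended
round barcode and a constant quality string. One seed reproduces a
campaign, including its FASTQ bytes, exactly.

## What the synthetic generator emulates — and what it does not

The default planted-pair study emulates the statistical structure the
analysis relies on: a 10^4-species RNA pool containing one cognate RNA at
K_D = 10 pM for one of 100 proteins, a 40-member family of weaker
(10 nM) motif-carrying siblings mirroring the consensus-family structure of
real selected pools, a uniform 1 µM off-target floor, three rounds at
effective protein concentration 0.1 nM (so that the planted pair separates
by roughly an order of magnitude per round on each side), and 10^5 reads
per sequenced pool. These sizes keep a full campaign-plus-analysis run
around twenty seconds while leaving order-of-magnitude margins on every
recovery assertion.

Not emulated: PCR chimeras and mutation during amplification, bead-surface
kinetics and mass transport, RNA secondary-structure effects on capture,
indel sequencing errors, and any correlation between protein sequence and
affinity (the landscape is planted, not biophysical). Passing tests
therefore demonstrate that the analysis recovers structure the model
plants, not that the model predicts laboratory enrichment rates.

## Enrichment analysis conventions

- The enrichment factor divides relative abundances, not raw counts, so
  differing sequencing depth per round cancels.
- A species absent (or unobserved) in the earlier round has an *undefined*
  EF — distinct from EF = 0 (present before, gone after) — and undefined
  EFs fail the monotonic filter. The filter boundary is inclusive
  (EF = 1.0 passes).
- Ranked outputs order by count descending with ties broken by
  lexicographically smaller sequence, so every ranking is deterministic.
- Diversity profiles use a singleton bin plus half-open multi-copy bins
  [2,10), [10,10^2), …, [10^5,∞) by default; the edges are a package
  convention and are configurable.
- Variable-region extraction anchors on the terminal 12 nt of each fixed
  flank with at most one substitution, trying an exact string match first
  and falling back to a Hamming scan; failures carry a reason code.
  Protein reads whose randomized window translates through a stop codon
  are excluded by default (a stop ends display, so such phage carry no
  functional protein); a flag retains them.

## Deconvolution

Re-selection of a focused library against single immobilized proteins is
summarized per motif subset by box statistics (quartiles by linear
interpolation, whiskers at 1.5 × IQR clamped to the data range). Calls use
the subset median: cognate at median ≥ 1.0 (inclusive), depleted below
0.5, neutral between; mutually orthogonal pairs are proposed when two
proteins are cognate for different subsets and depleted for each other's.
Because "significant" enrichment is read off box plots rather than a named
test, the package reports medians with a seeded percentile-bootstrap
interval (10^4 resamples) instead of a p-value.

The reference study's focused library is the most abundant post-selection
RNAs padded to a fixed synthesis size (1991) with pre-selection species,
plus 9 spiked control RNAs given broad weak affinity (5–20 nM) to every
scaffold-derived protein. The controls are what make the calls sharp: under
a protein with no cognate ligand in the library, the controls out-compete
everything else, so a non-cognate motif subset is measurably depleted
rather than carried along at EF ≈ 1. This mirrors the role of natural
kink-turn controls, which retain tens-of-nanomolar to sub-micromolar
affinity even for heavily mutated scaffold variants.

## Langmuir fitting

One (k_on, k_off, R_max) triple is fitted globally across all
concentrations, association and dissociation phases jointly, by bounded
nonlinear least squares — the single-interaction reading of a sensorgram
series; per-curve fits remain available for diagnostics (whether
instrument software fits phases jointly is not knowable from outputs, so
the joint fit is this package's documented choice).

Numerical choices:

- Parameters are fitted as log10 values with box bounds
  k_on ∈ [10^3, 10^10] M⁻¹s⁻¹ and k_off ∈ [10^−6, 1] s⁻¹; termination
  tolerances are 10^−12 (xtol/ftol/gtol), tighter than the 10^−10 target.
- Initialization: k_off from pooled log-linear regression of dissociation
  tails (points above 5% of the curve maximum); then a coarse log10 k_on
  grid (step 0.25) with R_max solved in closed form at each grid point —
  the model is linear in R_max — choosing the least-squares seed. This
  makes the noiseless simulate-then-fit round trip recover rates at
  machine precision across the tested 4 × 4 rate grid.
- Standard errors are delta-method transforms of the log-space errors;
  the reported K_D is always the exact quotient k_off/k_on of the same
  fit.
- No-binding call: the maximum corrected response (lightly smoothed with a
  9-point moving average so the call reflects signal amplitude rather than
  pointwise noise excursions) is compared against
  max(3 × noise SD, 1% of fitted R_max), with the noise SD estimated from
  the pre-injection baseline window (first 10 s) unless supplied.
- Replicate aggregation reports per-parameter sample means and SDs
  (n ≥ 2), with K_D aggregated as the mean of per-replicate ratios — not
  the ratio of mean rates; the two differ whenever rates co-vary across
  replicates, which is why a printed mean K_D need not equal the quotient
  of the printed mean rates.
- Selectivity folds are reported to 3 significant figures; in
  orthogonality matrices, entries are oriented off-target/cognate and
  no-binding entries are floored at a concentration-limit K_D bound
  (default 1 µM).

Degenerate inputs: a flat (zero or pure-noise) sensorgram set still
returns a result object, with the no-binding flag set and the convergence
flag reporting the optimizer's status; non-convergence is always carried
on the result, never raised silently.

## Reproducibility

All randomness flows from numpy Generators. A single master seed fans out
to per-stage seeds through a fixed integer derivation (stage label CRC
mixed with a Knuth multiplier, reduced below 2^31), so any stage can be
rerun in isolation. CLI runs record inputs, parameters, seed and output
checksums in a manifest sufficient to reproduce the run.

## Known limitations

- The per-round laboratory schedule (inputs, wash counts, incubation
  times) is not public; the shipped six-round default encodes only the
  documented structure — negative selection in rounds 1–2, urea in the
  last two rounds, monotonically tightening inputs and washes — and every
  value is overridable.
- Capture uses one effective concentration per pool rather than bead
  capacities and volumes; avidity and urea are phenomenological.
- Exact sequences are counted; near-duplicate reads produced by
  sequencing errors are separate species (the error rate is a simulation
  dial rather than a merging step in the analysis).
- The 1:1 Langmuir model excludes mass-transport limitation, bulk
  refractive-index jumps and surface heterogeneity; sensorgrams that
  violate 1:1 kinetics will fit poorly rather than being re-modelled.
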