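# Methods

This note documents the model, the numerical choices, and the synthetic
benchmarks the package ships with — including the choices that were
genuinely open and why they were resolved the way they were.

## Model and assumptions

The object of inference is a set of non-overlapping genomic regions, of
arbitrary length within `[γ_min, γ_max]`, that are differentially expressed
between two per-nucleotide count tracks.  Regions are represented as a
marked point process: a point anchors a region at a nucleotide and carries
its length as a mark, at most one point per anchor.  Inference minimises a
Gibbs energy rather than normalising a density, so only energy differences
ever matter.

Assumptions worth stating explicitly:

- **Counting model.** Reads land independently per nucleotide; region
  counts are binomial in the library total, Poisson in the limit.  No
  biological replicates and no overdispersion — one track per condition.
  With large library totals the z-score is very powerful, so `z_min` acts
  as an effect-size floor, not only a significance level.
- **Library totals** `n_i` are genome-wide totals supplied by the user;
  they are *not* inferred from the analysed window (the window is typically
  a small fraction of the library).  If absent, the window sum is used with
  a warning.
- **Additive per-region energies.** The total energy is a sum of per-point
  terms.  A consequence (see *Limitations*) is that the model inherently
  prefers many strong disjoint regions over one long region when candidates
  permit, which makes the quality of the candidate set part of the model in
  practice.

## The differential statistic

For region counts `C1, C2` with totals `n1, n2`, zero counts are replaced
by a pseudocount of 0.5 (zero-count regions must remain testable) and

```
M  = log2 C1 − log2 C2          A = (log2 C1 + log2 C2) / 2
p̂  = clamp(2^A / √(n1 n2), 1e-12, 1 − 1e-12)
E[M|A]   = log2(n1 / n2)
Var[M|A] = 4 (1 − p̂) / (p̂ · ln²2 · (n1 + n2))
z  = (M − E[M|A]) / √Var[M|A]
```

This is the delta-method normal approximation for the MA statistics of two
independent binomial counts, with the sampling probability estimated from
the abundance A (its geometric-mean form makes the conditional-mean
correction vanish for equal totals).  The test suite verifies the
conditional mean and variance against direct binomial simulation (three
Monte-Carlo standard errors at 1e5 draws) and against the classical pooled
two-proportion z-test.  Two caveats, both verified by simulation:

- at mean counts near 1 the test is strongly conservative (empirical
  type-I error ≈ 0.003 at nominal 0.05) — discreteness plus the
  pseudocount; calibration within [0.03, 0.08] holds from mean counts of
  ~10 upward;
- with strongly unequal totals (4× and more) and large fold changes the
  pooled two-proportion statistic drifts from this one by tens of percent
  because the two approximations pool the probability differently
  (geometric vs arithmetic mean); the Monte-Carlo moments confirm this
  implementation is the consistent one for the conditional model.

p-values are reported but every decision inside the optimiser acts on z;
a Benjamini–Hochberg column over the final regions is emitted for
convenience and is explicitly post-hoc.

## Energies

**Data energy.** `d_z = |z(region)| − w_n·|z(neighbour)|`, where the
neighbour statistic pools the k-nt flanks on both sides (clipped at track
boundaries; empty flanks give z = 0).  Absolute values are used so both
directions of change count; pooling the two flanks is the default, a
per-side maximum is available (`neighbor_mode="max"`).  The map to energy
is a linear ramp: +1 for `d_z ≤ z_min`, then `−(min(d_z, z_max) −
z_min)/(z_max − z_min)`, saturating at −1.  The ramp is the simplest map
with the required endpoints (+1 below threshold, indistinguishable beyond
`z_max`, range [−1, 0] in between).

**Prior energy.** Pair penalty `t = clamp((k − L)/(k + min(γ_p, γ_q)), 0,
1)` on the signed gap `L` (negative = overlap), aggregated per point as the
maximum over neighbours closer than k.  The normalised-gap form hits the
stated boundary conditions exactly: 0 at distance k, 1 for identical
stacked regions.

Defaults: `γ_min = 5`, `γ_max = 2000`, `z_min = 4`, `z_max = 40`, `k = 25`,
`w = 1`, `w_n = 0.5` — region size and effect-size bounds in nucleotides
and standard-normal units respectively; `k` is both the flank width of the
contrast and the crowding radius of the prior.

## Optimisation

Multiple birth-and-death dynamics with annealing (`β0 = 1`, `δ0 = 2`,
β ×= 1.02 and δ ×= 0.999 per iteration).  Births happen only at candidate
starts whose anchor is free: a mark is drawn ∝ `1 − U_d` over the allowed
lengths, and the point is born with probability `min(1, δ·v·b)`,
`b = (1 − U_d)/2`.  The intensity `v` is set once from the data so the
expected number of first-iteration births is `ρ·|S|` (ρ = 1 by default).
Deaths sweep the configuration worst-data-energy-first with probability
`δa/(1 + δa)`, `a = exp(β(U_d + w·U_p))`, recomputing each point's prior
energy against the configuration as thinned by earlier deletions — the
death rate must reflect the current configuration.  Randomness comes from
a seeded Mersenne twister; runs are bit-reproducible.

Two additions to the bare loop, both motivated by measured failure modes:

- **Convergence patience.** The textbook stop — an iteration whose births
  were all undone and whose deaths were all undone — triggers spuriously
  during lulls of the churn phase, freezing visibly suboptimal
  configurations.  The run stops only after 10 consecutive unchanged
  iterations.
- **Restarts.** The schedule cools in roughly a hundred effective
  iterations, and a single chain can lock into a local minimum — typically
  one long region spanning what the energy prefers as two short ones,
  because a region that fully contains a shorter one cancels the short
  region's energy exactly (`−1 + w·1 = 0` at `w = 1`), leaving no
  temperature-robust escape.  Eight independent chains are run and the
  final configuration with the lowest total energy is kept.

Finally, surviving regions are passed through a greedy reporting filter
(best point energy first) that enforces disjointness and an optional
minimum reporting gap (`min_gap`, default 0: only true overlaps are
suppressed).  Frozen chains can retain a pair of overlapping near-ties;
the filter guarantees the output contract regardless.

## Candidate reduction

Searching every (anchor, length) pair is quadratic and — more importantly —
offers the optimiser pathological candidates (fragments of long regions,
spans across background).  Region edges are where expression changes
sharply, so candidates are restricted to detected edges:

1. **Denoise** each track with the lifting scheme (4 scales): split
   even/odd, predict odd by linear interpolation of flanking evens, update
   evens with a quarter of the adjacent details (mean-preserving).  The
   transform is exactly invertible; constant and interior-linear signals
   have zero details.
2. **Bivariate shrinkage.** Each detail coefficient is thresholded jointly
   with its coarser-scale parent: `s1 ← s1·max(0, r − √3·σ_n²/σ)/r`,
   `r = √(s1² + s2²)`.  The local signal level σ pools the child window
   and the parent band — a true edge has energy at both scales, an
   isolated noise burst does not.  The noise floor `σ_n²` is per
   coefficient: for counting data it is the local rate (zero-detail
   reconstruction of the pyramid, minimum-filtered so the *low* flank of an
   edge sets the floor there) times a per-level constant of the lifting
   filters (1.502, 1.334, 0.877, 0.504, 0.271, …, measured once on long
   simulated Poisson tracks and rate-invariant); where there is no counting
   signal, a windowed MAD estimate serves instead, and a windowed MAD of
   exactly zero (noiseless data) disables shrinkage.  Poisson noise is
   heteroskedastic, which is why a single global noise estimate — the
   textbook choice — either erases weak edges or passes high-rate noise.
3. **Cycle spinning.** The transform is not translation invariant; the
   denoised signal is averaged over 8 circular shifts, cancelling the
   step artefacts of individual surviving noise coefficients.
4. **Ramp snapping.** Denoising renders a step as a 2–4 nt monotone ramp,
   which a one-step edge criterion misses even though the level shift is
   intact.  Each position is reassigned to the nearer of its two flanking
   5-nt medians, collapsing short ramps to single steps and flattening
   plateau noise.
5. **Edges and marks.** Starts are one-step rises ≥ t (default 5), ends
   one-step falls ≥ t, unioned over the two conditions; allowed marks at a
   start s are `{e − s : e ∈ E}` within the length bounds.

On the default benchmark this recovers every true boundary within ±3 nt
with essentially no interior or background false edges, and cuts the
candidate count by over two orders of magnitude.  The reduction is
optional (`reduce=False` admits every position and length) but on data of
any size it is also what keeps the optimiser's search space free of the
pathological candidates above.

## Synthetic benchmarks

The generator draws independent Poisson counts per nucleotide: background
rate 2 counts/nt shared by both conditions, planted regions multiplying one
condition's rate by a fold change (a negative-binomial option adds
overdispersion, off by default).  Library totals model the window as part
of a library of 1e6 mapped reads.  What it deliberately does not emulate:
replicate variability, mappability structure, fragment-level
autocorrelation of the noise, or genome-scale context — passing these
benchmarks shows the method's internal consistency at realistic count
depths, not performance on any particular real assay.

- **Recovery scenario** (default): 10 kb, three 8-fold regions of lengths
  50, 200 and 1000 nt, spaced further apart than `γ_max` so each is an
  independent detection problem.  Nucleotide-level Jaccard against truth is
  ≥ 0.99 across seeds; the acceptance threshold is 0.8.
- **Proximity scenario**: pairs of equal regions at gaps 5, 25 and 100 nt
  with k = 25.  Region length 40 and fold 24 put each region's z at ≈ 44,
  just beyond `z_max`: with the data energy saturated, what is reported for
  a pair is decided by the overlap prior and the neighbour contrast — the
  forces this scenario measures — rather than by the longer candidate's
  extra statistical power.  (At sub-saturating folds a region spanning a
  pair always carries a larger |z| than either member, a direct consequence
  of the statistic's consistency, and the spanning region wins regardless
  of the optimiser; the demonstration lives in the saturated regime.)
  Pairs are spaced 2500 nt > `γ_max` apart so no candidate can bridge two
  pairs.  Result, stable across seeds: the gap-5 pair is reported as one
  region, the gap-25 (= k) and gap-100 pairs as two.
- **Null control**: identical tracks (same planted structure in both
  conditions) across ten seeds produce zero regions — every candidate has
  z = 0, so no birth ever fires.

## Numerical choices and degenerate inputs

- Pseudocount 0.5 in logs; p̂ clamped to `(1e-12, 1 − 1e-12)`; `exp`
  overflow in the death rate capped (rates saturate at 1).
- Ties in the death sweep (equal data energy) follow insertion order;
  the mark draw breaks ties by the random draw itself.
- Tracks shorter than `2^scales` reduce the number of wavelet scales with
  a warning; signals shorter than 2 are rejected.
- An empty candidate set (no edge exceeds t — e.g. identical or flat
  tracks) yields an empty result with a warning at the pipeline level and
  an exception (`EmptyMarkSpaceError`) at the library level.
- Overlapping input records, negative counts and empty files are errors;
  missing interior positions are zeros by definition of the model.

## Limitations

- One track per condition: no replicate variance, so the z-score measures
  sampling noise only; biological variability must be judged externally.
- The additive energy prefers packing many strong regions; on data whose
  true regions are long and internally structured, interior edges that
  survive smoothing can split a region into abutting fragments (coverage is
  retained; region count is not).
- The annealing schedule is fast by construction; the restart mechanism
  compensates but global optimality is not guaranteed.
- The statistic saturates quickly at deep libraries; `z_min`/`z_max` are
  effect-size dials the user should set to the contrast scale of interest,
  not significance thresholds.
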