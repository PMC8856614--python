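# Methods

This note documents the models, defaults and numerical conventions behind
each analysis stage, the design choices made where the procedure was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Innervation profiles

A profile is a binary vector over an ordered glomerulus map (55 canonical
antennal-lobe names by default; any unique ordered list is accepted).
Hemisphere labels use the observer-view convention throughout: a neuron
stored as "R" sits in the animal's anatomical left hemisphere. Profiles
with an innervated-glomerulus count outside the empirically typical 6–24
band load with a warning, not an error — the band is an observation about
real collections, not a schema rule.

Frequency classes partition [0, 1] as: `always` (exactly 1), `high`
(>0.95), `variable` (0.10–0.84 inclusive), `rare` (<0.10), and `other`
for the (0.84, 0.95] gap. The descriptive bins in the source study do not
tile the unit interval, so the gaps get explicit classes rather than
being silently absorbed into a neighbor; the three edges are configurable
and validated for ordering.

Clustering uses distance 1 − Pearson r between binary vectors with
complete linkage (SciPy's nearest-neighbor-chain agglomeration, which is
deterministic for a fixed distance matrix). Zero-variance vectors (all-0
or all-1) have undefined correlation and are assigned the maximal
distance 2.0 to every other vector, with a warning. Optional leaf-order
optimization minimizes the summed distance between adjacent leaves; it is
off by default because no downstream statistic depends on leaf order.
Both axes (neurons and glomeruli) can be clustered. Dendrograms export to
Newick with branch lengths equal to merge-height differences.

## Symmetry index and random pairing

The symmetry index of two profiles is the Jaccard similarity of their
innervated sets. Two empty sets raise an error rather than defaulting to
0 or 1: a labeled neuron always innervates something, so a 0/0 indicates
an upstream data bug.

Null cohorts re-match hemispheres across brains. With n left and m right
profiles (m < n < 2m required):

- R-based / L-random: m of the n lefts are drawn without replacement and
  matched one-to-one with the m rights → m pairs.
- L-based / R-random: n − m rights are resampled uniformly without
  replacement from the m rights and appended, then the n rights are
  randomly matched with the n lefts → n pairs.

Same-brain pairs are excluded by re-drawing the matching (bounded
retries) and then repairing residual collisions by targeted swaps, so
the stated pair counts are always achieved. The resampling rule for the
n − m extra rights is the simplest unbiased reading of the procedure
(uniform, without replacement). Group comparison uses Kruskal-Wallis
followed by pairwise Wilcoxon rank-sum tests (exact enumeration for
small, tie-free samples; normal approximation otherwise).

A subtlety verified by the test suite: because the null cohort reuses the
same profiles as the intra cohort, the two index samples are positively
dependent and the Kruskal-Wallis p-value under a true null is
conservative rather than exactly uniform; with groups drawn from
independent cohorts uniformity holds. The design never manufactures a
spurious intra/inter difference.

## Dimorphism screen

Per glomerulus, a 2×2 innervated/not table between two groups is tested
with Pearson chi-square. Eligibility uses the *pooled* two-group
frequency: only glomeruli strictly inside (0, 1) are testable (pooled
saturation gives a zero expected cell). Pooling, rather than per-group
screening, never divides by zero and reproduces the "tested family"
regime of real cohorts. Bonferroni m equals the number of glomeruli
actually tested. No continuity correction by default (a `yates` flag is
provided); the correction choice in the original analysis is not
recorded anywhere, and the uncorrected Pearson statistic is the common
base behavior. Undefined correlations between zero-variance glomerulus
columns are reported as NaN, never imputed — silent zeros would corrupt
any downstream clustering of the correlation matrix.

## Neurite density

For glomerulus x with voxel count v_x and total fluorescence T_x:

    background per voxel  b = T_DM5 / v_DM5
    adjusted total        T'_x = T_x − b · v_x
    density               d_x = T'_x / (T'_VA1d + T'_VA1v + T'_DA1) / v_x

DM5 serves as background reference because the neuron never innervates
it; VA1d, VA1v and DA1 normalize because they are consistently densely
innervated. Exact algebraic consequences, tested to machine precision:
the reference density is 0; Σ_trio d_i·v_i = 1; densities are invariant
to global intensity rescaling and to adding a spatially uniform offset.
Negative adjusted totals (regions dimmer than the reference) propagate
into densities unclamped — low-density values below zero faithfully
signal insufficient background subtraction rather than being floored.
Masks must be disjoint (the equations assume disjoint compartments);
volumes are indexed (z, y, x), 0-based.

Sparse slice annotations are completed by shape-based interpolation:
signed Euclidean distance fields of the bracketing annotated slices are
linearly interpolated and thresholded at zero. Annotated slices are
reproduced bit-exact; slices outside the annotated range stay empty. A
nearest-slice copy is not provided as a separate mode because constant
annotations already interpolate to constant stacks. Equivalence with any
particular GUI tool's interpolation is qualitative, not bit-exact.

## Feeding-event detection

Baseline drift is removed by subtracting a centered rolling median
(window default one minute of samples, 301 at 200 ms; odd, ≥3; edge
windows shrink). A rolling median tracks slow drift while ignoring
feeding bouts that are short relative to the window. The vendor's
baseline algorithm is not public; the rolling median is this package's
choice and the window is configurable.

A feeding event is a *maximal* run of ≥ `min_run` (5) consecutive
corrected samples ≥ `threshold` (25 AU). Runs are never split or merged:
a 2×min_run run is one event, and two runs separated by a single
sub-threshold sample are two events. Events are assigned to 1-hour bins
by their start sample (events are short relative to the bin width; the
convention is pinned for reproducibility) over a 24-hour duration,
zero-filling empty bins and dropping (with a warning) events past the
duration.

One stated invariant had to be weakened to what is mathematically true:
raising `min_run` never increases the event count, and raising the
threshold never increases the number of in-event *samples*, but the
event *count* is not globally monotone in the threshold — a long run can
split into two runs that each still pass `min_run`. For well-separated
rectangular bouts (the feeding-trace regime) count monotonicity holds
and is tested in that form.

Feeding counts are analysed with factorial ANOVA (2 or 3 factors, all
interactions, type-II sums of squares for unbalanced data). With
`hc_adjust`, F-tests use the HC3 heteroscedasticity-consistent
covariance and the sum-of-squares column is omitted (it is undefined
under the robust covariance). HC3 is the strictest of the common
small-sample HC estimators; the precise flavor used in the original
analysis framework is not recorded. Post hoc pairwise comparisons are
Welch t-tests on marginal factor levels, Bonferroni-corrected across all
comparisons in the report. Any empty cell of the full factorial is an
error naming the cell.

## Synthetic data

Generator defaults define the study conditions exercised by the tests:

- **Cohorts** — independent Bernoulli draws per glomerulus. The
  paper-like preset: 6 glomeruli at 1.0 (DA1, VA1d, VA1v, DA4m, DL3,
  DL4), 3 at 0.97 (D, DM6, DC3), 9 evenly spaced over [0.10, 0.84]
  (VL2a and DL1 among them), remainder 0. The preset is an
  approximation of the published frequency structure, deterministic so
  cohorts differ only through the seed; it is not a fit to any
  per-glomerulus table. Group overrides plant frequency differences
  (e.g. VL2a at 0.349 vs 0.093 for the dimorphism tests, the two
  printed sex-specific frequencies, at the real group sizes 2268/496).
- **Pairs** — the right profile copies each left entry with probability
  `pair_concordance`, else redraws from the marginal; both hemispheres
  share a brain id, and `n_left_only` extra brains carry only a left
  profile so the random-pairing size regime m < n < 2m is realizable.
  Profiles are independent across glomeruli; real profiles have
  correlation structure the generator does not emulate, so passing
  tests certify the statistics, not biological realism.
- **Volumes** — non-overlapping ellipsoids on a (21, 76, 76) grid,
  uniform background 20, per-glomerulus densities with DM5 at 0, optional
  Poisson or Gaussian noise. Real stacks have non-uniform background and
  partial-volume edges; the phantom tests the arithmetic, not
  segmentation robustness.
- **Traces** — baseline 100 AU, optional linear drift, rectangular
  bouts (default length 10 samples, amplitude 50 AU = 2× threshold),
  artifacts shorter than the minimum run, Gaussian noise. Rectangular
  bouts suffice because the detector is purely threshold/run-length
  based; capacitance waveform shape is not emulated. Scheduled items
  keep a minimum gap (50 samples) so bouts never merge.

All generators are bit-reproducible under a fixed seed and return truth
records (frequencies, densities, event schedules) sufficient to
recompute every downstream expectation.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use the real cohort sizes
where the analysis depends on them (2268/496 profiles for the dimorphism
screen; 3300 for the mean-count identity; 200 complete brains for the
symmetry signal) and 100 seeded replicates for rate estimates
(dimorphism flag rate, null p-value behavior, noisy event recovery);
ANOVA power uses 60 replicates of 40 flies per mating group. Feeding
traces in the replicated checks are 30 minutes long — recovery is a
per-event property, so trace length beyond the scheduled bouts adds
nothing. Every stochastic quantity derives from an explicit seed;
`scripts/acceptance.py` spawns all of its generator seeds from the
single `--seed` argument.

## Known limitations

- Binary profiles only; arbor geometry and synapse-level connectivity
  are out of scope, as are segmentation, registration and the manual
  image scoring that produces profiles in practice.
- The correlation-distance clustering follows SciPy's deterministic
  merge order; with exactly tied distances other tie-break conventions
  can produce different but equally valid dendrograms (cophenetic
  structure is unaffected and is what the tests pin).
- The chi-square screen at very large, very unbalanced n is sensitive to
  tiny frequency differences; the screen reports effect frequencies
  alongside p-values so callers can judge magnitude.
- The feeding-event threshold (25 AU) was calibrated in the original
  study against synchronized video; this package treats it as a given
  constant and provides no recalibration machinery.
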